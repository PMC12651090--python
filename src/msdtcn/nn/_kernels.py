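"""JIT-compiled hot loops (im2col convolution, depthwise convolution, GELU).

All kernels are single-threaded and numerically straightforward; they exist
to fuse the gather/scatter steps around the BLAS matmuls and to avoid the
large numpy temporaries a pure-ndarray formulation would allocate.
"""

from __future__ import annotations

import numba
import numpy as np

F32 = np.float32


@numba.njit(cache=True, fastmath=True)
def conv_fwd(xp, w2, kh, kw, s, d, ho, wo):
    """xp: padded (N, C, Hp, Wp); w2: (Co, C*kh*kw). Returns (N, Co, ho*wo)."""
    n, c = xp.shape[0], xp.shape[1]
    co = w2.shape[0]
    col = np.empty((c * kh * kw, ho * wo), dtype=F32)
    out = np.empty((n, co, ho * wo), dtype=F32)
    for ni in range(n):
        for ci in range(c):
            for ki in range(kh):
                for kj in range(kw):
                    row = (ci * kh + ki) * kw + kj
                    for i in range(ho):
                        src = xp[ni, ci, i * s + ki * d]
                        for j in range(wo):
                            col[row, i * wo + j] = src[j * s + kj * d]
        out[ni] = np.dot(w2, col)
    return out


@numba.njit(cache=True, fastmath=True)
def conv_bwd(xp, w2, g, kh, kw, s, d, ho, wo):
    """Returns (dW2, dXpadded) for the conv_fwd layout; g: (N, Co, ho*wo)."""
    n, c = xp.shape[0], xp.shape[1]
    co = w2.shape[0]
    col = np.empty((c * kh * kw, ho * wo), dtype=F32)
    gw2 = np.zeros((co, c * kh * kw), dtype=F32)
    dxp = np.zeros_like(xp)
    for ni in range(n):
        for ci in range(c):
            for ki in range(kh):
                for kj in range(kw):
                    row = (ci * kh + ki) * kw + kj
                    for i in range(ho):
                        src = xp[ni, ci, i * s + ki * d]
                        for j in range(wo):
                            col[row, i * wo + j] = src[j * s + kj * d]
        gn = np.ascontiguousarray(g[ni])
        gw2 += np.dot(gn, col.T)
        dcol = np.dot(w2.T, gn)
        for ci in range(c):
            for ki in range(kh):
                for kj in range(kw):
                    row = (ci * kh + ki) * kw + kj
                    for i in range(ho):
                        dst = dxp[ni, ci, i * s + ki * d]
                        for j in range(wo):
                            dst[j * s + kj * d] += dcol[row, i * wo + j]
    return gw2, dxp


@numba.njit(cache=True, fastmath=True)
def dwconv_fwd(xp, w, kh, kw, s, d, ho, wo):
    """Depthwise: xp (N, C, Hp, Wp), w (C, kh, kw) -> (N, C, ho, wo)."""
    n, c = xp.shape[0], xp.shape[1]
    out = np.zeros((n, c, ho, wo), dtype=F32)
    for ni in range(n):
        for ci in range(c):
            for ki in range(kh):
                for kj in range(kw):
                    wv = w[ci, ki, kj]
                    for i in range(ho):
                        src = xp[ni, ci, i * s + ki * d]
                        dst = out[ni, ci, i]
                        for j in range(wo):
                            dst[j] += wv * src[j * s + kj * d]
    return out


@numba.njit(cache=True, fastmath=True)
def dwconv_bwd(xp, w, g, kh, kw, s, d, ho, wo):
    n, c = xp.shape[0], xp.shape[1]
    gw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    for ni in range(n):
        for ci in range(c):
            for ki in range(kh):
                for kj in range(kw):
                    wv = w[ci, ki, kj]
                    acc = F32(0.0)
                    for i in range(ho):
                        src = xp[ni, ci, i * s + ki * d]
                        dsrc = dxp[ni, ci, i * s + ki * d]
                        gn = g[ni, ci, i]
                        for j in range(wo):
                            acc += gn[j] * src[j * s + kj * d]
                            dsrc[j * s + kj * d] += wv * gn[j]
                    gw[ci, ki, kj] += acc
    return gw, dxp


_C0 = F32(0.7978845608028654)  # sqrt(2/pi)
_C1 = F32(0.044715)


@numba.njit(cache=True, fastmath=True)
def gelu_fwd(x):
    out = np.empty_like(x)
    t = np.empty_like(x)
    xf = x.reshape(-1)
    of = out.reshape(-1)
    tf = t.reshape(-1)
    for i in range(xf.size):
        v = xf[i]
        th = np.tanh(_C0 * (v + _C1 * v * v * v))
        tf[i] = th
        of[i] = F32(0.5) * v * (F32(1.0) + th)
    return out, t


@numba.njit(cache=True, fastmath=True)
def gelu_bwd(x, t, g):
    dx = np.empty_like(x)
    xf, tf, gf, df = x.reshape(-1), t.reshape(-1), g.reshape(-1), dx.reshape(-1)
    for i in range(xf.size):
        v = xf[i]
        th = tf[i]
        d_inner = _C0 * (F32(1.0) + F32(3.0) * _C1 * v * v)
        df[i] = gf[i] * (F32(0.5) * (F32(1.0) + th)
                         + F32(0.5) * v * (F32(1.0) - th * th) * d_inner)
    return dx
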