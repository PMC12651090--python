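"""Structured neural-network primitives (convolutions, norms, pooling).

Dense spatial convolutions gather a per-sample im2col buffer and run one
BLAS sgemm per sample (the gather/scatter loops are JIT-compiled); pointwise
1x1 convolutions go straight to batched matmul.  Backward passes re-derive
the padded/gathered inputs from the still-live parent activations instead of
caching them, keeping peak training memory near one copy of the activations.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, _make, astensor

__all__ = [
    "linear", "conv2d", "conv_transpose2d", "max_pool2d",
    "global_avg_pool", "layer_norm", "batch_norm2d", "bilinear_resize",
]


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """x: (..., Cin) @ weight (Cout, Cin)^T + bias."""
    xd, wd = x.data, weight.data
    out = xd @ wd.T

    def bw(g):
        x._accumulate(g @ wd)
        gw = np.tensordot(g.reshape(-1, g.shape[-1]), xd.reshape(-1, xd.shape[-1]),
                          axes=(0, 0))
        weight._accumulate(gw)
        if bias is not None:
            bias._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))

    parents = (x, weight) if bias is None else (x, weight, bias)
    if bias is not None:
        out = out + bias.data
    return _make(out, parents, bw)


def _conv_out_size(h: int, k: int, s: int, p: int, d: int) -> int:
    return (h + 2 * p - d * (k - 1) - 1) // s + 1


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, padding=0, dilation: int = 1,
           groups: int = 1) -> Tensor:
    """2-D cross-correlation on (N, C, H, W).

    ``weight`` is (Cout, Cin/groups, kH, kW); ``padding`` is an int or an
    (pH, pW) pair.  Only ``groups == 1`` (dense) and ``groups == Cin`` with
    ``Cout == Cin`` (depthwise) are supported, which covers every block in
    the network.  Dense spatial kernels run through a JIT-fused im2col +
    sgemm; 1x1 kernels skip the gather entirely.
    """
    from . import _kernels as K

    n, c, h, w = x.shape
    co, cig, kh, kw = weight.shape
    s, d = stride, dilation
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    ho = (h + 2 * ph - d * (kh - 1) - 1) // s + 1
    wo = (w + 2 * pw - d * (kw - 1) - 1) // s + 1
    depthwise = groups != 1
    if depthwise and (groups != c or co != c or cig != 1):
        raise ValueError("only dense or depthwise convolutions are supported")
    if d * (kh - 1) + 1 > h + 2 * ph or d * (kw - 1) + 1 > w + 2 * pw:
        raise ValueError("kernel larger than the (padded) input")
    wd = weight.data

    def padded(arr):
        if ph or pw:
            return np.pad(arr, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        return arr

    if depthwise:
        xp = padded(x.data)
        out = K.dwconv_fwd(xp, wd[:, 0], kh, kw, s, d, ho, wo)
        if bias is not None:
            out += bias.data[None, :, None, None]

        def bw_dw(g):
            gw, dxp = K.dwconv_bwd(padded(x.data), wd[:, 0],
                                   np.ascontiguousarray(g), kh, kw, s, d,
                                   ho, wo)
            if ph or pw:
                dxp = dxp[:, :, ph: ph + h, pw: pw + w]
            x._accumulate(dxp)
            weight._accumulate(gw.reshape(wd.shape))
            if bias is not None:
                bias._accumulate(g.sum(axis=(0, 2, 3)))

        parents = (x, weight) if bias is None else (x, weight, bias)
        return _make(out, parents, bw_dw)

    w2 = wd.reshape(co, c * kh * kw)

    if kh == kw == 1 and ph == pw == 0:
        xs = x.data[:, :, ::s, ::s] if s > 1 else x.data
        x3 = np.ascontiguousarray(xs.reshape(n, c, ho * wo))
        out = np.matmul(w2, x3).reshape(n, co, ho, wo)
        if bias is not None:
            out += bias.data[None, :, None, None]

        def bw_pw(g):
            g3 = g.reshape(n, co, -1)
            xs_b = x.data[:, :, ::s, ::s] if s > 1 else x.data
            x3_b = np.ascontiguousarray(xs_b.reshape(n, c, -1))
            weight._accumulate(np.tensordot(g3, x3_b,
                                            axes=([0, 2], [0, 2])
                                            ).reshape(wd.shape))
            dxs = np.matmul(w2.T, g3).reshape(n, c, ho, wo)
            if s > 1:
                dx = np.zeros_like(x.data)
                dx[:, :, ::s, ::s] = dxs
            else:
                dx = dxs
            x._accumulate(dx)
            if bias is not None:
                bias._accumulate(g.sum(axis=(0, 2, 3)))

        parents = (x, weight) if bias is None else (x, weight, bias)
        return _make(out, parents, bw_pw)

    xp = padded(x.data)
    out = K.conv_fwd(xp, w2, kh, kw, s, d, ho, wo).reshape(n, co, ho, wo)
    if bias is not None:
        out += bias.data[None, :, None, None]

    def bw(g):
        # re-pad rather than cache: x's buffer stays live as a graph parent
        gw2, dxp = K.conv_bwd(padded(x.data), w2, g.reshape(n, co, -1),
                              kh, kw, s, d, ho, wo)
        if ph or pw:
            dxp = dxp[:, :, ph: ph + h, pw: pw + w]
        x._accumulate(dxp)
        weight._accumulate(gw2.reshape(wd.shape))
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out, parents, bw)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
                     stride: int = 2, padding: int = 1) -> Tensor:
    """Transposed convolution; ``weight`` is (Cin, Cout, kH, kW)."""
    n, c, h, w = x.shape
    ci, co, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, weight {ci}")
    s, p = stride, padding
    hf, wf = (h - 1) * s + kh, (w - 1) * s + kw
    wd = weight.data
    xflat = x.data.reshape(n, c, -1)
    yfull = np.zeros((n, co, hf, wf), dtype=np.float32)
    for ki in range(kh):
        for kj in range(kw):
            contrib = np.matmul(wd[:, :, ki, kj].T, xflat).reshape(n, co, h, w)
            yfull[:, :, ki: ki + (h - 1) * s + 1: s,
                        kj: kj + (w - 1) * s + 1: s] += contrib
    out = yfull[:, :, p: hf - p, p: wf - p] if p else yfull
    out = np.ascontiguousarray(out)
    if bias is not None:
        out += bias.data[None, :, None, None]

    def bw(g):
        gfull = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p))) if p else g
        dx = np.zeros((n, c, h * w), dtype=np.float32)
        gw = np.zeros_like(wd)
        for ki in range(kh):
            for kj in range(kw):
                gs = gfull[:, :, ki: ki + (h - 1) * s + 1: s,
                                 kj: kj + (w - 1) * s + 1: s].reshape(n, co, -1)
                dx += np.matmul(wd[:, :, ki, kj], gs)
                gw[:, :, ki, kj] = np.tensordot(xflat, gs, axes=([0, 2], [0, 2]))
        x._accumulate(dx.reshape(n, c, h, w))
        weight._accumulate(gw)
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out, parents, bw)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2,
               padding: int = 1) -> Tensor:
    n, c, h, w = x.shape
    s, p, k = stride, padding, kernel
    ho, wo = _conv_out_size(h, k, s, p, 1), _conv_out_size(w, k, s, p, 1)
    xp = np.full((n, c, h + 2 * p, w + 2 * p), -np.inf, dtype=np.float32)
    xp[:, :, p: p + h, p: p + w] = x.data
    stack = np.empty((k * k, n, c, ho, wo), dtype=np.float32)
    for ki in range(k):
        for kj in range(k):
            stack[ki * k + kj] = xp[:, :, ki: ki + (ho - 1) * s + 1: s,
                                          kj: kj + (wo - 1) * s + 1: s]
    arg = stack.argmax(axis=0).astype(np.int8)
    out = np.take_along_axis(stack, arg[None].astype(np.intp), axis=0)[0]

    def bw(g):
        dxp = np.zeros_like(xp)
        for o in range(k * k):
            m = arg == o
            if not m.any():
                continue
            ki, kj = divmod(o, k)
            dxp[:, :, ki: ki + (ho - 1) * s + 1: s,
                      kj: kj + (wo - 1) * s + 1: s] += g * m
        x._accumulate(dxp[:, :, p: p + h, p: p + w])

    return _make(out, (x,), bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    n, c, h, w = x.shape

    def bw(g):
        x._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w),
                                      x.shape).astype(np.float32))

    return _make(x.data.mean(axis=(2, 3)), (x,), bw)


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, *, axis: int = -1,
               eps: float = 1e-6) -> Tensor:
    """Normalize over a single axis with affine parameters of that length."""
    ax = axis % x.ndim
    xd = x.data
    mu = xd.mean(axis=ax, keepdims=True)
    xc = xd - mu
    var = (xc * xc).mean(axis=ax, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xn = xc * inv
    shape = [1] * x.ndim
    shape[ax] = x.shape[ax]
    wb = weight.data.reshape(shape)
    out = xn * wb + bias.data.reshape(shape)
    m = x.shape[ax]

    def bw(g):
        xn_b = (x.data - mu) * inv  # recomputed; only mu/inv are cached
        red = tuple(i for i in range(x.ndim) if i != ax)
        weight._accumulate((g * xn_b).sum(axis=red))
        bias._accumulate(g.sum(axis=red))
        gh = g * wb
        dx = inv / m * (m * gh - gh.sum(axis=ax, keepdims=True)
                        - xn_b * (gh * xn_b).sum(axis=ax, keepdims=True))
        x._accumulate(dx.astype(np.float32))

    return _make(out, (x, weight, bias), bw)


def batch_norm2d(x: Tensor, weight: Tensor, bias: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray, *,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """BatchNorm over (N, H, W) per channel; updates running stats in place."""
    xd = x.data
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xn = (xd - mu[None, :, None, None]) * inv[None, :, None, None]
    out = xn * weight.data[None, :, None, None] + bias.data[None, :, None, None]
    n_elem = xd.shape[0] * xd.shape[2] * xd.shape[3]

    def bw(g):
        xn_b = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
        weight._accumulate((g * xn_b).sum(axis=(0, 2, 3)))
        bias._accumulate(g.sum(axis=(0, 2, 3)))
        gw = g * weight.data[None, :, None, None]
        if training:
            gsum = gw.sum(axis=(0, 2, 3), keepdims=True)
            gxn = (gw * xn_b).sum(axis=(0, 2, 3), keepdims=True)
            dx = inv[None, :, None, None] * (gw - gsum / n_elem
                                             - xn_b * gxn / n_elem)
        else:
            dx = gw * inv[None, :, None, None]
        x._accumulate(dx.astype(np.float32))

    return _make(out, (x, weight, bias), bw)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (align_corners=False)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        m[i, lo_c] += 1.0 - frac
        m[i, hi_c] += frac
    return m


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Differentiable separable bilinear resize of (N, C, H, W)."""
    n, c, h, w = x.shape
    a = Tensor(_interp_matrix(out_h, h))        # (Ho, H)
    b = Tensor(_interp_matrix(out_w, w).T)      # (W, Wo)
    t = astensor(x).reshape(n * c, h, w)
    t = a @ t                                   # (NC, Ho, W) via broadcasting
    t = t @ b                                   # (NC, Ho, Wo)
    return t.reshape(n, c, out_h, out_w)
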