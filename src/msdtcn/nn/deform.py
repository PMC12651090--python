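"""Multi-scale deformable sampling core.

Each query predicts, per attention head, a handful of fractional sampling
locations on every pyramid level; values are bilinearly interpolated there
(zero outside the feature map) and combined with softmax weights.  The hot
loops are JIT-compiled with numba; the autograd wrapper exposes gradients
with respect to values, sampling locations and attention weights.
"""

from __future__ import annotations

import numba
import numpy as np

from .tensor import Tensor, _make

__all__ = ["ms_deform_sample", "ms_deform_sample_reference"]


@numba.njit(cache=True, fastmath=True)
def _ms_deform_fwd(value, shapes, starts, loc, attn, out):
    n, q, m, l, p, _ = loc.shape
    d = value.shape[3]
    for bi in range(n):
        for qi in range(q):
            for mi in range(m):
                acc = out[bi, qi, mi]
                for li in range(l):
                    h, w = shapes[li, 0], shapes[li, 1]
                    base = starts[li]
                    for pi in range(p):
                        a = attn[bi, qi, mi, li, pi]
                        x = loc[bi, qi, mi, li, pi, 0] * w - 0.5
                        y = loc[bi, qi, mi, li, pi, 1] * h - 0.5
                        x0 = int(np.floor(x))
                        y0 = int(np.floor(y))
                        fx = x - x0
                        fy = y - y0
                        for dy in range(2):
                            yy = y0 + dy
                            if yy < 0 or yy >= h:
                                continue
                            wy = fy if dy == 1 else 1.0 - fy
                            for dx in range(2):
                                xx = x0 + dx
                                if xx < 0 or xx >= w:
                                    continue
                                wx = fx if dx == 1 else 1.0 - fx
                                wgt = a * wy * wx
                                src = value[bi, base + yy * w + xx, mi]
                                for di in range(d):
                                    acc[di] += wgt * src[di]


@numba.njit(cache=True, fastmath=True)
def _ms_deform_bwd(value, shapes, starts, loc, attn, gout,
                   dvalue, dloc, dattn):
    n, q, m, l, p, _ = loc.shape
    d = value.shape[3]
    for bi in range(n):
        for qi in range(q):
            for mi in range(m):
                g = gout[bi, qi, mi]
                for li in range(l):
                    h, w = shapes[li, 0], shapes[li, 1]
                    base = starts[li]
                    for pi in range(p):
                        a = attn[bi, qi, mi, li, pi]
                        x = loc[bi, qi, mi, li, pi, 0] * w - 0.5
                        y = loc[bi, qi, mi, li, pi, 1] * h - 0.5
                        x0 = int(np.floor(x))
                        y0 = int(np.floor(y))
                        fx = x - x0
                        fy = y - y0
                        sampled = 0.0
                        dsx = 0.0
                        dsy = 0.0
                        for dy in range(2):
                            yy = y0 + dy
                            if yy < 0 or yy >= h:
                                continue
                            wy = fy if dy == 1 else 1.0 - fy
                            sy = 1.0 if dy == 1 else -1.0
                            for dx in range(2):
                                xx = x0 + dx
                                if xx < 0 or xx >= w:
                                    continue
                                wx = fx if dx == 1 else 1.0 - fx
                                sx = 1.0 if dx == 1 else -1.0
                                src = value[bi, base + yy * w + xx, mi]
                                dst = dvalue[bi, base + yy * w + xx, mi]
                                gdot = 0.0
                                for di in range(d):
                                    gd = g[di]
                                    gdot += gd * src[di]
                                    dst[di] += a * wy * wx * gd
                                sampled += wy * wx * gdot
                                dsx += sx * wy * gdot
                                dsy += sy * wx * gdot
                        dattn[bi, qi, mi, li, pi] = sampled
                        dloc[bi, qi, mi, li, pi, 0] = a * dsx * w
                        dloc[bi, qi, mi, li, pi, 1] = a * dsy * h


def ms_deform_sample(value: Tensor, loc: Tensor, attn: Tensor,
                     shapes: np.ndarray, starts: np.ndarray) -> Tensor:
    """Differentiable multi-scale deformable sampling.

    Parameters
    ----------
    value : (N, S, M, D) per-head values for all S tokens over all levels.
    loc : (N, Q, M, L, P, 2) sampling locations, normalized to [0, 1]^2,
        ``loc[..., 0]`` horizontal (width axis), ``loc[..., 1]`` vertical.
    attn : (N, Q, M, L, P) attention weights.
    shapes : (L, 2) int array of per-level (H, W).
    starts : (L,) int array of per-level token offsets into S.

    Returns
    -------
    (N, Q, M, D) tensor.
    """
    shapes = np.ascontiguousarray(shapes, dtype=np.int64)
    starts = np.ascontiguousarray(starts, dtype=np.int64)
    vd = np.ascontiguousarray(value.data)
    ld = np.ascontiguousarray(loc.data)
    ad = np.ascontiguousarray(attn.data)
    n, q, m = ld.shape[0], ld.shape[1], ld.shape[2]
    out = np.zeros((n, q, m, vd.shape[3]), dtype=np.float32)
    _ms_deform_fwd(vd, shapes, starts, ld, ad, out)

    def bw(g):
        dvalue = np.zeros_like(vd)
        dloc = np.zeros_like(ld)
        dattn = np.zeros_like(ad)
        _ms_deform_bwd(vd, shapes, starts, ld, ad,
                       np.ascontiguousarray(g), dvalue, dloc, dattn)
        value._accumulate(dvalue)
        loc._accumulate(dloc)
        attn._accumulate(dattn)

    return _make(out, (value, loc, attn), bw)


def ms_deform_sample_reference(value: np.ndarray, loc: np.ndarray,
                               attn: np.ndarray, shapes, starts) -> np.ndarray:
    """Plain-python nested-loop oracle for the sampling operation.

    Independent of the JIT kernel: per (batch, query, head, level, point) it
    looks the four neighbouring texels up directly and blends them, skipping
    out-of-bounds corners (zero padding).  Intended for small instances only.
    """
    n, q, m, l, p, _ = loc.shape
    d = value.shape[3]
    out = np.zeros((n, q, m, d), dtype=np.float64)
    for bi in range(n):
        for qi in range(q):
            for mi in range(m):
                for li in range(l):
                    h, w = int(shapes[li][0]), int(shapes[li][1])
                    base = int(starts[li])
                    for pi in range(p):
                        a = float(attn[bi, qi, mi, li, pi])
                        x = float(loc[bi, qi, mi, li, pi, 0]) * w - 0.5
                        y = float(loc[bi, qi, mi, li, pi, 1]) * h - 0.5
                        x0, y0 = int(np.floor(x)), int(np.floor(y))
                        fx, fy = x - x0, y - y0
                        for dy, wy in ((0, 1 - fy), (1, fy)):
                            yy = y0 + dy
                            if not (0 <= yy < h):
                                continue
                            for dx, wx in ((0, 1 - fx), (1, fx)):
                                xx = x0 + dx
                                if not (0 <= xx < w):
                                    continue
                                out[bi, qi, mi] += (
                                    a * wy * wx
                                    * value[bi, base + yy * w + xx, mi])
    return out.astype(np.float32)
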