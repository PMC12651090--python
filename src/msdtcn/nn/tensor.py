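"""Minimal reverse-mode automatic differentiation on float32 numpy arrays.

A :class:`Tensor` wraps an ``np.ndarray`` and records the operations that
produced it.  Calling :meth:`Tensor.backward` on a scalar result walks the
recorded graph in reverse topological order and accumulates gradients into
every leaf tensor created with ``requires_grad=True``.  Closures and cached
activations are released as soon as a node's backward step has run, so peak
memory during training stays close to one live copy of the activations.

Only what the segmentation network needs is implemented; dense linear algebra
goes through BLAS via ``np.matmul``.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (evaluation / inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ utils
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None,
                 free_memory: bool = False) -> None:
        """Backpropagate through the recorded graph.

        With ``free_memory=True`` the ``data`` of interior nodes is dropped
        as soon as their backward step has run (training loops read outputs
        before calling backward); leaves and this root keep their data.
        """
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and (p._parents or p.requires_grad):
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free graph bookkeeping; keep gradients only on leaves
            had_parents = bool(node._parents)
            node._backward = None
            node._parents = ()
            if not node.requires_grad:
                node.grad = None
                if free_memory and had_parents and node is not self:
                    node.data = None  # type: ignore[assignment]

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[np.ndarray], None] | None) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = False
        out._parents = tuple(parents)
        out._backward = backward
    return out


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ------------------------------------------------------------------ arithmetic
def add(a: Tensor, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def bw(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), bw)


def sub(a: Tensor, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def bw(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(-g, b.shape))

    return _make(a.data - b.data, (a, b), bw)


def mul(a: Tensor, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    ad, bd = a.data, b.data

    def bw(g):
        a._accumulate(_unbroadcast(g * bd, a.shape))
        b._accumulate(_unbroadcast(g * ad, b.shape))

    return _make(ad * bd, (a, b), bw)


def div(a: Tensor, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    ad, bd = a.data, b.data

    def bw(g):
        a._accumulate(_unbroadcast(g / bd, a.shape))
        b._accumulate(_unbroadcast(-g * ad / (bd * bd), b.shape))

    return _make(ad / bd, (a, b), bw)


def neg(a: Tensor) -> Tensor:
    def bw(g):
        a._accumulate(-g)

    return _make(-a.data, (a,), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    ad, bd = a.data, b.data

    def bw(g):
        if ad.ndim == 1 or bd.ndim == 1:
            raise NotImplementedError("1-D matmul backward not needed")
        ga = np.matmul(g, np.swapaxes(bd, -1, -2))
        gb = np.matmul(np.swapaxes(ad, -1, -2), g)
        a._accumulate(_unbroadcast(ga, a.shape))
        b._accumulate(_unbroadcast(gb, b.shape))

    return _make(np.matmul(ad, bd), (a, b), bw)


def pow_(a: Tensor, exponent: float) -> Tensor:
    ad = a.data

    def bw(g):
        a._accumulate(g * exponent * ad ** (exponent - 1))

    return _make(ad ** exponent, (a,), bw)


# --------------------------------------------------------------- shape ops
def reshape(a: Tensor, shape) -> Tensor:
    old = a.shape

    def bw(g):
        a._accumulate(g.reshape(old))

    return _make(a.data.reshape(shape), (a,), bw)


def transpose(a: Tensor, axes: Sequence[int]) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))

    def bw(g):
        a._accumulate(np.ascontiguousarray(g.transpose(inv)))

    return _make(np.ascontiguousarray(a.data.transpose(axes)), (a,), bw)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tensors, bw)


def getitem(a: Tensor, idx) -> Tensor:
    def bw(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        a._accumulate(ga)

    return _make(a.data[idx], (a,), bw)


def pad2d(a: Tensor, pad: int) -> Tensor:
    """Zero-pad the two trailing spatial axes of an (N, C, H, W) tensor."""
    if pad == 0:
        return a

    def bw(g):
        a._accumulate(g[..., pad:-pad, pad:-pad])

    p = ((0, 0),) * (a.ndim - 2) + ((pad, pad), (pad, pad))
    return _make(np.pad(a.data, p), (a,), bw)


# ------------------------------------------------------------- reductions
def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    shape = a.shape

    def bw(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, shape).astype(np.float32))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, shape).astype(np.float32))

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.size
    else:
        ax = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[i] for i in ax]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


# ----------------------------------------------------------- nonlinearities
def relu(a: Tensor) -> Tensor:
    out = np.maximum(a.data, 0.0)

    def bw(g):
        a._accumulate(g * (out > 0))

    return _make(out, (a,), bw)


_SQRT_2_OVER_PI = np.float32(np.sqrt(2.0 / np.pi))


def gelu(a: Tensor) -> Tensor:
    """GELU, tanh approximation (matches the widely used fast variant)."""
    from . import _kernels as K
    x = np.ascontiguousarray(a.data)
    out, t = K.gelu_fwd(x)

    def bw(g):
        a._accumulate(K.gelu_bwd(x, t, np.ascontiguousarray(g)))

    return _make(out, (a,), bw)


def sigmoid(a: Tensor) -> Tensor:
    from scipy.special import expit  # numerically stable logistic
    s = expit(a.data)

    def bw(g):
        a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), bw)


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)

    def bw(g):
        a._accumulate(g * (1.0 - t * t))

    return _make(t, (a,), bw)


def exp(a: Tensor) -> Tensor:
    e = np.exp(a.data)

    def bw(g):
        a._accumulate(g * e)

    return _make(e, (a,), bw)


def log(a: Tensor) -> Tensor:
    ad = a.data

    def bw(g):
        a._accumulate(g / ad)

    return _make(np.log(ad), (a,), bw)


def sqrt(a: Tensor) -> Tensor:
    s = np.sqrt(a.data)

    def bw(g):
        a._accumulate(g * 0.5 / s)

    return _make(s, (a,), bw)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp; gradient passes only through the un-clamped region."""
    ad = a.data
    mask = (ad > lo) & (ad < hi)

    def bw(g):
        a._accumulate(g * mask)

    return _make(np.clip(ad, lo, hi), (a,), bw)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    x = a.data
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        a._accumulate(s * (g - dot))

    return _make(s, (a,), bw)


def dropout(a: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    if p <= 0.0:
        return a
    keep = (rng.random(a.shape) >= p).astype(np.float32) / np.float32(1.0 - p)

    def bw(g):
        a._accumulate(g * keep)

    return _make(a.data * keep, (a,), bw)


# Operator sugar -------------------------------------------------------------
Tensor.__add__ = lambda self, other: add(self, other)
Tensor.__radd__ = lambda self, other: add(self, other)
Tensor.__sub__ = lambda self, other: sub(self, other)
Tensor.__rsub__ = lambda self, other: sub(astensor(other), self)
Tensor.__mul__ = lambda self, other: mul(self, other)
Tensor.__rmul__ = lambda self, other: mul(self, other)
Tensor.__truediv__ = lambda self, other: div(self, astensor(other))
Tensor.__rtruediv__ = lambda self, other: div(astensor(other), self)
Tensor.__neg__ = lambda self: neg(self)
Tensor.__matmul__ = lambda self, other: matmul(self, other)
Tensor.__pow__ = lambda self, e: pow_(self, e)
Tensor.__getitem__ = lambda self, idx: getitem(self, idx)
Tensor.reshape = lambda self, *shape: reshape(
    self, shape[0] if len(shape) == 1 and isinstance(shape[0], (tuple, list)) else shape)
Tensor.transpose = lambda self, *axes: transpose(
    self, axes[0] if len(axes) == 1 and isinstance(axes[0], (tuple, list)) else axes)
Tensor.sum = lambda self, axis=None, keepdims=False: sum_(self, axis, keepdims)
Tensor.mean = lambda self, axis=None, keepdims=False: mean(self, axis, keepdims)
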