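"""Layer/module system on top of the autograd tensor.

Modules hold parameters (``Tensor`` with ``requires_grad=True``) and
non-trainable buffers (plain numpy arrays, e.g. BatchNorm running stats),
discoverable recursively through attribute traversal.  Weight initialization
is driven by an explicit ``np.random.Generator`` so that model construction
is fully reproducible from a seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor, dropout as _dropout, gelu, relu

__all__ = [
    "Module", "ModuleList", "Sequential", "Identity", "Linear", "Conv2d",
    "ConvTranspose2d", "LayerNorm", "BatchNorm2d", "ReLU", "GELU", "Dropout",
]


class Module:
    def __init__(self):
        self.training = True

    # -------------------------------------------------------------- traversal
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # ------------------------------------------------------------------ state
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buf:" + name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buf:"):
                buf = buffers[key[4:]]
                buf[...] = value
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                p.data[...] = np.asarray(value, dtype=np.float32)

    # ------------------------------------------------------------------- mode
    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._items = list(modules)

    def append(self, m: Module) -> None:
        self._items.append(m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class Sequential(ModuleList):
    def forward(self, x):
        for m in self._items:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return relu(x)


class GELU(Module):
    def forward(self, x):
        return gelu(x)


class Dropout(Module):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x):
        if not self.training or self.p <= 0.0:
            return x
        return _dropout(x, self.p, self.rng)


# ------------------------------------------------------------------ layers
def _kaiming(rng, shape, fan_in):
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


def _xavier_uniform(rng, shape, fan_in, fan_out):
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


def _trunc_normal(rng, shape, std=0.02):
    vals = rng.standard_normal(shape) * std
    return np.clip(vals, -2 * std, 2 * std).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True,
                 init: str = "xavier"):
        super().__init__()
        if init == "xavier":
            w = _xavier_uniform(rng, (out_features, in_features),
                                in_features, out_features)
        elif init == "trunc_normal":
            w = _trunc_normal(rng, (out_features, in_features))
        elif init == "zero":
            w = np.zeros((out_features, in_features), dtype=np.float32)
        else:
            w = _kaiming(rng, (out_features, in_features), in_features)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 rng: np.random.Generator, stride: int = 1, padding=0,
                 dilation: int = 1, groups: int = 1, bias: bool = True,
                 init: str = "kaiming"):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) \
            else kernel_size
        fan_in = (in_channels // groups) * kh * kw
        shape = (out_channels, in_channels // groups, kh, kw)
        if init == "trunc_normal":
            w = _trunc_normal(rng, shape)
        else:
            w = _kaiming(rng, shape, fan_in)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32),
                           requires_grad=True) if bias else None
        self.stride, self.dilation, self.groups = stride, dilation, groups
        self.padding = padding

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation,
                        groups=self.groups)


class ConvTranspose2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 2, padding: int = 1,
                 bias: bool = True):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size // (stride * stride)
        w = _kaiming(rng, (in_channels, out_channels, kernel_size, kernel_size),
                     max(fan_in, 1))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32),
                           requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias,
                                  stride=self.stride, padding=self.padding)


class LayerNorm(Module):
    """LayerNorm over one axis (tokens: last axis; maps: channel axis)."""

    def __init__(self, num_features: int, axis: int = -1, eps: float = 1e-6):
        super().__init__()
        self.weight = Tensor(np.ones(num_features, dtype=np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, dtype=np.float32),
                           requires_grad=True)
        self.axis, self.eps = axis, eps

    def forward(self, x):
        return F.layer_norm(x, self.weight, self.bias, axis=self.axis,
                            eps=self.eps)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.weight = Tensor(np.ones(num_features, dtype=np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, dtype=np.float32),
                           requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self.eps, self.momentum = eps, momentum

    def forward(self, x):
        return F.batch_norm2d(x, self.weight, self.bias, self.running_mean,
                              self.running_var, training=self.training,
                              momentum=self.momentum, eps=self.eps)
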