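"""Feature-fusion blocks: squeeze-and-excitation gating and the
multi-scale receptive-field (MSRF) module.

``SEFusion`` concatenates the CNN-branch and transformer-branch maps of one
level along channels, gates the concatenation with channel attention
(global average pool -> bottleneck MLP -> sigmoid), and maps it back to the
level width with a 1x1 convolution.

``MSRF`` runs three parallel branches over an input map — a 1x1 baseline; a
medium branch (1x1, then 1x3 and 3x1, then 3x3 dilated by 3); and a large
branch (1x1, then 1x5 and 5x1, then 5x5 dilated by 3) — concatenates them,
fuses with a 3x3 convolution and adds the input back.  Every branch keeps
the input width, so the residual add is well-typed at any size.  Effective
receptive fields of the medium/large convolution chains are 9x9 and 17x17.
"""

from __future__ import annotations

import numpy as np

from .nn import BatchNorm2d, Conv2d, Linear, Module, Sequential
from .nn import functional as F
from .nn.tensor import Tensor, concat, relu, sigmoid


class SEGate(Module):
    """Channel-attention weights z = sigmoid(FC2(ReLU(FC1(GAP(x)))))."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 16):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def forward(self, x) -> Tensor:
        z = F.global_avg_pool(x)
        return sigmoid(self.fc2(relu(self.fc1(z))))


class SEFusion(Module):
    """SE-gated fusion of a CNN map with its transformer-branch partner."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 16):
        super().__init__()
        self.gate = SEGate(2 * channels, rng, reduction)
        self.proj = Conv2d(2 * channels, channels, 1, rng)

    def forward(self, c, t) -> Tensor:
        if c.shape[-2:] != t.shape[-2:]:
            raise ValueError("fused maps must share spatial size")
        cat = concat([c, t], axis=1)
        z = self.gate(cat)
        n, ch = z.shape
        gated = cat * z.reshape(n, ch, 1, 1)
        return self.proj(gated)


class _ConvBNReLU(Module):
    def __init__(self, cin, cout, kernel, rng, padding=0, dilation=1):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, rng, padding=padding,
                           dilation=dilation, bias=False)
        self.bn = BatchNorm2d(cout)

    def forward(self, x):
        return relu(self.bn(self.conv(x)))


class MSRF(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        c = channels
        self.base = _ConvBNReLU(c, c, 1, rng)
        self.medium = Sequential([
            _ConvBNReLU(c, c, 1, rng),
            _ConvBNReLU(c, c, (1, 3), rng, padding=(0, 1)),
            _ConvBNReLU(c, c, (3, 1), rng, padding=(1, 0)),
            _ConvBNReLU(c, c, 3, rng, padding=3, dilation=3),
        ])
        self.large = Sequential([
            _ConvBNReLU(c, c, 1, rng),
            _ConvBNReLU(c, c, (1, 5), rng, padding=(0, 2)),
            _ConvBNReLU(c, c, (5, 1), rng, padding=(2, 0)),
            _ConvBNReLU(c, c, 5, rng, padding=6, dilation=3),
        ])
        self.fuse_conv = Conv2d(3 * c, c, 3, rng, padding=1, bias=False)
        self.fuse_bn = BatchNorm2d(c)

    def branch_outputs(self, x) -> tuple:
        """The three branch maps before concatenation (same shape as x)."""
        return self.base(x), self.medium(x), self.large(x)

    def forward(self, x) -> Tensor:
        b, m, l = self.branch_outputs(x)
        fused = self.fuse_bn(self.fuse_conv(concat([b, m, l], axis=1)))
        return fused + x
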