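"""The two convolutional feature extractors feeding the dual encoder.

* :class:`ConvNeXtEncoder` — the local-detail branch.  Hierarchical stages of
  ConvNeXt blocks (7x7 depthwise convolution, channel LayerNorm, a 4x
  pointwise expansion with GELU, and a residual add) produce a four-level
  pyramid C1..C4 with widths (96, 192, 384, 768) at strides 4/8/16/32.

* :class:`ResNet34Encoder` — the feature source for the deformable-attention
  branch.  Standard BasicBlock ResNet-34, tapped at five scales; the first
  tap is taken after the stem activation and *before* max-pooling so the
  highest-resolution map (stride 2) keeps fine boundary detail.

Both encoders accept any square input divisible by 32 and return maps whose
spatial sizes scale linearly with the input.
"""

from __future__ import annotations

import numpy as np

from .nn import BatchNorm2d, Conv2d, LayerNorm, Module, ModuleList
from .nn import functional as F
from .nn.tensor import gelu, relu


class ConvNeXtBlock(Module):
    """Residual block: x + W2 * GELU(W1 * LN(DWConv7x7(x)))."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.dwconv = Conv2d(dim, dim, 7, rng, padding=3, groups=dim,
                             init="trunc_normal")
        self.norm = LayerNorm(dim, axis=1)
        self.pwconv1 = Conv2d(dim, 4 * dim, 1, rng, init="trunc_normal")
        self.pwconv2 = Conv2d(4 * dim, dim, 1, rng, init="trunc_normal")

    def forward(self, x):
        y = self.dwconv(x)
        y = self.norm(y)
        y = self.pwconv1(y)
        y = gelu(y)
        y = self.pwconv2(y)
        return x + y


class ConvNeXtEncoder(Module):
    def __init__(self, rng: np.random.Generator,
                 depths: tuple = (3, 3, 27, 3),
                 dims: tuple = (96, 192, 384, 768)):
        super().__init__()
        self.dims = tuple(dims)
        self.stem = Conv2d(3, dims[0], 4, rng, stride=4, init="trunc_normal")
        self.stem_norm = LayerNorm(dims[0], axis=1)
        self.downsample_norms = ModuleList(
            [LayerNorm(dims[i], axis=1) for i in range(3)])
        self.downsamples = ModuleList(
            [Conv2d(dims[i], dims[i + 1], 2, rng, stride=2,
                    init="trunc_normal") for i in range(3)])
        self.stages = ModuleList(
            [ModuleList([ConvNeXtBlock(dims[i], rng)
                         for _ in range(depths[i])]) for i in range(4)])

    def forward(self, x) -> list:
        """Return the four stage outputs [C1, C2, C3, C4]."""
        if x.shape[-1] % 32 or x.shape[-2] % 32:
            raise ValueError("input spatial size must be divisible by 32")
        x = self.stem_norm(self.stem(x))
        feats = []
        for i in range(4):
            if i > 0:
                x = self.downsamples[i - 1](self.downsample_norms[i - 1](x))
            for block in self.stages[i]:
                x = block(x)
            feats.append(x)
        return feats


class BasicBlock(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 stride: int = 1):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, rng, stride=stride, padding=1,
                            bias=False)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng, padding=1, bias=False)
        self.bn2 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down_conv = Conv2d(cin, cout, 1, rng, stride=stride,
                                    bias=False)
            self.down_bn = BatchNorm2d(cout)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x):
        y = relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        if self.down_conv is not None:
            x = self.down_bn(self.down_conv(x))
        return relu(x + y)


class ResNet34Encoder(Module):
    LAYERS = ((64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2))

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(3, 64, 7, rng, stride=2, padding=3, bias=False)
        self.bn1 = BatchNorm2d(64)
        stages = []
        cin = 64
        for cout, blocks, stride in self.LAYERS:
            stage = [BasicBlock(cin, cout, rng, stride)]
            stage += [BasicBlock(cout, cout, rng) for _ in range(blocks - 1)]
            stages.append(ModuleList(stage))
            cin = cout
        self.layers = ModuleList(stages)

    def forward(self, x) -> list:
        """Return the five taps [R1..R5]; R1 precedes max-pooling."""
        if x.shape[-1] % 32 or x.shape[-2] % 32:
            raise ValueError("input spatial size must be divisible by 32")
        x = relu(self.bn1(self.conv1(x)))
        feats = [x]
        x = F.max_pool2d(x, 3, 2, 1)
        for stage in self.layers:
            for block in stage:
                x = block(x)
            feats.append(x)
        return feats
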