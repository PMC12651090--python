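"""Full network assembly: dual encoder, SE fusion, MSRF enhancement,
hierarchical feature-transfer decoder and segmentation head.

Data flow for a (N, 3, S, S) input, S divisible by 32 (default 224):

1. ConvNeXt branch -> C1..C4 at widths (96, 192, 384, 768).
2. ResNet-34 -> R1..R5 -> deformable encoder -> T0..T4 at widths
   (48, 96, 192, 384, 768); T0 keeps the stride-2 resolution.
3. Per level k=1..4, SE fusion of (Ck, Tk) -> Fk; MSRF on F1..F3 and on T0.
   F4 enters the decoder directly (no MSRF on the deepest level).
4. Decoder ladder D4=F4; Dk = Up(D(k+1)) + Fk_msrf down to D0 (48 channels,
   stride 2), where Up is a channel-halving transposed convolution
   (kernel 4, stride 2, padding 1) or, optionally, bilinear upsampling
   followed by a 1x1 convolution.
5. Head: transposed convolution 48->32 (k4, s2, p1), two 3x3 convolutions
   32->32->n_classes; the output is an (N, n_classes, S, S) logit map
   (sigmoid is applied outside the model).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .backbones import ConvNeXtEncoder, ResNet34Encoder
from .config import ModelConfig
from .deformable import DeformableBranch, T_WIDTHS
from .fusion import MSRF, SEFusion
from .nn import Conv2d, ConvTranspose2d, Module, ModuleList
from .nn import functional as F
from .nn.tensor import Tensor, no_grad, relu

__all__ = ["MSDTCNNet", "count_parameters", "save_checkpoint",
           "load_checkpoint"]


class _Upsample(Module):
    """Channel-halving 2x upsampling step of the decoder ladder."""

    def __init__(self, cin: int, cout: int, rng, mode: str = "deconv"):
        super().__init__()
        self.mode = mode
        if mode == "deconv":
            self.up = ConvTranspose2d(cin, cout, 4, rng, stride=2, padding=1)
        else:
            self.up = Conv2d(cin, cout, 1, rng)

    def forward(self, x):
        if self.mode == "deconv":
            return self.up(x)
        n, c, h, w = x.shape
        return self.up(F.bilinear_resize(x, 2 * h, 2 * w))


class MSDTCNNet(Module):
    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        cfg = (config or ModelConfig()).validate()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        self.convnext = ConvNeXtEncoder(rng, cfg.convnext_depths,
                                        cfg.convnext_dims)
        self.resnet = ResNet34Encoder(rng)
        self.deformable = DeformableBranch(
            rng, depth=cfg.transformer_depth, d_model=cfg.d_model,
            n_heads=cfg.n_heads, n_points=cfg.n_points,
            ffn_dim=cfg.ffn_dim, dropout=cfg.dropout)
        dims = cfg.convnext_dims
        self.fusions = ModuleList(
            [SEFusion(c, rng, cfg.se_reduction) for c in dims])
        # MSRF on the three intermediate fused levels and on T0; the deepest
        # fused map F4 bypasses MSRF and seeds the decoder directly.
        self.msrf_shallow = MSRF(T_WIDTHS[0], rng)
        self.msrfs = ModuleList([MSRF(c, rng) for c in dims[:3]])
        ladder = list(dims[::-1]) + [T_WIDTHS[0]]  # 768,384,192,96,48
        self.ups = ModuleList(
            [_Upsample(ladder[i], ladder[i + 1], rng, cfg.decoder_upsample)
             for i in range(4)])
        self.head_up = ConvTranspose2d(T_WIDTHS[0], 32, 4, rng,
                                       stride=2, padding=1)
        self.head_conv1 = Conv2d(32, 32, 3, rng, padding=1)
        self.head_conv2 = Conv2d(32, cfg.n_classes, 3, rng, padding=1)

    # ------------------------------------------------------------ pieces
    def fuse(self, c_pyr: list, t_pyr: list) -> list:
        """SE-fuse (Ck, Tk) per level; returns [F1..F4]."""
        return [fusion(c, t)
                for fusion, c, t in zip(self.fusions, c_pyr, t_pyr[1:])]

    def decode(self, f4, f3m, f2m, f1m, f0m) -> list:
        """HFT ladder; returns [D4, D3, D2, D1, D0]."""
        states = [f4]
        for up, skip in zip(self.ups, (f3m, f2m, f1m, f0m)):
            states.append(up(states[-1]) + skip)
        return states

    def head(self, d0) -> Tensor:
        y = relu(self.head_up(d0))
        y = relu(self.head_conv1(y))
        return self.head_conv2(y)

    # ------------------------------------------------------------ forward
    def forward(self, x) -> Tensor:
        """(N, 3, S, S) normalized input -> (N, n_classes, S, S) logits."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        c_pyr = self.convnext(x)
        r_pyr = self.resnet(x)
        t_pyr = self.deformable(r_pyr)
        fused = self.fuse(c_pyr, t_pyr)
        f1m, f2m, f3m = (self.msrfs[i](fused[i]) for i in range(3))
        f0m = self.msrf_shallow(t_pyr[0])
        states = self.decode(fused[3], f3m, f2m, f1m, f0m)
        return self.head(states[-1])

    def predict_proba(self, x) -> np.ndarray:
        """Inference-mode sigmoid probabilities as a numpy array."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                logits = self.forward(x).data
        finally:
            self.train(was_training)
        from scipy.special import expit
        return expit(logits)


def count_parameters(model_or_config) -> int:
    """Total number of trainable scalar parameters."""
    model = (model_or_config if isinstance(model_or_config, Module)
             else MSDTCNNet(model_or_config))
    return model.num_parameters()


def save_checkpoint(path: str | Path, model: MSDTCNNet,
                    extra: dict | None = None) -> None:
    """Single-file archive: weights + buffers (npz) and the config (json)."""
    buf = io.BytesIO()
    np.savez(buf, **model.state_dict())
    meta = {"config": asdict(model.config), "extra": extra or {}}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("state.npz", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta))


def load_checkpoint(path: str | Path) -> tuple[MSDTCNNet, dict]:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        state = np.load(io.BytesIO(zf.read("state.npz")))
        cfg_dict = meta["config"]
        for key in ("convnext_depths", "convnext_dims"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = MSDTCNNet(ModelConfig(**cfg_dict))
        model.load_state_dict({k: state[k] for k in state.files})
    return model, meta["extra"]
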