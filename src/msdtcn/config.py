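"""Configuration dataclasses with validated defaults and YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["SynthConfig", "PreprocConfig", "ModelConfig", "TrainConfig",
           "load_yaml", "save_yaml"]


@dataclass
class SynthConfig:
    """Synthetic dermoscopy generator settings.

    One irregular, star-convex lesion per image on a smoothly varying
    skin-toned background, plus optional dark curvilinear hair strokes that
    are drawn on the image only (never on the ground-truth mask).
    """

    image_size: int = 224
    lesion_area_range: tuple[float, float] = (0.05, 0.40)
    boundary_roughness: float = 0.25
    hair_count: int = 6
    hair_width_range: tuple[int, int] = (1, 3)
    seed: int = 0

    def validate(self) -> "SynthConfig":
        lo, hi = self.lesion_area_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("lesion_area_range must be within (0, 1)")
        if self.hair_count < 0:
            raise ValueError("hair_count must be >= 0")
        if self.hair_width_range[0] < 1:
            raise ValueError("hair widths must be >= 1 pixel")
        if self.image_size < 32:
            raise ValueError("image_size too small")
        return self


@dataclass
class PreprocConfig:
    """Hair-removal, augmentation and normalization settings.

    The black-hat structuring element is rectangular (``blackhat_kernel``
    pixels square); the hair mask keeps black-hat responses above
    ``hair_threshold`` on the 8-bit scale.  Normalization defaults to the
    ImageNet statistics used by the pretrained backbones.
    """

    blackhat_kernel: int = 17
    hair_threshold: int = 10
    inpaint_radius: int = 3
    rotation_limit: float = 15.0
    flip_prob: float = 0.5
    jitter: float = 0.03
    target_size: int = 224
    normalization_mean: tuple[float, float, float] = (0.485, 0.456, 0.406)
    normalization_std: tuple[float, float, float] = (0.229, 0.224, 0.225)

    def validate(self) -> "PreprocConfig":
        if self.blackhat_kernel < 3 or self.blackhat_kernel % 2 == 0:
            raise ValueError("blackhat_kernel must be odd and >= 3")
        if not 0 <= self.hair_threshold <= 255:
            raise ValueError("hair_threshold must be in [0, 255]")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        return self


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults assemble the full network: ConvNeXt local branch with stage
    widths (96, 192, 384, 768) and depths (3, 3, 27, 3); ResNet-34 feeding a
    12-layer width-256 deformable-attention encoder (8 heads, 4 sampling
    points per head per level, feed-forward width 1024); SE fusion with
    reduction 16; channel-preserving MSRF blocks; transposed-convolution
    hierarchical decoder and the three-stage segmentation head.
    """

    n_classes: int = 1
    convnext_depths: tuple[int, int, int, int] = (3, 3, 27, 3)
    convnext_dims: tuple[int, int, int, int] = (96, 192, 384, 768)
    transformer_depth: int = 12
    d_model: int = 256
    n_heads: int = 8
    n_points: int = 4
    ffn_dim: int = 1024
    dropout: float = 0.1
    se_reduction: int = 16
    decoder_upsample: str = "deconv"  # or "bilinear"
    seed: int = 0

    def validate(self) -> "ModelConfig":
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.transformer_depth < 0:
            raise ValueError("transformer_depth must be >= 0")
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.decoder_upsample not in ("deconv", "bilinear"):
            raise ValueError("decoder_upsample must be 'deconv' or 'bilinear'")
        return self


@dataclass
class TrainConfig:
    """Optimization settings: Adam with lr 1e-3, betas (0.5, 0.999), no
    weight decay, batch size 4; checkpoint kept at the best validation Dice."""

    learning_rate: float = 1e-3
    betas: tuple[float, float] = (0.5, 0.999)
    weight_decay: float = 0.0
    batch_size: int = 4
    epochs: int = 100
    seed: int = 42
    device: str = "cpu"
    checkpoint_dir: str = "checkpoints"

    def validate(self) -> "TrainConfig":
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not all(0.0 < b < 1.0 for b in self.betas):
            raise ValueError("betas must lie in (0, 1)")
        return self


_SECTIONS = {"synth": SynthConfig, "preprocess": PreprocConfig,
             "model": ModelConfig, "train": TrainConfig}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _from_dict(cls, d: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in d:
            v = d[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs).validate()


def save_yaml(path: str | Path, **sections) -> None:
    """Write config sections (synth=, preprocess=, model=, train=) as YAML."""
    payload = {name: _to_plain(cfg) for name, cfg in sections.items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_yaml(path: str | Path) -> dict:
    """Load a YAML config file into the matching dataclasses."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return {name: _from_dict(_SECTIONS[name], section)
            for name, section in raw.items() if name in _SECTIONS}
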