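"""Dataset splitting, training/evaluation/prediction entry points.

Thin functional wrappers over :class:`~msdtcn.estimator.SkinLesionSegmenter`
plus checkpoint and report I/O; the command-line interface calls these.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .config import ModelConfig, TrainConfig
from .estimator import SkinLesionSegmenter
from .metrics import MetricsReport, confusion, metrics, write_reports
from .model import load_checkpoint, save_checkpoint
from .preprocessing import resize_normalize
from .synth import Sample

__all__ = ["SplitManifest", "split_dataset", "train", "evaluate", "predict"]


@dataclass
class SplitManifest:
    """Disjoint train/val/test id lists covering the dataset."""

    train: list[str]
    val: list[str]
    test: list[str]
    seed: int = 42

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SplitManifest":
        return cls(**json.loads(Path(path).read_text()))


def split_dataset(ids: list[str], counts: tuple[int, int, int] | None = None,
                  fractions: tuple[float, float, float] | None = None,
                  seed: int = 42) -> SplitManifest:
    """Seeded shuffle, then partition into train/val/test.

    Exactly one of ``counts`` or ``fractions`` must be given; with
    fractions the test split absorbs the rounding remainder.
    """
    if (counts is None) == (fractions is None):
        raise ValueError("give exactly one of counts or fractions")
    n = len(ids)
    if counts is None:
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        counts = (n_train, n_val, n - n_train - n_val)
    if sum(counts) > n:
        raise ValueError(f"counts {counts} exceed dataset size {n}")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    a, b, c = counts
    return SplitManifest(train=shuffled[:a], val=shuffled[a:a + b],
                         test=shuffled[a + b:a + b + c], seed=seed)


def train(samples: list[Sample], val_samples: list[Sample] | None,
          checkpoint_path: str | Path,
          model_cfg: ModelConfig | None = None,
          train_cfg: TrainConfig | None = None,
          max_steps: int | None = None, augment: bool = True,
          verbose: bool = False) -> Path:
    """Fit the network and save the best-validation-Dice checkpoint."""
    mc = (model_cfg or ModelConfig()).validate()
    tc = (train_cfg or TrainConfig()).validate()
    est = SkinLesionSegmenter(
        transformer_depth=mc.transformer_depth,
        convnext_depths=mc.convnext_depths,
        decoder_upsample=mc.decoder_upsample, dropout=mc.dropout,
        learning_rate=tc.learning_rate, betas=tc.betas,
        weight_decay=tc.weight_decay, batch_size=tc.batch_size,
        epochs=tc.epochs, max_steps=max_steps, augment=augment,
        seed=tc.seed, verbose=verbose)
    est.fit(samples, validation_data=(
        (val_samples, [s.mask for s in val_samples]) if val_samples else None))
    path = Path(checkpoint_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    save_checkpoint(path, est.model_,
                    extra={"best_val_dice": est.best_val_dice_,
                           "n_iter": est.n_iter_,
                           "history_tail": est.history_[-5:]})
    return path


def evaluate(checkpoint_path: str | Path, samples: list[Sample],
             report_prefix: str | Path | None = None
             ) -> tuple[MetricsReport, list[MetricsReport]]:
    """Deterministic evaluation pass (no augmentation, threshold 0.5)."""
    if not samples:
        raise ValueError("empty evaluation split")
    model, _ = load_checkpoint(checkpoint_path)
    reports = []
    for s in samples:
        x, m = resize_normalize(s)
        prob = model.predict_proba(x[None])[0, 0]
        reports.append(metrics(confusion((prob > 0.5).astype(np.uint8), m)))
    if report_prefix is not None:
        summary = write_reports(report_prefix, [s.id for s in samples],
                                reports)
    else:
        from .metrics import aggregate_reports
        summary = aggregate_reports(reports)
    return summary, reports


def _contours(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a binary mask (mask minus its erosion)."""
    from scipy.ndimage import binary_erosion
    m = mask.astype(bool)
    return m & ~binary_erosion(m)


def predict(checkpoint_path: str | Path, image_path: str | Path,
            out_mask_path: str | Path,
            gt_mask_path: str | Path | None = None,
            overlay_path: str | Path | None = None) -> np.ndarray:
    """Segment one image file; write a 0/255 mask PNG and optional overlay.

    Logits are computed at the model resolution and the thresholded mask is
    resized back to the input resolution with nearest-neighbour sampling.
    The overlay draws the predicted contour in blue and, when a reference
    mask is supplied, the ground-truth contour in red.
    """
    from skimage.transform import resize as sk_resize
    image = np.asarray(Image.open(image_path).convert("RGB"))
    model, _ = load_checkpoint(checkpoint_path)
    x, _ = resize_normalize(Sample(image=image,
                                   mask=np.zeros(image.shape[:2], np.uint8),
                                   id="query"))
    prob = model.predict_proba(x[None])[0, 0]
    mask = (prob > 0.5).astype(np.uint8)
    if mask.shape != image.shape[:2]:
        mask = sk_resize(mask, image.shape[:2], order=0,
                         preserve_range=True).astype(np.uint8)
    out_mask_path = Path(out_mask_path)
    out_mask_path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(mask * 255).save(out_mask_path)
    if overlay_path is not None:
        overlay = image.copy()
        if gt_mask_path is not None:
            gt = (np.asarray(Image.open(gt_mask_path).convert("L")) > 127)
            overlay[_contours(gt)] = (255, 0, 0)
        overlay[_contours(mask)] = (0, 0, 255)
        Image.fromarray(overlay).save(overlay_path)
    return mask
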