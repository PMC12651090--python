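"""Synthetic dermoscopy image generator.

Produces reproducible dermoscopy-like samples for testing and smoke
training: a smoothly varying skin-toned background, one connected darker
lesion with an irregular (star-convex) boundary and interior texture, a
matching binary ground-truth mask, and optional thin dark curvilinear hair
strokes drawn over the image only — the mask is never affected by hair.

The lesion boundary is a radial polygon r(theta) = r_base(theta) * (1 +
roughness * n(theta)) around a random center, where r_base traces an
axis-aligned ellipse (so roughness 0 gives an exact ellipse) and n(theta) is
smooth periodic noise from a low-order Fourier series.  The ellipse area is
drawn uniformly from ``lesion_area_range`` and the rasterized mask is
rejection-sampled until its pixel-count area fraction falls inside the same
range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon
from skimage.morphology import closing as _closing, disk

from .config import SynthConfig

__all__ = ["Sample", "generate_lesion_mask", "render_dermoscopy",
           "generate_sample", "generate_dataset", "load_dataset"]

_MAX_ATTEMPTS = 50
_FOURIER_ORDERS = (2, 3, 4, 5, 6)

# default palette (8-bit RGB)
_SKIN_BASE = np.array([224.0, 172.0, 150.0])
_LESION_BASE = np.array([120.0, 78.0, 62.0])
_HAIR_SHADE = 28.0


@dataclass
class Sample:
    """An RGB image, its binary lesion mask, and an identifier."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray   # (H, W) {0, 1} uint8
    id: str

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask spatial sizes differ")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask values must be binary")


def _radial_profile(rng: np.random.Generator, roughness: float,
                    n_theta: int = 720) -> np.ndarray:
    """Smooth periodic perturbation n(theta), normalized to max |n| = 1."""
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    noise = np.zeros(n_theta)
    for order in _FOURIER_ORDERS:
        a, b = rng.standard_normal(2) / order
        noise += a * np.cos(order * theta) + b * np.sin(order * theta)
    peak = np.abs(noise).max()
    if peak > 0:
        noise /= peak
    return 1.0 + roughness * noise


def generate_lesion_mask(cfg: SynthConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """One connected, star-convex lesion mask with controlled area fraction.

    Raises ``RuntimeError`` if rejection sampling cannot place a lesion whose
    pixelized area fraction lands inside ``lesion_area_range``.
    """
    cfg.validate()
    size = cfg.image_size
    lo, hi = cfg.lesion_area_range
    total = size * size
    theta = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    for _ in range(_MAX_ATTEMPTS):
        target = rng.uniform(lo, hi)
        # axis-aligned ellipse with the target area: pi*a*b = target*total
        aspect = rng.uniform(0.6, 1.0)
        b = np.sqrt(target * total / (np.pi * aspect))
        a = aspect * b
        profile = _radial_profile(rng, cfg.boundary_roughness)
        r_ellipse = (a * b) / np.sqrt((b * np.cos(theta)) ** 2
                                      + (a * np.sin(theta)) ** 2)
        radius = r_ellipse * profile
        margin = radius.max() + 2
        if 2 * margin >= size:
            continue
        cy = rng.uniform(margin, size - margin)
        cx = rng.uniform(margin, size - margin)
        rows = cy + radius * np.sin(theta)
        cols = cx + radius * np.cos(theta)
        rr, cc = draw_polygon(rows, cols, shape=(size, size))
        mask = np.zeros((size, size), dtype=bool)
        mask[rr, cc] = True
        mask = _closing(mask, disk(2))
        frac = mask.sum() / total
        if lo <= frac <= hi:
            return mask.astype(np.uint8)
    raise RuntimeError("could not sample a lesion mask satisfying the "
                       "area-range constraint; config may be infeasible")


def _quadratic_bezier(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 2) * p0 + 2 * (1 - t) * t * p1 + (t ** 2) * p2


def _draw_hairs(image: np.ndarray, cfg: SynthConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Overlay dark antialiased quadratic-curve strokes; returns new array."""
    size = cfg.image_size
    wmin, wmax = cfg.hair_width_range
    out = image.copy()
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(cfg.hair_count):
        pts = rng.uniform(-0.15 * size, 1.15 * size, size=(3, 2))
        curve = _quadratic_bezier(pts[0], pts[1], pts[2], 3 * size)
        width = rng.uniform(wmin, wmax)
        shade = _HAIR_SHADE + rng.uniform(-10.0, 15.0)
        # soft alpha from distance to the sampled polyline (radius ~ width/2)
        alpha = np.zeros((size, size), dtype=np.float32)
        half = width / 2.0
        reach = int(np.ceil(half)) + 1
        for py, px in curve:
            iy, ix = int(round(py)), int(round(px))
            y0, y1 = max(iy - reach, 0), min(iy + reach + 1, size)
            x0, x1 = max(ix - reach, 0), min(ix + reach + 1, size)
            if y0 >= y1 or x0 >= x1:
                continue
            d = np.hypot(yy[y0:y1, x0:x1] - py, xx[y0:y1, x0:x1] - px)
            a = np.clip(half + 0.5 - d, 0.0, 1.0)
            np.maximum(alpha[y0:y1, x0:x1], a, out=alpha[y0:y1, x0:x1])
        out = out * (1.0 - alpha[..., None]) + shade * alpha[..., None]
    return out


def render_dermoscopy(mask: np.ndarray, cfg: SynthConfig,
                      rng: np.random.Generator, sample_id: str = "sample",
                      ) -> Sample:
    """Render a dermoscopy-like image for a lesion mask.

    The background is a low-frequency skin-tone field; lesion pixels are
    darker and browner with their own texture, blended over a feathered
    (~1.5 px) boundary so edges are not knife-sharp.  Hair strokes, if any,
    are composited onto the image only.
    """
    cfg.validate()
    size = cfg.image_size
    grad = gaussian_filter(rng.standard_normal((size, size)), size / 6)
    grad = grad / (np.abs(grad).max() + 1e-9)
    skin = _SKIN_BASE[None, None, :] + 18.0 * grad[..., None]
    skin = skin + rng.uniform(-8, 8, size=3)[None, None, :]
    texture = gaussian_filter(rng.standard_normal((size, size)), 2.0)
    texture = texture / (np.abs(texture).max() + 1e-9)
    lesion = _LESION_BASE[None, None, :] * (1.0 + 0.18 * texture[..., None])
    lesion = lesion + rng.uniform(-12, 12, size=3)[None, None, :]
    edge = gaussian_filter(mask.astype(np.float32), 1.5)[..., None]
    image = skin * (1.0 - edge) + lesion * edge
    if cfg.hair_count > 0:
        image = _draw_hairs(image, cfg, rng)
    image = np.clip(image, 0, 255).round().astype(np.uint8)
    return Sample(image=image, mask=mask.astype(np.uint8), id=sample_id)


def generate_sample(cfg: SynthConfig, seed: int | None = None,
                    sample_id: str | None = None) -> Sample:
    """Mask + rendering from one seeded stream; fully deterministic."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    mask = generate_lesion_mask(cfg, rng)
    return render_dermoscopy(mask, cfg, rng,
                             sample_id or f"synth_{seed:08d}")


def generate_dataset(n: int, cfg: SynthConfig, out_dir: str | Path) -> dict:
    """Write n image/mask PNG pairs and a manifest; byte-reproducible.

    Layout: ``images/<id>.png`` (8-bit RGB), ``masks/<id>.png`` (8-bit
    single channel, 0/255), ``manifest.json`` with ids and per-sample seeds.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg.validate()
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(cfg.seed)
    seeds = [int(s) for s in root.integers(0, 2 ** 31 - 1, size=n)]
    entries = []
    for i, seed in enumerate(seeds):
        sample = generate_sample(cfg, seed=seed, sample_id=f"synth_{i:04d}")
        Image.fromarray(sample.image).save(out / "images" / f"{sample.id}.png")
        Image.fromarray((sample.mask * 255).astype(np.uint8)).save(
            out / "masks" / f"{sample.id}.png")
        entries.append({"id": sample.id, "seed": seed})
    manifest = {"n": n, "seed": cfg.seed, "image_size": cfg.image_size,
                "samples": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_dataset(root: str | Path) -> list[Sample]:
    """Load image/mask pairs listed by a dataset manifest."""
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    samples = []
    for entry in manifest["samples"]:
        sid = entry["id"]
        image = np.asarray(Image.open(root / "images" / f"{sid}.png"))
        mask = np.asarray(Image.open(root / "masks" / f"{sid}.png"))
        samples.append(Sample(image=image, mask=(mask > 127).astype(np.uint8),
                              id=sid))
    return samples
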