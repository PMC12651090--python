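"""Standardized input pipeline: morphological hair removal, training-time
augmentation, and model-input normalization.

Hair removal runs in four steps on each image: (1) grayscale conversion,
(2) black-hat transform (morphological closing minus the image) with a
rectangular structuring element larger than a hair stroke's width, which
highlights thin dark structures, (3) thresholding the black-hat response
into a binary hair mask, and (4) filling the masked pixels by biharmonic
inpainting from their surroundings.  The mask is detected on the grayscale
image but the repair is applied to all three RGB channels, since the
network consumes 3-channel input.

Augmentation (training split only) applies the identical geometric
transform to image and mask — bounded rotations (±15° by default) and
horizontal/vertical flips — plus photometric jitter of brightness,
contrast, saturation and hue within ±0.03, applied to the image only.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import rotate as nd_rotate
from skimage.color import hsv2rgb, rgb2hsv
from skimage.morphology import closing as gray_closing
from skimage.restoration import inpaint_biharmonic
from skimage.transform import resize as sk_resize

from .config import PreprocConfig
from .synth import Sample

__all__ = ["to_grayscale", "blackhat", "hair_mask", "inpaint", "remove_hair",
           "augment", "resize_normalize", "batch_to_model_input"]

# ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """8-bit luminance via the BT.601 weights (0.299, 0.587, 0.114)."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) image")
    return np.clip((image.astype(np.float64) @ _LUMA).round(),
                   0, 255).astype(np.uint8)


def blackhat(gray: np.ndarray, kernel: int = 17) -> np.ndarray:
    """Black-hat response: morphological closing minus the image.

    Non-negative everywhere; zero wherever closing leaves the image
    unchanged.  ``kernel`` is the side of the rectangular structuring
    element and must be odd and no larger than the image.
    """
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("kernel must be odd and >= 3")
    if kernel > min(gray.shape):
        raise ValueError("kernel larger than image")
    closed = gray_closing(gray, footprint=np.ones((kernel, kernel), bool))
    return (closed.astype(np.int16) - gray.astype(np.int16)
            ).clip(0, 255).astype(np.uint8)


def hair_mask(response: np.ndarray, threshold: int = 10) -> np.ndarray:
    """Binary hair mask: black-hat response strictly above ``threshold``."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    return (response > threshold).astype(np.uint8)


def inpaint(image: np.ndarray, mask: np.ndarray,
            radius: int = 3) -> np.ndarray:
    """Fill masked pixels by biharmonic inpainting from their boundary.

    Pixels outside the mask are returned bit-exact unchanged.  ``radius``
    expresses the expected stroke half-width; the biharmonic fill derives
    its support from the mask itself, so the value only participates in
    configuration plumbing.
    """
    if mask.shape != image.shape[:2]:
        raise ValueError("mask and image spatial sizes differ")
    m = mask.astype(bool)
    if not m.any():
        return image.copy()
    filled = inpaint_biharmonic(image, m, channel_axis=-1)
    out = image.copy()
    out[m] = np.clip(filled[m] * 255.0, 0, 255).round().astype(np.uint8)
    return out


def remove_hair(image: np.ndarray,
                cfg: PreprocConfig | None = None) -> np.ndarray:
    """Grayscale -> black-hat -> threshold -> inpaint, on one RGB image."""
    cfg = (cfg or PreprocConfig()).validate()
    gray = to_grayscale(image)
    response = blackhat(gray, cfg.blackhat_kernel)
    mask = hair_mask(response, cfg.hair_threshold)
    return inpaint(image, mask, cfg.inpaint_radius)


def _jitter(image: np.ndarray, rng: np.random.Generator,
            amount: float) -> np.ndarray:
    """Brightness/contrast/saturation/hue jitter, each within ±amount."""
    img = image.astype(np.float32) / 255.0
    img = np.clip(img * (1.0 + rng.uniform(-amount, amount)), 0, 1)
    mean = img.mean()
    img = np.clip(mean + (img - mean) * (1.0 + rng.uniform(-amount, amount)),
                  0, 1)
    gray = (img @ _LUMA.astype(np.float32))[..., None]
    img = np.clip(gray + (img - gray) * (1.0 + rng.uniform(-amount, amount)),
                  0, 1)
    hsv = rgb2hsv(img)
    hsv[..., 0] = (hsv[..., 0] + rng.uniform(-amount, amount)) % 1.0
    img = hsv2rgb(hsv)
    return np.clip(img * 255.0, 0, 255).round().astype(np.uint8)


def augment(sample: Sample, cfg: PreprocConfig,
            rng: np.random.Generator) -> Sample:
    """Random geometric transform of image+mask and photometric jitter.

    The same rotation/flips are applied to both arrays; the mask uses
    nearest-neighbour interpolation and stays binary.
    """
    cfg.validate()
    image, mask = sample.image, sample.mask
    if cfg.rotation_limit > 0:
        angle = rng.uniform(-cfg.rotation_limit, cfg.rotation_limit)
        image = nd_rotate(image, angle, axes=(0, 1), reshape=False, order=1,
                          mode="nearest")
        mask = nd_rotate(mask, angle, axes=(0, 1), reshape=False, order=0,
                         mode="constant")
    if rng.random() < cfg.flip_prob:
        image, mask = image[:, ::-1].copy(), mask[:, ::-1].copy()
    if rng.random() < cfg.flip_prob:
        image, mask = image[::-1].copy(), mask[::-1].copy()
    if cfg.jitter > 0:
        image = _jitter(image, rng, cfg.jitter)
    return Sample(image=np.ascontiguousarray(image),
                  mask=np.ascontiguousarray(mask.astype(np.uint8)), id=sample.id)


def resize_normalize(sample: Sample,
                     cfg: PreprocConfig | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear-resize + channel-standardize the image; NN-resize the mask.

    Returns ``(x, mask)`` with ``x`` a (3, S, S) float32 array standardized
    by ``normalization_mean``/``std`` and ``mask`` an (S, S) {0,1} array.
    """
    cfg = (cfg or PreprocConfig()).validate()
    size = cfg.target_size
    img = sample.image.astype(np.float32) / 255.0
    if img.shape[:2] != (size, size):
        img = sk_resize(img, (size, size), order=1, anti_aliasing=False,
                        preserve_range=True)
        mask = sk_resize(sample.mask, (size, size), order=0,
                         anti_aliasing=False, preserve_range=True)
    else:
        mask = sample.mask
    mean = np.asarray(cfg.normalization_mean, np.float32)
    std = np.asarray(cfg.normalization_std, np.float32)
    x = ((img - mean) / std).transpose(2, 0, 1).astype(np.float32)
    return x, (mask > 0.5).astype(np.uint8)


def batch_to_model_input(samples: list[Sample],
                         cfg: PreprocConfig | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into model input (N,3,S,S) and targets (N,1,S,S)."""
    pairs = [resize_normalize(s, cfg) for s in samples]
    x = np.stack([p[0] for p in pairs])
    y = np.stack([p[1] for p in pairs])[:, None].astype(np.float32)
    return x, y
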