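"""Hair-removal pipeline, augmentation and normalization contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msdtcn.config import PreprocConfig, SynthConfig
from msdtcn.preprocessing import (augment, batch_to_model_input, blackhat,
                                  hair_mask, inpaint, remove_hair,
                                  resize_normalize, to_grayscale)
from msdtcn.synth import Sample, generate_sample


# ---------------------------------------------------------------- grayscale
def test_grayscale_of_gray_input_is_identity(rng):
    v = rng.integers(0, 256, size=(6, 7), dtype=np.uint8)
    image = np.repeat(v[..., None], 3, axis=-1)
    assert np.array_equal(to_grayscale(image), v)


def test_grayscale_bt601_red_weight():
    red = np.zeros((2, 2, 3), np.uint8)
    red[..., 0] = 255
    assert np.all(to_grayscale(red) == 76)  # round(0.299 * 255)


def test_grayscale_rejects_wrong_channels():
    with pytest.raises(ValueError):
        to_grayscale(np.zeros((4, 4), np.uint8))


# ----------------------------------------------------------------- blackhat
def test_blackhat_of_constant_image_is_zero():
    img = np.full((20, 20), 137, np.uint8)
    assert not blackhat(img, 5).any()


def test_blackhat_recovers_dark_line_on_bright_field():
    img = np.full((15, 15), 200, np.uint8)
    img[7, :] = 50
    resp = blackhat(img, 5)
    assert np.all(resp[7, :] == 150)
    assert not resp[:5].any() and not resp[10:].any()
    mask = hair_mask(resp, 10)
    expected = np.zeros((15, 15), np.uint8)
    expected[7, :] = 1
    assert np.array_equal(mask, expected)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_blackhat_nonnegative_for_random_inputs(seed):
    img = np.random.default_rng(seed).integers(0, 256, (12, 12), np.uint8)
    resp = blackhat(img, 5)
    assert resp.dtype == np.uint8 and int(resp.min()) >= 0


def test_blackhat_kernel_larger_than_image_raises():
    with pytest.raises(ValueError):
        blackhat(np.zeros((8, 8), np.uint8), 17)


# ---------------------------------------------------------------- hair mask
def test_hair_mask_boundaries():
    resp = np.zeros((5, 5), np.uint8)
    assert not hair_mask(resp, 10).any()
    resp[:] = 255
    assert not hair_mask(resp, 255).any()  # strict threshold at the top


# ------------------------------------------------------------------ inpaint
def test_inpaint_empty_mask_is_bit_exact_noop(rng):
    img = rng.integers(0, 256, (16, 16, 3), np.uint8)
    out = inpaint(img, np.zeros((16, 16), np.uint8))
    assert np.array_equal(out, img)


def test_inpaint_constant_image_stays_constant(rng):
    img = np.full((20, 20, 3), 180, np.uint8)
    mask = np.zeros((20, 20), np.uint8)
    mask[8:12, 5:15] = 1
    out = inpaint(img, mask)
    assert np.array_equal(out, img)


def test_inpaint_never_touches_pixels_outside_mask(rng):
    img = rng.integers(0, 256, (24, 24, 3), np.uint8)
    mask = np.zeros((24, 24), np.uint8)
    mask[10:14, 3:20] = 1
    out = inpaint(img, mask)
    outside = mask == 0
    assert np.array_equal(out[outside], img[outside])


# -------------------------------------------------------------- remove_hair
def test_remove_hair_on_hair_free_image_is_near_noop():
    clean = generate_sample(SynthConfig(hair_count=0), seed=21)
    out = remove_hair(clean.image)
    changed = (out != clean.image).any(axis=-1).mean()
    assert changed < 0.05  # only spurious texture responses get repainted


def test_remove_hair_reduces_error_to_hair_free_twin():
    hairy = generate_sample(SynthConfig(hair_count=20), seed=33)
    clean = generate_sample(SynthConfig(hair_count=0), seed=33)
    repaired = remove_hair(hairy.image)
    before = np.abs(hairy.image.astype(float) - clean.image.astype(float)).mean()
    after = np.abs(repaired.astype(float) - clean.image.astype(float)).mean()
    assert after < before


def test_remove_hair_is_idempotent_within_tolerance():
    hairy = generate_sample(SynthConfig(hair_count=12), seed=8)
    once = remove_hair(hairy.image)
    twice = remove_hair(once)
    cfg = PreprocConfig()
    first_mask = hair_mask(blackhat(to_grayscale(hairy.image),
                                    cfg.blackhat_kernel), cfg.hair_threshold)
    second_mask = hair_mask(blackhat(to_grayscale(once), cfg.blackhat_kernel),
                            cfg.hair_threshold)
    assert second_mask.mean() < 0.5 * first_mask.mean()  # near-empty rerun
    mae = np.abs(twice.astype(np.float64) - once.astype(np.float64)).mean()
    assert mae < 1.0  # a second pass barely changes the image


# ------------------------------------------------------------------ augment
class _ScriptedRng:
    """Deterministic stand-in driving augment()'s random draws."""

    def __init__(self, uniforms, randoms):
        self._uniforms = list(uniforms)
        self._randoms = list(randoms)

    def uniform(self, lo, hi, size=None):
        return self._uniforms.pop(0)

    def random(self):
        return self._randoms.pop(0)


@pytest.fixture
def lesion_sample():
    mask = np.zeros((96, 96), np.uint8)
    yy, xx = np.mgrid[0:96, 0:96]
    mask[((yy - 48) ** 2 / 900 + (xx - 48) ** 2 / 324) <= 1] = 1
    img = (mask * 120 + 100).astype(np.uint8)[..., None].repeat(3, axis=2)
    return Sample(image=img, mask=mask, id="toy")


def test_augment_all_disabled_is_identity(lesion_sample):
    cfg = PreprocConfig(rotation_limit=0.0, flip_prob=0.0, jitter=0.0)
    out = augment(lesion_sample, cfg, np.random.default_rng(0))
    assert np.array_equal(out.image, lesion_sample.image)
    assert np.array_equal(out.mask, lesion_sample.mask)


def test_forced_flip_mirrors_both_and_is_involutive(lesion_sample):
    cfg = PreprocConfig(rotation_limit=0.0, flip_prob=1.0, jitter=0.0)
    once = augment(lesion_sample, cfg,
                   _ScriptedRng([], [0.0, 1.0]))  # horizontal only
    assert np.array_equal(once.mask, lesion_sample.mask[:, ::-1])
    assert np.array_equal(once.image, lesion_sample.image[:, ::-1])
    twice = augment(once, cfg, _ScriptedRng([], [0.0, 1.0]))
    assert np.array_equal(twice.mask, lesion_sample.mask)


def test_rotation_roundtrip_keeps_mask_iou(lesion_sample):
    cfg = PreprocConfig(jitter=0.0, flip_prob=0.0)
    fwd = augment(lesion_sample, cfg, _ScriptedRng([15.0], [1.0, 1.0]))
    back = augment(fwd, cfg, _ScriptedRng([-15.0], [1.0, 1.0]))
    inter = (back.mask & lesion_sample.mask).sum()
    union = (back.mask | lesion_sample.mask).sum()
    assert inter / union >= 0.95


def test_augment_preserves_binarity_and_alignment(lesion_sample):
    cfg = PreprocConfig()
    for seed in range(5):
        out = augment(lesion_sample, cfg, np.random.default_rng(seed))
        assert out.image.shape[:2] == out.mask.shape
        assert set(np.unique(out.mask)) <= {0, 1}


# --------------------------------------------------------- resize/normalize
def test_resize_normalize_identity_size_only_normalizes(rng):
    img = rng.integers(0, 256, (224, 224, 3), np.uint8)
    mask = rng.integers(0, 2, (224, 224)).astype(np.uint8)
    cfg = PreprocConfig()
    x, m = resize_normalize(Sample(image=img, mask=mask, id="t"), cfg)
    mean = np.array(cfg.normalization_mean, np.float32)
    std = np.array(cfg.normalization_std, np.float32)
    expected = ((img / 255.0 - mean) / std).transpose(2, 0, 1)
    assert np.allclose(x, expected, atol=1e-6)
    assert np.array_equal(m, mask)


def test_resize_normalize_downscales_mask_exactly():
    mask = np.zeros((448, 448), np.uint8)
    mask[112:336, 112:336] = 1  # centered square, side 224
    img = np.zeros((448, 448, 3), np.uint8)
    x, m = resize_normalize(Sample(image=img, mask=mask, id="t"),
                            PreprocConfig())
    assert m.shape == (224, 224)
    expected = np.zeros((224, 224), np.uint8)
    expected[56:168, 56:168] = 1
    assert np.array_equal(m, expected)


def test_normalized_mean_image_maps_to_zero():
    cfg = PreprocConfig()
    img = np.round(np.array(cfg.normalization_mean) * 255).astype(np.uint8)
    img = np.broadcast_to(img, (224, 224, 3)).copy()
    x, _ = resize_normalize(Sample(image=img,
                                   mask=np.zeros((224, 224), np.uint8),
                                   id="t"), cfg)
    assert np.abs(x.mean(axis=(1, 2))) .max() < 0.02


def test_batch_to_model_input_shapes(small_samples):
    x, y = batch_to_model_input(small_samples)
    assert x.shape == (4, 3, 224, 224)
    assert y.shape == (4, 1, 224, 224)
    assert set(np.unique(y)) <= {0.0, 1.0}
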