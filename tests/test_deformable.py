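"""Deformable-attention branch: alignment, embeddings, sampling, encoder."""

import numpy as np
import pytest

from msdtcn.deformable import (DeformableBranch, MSDeformAttn,
                               reference_points,
                               sinusoidal_position_embedding)
from msdtcn.nn.deform import ms_deform_sample, ms_deform_sample_reference
from msdtcn.nn.tensor import Tensor, softmax


@pytest.fixture
def nprng():
    return np.random.default_rng(42)


@pytest.fixture
def branch(nprng):
    return DeformableBranch(nprng, depth=1)


def _fake_pyramid(nprng, n=1, widths=(64, 64, 128, 256, 512),
                  sizes=((16, 16), (8, 8), (4, 4), (2, 2), (1, 1))):
    return [Tensor(nprng.standard_normal((n, c, h, w)).astype(np.float32))
            for c, (h, w) in zip(widths, sizes)]


class TestAlignment:
    def test_widths_unified_to_256(self, branch, nprng):
        aligned = branch.align_channels(_fake_pyramid(nprng))
        assert all(a.shape[1] == 256 for a in aligned)
        assert [a.shape[-1] for a in aligned] == [16, 8, 4, 2, 1]

    def test_identity_block_weights_copy_input_channels(self, branch, nprng):
        conv = branch.align[0]
        conv.weight.data[...] = 0.0
        conv.weight.data[:64, :, 0, 0] = np.eye(64)
        conv.bias.data[...] = 0.0
        x = _fake_pyramid(nprng)[0]
        out = conv(x)
        assert np.allclose(out.data[:, :64], x.data, atol=1e-6)
        assert not out.data[:, 64:].any()

    def test_per_level_weights_are_independent(self, branch, nprng):
        pyr = _fake_pyramid(nprng)
        before = [a.data.copy() for a in branch.align_channels(pyr)]
        branch.align[3].weight.data[...] += 1.0
        after = [a.data for a in branch.align_channels(pyr)]
        for i in range(5):
            if i == 3:
                assert not np.allclose(before[i], after[i])
            else:
                assert np.array_equal(before[i], after[i])


class TestEmbeddings:
    def test_level_embedding_offsets_same_position(self, branch):
        shapes = np.array([[4, 4], [4, 4]])
        pos = branch.positional_embeddings(shapes).data
        diff = pos[16:] - pos[:16]  # same (row, col), different level
        expected = (branch.level_embed.data[1] - branch.level_embed.data[0])
        assert np.allclose(diff, expected[None, :], atol=1e-6)

    def test_distinct_positions_distinct_codes(self):
        emb = sinusoidal_position_embedding(6, 6, 256)
        assert np.isfinite(emb).all()
        # all pairwise distinct rows
        assert np.unique(emb.round(5), axis=0).shape[0] == 36

    def test_sinusoidal_part_deterministic(self):
        a = sinusoidal_position_embedding(5, 7, 256)
        b = sinusoidal_position_embedding(5, 7, 256)
        assert np.array_equal(a, b)

    def test_reference_points_are_normalized_centers(self):
        ref = reference_points([(2, 2)])
        assert np.allclose(sorted(set(ref[:, 0])), [0.25, 0.75])
        assert ref.min() > 0 and ref.max() < 1


class TestDeformableSampling:
    def test_vectorized_matches_bruteforce_oracle(self, nprng):
        shapes = np.array([[3, 3], [2, 2]], np.int64)
        starts = np.array([0, 9], np.int64)
        value = nprng.standard_normal((2, 13, 3, 4)).astype(np.float32)
        loc = nprng.uniform(-0.2, 1.2, (2, 5, 3, 2, 4, 2)).astype(np.float32)
        attn = nprng.random((2, 5, 3, 2, 4)).astype(np.float32)
        out = ms_deform_sample(Tensor(value), Tensor(loc), Tensor(attn),
                               shapes, starts).data
        ref = ms_deform_sample_reference(value, loc, attn, shapes, starts)
        assert np.abs(out - ref).max() < 1e-5

    def test_degenerate_config_returns_value_at_reference(self, nprng):
        attn = MSDeformAttn(nprng, d_model=8, n_levels=1, n_heads=1,
                            n_points=1)
        attn.sampling_offsets.weight.data[...] = 0.0
        attn.sampling_offsets.bias.data[...] = 0.0
        attn.attention_weights.weight.data[...] = 0.0
        attn.attention_weights.bias.data[...] = 0.0
        attn.value_proj.weight.data[...] = np.eye(8)
        attn.value_proj.bias.data[...] = 0.0
        attn.output_proj.weight.data[...] = np.eye(8)
        attn.output_proj.bias.data[...] = 0.0
        shapes = np.array([[3, 4]], np.int64)
        starts = np.array([0], np.int64)
        src = Tensor(nprng.standard_normal((1, 12, 8)).astype(np.float32))
        out = attn(src, src, reference_points([(3, 4)]), shapes, starts)
        assert np.allclose(out.data, src.data, atol=1e-6)

    def test_attention_weights_normalized(self, nprng):
        attn = MSDeformAttn(nprng, d_model=16, n_levels=2, n_heads=4,
                            n_points=3)
        q = Tensor(nprng.standard_normal((2, 7, 16)).astype(np.float32))
        w = softmax(attn.attention_weights(q).reshape(2, 7, 4, 6), axis=-1)
        assert np.allclose(w.data.sum(-1), 1.0, atol=1e-6)

    def test_sampling_gradients_match_finite_differences(self, nprng):
        shapes = np.array([[3, 3], [2, 2]], np.int64)
        starts = np.array([0, 9], np.int64)
        value = nprng.standard_normal((1, 13, 2, 3)).astype(np.float32)
        loc = nprng.uniform(0.2, 0.8, (1, 4, 2, 2, 2, 2)).astype(np.float32)
        attn = nprng.random((1, 4, 2, 2, 2)).astype(np.float32)
        tv, tl, ta = (Tensor(a, requires_grad=True)
                      for a in (value, loc, attn))
        out = ms_deform_sample(tv, tl, ta, shapes, starts)
        w = nprng.standard_normal(out.shape).astype(np.float32)
        out.backward(w)
        for t, arr in ((tv, value), (tl, loc), (ta, attn)):
            flat = arr.reshape(-1)
            gf = t.grad.reshape(-1)
            for j in nprng.integers(0, flat.size, 8):
                orig = flat[j]
                eps = 1e-3
                flat[j] = orig + eps
                fp = np.sum(ms_deform_sample_reference(
                    value, loc, attn, shapes, starts).astype(np.float64) * w)
                flat[j] = orig - eps
                fm = np.sum(ms_deform_sample_reference(
                    value, loc, attn, shapes, starts).astype(np.float64) * w)
                flat[j] = orig
                num = (fp - fm) / (2 * eps)
                assert abs(num - gf[j]) < 5e-2 * max(1.0, abs(num))


class TestEncoder:
    def test_token_count_and_width_preserved(self, nprng):
        branch = DeformableBranch(nprng, depth=2)
        pyr = _fake_pyramid(nprng)
        aligned = branch.align_channels(pyr)
        shapes = branch.level_shapes(aligned)
        tokens = branch.tokenize(aligned)
        pos = branch.positional_embeddings(shapes)
        mem = branch.encode(tokens, pos, shapes)
        assert mem.shape == tokens.shape == (1, 16 ** 2 + 8 ** 2 + 4 ** 2
                                             + 2 ** 2 + 1, 256)

    def test_zero_layer_encoder_is_identity(self, nprng):
        branch = DeformableBranch(nprng, depth=0)
        aligned = branch.align_channels(_fake_pyramid(nprng))
        shapes = branch.level_shapes(aligned)
        tokens = branch.tokenize(aligned)
        pos = branch.positional_embeddings(shapes)
        mem = branch.encode(tokens, pos, shapes)
        assert np.array_equal(mem.data, tokens.data)

    def test_split_reconstructs_levels_losslessly(self, nprng):
        branch = DeformableBranch(nprng, depth=0)
        aligned = branch.align_channels(_fake_pyramid(nprng))
        shapes = branch.level_shapes(aligned)
        starts = branch.level_starts(shapes)
        mem = branch.tokenize(aligned)
        for a, (h, w), s0 in zip(aligned, shapes, starts):
            level = mem.data[:, s0: s0 + h * w].transpose(0, 2, 1)
            assert np.array_equal(level.reshape(a.shape), a.data)

    def test_zero_memory_projects_to_broadcast_biases(self, nprng):
        branch = DeformableBranch(nprng, depth=0)
        shapes = np.array([[4, 4], [2, 2], [2, 2], [1, 1], [1, 1]], np.int64)
        mem = Tensor(np.zeros((1, 26, 256), np.float32))
        outs = branch.split_project(mem, shapes)
        for conv, out in zip(branch.out_projs, outs):
            expected = np.broadcast_to(conv.bias.data[None, :, None, None],
                                       out.shape)
            assert np.allclose(out.data, expected, atol=1e-6)

    def test_branch_output_widths(self, nprng, branch):
        t_pyr = branch(_fake_pyramid(nprng))
        assert [t.shape[1] for t in t_pyr] == [48, 96, 192, 384, 768]
        assert [t.shape[-1] for t in t_pyr] == [16, 8, 4, 2, 1]

    def test_encoder_outputs_finite_over_seeds(self):
        for seed in range(3):
            nprng = np.random.default_rng(seed)
            branch = DeformableBranch(nprng, depth=1)
            out = branch(_fake_pyramid(nprng))
            assert all(np.isfinite(t.data).all() for t in out)
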