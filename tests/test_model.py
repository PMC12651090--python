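"""Full network assembly: decoder ladder, head, forward contracts,
parameter accounting and checkpointing."""

import numpy as np
import pytest

from msdtcn.config import ModelConfig
from msdtcn.model import (MSDTCNNet, count_parameters, load_checkpoint,
                          save_checkpoint)
from msdtcn.nn.tensor import Tensor

TINY = dict(convnext_depths=(1, 1, 1, 1), transformer_depth=1, dropout=0.0)


@pytest.fixture(scope="module")
def tiny_model():
    return MSDTCNNet(ModelConfig(**TINY, seed=1)).eval()


class TestDecoder:
    def test_upsample_halves_channels_doubles_space(self, tiny_model, rng):
        x = Tensor(rng.standard_normal((1, 768, 3, 5)).astype(np.float32))
        out = tiny_model.ups[0](x)
        assert out.shape == (1, 384, 6, 10)

    def test_upsample_zero_weights_zero_output(self, rng):
        m = MSDTCNNet(ModelConfig(**TINY, seed=2))
        up = m.ups[1]
        up.up.weight.data[...] = 0.0
        up.up.bias.data[...] = 0.0
        x = Tensor(rng.standard_normal((1, 384, 4, 4)).astype(np.float32))
        assert not up(x).data.any()

    def test_decode_with_zero_skips_is_pure_upsampling_chain(self, tiny_model,
                                                            rng):
        f4 = Tensor(rng.standard_normal((1, 768, 2, 2)).astype(np.float32))
        zeros = [Tensor(np.zeros((1, c, s, s), np.float32))
                 for c, s in ((384, 4), (192, 8), (96, 16), (48, 32))]
        states = tiny_model.decode(f4, *zeros)
        chain = f4
        for up, state in zip(tiny_model.ups, states[1:]):
            chain = up(chain)
            assert np.array_equal(state.data, chain.data)

    def test_decode_linear_in_skip_contributions(self, tiny_model, rng):
        f4 = Tensor(rng.standard_normal((1, 768, 2, 2)).astype(np.float32))
        a = rng.standard_normal((1, 384, 4, 4)).astype(np.float32)
        b = rng.standard_normal((1, 384, 4, 4)).astype(np.float32)
        rest = [Tensor(np.zeros((1, c, s, s), np.float32))
                for c, s in ((192, 8), (96, 16), (48, 32))]
        d3_sum = tiny_model.decode(f4, Tensor(a + b), *rest)[1]
        d3_a = tiny_model.decode(f4, Tensor(a), *rest)[1]
        assert np.allclose(d3_sum.data, d3_a.data + b, atol=1e-5)

    def test_bilinear_upsample_variant_shapes(self, rng):
        m = MSDTCNNet(ModelConfig(**TINY, decoder_upsample="bilinear", seed=3))
        x = Tensor(rng.standard_normal((1, 768, 2, 2)).astype(np.float32))
        assert m.ups[0](x).shape == (1, 384, 4, 4)


class TestHead:
    def test_head_upsamples_to_input_resolution(self, tiny_model, rng):
        d0 = Tensor(rng.standard_normal((1, 48, 8, 8)).astype(np.float32))
        assert tiny_model.head(d0).shape == (1, 1, 16, 16)

    def test_multiclass_head_width(self, rng):
        m = MSDTCNNet(ModelConfig(**TINY, n_classes=3, seed=4))
        d0 = Tensor(rng.standard_normal((1, 48, 8, 8)).astype(np.float32))
        assert m.head(d0).shape == (1, 3, 16, 16)

    def test_zero_weights_constant_bias_logits(self, rng):
        m = MSDTCNNet(ModelConfig(**TINY, seed=5))
        for conv in (m.head_up, m.head_conv1, m.head_conv2):
            conv.weight.data[...] = 0.0
            conv.bias.data[...] = 0.0
        m.head_conv2.bias.data[...] = -2.5
        d0 = Tensor(rng.standard_normal((1, 48, 4, 4)).astype(np.float32))
        assert np.allclose(m.head(d0).data, -2.5)


class TestForward:
    def test_end_to_end_shape_contract_at_64(self, tiny_model, rng):
        x = rng.standard_normal((1, 3, 64, 64)).astype(np.float32)
        assert tiny_model.forward(x).shape == (1, 1, 64, 64)

    def test_forward_deterministic_in_eval_mode(self, tiny_model, rng):
        x = rng.standard_normal((1, 3, 64, 64)).astype(np.float32)
        a = tiny_model.predict_proba(x)
        b = tiny_model.predict_proba(x)
        assert np.array_equal(a, b)

    def test_batch_items_independent(self, tiny_model, rng):
        x = rng.standard_normal((1, 3, 64, 64)).astype(np.float32)
        batch = np.concatenate([x, x])
        out = tiny_model.predict_proba(batch)
        assert np.allclose(out[0], out[1], atol=1e-5)

    def test_deepest_fused_level_bypasses_msrf(self, tiny_model):
        """MSRF runs on the three intermediate fused levels and on the
        shallow transformer map only; no MSRF instance has width 768."""
        widths = [m.base.conv.weight.shape[0] for m in tiny_model.msrfs]
        assert widths == [96, 192, 384]
        assert tiny_model.msrf_shallow.base.conv.weight.shape[0] == 48
        assert 768 not in widths

    def test_gradient_reaches_every_parameter_after_warmup(self, rng):
        """After one optimizer step, every trainable parameter (including
        the positional level embedding behind the zero-initialized offset
        heads) receives a nonzero gradient."""
        from msdtcn.losses import hybrid_loss
        from msdtcn.nn import Adam
        from msdtcn.nn.tensor import sigmoid
        m = MSDTCNNet(ModelConfig(convnext_depths=(1, 1, 1, 1),
                                  transformer_depth=2, dropout=0.0, seed=3))
        opt = Adam(m.parameters(), lr=1e-3, betas=(0.5, 0.999))
        x = rng.standard_normal((2, 3, 64, 64)).astype(np.float32)
        y = (rng.random((2, 1, 64, 64)) > 0.7).astype(np.float32)
        for _ in range(2):
            loss = hybrid_loss(sigmoid(m.forward(x)), Tensor(y))
            loss.backward(free_memory=True)
            dead = [n for n, p in m.named_parameters()
                    if p.grad is None or not np.any(p.grad)]
            opt.step()
            opt.zero_grad()
        assert dead == []


class TestParameterCount:
    def test_extra_classes_add_exact_head_weights(self):
        base = count_parameters(ModelConfig(**TINY, n_classes=1, seed=0))
        tri = count_parameters(ModelConfig(**TINY, n_classes=3, seed=0))
        assert tri - base == 2 * (32 * 9) + 2

    def test_transformer_depth_adds_exact_per_layer_block(self):
        d2 = count_parameters(ModelConfig(convnext_depths=(1, 1, 1, 1),
                                          transformer_depth=2, seed=0))
        d4 = count_parameters(ModelConfig(convnext_depths=(1, 1, 1, 1),
                                          transformer_depth=4, seed=0))
        d6 = count_parameters(ModelConfig(convnext_depths=(1, 1, 1, 1),
                                          transformer_depth=6, seed=0))
        per_layer = (d4 - d2) // 2
        assert d6 - d4 == 2 * per_layer
        # offsets + weights + value/output proj + FFN + 2 norms at width 256
        expected = (256 * 320 + 320) + (256 * 160 + 160) + 2 * (256 * 256 + 256) \
            + (256 * 1024 + 1024) + (1024 * 256 + 256) + 2 * 512
        assert per_layer == expected

    def test_random_vs_fixed_seed_same_count(self):
        assert (count_parameters(ModelConfig(**TINY, seed=0))
                == count_parameters(ModelConfig(**TINY, seed=99)))


class TestCheckpoint:
    def test_roundtrip_restores_weights_and_outputs(self, tmp_path, rng):
        m = MSDTCNNet(ModelConfig(**TINY, seed=6)).eval()
        x = rng.standard_normal((1, 3, 64, 64)).astype(np.float32)
        before = m.predict_proba(x)
        path = tmp_path / "ckpt.msdtcn"
        save_checkpoint(path, m, extra={"note": "test"})
        restored, extra = load_checkpoint(path)
        assert extra == {"note": "test"}
        after = restored.eval().predict_proba(x)
        assert np.array_equal(before, after)
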