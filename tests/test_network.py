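"""Sub-pixel operator oracles and encoder-decoder contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ventseg.network import (FeatureMap, ModelConfig, SegModel, build_model,
                             subpixel_inverse, subpixel_rearrange,
                             subpixel_stage)


def brute_force_rearrange(x, r):
    """Independent index-arithmetic oracle: o[i,j,c] = x[i//r, j//r,
    c*r*r + (i%r)*r + (j%r)]."""
    h, w, crr = x.shape
    c = crr // (r * r)
    out = np.empty((h * r, w * r, c), dtype=x.dtype)
    for i in range(h * r):
        for j in range(w * r):
            for cc in range(c):
                out[i, j, cc] = x[i // r, j // r, cc * r * r + (i % r) * r + (j % r)]
    return out


class TestSubpixelRearrange:
    def test_exhaustive_small_tensors(self):
        rng = np.random.default_rng(0)
        for h in (1, 2, 3):
            for w in (1, 2, 3):
                for r in (1, 2, 3):
                    for c in (1, 2):
                        x = rng.normal(size=(h, w, c * r * r))
                        np.testing.assert_array_equal(
                            subpixel_rearrange(x, r), brute_force_rearrange(x, r))

    def test_documented_2x2_example(self):
        x = np.array([[[0.0, 1.0, 2.0, 3.0]]])  # 1x1x4, values v0..v3
        np.testing.assert_array_equal(
            subpixel_rearrange(x, 2)[:, :, 0], [[0.0, 1.0], [2.0, 3.0]])

    def test_r1_is_identity(self):
        x = np.random.default_rng(1).normal(size=(3, 4, 5))
        np.testing.assert_array_equal(subpixel_rearrange(x, 1), x)

    def test_rejects_indivisible_channels(self):
        with pytest.raises(ValueError, match="divisible"):
            subpixel_rearrange(np.zeros((2, 2, 6)), 2)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(1, 4), st.integers(1, 4), st.integers(1, 3),
           st.integers(1, 3), st.integers(0, 2**31 - 1))
    def test_bijection_and_multiset(self, h, w, r, c, seed):
        x = np.random.default_rng(seed).normal(size=(h, w, c * r * r))
        y = subpixel_rearrange(x, r)
        assert y.shape == (h * r, w * r, c)
        np.testing.assert_array_equal(subpixel_inverse(y, r), x)
        assert sorted(y.ravel()) == sorted(x.ravel())


class TestSubpixelStage:
    def test_identity_kernel_reduces_to_rearrange(self):
        rng = np.random.default_rng(2)
        c_in, r = 8, 2
        x = rng.normal(size=(3, 3, c_in)).astype(np.float64)
        w = np.eye(c_in)[:, :, None, None]  # 1x1 identity convolution
        b = np.zeros(c_in)
        out = subpixel_stage(FeatureMap(x), w, b, r)
        np.testing.assert_allclose(out.tensor, subpixel_rearrange(x, r),
                                   atol=1e-12)
        assert out.level == 1

    def test_zero_weights_constant_bias(self):
        x = np.random.default_rng(3).normal(size=(2, 2, 4))
        w = np.zeros((8, 4, 3, 3))
        out = subpixel_stage(FeatureMap(x), w, np.full(8, 2.5), 2)
        np.testing.assert_allclose(out.tensor, 2.5)

    @pytest.mark.parametrize("r", [1, 2, 4])
    def test_output_scale(self, r):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(5, 3, 4))
        w = rng.normal(size=(2 * r * r, 4, 3, 3))
        out = subpixel_stage(FeatureMap(x), w, np.zeros(2 * r * r), r)
        assert out.tensor.shape == (5 * r, 3 * r, 2)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channels"):
            subpixel_stage(FeatureMap(np.zeros((2, 2, 3))),
                           np.zeros((4, 5, 1, 1)), np.zeros(4), 2)


class TestModel:
    def test_config_rejects_inconsistent_upscale(self):
        with pytest.raises(ValueError, match="downsampling"):
            ModelConfig(upscale_factor=3)

    def test_same_seed_same_parameters(self):
        a, b = build_model(ModelConfig(seed=9)), build_model(ModelConfig(seed=9))
        for la, lb in zip(a.layers(), b.layers()):
            for k in la.params:
                np.testing.assert_array_equal(la.params[k], lb.params[k])

    def test_probabilities_normalized_64x64(self):
        m = build_model(ModelConfig(seed=0))
        p = m.predict_proba(np.random.default_rng(0)
                            .normal(size=(64, 64, 3)).astype(np.float32))
        assert p.shape == (64, 64, 2)
        np.testing.assert_allclose(p.sum(axis=2), 1.0, atol=1e-5)
        assert (p >= 0).all()

    def test_not_degenerate_at_init(self):
        m = build_model(ModelConfig(seed=0))
        p0 = m.predict_proba(np.zeros((32, 32, 3), dtype=np.float32))
        p1 = m.predict_proba(np.ones((32, 32, 3), dtype=np.float32))
        assert not np.allclose(p0, p1)

    @pytest.mark.parametrize("hw", [(32, 32), (30, 34), (17, 23)])
    def test_shape_contract_with_padding(self, hw):
        m = build_model(ModelConfig(seed=1))
        x = np.random.default_rng(2).normal(size=(*hw, 3)).astype(np.float32)
        assert m.predict_proba(x).shape == (*hw, 2)

    def test_pretrained_unavailable_raises(self):
        with pytest.raises(RuntimeError, match="pretrained=False"):
            build_model(ModelConfig(encoder="resnet34", pretrained=True))

    def test_resnet34_forward_shape(self):
        m = build_model(ModelConfig(encoder="resnet34", seed=0))
        x = np.random.default_rng(0).normal(size=(64, 64, 3)).astype(np.float32)
        p = m.predict_proba(x)
        assert p.shape == (64, 64, 2)
        np.testing.assert_allclose(p.sum(axis=2), 1.0, atol=1e-5)

    def test_checkpoint_round_trip(self, tmp_path):
        m = build_model(ModelConfig(seed=3, skip_connections=False))
        p1 = tmp_path / "m.npz"
        m.save(p1)
        m2 = SegModel.load(p1)
        assert m2.config.skip_connections is False
        p2 = tmp_path / "m2.npz"
        m2.save(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_one_supervised_step_reduces_loss(self):
        """Gradient flow: an optimizer step on one sample lowers its loss."""
        from ventseg.nn import SGD, softmax
        from ventseg.objectives import supervised_loss, supervised_loss_grad
        from ventseg.nn import softmax_backward

        m = build_model(ModelConfig(seed=4))
        m.set_training(True)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(1, 3, 32, 32)).astype(np.float32)
        y = (rng.random((1, 32, 32)) < 0.3).astype(np.int64)
        opt = SGD(m.layers(), lr=0.05)

        def step():
            opt.zero_grad()
            p = softmax(m.forward_logits(x), axis=1).transpose(0, 2, 3, 1)
            loss = supervised_loss(p, y)
            dp = supervised_loss_grad(p, y)
            m.backward(softmax_backward(p, dp, axis=3).transpose(0, 3, 1, 2))
            opt.step()
            return loss

        l0 = step()
        l1 = step()
        assert l1 < l0
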