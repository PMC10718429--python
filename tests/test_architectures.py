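import numpy as np
import pytest

from sharpseg.architectures import (ModelSpec, SegmentationModel, attention_gate,
                                    build_model, sharpen_features)
from sharpseg.nn import ops
from sharpseg.nn.autodiff import Var
from sharpseg.nn.layers import AttentionGate
from sharpseg.nn.ops import SHARPEN_KERNEL


def brute_force_sharpen(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Independent sliding-window depthwise convolution with edge replication."""
    B, H, W, C = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)), mode="edge")
    out = np.zeros_like(x, dtype=float)
    for b in range(B):
        for i in range(H):
            for j in range(W):
                for c in range(C):
                    acc = 0.0
                    for di in range(3):
                        for dj in range(3):
                            acc += kernel[di, dj] * xp[b, i + di, j + dj, c]
                    out[b, i, j, c] = acc
    return out


class TestSharpenFeatures:
    def test_kernel_is_dc_preserving(self):
        assert SHARPEN_KERNEL.sum() == pytest.approx(1.0)
        assert (SHARPEN_KERNEL == np.array([[0, -1, 0], [-1, 5, -1], [0, -1, 0]])).all()

    def test_constant_map_is_fixed_point(self):
        x = np.full((1, 7, 5, 3), 4.25, dtype=np.float32)
        assert np.allclose(sharpen_features(x), x, atol=1e-6)

    def test_impulse_response(self):
        x = np.zeros((1, 5, 5, 1), dtype=np.float32)
        x[0, 2, 2, 0] = 1.0
        out = sharpen_features(x)[0, :, :, 0]
        assert np.allclose(out[1:4, 1:4], SHARPEN_KERNEL)
        assert out[0, 0] == 0 and out[4, 4] == 0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            shape = (1, int(rng.integers(3, 9)), int(rng.integers(3, 9)),
                     int(rng.integers(1, 5)))
            x = rng.standard_normal(shape).astype(np.float32)
            assert np.allclose(sharpen_features(x),
                               brute_force_sharpen(x, SHARPEN_KERNEL), atol=1e-5)

    def test_row_ramp_against_oracle(self):
        x = np.arange(5, dtype=np.float32).reshape(1, 1, 5, 1)
        assert np.allclose(sharpen_features(x),
                           brute_force_sharpen(x, SHARPEN_KERNEL), atol=1e-6)


class TestAttentionGate:
    def test_zero_weights_halve_input(self, rng):
        gate = AttentionGate(c_skip=3, c_gate=4, rng=rng)
        for layer in (gate.upsample, gate.w_x, gate.w_g, gate.w_s):
            layer.w.data[:] = 0.0
        x = rng.standard_normal((2, 8, 8, 3)).astype(np.float32)
        g = rng.standard_normal((2, 4, 4, 4)).astype(np.float32)
        out = attention_gate(x, g, gate)
        # swish(0)=0, sigmoid(0)=0.5, so every coefficient is exactly 1/2
        assert np.allclose(out, 0.5 * x, atol=1e-7)

    def test_scalar_toy_chain(self, rng):
        """1-pixel, 1-channel gate with unit weights: a = sigmoid(swish(2))."""
        gate = AttentionGate(c_skip=1, c_gate=1, rng=rng, c_int=1)
        gate.upsample.w.data[:] = 1.0  # upsampled gating signal equals g
        gate.w_x.w.data[:] = 1.0
        gate.w_g.w.data[:] = 1.0
        gate.w_s.w.data[:] = 1.0
        x = np.ones((1, 2, 2, 1), dtype=np.float32)
        g = np.ones((1, 1, 1, 1), dtype=np.float32)
        out = attention_gate(x, g, gate)
        expected = 1.0 / (1.0 + np.exp(-2.0 / (1.0 + np.exp(-2.0)) * 2.0 / 2.0))
        # sigmoid(swish(1+1)) = sigmoid(2*sigmoid(2)) ~ 0.8534
        assert out.flat[0] == pytest.approx(0.8534, abs=2e-4)
        assert out.flat[0] == pytest.approx(expected, abs=1e-6)

    def test_coefficients_strictly_in_unit_interval(self, rng):
        gate = AttentionGate(c_skip=4, c_gate=8, rng=rng)
        x = Var((rng.standard_normal((2, 8, 8, 4)) * 3).astype(np.float32))
        g = Var((rng.standard_normal((2, 4, 4, 8)) * 3).astype(np.float32))
        a = gate.coefficients(x, g).data
        assert (a > 0).all() and (a < 1).all()

    def test_spatial_mismatch_rejected(self, rng):
        gate = AttentionGate(c_skip=2, c_gate=2, rng=rng)
        x = np.zeros((1, 8, 8, 2), dtype=np.float32)
        g = np.zeros((1, 2, 2, 2), dtype=np.float32)  # upsamples to 4x4, not 8x8
        with pytest.raises(ValueError):
            attention_gate(x, g, gate)


class TestBuildModel:
    @pytest.mark.parametrize("variant", ["unet", "sharp", "attention", "sharp_attention"])
    def test_output_shape_and_codomain(self, variant):
        spec = ModelSpec(variant=variant, depth=3, base_filters=4, input_side=32)
        model = build_model(spec, seed=0)
        x = np.random.default_rng(1).random((2, 32, 32, 1)).astype(np.float32)
        probs = model.predict(x)
        assert probs.shape == (2, 32, 32, 1)
        assert (probs > 0).all() and (probs < 1).all()

    def test_sharp_and_unet_parameter_counts_equal(self):
        kwargs = dict(depth=4, base_filters=4, input_side=32)
        unet = build_model(ModelSpec(variant="unet", **kwargs), seed=0)
        sharp = build_model(ModelSpec(variant="sharp", **kwargs), seed=0)
        assert unet.parameter_count() == sharp.parameter_count()

    def test_sharp_attention_site_counts(self):
        spec = ModelSpec(variant="sharp_attention", depth=4, base_filters=4,
                         input_side=32)
        model = build_model(spec, seed=0)
        assert model.n_sharpen_sites == 3  # deepest sharpening filter removed
        assert model.n_attention_gates == 4

    def test_invalid_input_side(self):
        with pytest.raises(ValueError):
            ModelSpec(variant="unet", depth=4, input_side=100)

    def test_forward_determinism_without_dropout(self):
        spec = ModelSpec(variant="sharp_attention", depth=2, base_filters=4,
                         input_side=16)
        model = build_model(spec, seed=3)
        x = np.random.default_rng(0).random((2, 16, 16, 1)).astype(np.float32)
        assert (model.predict(x) == model.predict(x)).all()

    @pytest.mark.parametrize("variant", ["unet", "sharp", "attention", "sharp_attention"])
    def test_gradient_reaches_every_parameter(self, variant):
        spec = ModelSpec(variant=variant, depth=2, base_filters=4, input_side=16)
        model = build_model(spec, seed=4)
        r = np.random.default_rng(5)
        x = r.random((2, 16, 16, 1)).astype(np.float32)
        y = (r.random((2, 16, 16, 1)) < 0.3).astype(np.float32)
        logits = model.forward(x, training=False)
        loss, _, _ = ops.bce_dice_from_logits(logits, y)
        loss.backward()
        for p in model.parameters():
            assert p.grad is not None and np.any(p.grad != 0)

    def test_save_load_round_trip(self, tmp_path):
        spec = ModelSpec(variant="attention", depth=2, base_filters=4, input_side=16)
        model = build_model(spec, seed=6)
        x = np.random.default_rng(2).random((1, 16, 16, 1)).astype(np.float32)
        before = model.predict(x)
        model.save(tmp_path / "ckpt")
        loaded = SegmentationModel.load(tmp_path / "ckpt")
        assert loaded.spec == spec
        assert np.allclose(loaded.predict(x), before)
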