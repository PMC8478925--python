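"""Adversarial staining model: losses, gradients, training, stitching."""

from types import SimpleNamespace

import numpy as np
import pytest

from virtualck import nn
from virtualck.stains import StainBasis
from virtualck.virtual_stain import (
    LossTerms,
    ModelState,
    TrainingConfig,
    compute_losses,
    generate_and_stitch,
    generator_forward,
    hed_transform,
    train,
)

from conftest import reduced_training_config


def hed_l1_oracle(y: np.ndarray, yhat: np.ndarray, eps: float = 1.0) -> float:
    """Independent re-implementation: per-pixel OD, 3x3 solve, mean abs diff.

    Works on HxWx3 uint8 arrays; deliberately uses a linear solve rather than
    the cached inverse used by the implementation.
    """
    basis = StainBasis().matrix
    def to_hed(img):
        od = -np.log10((img.astype(float) + eps) / 255.0)
        return np.linalg.solve(basis.T, od.reshape(-1, 3).T).T
    return float(np.mean(np.abs(to_hed(y) - to_hed(yhat))))


class TestComputeLosses:
    def _scores(self, value, shape=(1, 4, 4)):
        return np.full(shape, value)

    def test_identical_images_have_zero_l1(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        y = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        terms = compute_losses(x, y, y.copy(), self._scores(0.5), self._scores(0.5), TrainingConfig())
        assert terms.l1_rgb == 0.0
        assert terms.l1_hed == 0.0

    def test_constant_offset_l1_rgb(self):
        x = np.full((8, 8, 3), 100, dtype=np.uint8)
        y = np.full((8, 8, 3), 120, dtype=np.uint8)
        yhat = np.full((8, 8, 3), 110, dtype=np.uint8)
        terms = compute_losses(x, y, yhat, self._scores(0.5), self._scores(0.5), TrainingConfig())
        assert terms.l1_rgb == pytest.approx(10 / 255, abs=1e-12)

    def test_l1_hed_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        cfg = TrainingConfig()
        for _ in range(20):
            x = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
            y = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
            yhat = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
            terms = compute_losses(x, y, yhat, self._scores(0.5), self._scores(0.5), cfg)
            assert terms.l1_hed == pytest.approx(hed_l1_oracle(y, yhat), abs=1e-6)

    def test_total_is_linear_in_lambdas(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        y = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        yhat = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        sr, sf = self._scores(0.7), self._scores(0.3)

        def total(l1, l2):
            return compute_losses(x, y, yhat, sr, sf, TrainingConfig(lambda1=l1, lambda2=l2)).total

        t00, t10, t01 = total(0, 0), total(1, 0), total(0, 1)
        assert total(10, 0.9) == pytest.approx(t00 + 10 * (t10 - t00) + 0.9 * (t01 - t00), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_losses(
                np.zeros((8, 8, 3), np.uint8),
                np.zeros((8, 8, 3), np.uint8),
                np.zeros((4, 4, 3), np.uint8),
                self._scores(0.5),
                self._scores(0.5),
                TrainingConfig(),
            )


class TestGradients:
    """Finite-difference checks of the hand-written backward passes."""

    @pytest.mark.parametrize("layer_factory", [
        lambda rng: nn.Conv2d(2, 3, rng),
        lambda rng: nn.ConvTranspose2d(3, 2, rng),
        lambda rng: nn.InstanceNorm(3),
        lambda rng: nn.Sequential([nn.Conv2d(3, 4, rng), nn.LeakyReLU(0.2), nn.InstanceNorm(4)]),
    ])
    def test_parameter_and_input_gradients(self, layer_factory):
        rng = np.random.default_rng(0)
        layer = layer_factory(rng)
        cin = getattr(layer, "cin", 3)
        x = rng.standard_normal((cin, 8, 8)).astype(np.float32)
        weight = rng.standard_normal(layer.forward(x).shape).astype(np.float32)

        def loss(inp):
            return float(np.sum(layer.forward(inp) * weight))

        layer.zero_grad()
        layer.forward(x)
        gx = layer.backward(weight)
        # input gradient
        h = 1e-3
        for idx in [(0, 2, 3), (cin - 1, 7, 1)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            num = (loss(xp) - loss(xm)) / (2 * h)
            assert gx[idx] == pytest.approx(num, rel=5e-2, abs=5e-3)
        # parameter gradient (first parameter tensor, one entry)
        params = layer.params()
        if params:
            layer.zero_grad()
            layer.forward(x)
            layer.backward(weight)
            p, g = params[0]
            flat_idx = 1
            orig = p.flat[flat_idx]
            p.flat[flat_idx] = orig + h
            lp = loss(x)
            p.flat[flat_idx] = orig - h
            lm = loss(x)
            p.flat[flat_idx] = orig
            assert g.flat[flat_idx] == pytest.approx((lp - lm) / (2 * h), rel=5e-2, abs=5e-3)

    def test_hed_transform_gradient(self):
        rng = np.random.default_rng(3)
        from virtualck.virtual_stain import _l1_hed

        y = rng.uniform(0.1, 0.9, (3, 4, 4))
        yhat = rng.uniform(0.1, 0.9, (3, 4, 4))
        loss, grad = _l1_hed(y, yhat, StainBasis(), 1.0)
        h = 1e-6
        for idx in [(0, 1, 2), (2, 3, 3)]:
            yp, ym = yhat.copy(), yhat.copy()
            yp[idx] += h
            ym[idx] -= h
            lp = _l1_hed(y, yp, StainBasis(), 1.0)[0]
            lm = _l1_hed(y, ym, StainBasis(), 1.0)[0]
            assert grad[idx] == pytest.approx((lp - lm) / (2 * h), rel=1e-3)


class TestGenerator:
    def test_output_shape_and_range(self, tiny_model, training_pairs):
        out = generator_forward(training_pairs[0].he, tiny_model)
        assert out.pixels.shape == training_pairs[0].he.shape
        assert out.pixels.dtype == np.uint8

    def test_inference_is_deterministic(self, tiny_model, training_pairs):
        a = generator_forward(training_pairs[0].he, tiny_model).pixels
        b = generator_forward(training_pairs[0].he, tiny_model).pixels
        assert np.array_equal(a, b)

    def test_indivisible_size_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            generator_forward(np.zeros((66, 66, 3), np.uint8), tiny_model)


class TestTraining:
    def test_l1_decreases_from_initial(self, tiny_model):
        assert tiny_model.loss_log[-1]["l1_rgb"] < tiny_model.initial_l1_rgb

    def test_loss_log_length_matches_epochs(self, training_pairs):
        class _DS:
            pairs = training_pairs[:2]

        cfg = reduced_training_config(seed=1, epochs=3, max_g_steps=None)
        state = train(_DS(), cfg)
        assert len(state.loss_log) == 3

    def test_empty_dataset_rejected(self):
        class _DS:
            pairs = []

        with pytest.raises(ValueError):
            train(_DS(), reduced_training_config())

    def test_generated_dab_area_tracks_truth(self, tiny_model, training_pairs):
        """On phantoms where CK is a deterministic recoloring of H&E content,
        the generated DAB-positive area should land near the true tumor area."""
        from virtualck.tsr import tumor_mask

        true_frac = np.mean([tumor_mask(p.ck).mean() for p in training_pairs])
        gen_frac = np.mean(
            [tumor_mask(generator_forward(p.he, tiny_model).pixels).mean() for p in training_pairs]
        )
        assert abs(gen_frac - true_frac) <= 0.10


class TestStitching:
    def _identity_model(self):
        return ModelState(
            generator=SimpleNamespace(forward=lambda x: x),
            discriminator=None,
            config=TrainingConfig(),
        )

    def test_identity_stub_round_trips_region(self):
        rng = np.random.default_rng(0)
        region = rng.integers(0, 256, (128, 192, 3), dtype=np.uint8)
        out = generate_and_stitch(region, self._identity_model(), tile=64)
        assert np.array_equal(out.pixels, region)
        assert not out.margin_filled

    def test_margins_filled_white_and_flagged(self):
        region = np.zeros((100, 130, 3), dtype=np.uint8)
        out = generate_and_stitch(region, self._identity_model(), tile=64)
        assert out.margin_filled
        assert out.covered == (64, 128)
        assert np.all(out.pixels[64:] == 255)
        assert np.all(out.pixels[:, 128:] == 255)

    def test_tile_zero_matches_single_forward(self, tiny_model, small_phantom):
        he = small_phantom[0].pixels[:128, :128]
        stitched = generate_and_stitch(he, tiny_model, tile=64)
        single = generator_forward(he[:64, :64], tiny_model)
        assert np.array_equal(stitched.pixels[:64, :64], single.pixels)

    def test_too_small_region_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            generate_and_stitch(np.zeros((32, 32, 3), np.uint8), tiny_model, tile=64)
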