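"""Registration: adaptive masking, FFT cross-correlation, shift recovery."""

import numpy as np
import pytest

from virtualck.phantoms import make_shifted_pair
from virtualck.registration import (
    DegenerateInputError,
    ShiftVector,
    estimate_global_shift,
    estimate_local_shifts,
    registration_mask,
    shift_from_cross_correlation,
)

from conftest import brute_force_shift


def gaussian_weighted_mean_oracle(img: np.ndarray, block_size: int) -> np.ndarray:
    """Direct (non-separable) Gaussian-weighted local mean with reflect
    padding — the independent oracle for the adaptive threshold."""
    sigma = (block_size - 1) / 6.0
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    w1 = np.exp(-(x**2) / (2 * sigma**2))
    w1 /= w1.sum()
    w2 = np.outer(w1, w1)
    pad = np.pad(img.astype(float), radius, mode="reflect")
    out = np.empty_like(img, dtype=float)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            out[r, c] = np.sum(pad[r : r + 2 * radius + 1, c : c + 2 * radius + 1] * w2)
    return out


class TestRegistrationMask:
    def test_bright_square_on_dark_background(self):
        """A bright block is foreground while the dark surround, lifted above
        threshold by the wide Gaussian window, is rejected."""
        img = np.full((64, 64), 10.0)
        img[22:42, 22:42] = 200.0
        mask = registration_mask(img, block_size=151, offset=10, min_area=0)
        assert mask[22:42, 22:42].all()
        outside = mask.copy()
        outside[22:42, 22:42] = False
        assert not outside.any()
        # independent oracle: thresholds agree, so masks agree
        oracle = gaussian_weighted_mean_oracle(img, 151) - 10
        assert np.array_equal(mask, img > oracle)

    def test_small_object_removal_boundary(self):
        img = np.zeros((64, 64))
        img[2:12, 2:17] = 200  # area 150 -> removed
        img[30:40, 30:50] = 200  # area 200 -> kept
        mask = registration_mask(img, block_size=15, offset=10, min_area=200)
        assert not mask[2:12, 2:17].any()
        assert mask[30:40, 30:50].all()

    def test_shift_equivariance(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (96, 96))
        shifted = np.roll(img, (5, 7), axis=(0, 1))
        m1 = registration_mask(img, block_size=15, offset=10, min_area=0)
        m2 = registration_mask(shifted, block_size=15, offset=10, min_area=0)
        interior = np.s_[20:76, 20:76]
        assert np.array_equal(np.roll(m1, (5, 7), axis=(0, 1))[interior], m2[interior])

    def test_even_block_rejected(self):
        with pytest.raises(ValueError):
            registration_mask(np.zeros((32, 32)), block_size=10)


class TestCrossCorrelationShift:
    def test_identical_masks_give_zero(self):
        rng = np.random.default_rng(1)
        m = rng.random((32, 32)) > 0.5
        s = shift_from_cross_correlation(m, m)
        assert (s.drow, s.dcol) == (0, 0)

    def test_planted_translation_recovered(self):
        base = np.zeros((32, 32), dtype=bool)
        base[4:10, 12:20] = True
        moved = np.roll(base, (12, -7), axis=(0, 1))
        s = shift_from_cross_correlation(base, moved)
        assert (s.drow, s.dcol) == (12, -7)

    def test_fft_equals_brute_force_on_random_masks(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            a = rng.random((16, 16)) > 0.6
            b = rng.random((16, 16)) > 0.6
            if not a.any() or not b.any():
                continue
            s = shift_from_cross_correlation(a, b)
            assert (s.drow, s.dcol) == brute_force_shift(a, b)

    def test_empty_mask_raises(self):
        with pytest.raises(DegenerateInputError):
            shift_from_cross_correlation(np.zeros((8, 8), bool), np.ones((8, 8), bool))


class TestGlobalShift:
    def test_planted_multiple_of_downsample_recovered_exactly(self, registration_phantom):
        he, ck, _ = make_shifted_pair(registration_phantom, ShiftVector(64, -96))
        s = estimate_global_shift(he, ck, downsample=32)
        assert (s.drow, s.dcol) == (64, -96)

    def test_zero_shift_pair(self, registration_phantom):
        he, ck, _ = registration_phantom
        s = estimate_global_shift(he, ck, downsample=32)
        assert (s.drow, s.dcol) == (0, 0)

    def test_non_multiple_shift_within_quantization(self, registration_phantom):
        he, ck, _ = make_shifted_pair(registration_phantom, ShiftVector(70, 0))
        s = estimate_global_shift(he, ck, downsample=32)
        assert abs(s.drow - 70) <= 32 and abs(s.dcol) <= 32

    def test_blank_slide_raises(self):
        white = np.full((256, 256, 3), 255, dtype=np.uint8)
        with pytest.raises(DegenerateInputError):
            estimate_global_shift(white, white, downsample=4, block_size=15, min_area=10)


class TestLocalShifts:
    def test_uniform_planted_shift_recovered_per_region(self, planted_shift_pair):
        he, ck, truth = planted_shift_pair
        g = estimate_global_shift(he, ck, downsample=32)
        local = estimate_local_shifts(
            he, ck, g, region_size=1024, patch_size=256, block_size=51, min_area=50
        )
        for _, s in local.entries:
            assert (s.drow, s.dcol) == (64, -96)

    def test_residual_shift_recovered_exactly(self, registration_phantom):
        he, ck, _ = make_shifted_pair(registration_phantom, ShiftVector(70, 0))
        g = estimate_global_shift(he, ck, downsample=32)
        local = estimate_local_shifts(
            he, ck, g, region_size=1024, patch_size=256, block_size=51, min_area=50
        )
        for _, s in local.entries:
            assert (s.drow, s.dcol) == (70, 0)

    def test_corrupted_patch_rejected_by_mad_rule(self, planted_shift_pair):
        he, ck, _ = planted_shift_pair
        rng = np.random.default_rng(9)
        ck_px = ck.pixels.copy()
        # corrupt one aligned patch with noise to provoke a wild shift
        ck_px[1088:1344, 1088 - 96 : 1344 - 96] = rng.integers(0, 256, (256, 256, 3), dtype=np.uint8)
        g = estimate_global_shift(he, ck_px, downsample=32)
        local = estimate_local_shifts(
            he, ck_px, g, region_size=1024, patch_size=256, block_size=51, min_area=50
        )
        s = local.shift_at((1024, 1024))
        assert abs(s.drow - 64) <= 1 and abs(s.dcol + 96) <= 1

    def test_all_white_region_falls_back_to_global(self):
        white = np.full((256, 256, 3), 255, dtype=np.uint8)
        g = ShiftVector(8, -8)
        local = estimate_local_shifts(white, white, g, region_size=256, patch_size=128,
                                      block_size=15, min_area=10)
        assert local.entries == [((0, 0), ShiftVector(8, -8, 1))]
        assert local.inlier_counts[(0, 0)] == 0

    def test_invalid_region_patch_combination(self):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            estimate_local_shifts(img, img, ShiftVector(0, 0), region_size=100, patch_size=64)
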