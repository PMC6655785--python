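"""Phase correlation, rotation recovery, and the slope-consistency filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.transform import rotate

import slidealign as sa
from slidealign.registration import integer_phase_correlate

from conftest import tissue_crop


@pytest.fixture()
def crop(fixed_level0):
    rng = np.random.default_rng(0)
    return tissue_crop(fixed_level0, rng, 256)


class TestGrayscale:
    def test_luminance_weights(self):
        white = sa.Patch(np.full((4, 4, 3), 255, np.uint8), 0, (0, 0), (4, 4))
        assert (sa.to_grayscale(white) == 255).all()
        red = np.zeros((4, 4, 3), np.uint8)
        red[..., 0] = 255
        np.testing.assert_allclose(sa.to_grayscale(red), 0.299 * 255)

    def test_grayscale_passthrough(self):
        arr = np.arange(16.0).reshape(4, 4)
        np.testing.assert_array_equal(sa.to_grayscale(arr), arr)


class TestPhaseCorrelate:
    def test_identical_patches_zero_shift_max_score(self, crop):
        s = sa.phase_correlate(crop, crop)
        assert (s.dx, s.dy) == (0.0, 0.0)
        assert s.score == pytest.approx(1.0, abs=1e-6)
        assert s.success

    def test_integer_circular_shift_recovered_exactly(self, crop):
        rolled = np.roll(crop, (-3, 5), axis=(0, 1))
        assert integer_phase_correlate(crop, rolled) == (5, -3)

    def test_antisymmetry(self, crop):
        rolled = np.roll(crop, (7, -11), axis=(0, 1))
        ab = sa.phase_correlate(crop, rolled)
        ba = sa.phase_correlate(rolled, crop)
        assert ab.dx == pytest.approx(-ba.dx, abs=0.1)
        assert ab.dy == pytest.approx(-ba.dy, abs=0.1)

    def test_independent_noise_fails_under_floor(self):
        rng = np.random.default_rng(3)
        a = rng.normal(128, 30, (256, 256))
        b = rng.normal(128, 30, (256, 256))
        assert not sa.phase_correlate(a, b).success

    def test_constant_input_is_failure(self, crop):
        flat = np.full_like(crop, 128.0)
        s = sa.phase_correlate(crop, flat)
        assert not s.success and s.score == 0.0

    def test_shape_mismatch_raises(self, crop):
        with pytest.raises(ValueError, match="mismatch"):
            sa.phase_correlate(crop, crop[:-1])

    def test_subpixel_spectral_shift(self, crop):
        """A band-limited 2.5 px shift is recovered within a quarter pixel."""
        ky = np.fft.fftfreq(256)[:, None]
        kx = np.fft.fftfreq(256)[None, :]
        shifted = np.fft.ifft2(np.fft.fft2(crop) * np.exp(-2j * np.pi * kx * 2.5)).real
        s = sa.phase_correlate(crop, shifted)
        assert 2.25 <= s.dx <= 2.75
        assert abs(s.dy) <= 0.25

    def test_agrees_with_skimage_reference(self, crop):
        """Independent cross-check against scikit-image's phase correlation."""
        from skimage.registration import phase_cross_correlation

        rolled = np.roll(crop, (9, -6), axis=(0, 1))
        s = sa.phase_correlate(crop, rolled)
        (ref_dy, ref_dx), _, _ = phase_cross_correlation(
            crop, rolled, upsample_factor=64, normalization="phase"
        )
        # scikit-image reports the shift needed to register moving onto
        # reference, i.e. the negative of our floating-onto-fixed offset
        assert s.dx == pytest.approx(-ref_dx, abs=0.05)
        assert s.dy == pytest.approx(-ref_dy, abs=0.05)

    def test_score_decreases_with_noise(self, fixed_level0):
        """Median match score over 20 seeds never rises with extra noise."""
        rng = np.random.default_rng(1)
        crop = tissue_crop(fixed_level0, rng, 128)
        medians = []
        for sigma in (0.0, 15.0, 40.0):
            scores = []
            for seed in range(20):
                noisy = crop + np.random.default_rng(seed).normal(0, sigma, crop.shape)
                scores.append(sa.phase_correlate(crop, noisy).score)
            medians.append(np.median(scores))
        assert medians[0] >= medians[1] >= medians[2]

    @settings(max_examples=15, deadline=None)
    @given(a=st.integers(-31, 31), b=st.integers(-31, 31))
    def test_shift_theorem_property(self, fixed_level0, a, b):
        crop = tissue_crop(fixed_level0, np.random.default_rng(7), 128)
        assert integer_phase_correlate(crop, np.roll(crop, (b, a), axis=(0, 1))) == (a, b)


class TestRotation:
    def test_unrotated_pair_near_zero(self, crop):
        theta, _ = sa.estimate_rotation(crop, crop)
        assert abs(theta) <= 0.1

    def test_three_degree_rotation_recovered(self, crop):
        q = rotate(crop, 3.0, mode="edge", preserve_range=True)
        theta, _ = sa.estimate_rotation(crop, q)
        assert theta == pytest.approx(3.0, abs=0.5)

    def test_rotation_disabled_passthrough(self, crop):
        rgb = np.stack([crop.astype(np.uint8)] * 3, axis=-1)
        p = sa.Patch(rgb, 1, (0, 0), (256, 256))
        s = sa.register_patch_pair(p, p, rotation_enabled=False)
        assert s.theta == 0.0


class TestRegisterPatchPair:
    def test_known_residual_recovered(self, crop):
        rolled = np.roll(crop, (-4, 7), axis=(0, 1))
        p1 = sa.Patch(np.stack([crop.astype(np.uint8)] * 3, -1), 2, (32, 16), (256, 256))
        p2 = sa.Patch(np.stack([rolled.astype(np.uint8)] * 3, -1), 2, (32, 16), (256, 256))
        s = sa.register_patch_pair(p1, p2)
        assert s.dx == pytest.approx(7, abs=0.5)
        assert s.dy == pytest.approx(-4, abs=0.5)
        assert s.level == 2 and s.patch_origin_l0 == (32, 16)

    def test_blank_glass_pair_fails(self):
        blank = sa.Patch(np.full((64, 64, 3), 255, np.uint8), 1, (0, 0), (64, 64))
        assert not sa.register_patch_pair(blank, blank).success

    def test_rotated_pair_recovers_theta_and_shift(self, crop):
        from scipy import ndimage

        q = rotate(crop, 2.0, mode="edge", preserve_range=True)
        q = ndimage.shift(q, (3, 7), order=3, mode="nearest")
        p1 = sa.Patch(np.stack([crop.astype(np.uint8)] * 3, -1), 1, (0, 0), (256, 256))
        p2 = sa.Patch(np.stack([q.astype(np.uint8)] * 3, -1), 1, (0, 0), (256, 256))
        s = sa.register_patch_pair(p1, p2, rotation_enabled=True)
        assert s.theta == pytest.approx(2.0, abs=0.5)
        assert s.dx == pytest.approx(7, abs=1.0)
        assert s.dy == pytest.approx(3, abs=1.0)

    def test_level_mismatch_raises(self, crop):
        rgb = np.stack([crop.astype(np.uint8)] * 3, -1)
        p1 = sa.Patch(rgb, 1, (0, 0), (256, 256))
        p2 = sa.Patch(rgb, 2, (0, 0), (256, 256))
        with pytest.raises(ValueError, match="same pyramid level"):
            sa.register_patch_pair(p1, p2)


class TestSlopeFilter:
    def test_common_displacement_all_kept(self):
        matches = [
            sa.MatchPair((x, y), (x + 10.0, y + 4.0))
            for x, y in [(5, 5), (40, 80), (90, 20), (130, 100)]
        ]
        assert sa.filter_matches_by_slope(matches, tolerance=5.0) == matches

    def test_single_outlier_removed(self):
        # 9 parallel pairs + 1 whose connecting line is ~40 degrees off
        good = [
            sa.MatchPair((float(x), float(y)), (float(x + 8), float(y + 3)))
            for x, y in [(10, 10), (20, 60), (35, 30), (50, 90), (70, 15),
                         (85, 55), (100, 75), (115, 25), (125, 95)]
        ]
        bad = sa.MatchPair((60.0, 50.0), (68.0, 480.0))
        kept = sa.filter_matches_by_slope(good + [bad], tolerance=5.0)
        assert bad not in kept
        assert set(map(id, good)) <= set(map(id, kept))

    def test_empty_input(self):
        assert sa.filter_matches_by_slope([], tolerance=5.0) == []
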