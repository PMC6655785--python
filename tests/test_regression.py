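"""Cross-level scaling, the weighted slope fit, and the global estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import slidealign as sa
from slidealign.registration import OffsetSample

SCALING = sa.LevelScaling((1.0, 4.0, 16.0, 32.0))


def sample(dx, dy, level=1, score=0.8, success=True, theta=0.0):
    return OffsetSample(dx, dy, theta=theta, score=score, level=level, success=success)


def make_pool(rng, truth, sigma_local, n_per_level=30, outlier_frac=0.0,
              levels=(1, 2, 3)):
    """Simulated per-patch offsets: level-local truth + noise, plus outliers
    drawn uniformly in the level-0 square [-200, 200]^2."""
    pool = []
    for lv in levels:
        d = SCALING.downsample(lv)
        for _ in range(n_per_level):
            if rng.random() < outlier_frac:
                ox, oy = rng.uniform(-200, 200, 2)
                pool.append(sample(ox / d, oy / d, lv))
            else:
                dx = truth[0] / d + rng.normal(0, sigma_local)
                dy = truth[1] / d + rng.normal(0, sigma_local)
                pool.append(sample(dx, dy, lv))
    return pool


def pooled_mean_estimate(pool):
    """Naive baseline: unweighted mean of the level-0-scaled offsets."""
    pts = np.array(
        [[s.dx * SCALING.downsample(s.level), s.dy * SCALING.downsample(s.level)]
         for s in pool]
    )
    return pts.mean(axis=0)


class TestScaling:
    @pytest.mark.parametrize(
        "dx,dy,level,expected",
        [(3, -2, 2, (48, -32)), (5, 7, 0, (5, 7)), (1.5, 0, 3, (48, 0))],
    )
    def test_scale_offset(self, dx, dy, level, expected):
        out = sa.scale_offset_to_level0(sample(dx, dy, level), SCALING)
        assert (out.dx, out.dy) == expected
        assert out.level == 0

    def test_unknown_level_raises(self):
        with pytest.raises(IndexError):
            sa.scale_offset_to_level0(sample(1, 1, level=7), SCALING)

    def test_resolution_ratios_match_expected_pyramid(self):
        assert [SCALING.resolution_ratio(l) for l in (1, 2, 3)] == [0.25, 0.25, 0.5]


class TestWeightedSlope:
    def test_collinear_points_exact(self):
        pts = np.array([[1.0, 2.0], [3.0, 6.0], [-2.0, -4.0]])
        m, swapped = sa.fit_weighted_slope(pts, np.array([1.0, 5.0, 2.0]))
        assert m == pytest.approx(2.0, rel=1e-14)
        assert not swapped

    def test_weighted_two_point_hand_computation(self):
        pts = np.array([[1.0, 1.0], [1.0, 3.0]])
        m, _ = sa.fit_weighted_slope(pts, np.array([3.0, 1.0]))
        assert m == pytest.approx(1.5)

    def test_near_vertical_axis_swap(self):
        pts = np.array([[0.0, 10.0], [0.0, 40.0], [0.0, 25.0]])
        m, swapped = sa.fit_weighted_slope(pts, np.ones(3))
        assert swapped and m == pytest.approx(0.0)

    def test_matches_grid_search_minimizer(self):
        """Closed form equals brute-force minimization of the weighted
        squared residual cost within one grid step."""
        rng = np.random.default_rng(8)
        grid = np.arange(-10.0, 10.0001, 1e-4)
        for _ in range(20):
            n = rng.integers(5, 30)
            pts = rng.normal(0, 5, (n, 2))
            w = rng.uniform(0.05, 1.0, n)
            m, swapped = sa.fit_weighted_slope(pts, w)
            assert not swapped
            cost = (
                w[None, :] * (pts[None, :, 1] - grid[:, None] * pts[None, :, 0]) ** 2
            ).sum(axis=1)
            m_grid = grid[int(np.argmin(cost))]
            assert abs(m - m_grid) <= 1e-4 + 1e-9

    @settings(max_examples=40, deadline=None)
    @given(
        m_true=st.floats(-5, 5),
        xs=st.lists(st.floats(0.5, 50), min_size=2, max_size=8),
    )
    def test_recovers_exact_slope_from_line(self, m_true, xs):
        pts = np.array([[x, m_true * x] for x in xs])
        m, swapped = sa.fit_weighted_slope(pts, np.ones(len(xs)))
        assert not swapped
        assert m == pytest.approx(m_true, abs=1e-9)


class TestGlobalTransform:
    def test_exact_recovery_noise_free(self):
        truth = (100.0, -40.0)
        pool = make_pool(np.random.default_rng(0), truth, sigma_local=0.0)
        t = sa.estimate_global_transform(pool, SCALING)
        assert t.dx0 == pytest.approx(truth[0], abs=1e-9)
        assert t.dy0 == pytest.approx(truth[1], abs=1e-9)
        assert t.slope_m == pytest.approx(-0.4, abs=1e-9)
        assert all(r == pytest.approx(0.0, abs=1e-9) for r in t.per_level_residuals.values())

    def test_exact_recovery_any_level_subset(self):
        truth = (-60.0, 90.0)
        for levels in [(1,), (2, 3), (1, 3)]:
            pool = make_pool(np.random.default_rng(1), truth, 0.0, levels=levels)
            t = sa.estimate_global_transform(pool, SCALING)
            assert (t.dx0, t.dy0) == pytest.approx(truth, abs=1e-9)

    def test_initial_offset_added_back(self):
        truth = (100.0, -40.0)
        pre = (96.0, -32.0)
        pool = make_pool(np.random.default_rng(2), (truth[0] - pre[0], truth[1] - pre[1]), 0.0)
        t = sa.estimate_global_transform(pool, SCALING, initial=pre)
        assert (t.dx0, t.dy0) == pytest.approx(truth, abs=1e-9)

    def test_scale_equivariance(self):
        truth = (40.0, 24.0)
        pool = make_pool(np.random.default_rng(3), truth, sigma_local=0.5)
        t1 = sa.estimate_global_transform(pool, SCALING)
        doubled = sa.LevelScaling(tuple(2 * d for d in (1.0, 4.0, 16.0, 32.0)))
        t2 = sa.estimate_global_transform(pool, doubled)
        assert t2.dx0 == pytest.approx(2 * t1.dx0, rel=1e-12)
        assert t2.dy0 == pytest.approx(2 * t1.dy0, rel=1e-12)

    def test_no_successful_samples_degrades_to_initial(self):
        pool = [sample(1, 1, success=False)]
        t = sa.estimate_global_transform(pool, SCALING, initial=(10.0, 20.0))
        assert t.quality_flag == "degraded"
        assert (t.dx0, t.dy0) == (10.0, 20.0)

    def test_gaussian_noise_median_error_bound(self):
        """sigma = 2 level-local px, 30 patches x 3 levels: median level-0
        error over 100 seeds stays below 6 px."""
        truth = (100.0, -40.0)
        errs = []
        for seed in range(100):
            pool = make_pool(np.random.default_rng(seed), truth, sigma_local=2.0)
            t = sa.estimate_global_transform(pool, SCALING)
            errs.append(math.hypot(t.dx0 - truth[0], t.dy0 - truth[1]))
        assert np.median(errs) < 6.0

    def test_kde_beats_pooled_mean_with_outliers(self):
        truth = (100.0, -40.0)
        kde_err, mean_err = [], []
        for seed in range(100):
            pool = make_pool(
                np.random.default_rng(seed), truth, sigma_local=1.0, outlier_frac=0.3
            )
            t = sa.estimate_global_transform(pool, SCALING)
            kde_err.append(math.hypot(t.dx0 - truth[0], t.dy0 - truth[1]))
            mx, my = pooled_mean_estimate(pool)
            mean_err.append(math.hypot(mx - truth[0], my - truth[1]))
        assert np.median(kde_err) < np.median(mean_err)

    def test_weighting_mode_validation(self):
        with pytest.raises(ValueError):
            sa.estimate_global_transform([sample(1, 1)], SCALING, weighting_mode="bogus")

    def test_theta_weighted_circular_mean(self):
        pool = [sample(10, 10, theta=1.0), sample(10, 10, theta=2.0)]
        t = sa.estimate_global_transform(pool, SCALING)
        assert t.theta == pytest.approx(1.5, abs=1e-9)


class TestEvaluateError:
    def test_identical_zero(self):
        t = sa.GlobalTransform(5.0, 6.0)
        assert sa.evaluate_error(t, t) == (0.0, 0.0, 0.0)

    def test_three_four_five(self):
        e, ex, ey = sa.evaluate_error(
            sa.GlobalTransform(3.0, 4.0), sa.GlobalTransform(0.0, 0.0)
        )
        assert (e, ex, ey) == (5.0, 3.0, 4.0)
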