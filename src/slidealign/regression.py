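"""Cross-level fusion of weighted offsets into one level-0 transform.

Pyramid levels of a WSI are exact rescalings of one scene, so a patch offset
``(dx, dy)`` measured at a level with downsample ``D`` corresponds to
``D · (dx, dy)`` at level 0.  After scaling, offsets from every level should
coincide; in practice each level contributes a noisy cloud.  Two mechanisms
combine them robustly:

* every sample carries a KDE consensus weight (see :mod:`slidealign.kde`)
  plus a per-level factor ``R_l`` — the resolution ratio of the level to the
  next finer one (``{0.25, 0.25, 0.5}`` for a 1:4:16:32 pyramid);
* a weighted regression through the origin of ``y`` offsets against ``x``
  offsets recovers the direction of the true displacement, and the weighted
  projection of the cloud onto that direction gives the point estimate.

The regression cost is the weighted **squared** residual
``Σ R_l · f̂ · (y − m·x)²`` — an unsquared residual would be unbounded
below — with the closed-form minimizer ``m = Σ w·x·y / Σ w·x²``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .kde import kde_weights
from .registration import OffsetSample

__all__ = [
    "GlobalTransform",
    "LevelScaling",
    "scale_offset_to_level0",
    "fit_weighted_slope",
    "estimate_global_transform",
    "evaluate_error",
]


@dataclass(frozen=True)
class GlobalTransform:
    """Final level-0 rigid transform plus fit diagnostics.

    ``dx0``/``dy0`` include the initial thumbnail offset.  ``slope_m`` is the
    fitted ratio dy0/dx0 of the regression line through the origin;
    ``per_level_residuals`` maps level index to the weighted RMS distance of
    that level's scaled samples from the estimate.
    """

    dx0: float
    dy0: float
    theta: float = 0.0
    slope_m: float = float("nan")
    n_samples_used: int = 0
    per_level_residuals: dict[int, float] = field(default_factory=dict)
    quality_flag: str = "ok"

    def as_dict(self) -> dict:
        return {
            "dx0": self.dx0,
            "dy0": self.dy0,
            "theta_deg": self.theta,
            "slope_m": self.slope_m,
            "n_samples": self.n_samples_used,
            "quality_flag": self.quality_flag,
        }


@dataclass(frozen=True)
class LevelScaling:
    """Per-level downsample factors and derived cross-level ratios."""

    downsample_per_level: tuple[float, ...]

    def downsample(self, level: int) -> float:
        if not 0 <= level < len(self.downsample_per_level):
            raise IndexError(f"unknown level {level}")
        return self.downsample_per_level[level]

    def resolution_ratio(self, level: int) -> float:
        """R_l: pixel-pitch ratio of this level to the next finer level.

        For a 1:4:16:32 pyramid the used levels 1..3 give {0.25, 0.25, 0.5}.
        Level 0 has no finer neighbour; its ratio to level 1 is used.
        """
        ds = self.downsample_per_level
        if not 0 <= level < len(ds):
            raise IndexError(f"unknown level {level}")
        if level == 0:
            return ds[0] / ds[1]
        return ds[level - 1] / ds[level]


def scale_offset_to_level0(sample: OffsetSample, scaling: LevelScaling) -> OffsetSample:
    """Map a level-local offset to the level-0 frame: multiply by downsample."""
    d = scaling.downsample(sample.level)
    return replace(sample, dx=sample.dx * d, dy=sample.dy * d, level=0)


def fit_weighted_slope(
    points: np.ndarray, weights: np.ndarray
) -> tuple[float, bool]:
    """Weighted least squares through the origin: minimize Σ w (y − m·x)².

    Returns ``(m, swapped)``.  When the weighted energy on the x axis
    vanishes (near-vertical displacement), the axes are swapped and the
    inverse slope is fitted instead; ``swapped=True`` flags that the line is
    parameterized as ``x = m'·y``.
    """
    points = np.asarray(points, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if points.shape[0] < 1:
        raise ValueError("no points")
    x, y = points[:, 0], points[:, 1]
    sxx = float(np.sum(weights * x * x))
    syy = float(np.sum(weights * y * y))
    sxy = float(np.sum(weights * x * y))
    if sxx == 0.0 and syy == 0.0:
        return 0.0, False
    # near-vertical displacement: fit x = m'·y on the better-conditioned axis
    if sxx <= 1e-9 * syy:
        return sxy / syy, True
    return sxy / sxx, False


def _direction(m: float, swapped: bool) -> np.ndarray:
    u = np.array([m, 1.0]) if swapped else np.array([1.0, m])
    return u / math.hypot(u[0], u[1])


def _circular_mean(thetas: np.ndarray, weights: np.ndarray) -> float:
    rad = np.radians(thetas)
    c = float(np.sum(weights * np.cos(rad)))
    s = float(np.sum(weights * np.sin(rad)))
    if c == 0.0 and s == 0.0:
        return 0.0
    return math.degrees(math.atan2(s, c))


def estimate_global_transform(
    samples: list[OffsetSample],
    scaling: LevelScaling,
    initial: tuple[float, float] = (0.0, 0.0),
    *,
    weighting_mode: str = "kde",
    regression_mode: str = "projection",
    kde_per_level: bool = False,
    kde_include_failures: bool = False,
    kde_diagonal: bool = False,
    use_theta_weights: bool = False,
) -> GlobalTransform:
    """Fuse per-patch offsets from all levels into one level-0 transform.

    Pipeline: scale every sample to level 0 → consensus-weight the pooled
    offsets (``kde`` | ``score`` | ``uniform``) → multiply in the per-level
    ratio R_l → fit the slope through the origin → project the weighted
    cloud onto the fitted direction (``projection``) or take the plain
    weighted mean (``weighted_mean``) → add back the initial thumbnail
    offset.  θ is the weighted circular mean of the sample angles.

    With no usable samples the initial offset is returned with
    ``quality_flag="degraded"``.
    """
    if weighting_mode not in ("kde", "score", "uniform"):
        raise ValueError(f"unknown weighting_mode {weighting_mode!r}")
    if regression_mode not in ("projection", "weighted_mean"):
        raise ValueError(f"unknown regression_mode {regression_mode!r}")
    pool = samples if kde_include_failures else [s for s in samples if s.success]
    if not pool:
        return GlobalTransform(
            initial[0], initial[1], quality_flag="degraded", n_samples_used=0
        )
    scaled = [scale_offset_to_level0(s, scaling) for s in pool]
    levels = np.array([s.level for s in pool])
    pts = np.array([[s.dx, s.dy] for s in scaled])

    if weighting_mode == "kde":
        conf = _kde_confidence(
            scaled, levels, per_level=kde_per_level,
            diagonal=kde_diagonal, use_theta=use_theta_weights,
        )
    elif weighting_mode == "score":
        sc = np.array([s.score for s in pool])
        conf = sc / sc.max() if sc.max() > 0 else np.ones(len(pool))
    else:
        conf = np.ones(len(pool))

    rl = np.array([scaling.resolution_ratio(int(l)) for l in levels])
    w = rl * conf
    if w.sum() == 0.0:
        w = rl.copy()

    m, swapped = fit_weighted_slope(pts, w)
    if regression_mode == "projection":
        u = _direction(m, swapped)
        s_hat = float(np.sum(w * (pts @ u)) / w.sum())
        est = s_hat * u
    else:
        est = np.array(
            [np.sum(w * pts[:, 0]) / w.sum(), np.sum(w * pts[:, 1]) / w.sum()]
        )

    slope = (1.0 / m if swapped and m != 0.0 else (math.inf if swapped else m))
    theta = _circular_mean(np.array([s.theta for s in pool]), w)

    residuals: dict[int, float] = {}
    for lv in sorted(set(int(l) for l in levels)):
        sel = levels == lv
        r2 = np.sum(w[sel] * np.sum((pts[sel] - est) ** 2, axis=1))
        residuals[lv] = float(np.sqrt(r2 / w[sel].sum())) if w[sel].sum() > 0 else 0.0

    return GlobalTransform(
        dx0=float(est[0] + initial[0]),
        dy0=float(est[1] + initial[1]),
        theta=theta,
        slope_m=float(slope),
        n_samples_used=len(pool),
        per_level_residuals=residuals,
    )


def _kde_confidence(
    scaled: list[OffsetSample],
    levels: np.ndarray,
    *,
    per_level: bool,
    diagonal: bool,
    use_theta: bool,
) -> np.ndarray:
    if not per_level:
        wo = kde_weights(scaled, use_theta=use_theta, diagonal_bandwidth=diagonal)
        return np.array([w.weight for w in wo])
    conf = np.empty(len(scaled))
    for lv in set(int(l) for l in levels):
        idx = np.flatnonzero(levels == lv)
        wo = kde_weights(
            [scaled[i] for i in idx], use_theta=use_theta, diagonal_bandwidth=diagonal
        )
        conf[idx] = [w.weight for w in wo]
    return conf


def evaluate_error(
    estimate: GlobalTransform, truth: GlobalTransform
) -> tuple[float, float, float]:
    """Euclidean level-0 registration error plus per-axis signed errors."""
    ex = estimate.dx0 - truth.dx0
    ey = estimate.dy0 - truth.dy0
    return math.hypot(ex, ey), ex, ey
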