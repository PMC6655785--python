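"""Consensus weighting of patch offsets by kernel density estimation.

Similarity scores returned by patch registration do not reliably separate
good alignments from failures on re-stained pairs — the two stains differ in
hue, contrast and local detail, so a failed alignment can still score high.
What failures cannot do is *agree with each other*: correct offsets from many
patches of one slide pair cluster tightly, while failures scatter.  A
bivariate Gaussian KDE over the pooled offsets therefore measures each
sample's consistency with the pool, and the normalized density becomes its
confidence weight.

Bandwidth follows Scott's rule, ``h = n^(-1/(d+4))``, applied as a scalar
factor to the sample covariance (equal factor on both axes — there is no
prior reason to smooth x and y differently).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .registration import OffsetSample

__all__ = [
    "WeightedOffset",
    "KdeModel",
    "scott_bandwidth",
    "kde_weights",
    "kde_mode",
    "kde_density",
    "weighted_pool_to_frame",
]


@dataclass(frozen=True)
class WeightedOffset:
    """An offset sample plus its KDE confidence."""

    sample: OffsetSample
    density: float
    weight: float


@dataclass(frozen=True)
class KdeModel:
    """Fitted KDE parameters: bandwidth factor h, 2×2 bandwidth matrix H."""

    h: float
    H: np.ndarray
    n: int
    d: int = 2


def scott_bandwidth(n: int, d: int) -> float:
    """Scott's-rule bandwidth factor ``n**(-1/(d+4))``."""
    if n < 1:
        raise ValueError("need at least one sample")
    if d < 1:
        raise ValueError("dimensionality must be >= 1")
    return float(n) ** (-1.0 / (d + 4))


def _bandwidth_matrix(points: np.ndarray, diagonal: bool) -> np.ndarray | None:
    """H = h² Σ̂ (or h² σ̂² I when ``diagonal``); None when degenerate."""
    n = points.shape[0]
    h = scott_bandwidth(n, 2)
    if diagonal:
        var = float(points.var(axis=0, ddof=1).mean())
        if var <= 0.0:
            return None
        return h * h * var * np.eye(2)
    cov = np.cov(points.T, ddof=1)
    if not np.all(np.isfinite(cov)) or np.linalg.det(cov) <= 0.0:
        # fall back to an isotropic bandwidth when the covariance is singular
        var = float(points.var(axis=0, ddof=1).mean())
        if var <= 0.0:
            return None
        return h * h * var * np.eye(2)
    return h * h * cov


def kde_density(points: np.ndarray, eval_points: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Gaussian-mixture density: mean of bivariate normals N(·; pᵢ, H)."""
    Hinv = np.linalg.inv(H)
    norm = 1.0 / (2.0 * np.pi * np.sqrt(np.linalg.det(H)))
    diff = eval_points[:, None, :] - points[None, :, :]  # m × n × 2
    q = np.einsum("mni,ij,mnj->mn", diff, Hinv, diff)
    return norm * np.exp(-0.5 * q).mean(axis=1)


def kde_weights(
    samples: list[OffsetSample],
    *,
    use_theta: bool = False,
    diagonal_bandwidth: bool = False,
) -> list[WeightedOffset]:
    """Weight each offset by its normalized pool density.

    Offsets must already be expressed in a common frame (scaled to level 0
    before pooling).  Degenerate pools — a single sample, or zero variance —
    carry no disagreement to resolve and get uniform weight 1.  When
    ``use_theta``, a separate 1-D KDE over the rotation angles multiplies in.
    """
    if not samples:
        raise ValueError("empty sample pool")
    pts = np.array([[s.dx, s.dy] for s in samples], dtype=np.float64)
    n = len(samples)
    if n == 1:
        return [WeightedOffset(samples[0], float("nan"), 1.0)]
    H = _bandwidth_matrix(pts, diagonal_bandwidth)
    if H is None:
        dens = np.full(n, np.nan)
        weights = np.ones(n)
    else:
        dens = kde_density(pts, pts, H)
        weights = dens / dens.max()
    if use_theta:
        weights = weights * _theta_weights(np.array([s.theta for s in samples]))
        weights = weights / weights.max()
    return [
        WeightedOffset(s, float(d), float(w))
        for s, d, w in zip(samples, dens, weights)
    ]


def _theta_weights(thetas: np.ndarray) -> np.ndarray:
    n = thetas.size
    sigma = float(np.std(thetas, ddof=1)) if n > 1 else 0.0
    if sigma == 0.0:
        return np.ones(n)
    h = sigma * scott_bandwidth(n, 1)
    d = np.exp(-0.5 * ((thetas[:, None] - thetas[None, :]) / h) ** 2).sum(axis=1)
    return d / d.max()


def weighted_pool_to_frame(pool: list[WeightedOffset]):
    """Weighted pool as a DataFrame: all offset fields plus density, weight."""
    import pandas as pd

    return pd.DataFrame(
        [{**w.sample.as_row(), "density": w.density, "weight": w.weight} for w in pool]
    )


def fit_kde(samples: list[OffsetSample], *, diagonal_bandwidth: bool = False) -> KdeModel | None:
    """Fitted model for diagnostics; None when the pool is degenerate."""
    pts = np.array([[s.dx, s.dy] for s in samples], dtype=np.float64)
    if pts.shape[0] < 2:
        return None
    H = _bandwidth_matrix(pts, diagonal_bandwidth)
    if H is None:
        return None
    return KdeModel(scott_bandwidth(len(samples), 2), H, len(samples))


def kde_mode(
    samples: list[OffsetSample],
    grid_resolution: float = 0.5,
    *,
    diagonal_bandwidth: bool = False,
) -> tuple[float, float]:
    """Argmax of the pooled density on a grid over the sample bounding box.

    Diagnostic output: the pipeline's final estimate comes from the weighted
    hierarchical regression, not from this mode.
    """
    if not samples:
        raise ValueError("empty sample pool")
    pts = np.array([[s.dx, s.dy] for s in samples], dtype=np.float64)
    if pts.shape[0] == 1 or (np.ptp(pts[:, 0]) == 0 and np.ptp(pts[:, 1]) == 0):
        return float(pts[0, 0]), float(pts[0, 1])
    H = _bandwidth_matrix(pts, diagonal_bandwidth)
    if H is None:
        return float(pts[:, 0].mean()), float(pts[:, 1].mean())
    pad = 2.0 * np.sqrt(np.diag(H))
    xs = np.arange(pts[:, 0].min() - pad[0], pts[:, 0].max() + pad[0], grid_resolution)
    ys = np.arange(pts[:, 1].min() - pad[1], pts[:, 1].max() + pad[1], grid_resolution)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    dens = kde_density(pts, grid, H)
    k = int(np.argmax(dens))
    return float(grid[k, 0]), float(grid[k, 1])
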