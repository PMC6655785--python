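"""Rigid registration of one fixed/floating patch pair.

The workhorse is Fourier phase correlation: the cross-power spectrum
``F1* · F2 / |F1* · F2|`` of two translated copies of the same scene is a
pure phase ramp, so its inverse transform is an impulse at the displacement.
Re-stained slides sit on the same glass, so a translation (plus at most a
small rotation) is the whole model — no scale, no affine, no deformation.

Sign convention: ``phase_correlate(fixed, floating) -> (dx, dy)`` such that
floating content appears at the fixed content's position **plus** (dx, dy),
i.e. ``floating(x, y) = fixed(x - dx, y - dy)``.

Also provided: a log-polar rotation estimator for the small-angle case, and
the slope-consistency filter for externally supplied keypoint matches
(matched points between two renditions of the same tissue must be joined by
near-parallel lines; matches whose line direction strays from the modal
direction are discarded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import rotate as _sk_rotate
from skimage.transform import warp_polar

from .pyramid_io import Patch

__all__ = [
    "OffsetSample",
    "MatchPair",
    "to_grayscale",
    "phase_correlate",
    "estimate_rotation",
    "register_patch_pair",
    "filter_matches_by_slope",
    "DEFAULT_SCORE_FLOOR",
]

# Peak of the whitened correlation surface for two unrelated 256^2 patches
# sits near 0.02; matched tissue patches score >= 0.1.  The floor separates
# the two populations with an order-of-magnitude margin on each side.  For
# smaller patches the null peak grows like sqrt(2 ln(hw) / hw), so the
# effective floor is the larger of this constant and a null-calibrated bound.
DEFAULT_SCORE_FLOOR = 0.05


def _null_peak_bound(h: int, w: int) -> float:
    """~3x the expected correlation peak for two unrelated patches."""
    n = h * w
    return 3.0 * math.sqrt(2.0 * math.log(n) / n)


@dataclass(frozen=True)
class OffsetSample:
    """One patch-pair registration result.

    ``dx``/``dy`` are level-local pixels, residual to any global pre-shift
    the caller applied before reading the floating patch.  ``score`` is the
    peak of the whitened correlation surface clipped to [0, 1]; ``success``
    is score >= the configured floor.
    """

    dx: float
    dy: float
    theta: float = 0.0
    score: float = 0.0
    level: int = 0
    patch_origin_l0: tuple[int, int] = (0, 0)
    success: bool = True

    def as_row(self) -> dict:
        return {
            "level": self.level,
            "origin_x": self.patch_origin_l0[0],
            "origin_y": self.patch_origin_l0[1],
            "dx": self.dx,
            "dy": self.dy,
            "theta": self.theta,
            "score": self.score,
            "success": self.success,
        }


@dataclass(frozen=True)
class MatchPair:
    """A matched keypoint pair from any external detector/matcher."""

    p_fixed: tuple[float, float]
    p_float: tuple[float, float]
    descriptor_distance: float = 0.0


def to_grayscale(patch: Patch | np.ndarray) -> np.ndarray:
    """Luminance conversion (0.299 R + 0.587 G + 0.114 B), float in [0, 255]."""
    pix = patch.pixels if isinstance(patch, Patch) else patch
    arr = np.asarray(pix, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError("expected H×W×3 or H×W input")
    return arr @ np.array([0.299, 0.587, 0.114])


def _cross_power_spectrum(fixed: np.ndarray, floating: np.ndarray, window: bool):
    f1 = fixed - fixed.mean()
    f2 = floating - floating.mean()
    if window:
        w = np.hanning(f1.shape[0])[:, None] * np.hanning(f1.shape[1])[None, :]
        f1 = f1 * w
        f2 = f2 * w
    F1 = np.fft.fft2(f1)
    F2 = np.fft.fft2(f2)
    R = np.conj(F1) * F2
    mag = np.abs(R)
    top = mag.max()
    if top == 0.0:
        return None
    # epsilon keeps the whitening finite where the spectrum vanishes
    return R / (mag + 1e-15 * top)


def _signed(idx: int, n: int) -> int:
    return idx - n if idx > n // 2 else idx


def _upsampled_argmax(
    R: np.ndarray, dx: float, dy: float, upsample: int, radius: float = 1.5
) -> tuple[float, float]:
    """Argmax of ifft2(R) on a fine grid around (dx, dy) by matrix DFT."""
    h, w = R.shape
    step = 1.0 / upsample
    ys = dy + np.arange(-radius, radius + step / 2, step)
    xs = dx + np.arange(-radius, radius + step / 2, step)
    ky = np.fft.fftfreq(h)[:, None]
    kx = np.fft.fftfreq(w)[:, None]
    Ey = np.exp(2j * np.pi * ky * ys[None, :])  # h × ny
    Ex = np.exp(2j * np.pi * kx * xs[None, :])  # w × nx
    C = (Ey.T @ R @ Ex).real / (h * w)
    iy, ix = np.unravel_index(int(np.argmax(C)), C.shape)
    return float(xs[ix]), float(ys[iy])


def _quadratic_offset(cm: float, c0: float, cp: float) -> float:
    den = cm - 2.0 * c0 + cp
    if den >= 0.0:
        return 0.0
    off = 0.5 * (cm - cp) / den
    return float(np.clip(off, -0.5, 0.5))


def phase_correlate(
    fixed: np.ndarray,
    floating: np.ndarray,
    *,
    window: bool = True,
    subpixel: str = "upsample",
    upsample_factor: int = 64,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> OffsetSample:
    """Register two equal-shaped grayscale arrays by phase correlation.

    Pipeline: mean removal → Hann window → cross-power spectrum → inverse
    transform → integer peak mapped to the signed range [-N/2, N/2) →
    subpixel refinement (``"upsample"``: local matrix-DFT evaluation of the
    correlation surface; ``"quadratic"``: 3-point parabola per axis;
    ``"none"``).  ``score`` is the integer-peak height of the normalized
    surface; ``success`` requires score >= max(``score_floor``, the
    null-calibrated bound for this patch size).
    """
    fixed = np.asarray(fixed, dtype=np.float64)
    floating = np.asarray(floating, dtype=np.float64)
    if fixed.shape != floating.shape:
        raise ValueError(f"shape mismatch: {fixed.shape} vs {floating.shape}")
    if fixed.ndim != 2:
        raise ValueError("phase_correlate expects 2-D arrays")
    if np.ptp(fixed) == 0.0 or np.ptp(floating) == 0.0:
        return OffsetSample(0.0, 0.0, score=0.0, success=False)
    R = _cross_power_spectrum(fixed, floating, window)
    if R is None:
        return OffsetSample(0.0, 0.0, score=0.0, success=False)
    corr = np.fft.ifft2(R).real
    h, w = corr.shape
    py, px = np.unravel_index(int(np.argmax(corr)), corr.shape)
    score = float(np.clip(corr[py, px], 0.0, 1.0))
    dx, dy = float(_signed(px, w)), float(_signed(py, h))
    if subpixel == "upsample":
        dx, dy = _upsampled_argmax(R, dx, dy, upsample_factor)
    elif subpixel == "quadratic":
        dx += _quadratic_offset(
            corr[py, (px - 1) % w], corr[py, px], corr[py, (px + 1) % w]
        )
        dy += _quadratic_offset(
            corr[(py - 1) % h, px], corr[py, px], corr[(py + 1) % h, px]
        )
    elif subpixel != "none":
        raise ValueError(f"unknown subpixel mode: {subpixel!r}")
    floor = max(score_floor, _null_peak_bound(h, w))
    return OffsetSample(dx, dy, score=score, success=score >= floor)


def integer_phase_correlate(
    fixed: np.ndarray, floating: np.ndarray, **kw
) -> tuple[int, int]:
    """Integer-stage shift only (no subpixel refinement)."""
    s = phase_correlate(fixed, floating, subpixel="none", **kw)
    return int(round(s.dx)), int(round(s.dy))


def _highpass_emphasis(shape: tuple[int, int]) -> np.ndarray:
    # suppress the low-frequency bulk of the centred magnitude spectrum,
    # which is angularly coarse and would otherwise dominate the correlation
    y = np.cos(np.linspace(-np.pi / 2, np.pi / 2, shape[0]))[:, None]
    x = np.cos(np.linspace(-np.pi / 2, np.pi / 2, shape[1]))[None, :]
    X = y * x
    return (1.0 - X) * (2.0 - X)


def estimate_rotation(
    fixed: np.ndarray,
    floating: np.ndarray,
    *,
    max_deg: float = 5.0,
    n_theta: int = 720,
) -> tuple[float, float]:
    """Recover a small rotation from the log-polar spectral magnitudes.

    Rotating an image rotates the magnitude of its Fourier spectrum by the
    same angle, and in a (log-)polar resampling that rotation becomes a
    shift along the angle axis, recoverable by phase correlation.  A
    high-pass emphasis is applied to the centred magnitude first.  The
    search is clipped to ±``max_deg`` — re-stained slides sit flat on the
    glass, so only small angles are physical.  Scale is fixed at 1.

    Returns (theta_degrees, score); theta follows the convention of
    ``skimage.transform.rotate``: the floating patch looks like
    ``rotate(fixed, theta)``.
    """
    fixed = np.asarray(fixed, dtype=np.float64)
    floating = np.asarray(floating, dtype=np.float64)
    if fixed.shape != floating.shape:
        raise ValueError("shape mismatch")
    if fixed.shape[0] != fixed.shape[1]:
        raise ValueError("rotation estimation expects square patches")
    radius = fixed.shape[0] // 2
    emphasis = _highpass_emphasis(fixed.shape)

    def logpolar_mag(img: np.ndarray) -> np.ndarray:
        img = img - img.mean()
        w = np.hanning(img.shape[0])[:, None] * np.hanning(img.shape[1])[None, :]
        mag = np.abs(np.fft.fftshift(np.fft.fft2(img * w))) * emphasis
        return warp_polar(
            mag, radius=radius, output_shape=(n_theta, radius), scaling="log", order=1
        )

    R = _cross_power_spectrum(logpolar_mag(fixed), logpolar_mag(floating), window=False)
    if R is None:
        return 0.0, 0.0
    corr = np.fft.ifft2(R).real
    # scale is fixed at 1: admit only a ±1 bin radial (log-scale) shift
    band = np.concatenate([corr[:, :2], corr[:, -1:]], axis=1)
    prof = band.max(axis=1)
    step = 360.0 / n_theta
    max_bins = int(math.ceil(max_deg / step))
    idx = np.arange(-max_bins, max_bins + 1)
    window_vals = prof[idx % n_theta]
    k = int(np.argmax(window_vals))
    score = float(np.clip(window_vals[k], 0.0, 1.0))
    shift_bins = float(idx[k]) + _quadratic_offset(
        prof[(idx[k] - 1) % n_theta], window_vals[k], prof[(idx[k] + 1) % n_theta]
    )
    # a positive image rotation shifts log-polar content to negative angle rows
    theta = -shift_bins * step
    return float(np.clip(theta, -max_deg, max_deg)), score


def register_patch_pair(
    fixed: Patch,
    floating: Patch,
    *,
    rotation_enabled: bool = False,
    rotation_max_deg: float = 5.0,
    score_floor: float = DEFAULT_SCORE_FLOOR,
    subpixel: str = "upsample",
) -> OffsetSample:
    """Full rigid registration of one fixed/floating patch pair.

    Grayscale → (optional) rotation estimation and derotation of the
    floating patch → phase correlation.  The returned (dx, dy) are
    level-local and exclude any global pre-shift applied when the floating
    patch was read; failed registrations come back with ``success=False``
    and stay in the pool for downstream down-weighting.
    """
    if fixed.level != floating.level:
        raise ValueError("patches must come from the same pyramid level")
    if fixed.pixels.shape != floating.pixels.shape:
        raise ValueError("patches must have the same size")
    g1 = to_grayscale(fixed)
    g2 = to_grayscale(floating)
    theta, rot_score = 0.0, 1.0
    if rotation_enabled and np.ptp(g1) > 0 and np.ptp(g2) > 0:
        theta, rot_score = estimate_rotation(g1, g2, max_deg=rotation_max_deg)
        if theta != 0.0:
            g2 = _sk_rotate(g2, -theta, mode="edge", preserve_range=True)
    s = phase_correlate(
        g1, g2, subpixel=subpixel, score_floor=score_floor
    )
    return replace(
        s,
        theta=theta,
        level=fixed.level,
        patch_origin_l0=fixed.origin_l0,
    )


def filter_matches_by_slope(
    matches: list[MatchPair],
    tolerance: float = 5.0,
    *,
    frame_offset: float | None = None,
    patch_width: float = 512.0,
) -> list[MatchPair]:
    """Keep keypoint matches whose connecting lines share the modal slope.

    With the floating frame drawn to the right of the fixed frame (offset by
    ``patch_width`` unless ``frame_offset`` is given), lines joining truly
    corresponding points are parallel; mismatches point elsewhere.  The modal
    direction is found by a 1-D Gaussian KDE over line angles and matches
    within ±``tolerance`` degrees of the mode are retained.
    """
    if not matches:
        return []
    off = patch_width if frame_offset is None else frame_offset
    angles = np.array(
        [
            math.degrees(
                math.atan2(
                    m.p_float[1] - m.p_fixed[1],
                    (m.p_float[0] + off) - m.p_fixed[0],
                )
            )
            for m in matches
        ]
    )
    mode = _kde_mode_1d(angles)
    dev = np.abs((angles - mode + 180.0) % 360.0 - 180.0)
    return [m for m, d in zip(matches, dev) if d <= tolerance]


def _kde_mode_1d(values: np.ndarray) -> float:
    """Mode of a 1-D Gaussian KDE with the Scott bandwidth factor."""
    n = values.size
    sigma = float(np.std(values))
    if n == 1 or sigma == 0.0:
        return float(np.median(values))
    h = sigma * n ** (-1.0 / 5.0)
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, 2048)
    dens = np.exp(-0.5 * ((grid[:, None] - values[None, :]) / h) ** 2).sum(axis=1)
    return float(grid[int(np.argmax(dens))])
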