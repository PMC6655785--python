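"""Tissue localisation, patch sampling, and the coarse thumbnail offset.

Brightfield slide background is blank glass — near-white — while tissue is
darker, so a brightness threshold on the grayscale thumbnail localises
content-rich area.  Patch origins are drawn only where the patch footprint is
mostly tissue: texture-free glass cannot be registered.  A coarse global
offset from thumbnail phase correlation pre-shifts all floating-image reads
so per-patch registration only resolves a small residual, keeping shifts far
from the wrap-around ambiguity of circular correlation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from . import registration
from .pyramid_io import Patch, PyramidImage, get_thumbnail
from .registration import OffsetSample, to_grayscale

__all__ = [
    "TissueMask",
    "SamplePlan",
    "tissue_mask",
    "sample_patch_locations",
    "initial_offset",
    "FALLBACK_THRESHOLD",
]

# Glass background in 8-bit brightfield scans sits above ~230; used when the
# histogram is too degenerate for Otsu.
FALLBACK_THRESHOLD = 220.0


@dataclass(frozen=True)
class TissueMask:
    """Boolean tissue map at thumbnail resolution."""

    mask: np.ndarray
    threshold: float
    coverage: float


@dataclass(frozen=True)
class SamplePlan:
    """Seeded patch-origin plan: level-0 origins grouped by pyramid level."""

    locations: dict[int, list[tuple[int, int]]]
    patches_per_level: int
    patch_size: int
    patch_size_by_level: dict[int, int]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "patches_per_level": self.patches_per_level,
                "patch_size": self.patch_size,
                "patch_size_by_level": {
                    str(k): v for k, v in self.patch_size_by_level.items()
                },
                "locations": {
                    str(k): [list(xy) for xy in v] for k, v in self.locations.items()
                },
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SamplePlan":
        d = json.loads(text)
        return cls(
            locations={
                int(k): [tuple(xy) for xy in v] for k, v in d["locations"].items()
            },
            patches_per_level=d["patches_per_level"],
            patch_size=d["patch_size"],
            patch_size_by_level={
                int(k): v for k, v in d["patch_size_by_level"].items()
            },
            seed=d["seed"],
        )


def tissue_mask(thumb: Patch | np.ndarray, threshold: float | str = "auto") -> TissueMask:
    """Threshold the thumbnail: tissue is darker than glass.

    ``"auto"`` picks the threshold by Otsu's bimodal-histogram criterion,
    falling back to a fixed near-white cut when the histogram is degenerate.
    Connected components smaller than 0.1% of the thumbnail are removed as
    debris.
    """
    gray = to_grayscale(thumb)
    if threshold == "auto":
        thr = FALLBACK_THRESHOLD if np.ptp(gray) == 0 else float(threshold_otsu(gray))
    else:
        thr = float(threshold)
    mask = gray < thr
    min_size = max(int(0.001 * mask.size), 1)
    if mask.any():
        # drop debris components covering < 0.1% of the thumbnail
        mask = remove_small_objects(mask, max_size=min_size - 1)
    coverage = float(mask.mean())
    if coverage == 0.0:
        warnings.warn("tissue mask is empty (blank slide?)", stacklevel=2)
    return TissueMask(mask, thr, coverage)


def _integral(mask: np.ndarray) -> np.ndarray:
    ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(mask.astype(np.int64), axis=0), axis=1)
    return ii


def _tissue_fraction(ii: np.ndarray, x0f: float, y0f: float, x1f: float, y1f: float) -> float:
    h, w = ii.shape[0] - 1, ii.shape[1] - 1
    x0, y0 = int(np.clip(np.floor(x0f), 0, w)), int(np.clip(np.floor(y0f), 0, h))
    x1, y1 = int(np.clip(np.ceil(x1f), 0, w)), int(np.clip(np.ceil(y1f), 0, h))
    area = (x1 - x0) * (y1 - y0)
    if area <= 0:
        return 0.0
    s = ii[y1, x1] - ii[y0, x1] - ii[y1, x0] + ii[y0, x0]
    return s / area


def sample_patch_locations(
    mask: TissueMask,
    img: PyramidImage,
    patches_per_level: int,
    levels: list[int] | None = None,
    patch_size: int = 512,
    seed: int = 0,
    *,
    min_tissue_fraction: float = 0.5,
) -> SamplePlan:
    """Draw seeded patch origins inside the tissue mask, per level.

    Candidates lie on a half-patch stride grid in level-local coordinates;
    only footprints at least ``min_tissue_fraction`` inside the mask are
    eligible, and ``patches_per_level`` of them are drawn uniformly without
    replacement.  Each level uses its own RNG stream keyed by
    ``(seed, level)``, so changing one level's draw does not perturb
    another's.  The patch size is clamped to the level dimensions.  Default
    levels are the three lowest-resolution ones.
    """
    if patches_per_level < 1:
        raise ValueError("patches_per_level must be >= 1")
    if not mask.mask.any():
        raise ValueError("cannot sample from an empty tissue mask")
    if levels is None:
        levels = list(range(max(img.n_levels - 3, 0), img.n_levels))
    thumb_ds = img.levels[-1].downsample
    ii = _integral(mask.mask)
    locations: dict[int, list[tuple[int, int]]] = {}
    size_by_level: dict[int, int] = {}
    for lv_idx in levels:
        lv = img.levels[lv_idx]
        psize = min(patch_size, lv.width, lv.height)
        size_by_level[lv_idx] = psize
        stride = max(psize // 2, 1)
        xs = _grid_starts(lv.width, psize, stride)
        ys = _grid_starts(lv.height, psize, stride)
        scale = lv.downsample / thumb_ds  # level-local px -> thumbnail px
        cand = [
            (x, y)
            for y in ys
            for x in xs
            if _tissue_fraction(
                ii, x * scale, y * scale, (x + psize) * scale, (y + psize) * scale
            )
            >= min_tissue_fraction
        ]
        rng = np.random.default_rng([seed, lv_idx])
        if len(cand) < patches_per_level:
            warnings.warn(
                f"level {lv_idx}: only {len(cand)} candidate origins for "
                f"{patches_per_level} requested patches",
                stacklevel=2,
            )
            chosen = cand
        else:
            idx = rng.choice(len(cand), size=patches_per_level, replace=False)
            chosen = [cand[i] for i in sorted(idx)]
        d = lv.downsample
        locations[lv_idx] = [(int(round(x * d)), int(round(y * d))) for x, y in chosen]
    return SamplePlan(locations, patches_per_level, patch_size, size_by_level, seed)


def _grid_starts(extent: int, size: int, stride: int) -> list[int]:
    starts = list(range(0, max(extent - size, 0) + 1, stride))
    last = extent - size
    if last >= 0 and starts[-1] != last:
        starts.append(last)
    return starts


def initial_offset(
    fixed: PyramidImage,
    floating: PyramidImage,
    *,
    score_floor: float = registration.DEFAULT_SCORE_FLOOR,
) -> OffsetSample:
    """Coarse global level-0 offset from thumbnail phase correlation.

    The thumbnail shift is scaled to level 0 by the thumbnail downsample.
    When the thumbnails cannot be registered (score below the floor) the
    offset falls back to zero with a warning, flagged ``success=False``.
    """
    t1 = get_thumbnail(fixed)
    t2 = get_thumbnail(floating)
    g1 = to_grayscale(t1)
    g2 = to_grayscale(t2)
    h = min(g1.shape[0], g2.shape[0])
    w = min(g1.shape[1], g2.shape[1])
    s = registration.phase_correlate(g1[:h, :w], g2[:h, :w], score_floor=score_floor)
    d = fixed.levels[-1].downsample
    if not s.success:
        warnings.warn(
            "thumbnail registration failed; falling back to zero initial offset",
            stacklevel=2,
        )
        return OffsetSample(0.0, 0.0, score=s.score, level=0, success=False)
    return OffsetSample(s.dx * d, s.dy * d, score=s.score, level=0, success=True)
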