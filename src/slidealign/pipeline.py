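"""End-to-end registration pipeline: thumbnails → patches → KDE → regression.

``register_pair`` wires the stages together:

1. coarse global offset from thumbnail phase correlation;
2. tissue masking and seeded patch sampling on the coarse pyramid levels;
3. per-patch phase correlation, with floating reads pre-shifted by the
   coarse offset (rounded to the pyramid grid so the pre-shift is exact at
   every level and per-patch correlation only resolves a small residual);
4. KDE consensus weighting of the pooled level-0 offsets;
5. weighted hierarchical regression to the final level-0 transform.
"""

from __future__ import annotations

import json
import logging

from dataclasses import asdict, dataclass

import pandas as pd

from .pyramid_io import PyramidImage, get_thumbnail, read_region
from .registration import DEFAULT_SCORE_FLOOR, OffsetSample, register_patch_pair
from .regression import GlobalTransform, LevelScaling, estimate_global_transform
from .sampling import initial_offset, sample_patch_locations, tissue_mask

__all__ = ["RunConfig", "register_pair", "samples_to_frame"]

logger = logging.getLogger("slidealign")

_WEIGHTING_MODES = ("kde", "score", "uniform")
_REGRESSION_MODES = ("projection", "weighted_mean")
_SUBPIXEL_MODES = ("upsample", "quadratic", "none")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; defaults are the recommended settings."""

    patch_size: int = 512
    patches_per_level: int = 30
    levels_used: tuple[int, ...] | None = None  # None = three coarsest levels
    score_floor: float = DEFAULT_SCORE_FLOOR
    rotation_enabled: bool = False
    rotation_max_deg: float = 5.0
    kde_include_failures: bool = False
    kde_per_level: bool = False
    kde_diagonal: bool = False
    weighting_mode: str = "kde"
    regression_mode: str = "projection"
    subpixel: str = "upsample"
    mask_threshold: float | str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size < 8:
            raise ValueError("patch_size must be >= 8")
        if self.patches_per_level < 1:
            raise ValueError("patches_per_level must be >= 1")
        if self.score_floor < 0 or self.rotation_max_deg <= 0:
            raise ValueError("score_floor and rotation_max_deg must be positive")
        if self.weighting_mode not in _WEIGHTING_MODES:
            raise ValueError(f"weighting_mode must be one of {_WEIGHTING_MODES}")
        if self.regression_mode not in _REGRESSION_MODES:
            raise ValueError(f"regression_mode must be one of {_REGRESSION_MODES}")
        if self.subpixel not in _SUBPIXEL_MODES:
            raise ValueError(f"subpixel must be one of {_SUBPIXEL_MODES}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.pop("comment", None)
        if data.get("levels_used") is not None:
            data["levels_used"] = tuple(data["levels_used"])
        return cls(**data)


def _round_to_grid(value: float, grid: int) -> int:
    return int(round(value / grid)) * grid


def register_pair(
    fixed: PyramidImage,
    floating: PyramidImage,
    config: RunConfig = RunConfig(),
) -> tuple[GlobalTransform, list[OffsetSample]]:
    """Register a floating pyramid onto a fixed one.

    Returns the final level-0 transform together with every per-patch offset
    sample (residuals, level-local pixels) for diagnostics and serialization.
    """
    scaling = LevelScaling(tuple(lv.downsample for lv in fixed.levels))
    init = initial_offset(fixed, floating, score_floor=config.score_floor)
    levels = (
        list(config.levels_used)
        if config.levels_used is not None
        else list(range(max(fixed.n_levels - 3, 0), fixed.n_levels))
    )
    # snap the pre-shift to the coarsest used grid so it is exact on every level
    grid = int(round(max(scaling.downsample(l) for l in levels)))
    pre = (_round_to_grid(init.dx, grid), _round_to_grid(init.dy, grid))
    logger.info("initial offset %.1f,%.1f (score %.3f) -> pre-shift %s", init.dx, init.dy, init.score, pre)

    thumb = get_thumbnail(fixed)
    mask = tissue_mask(thumb, config.mask_threshold)
    logger.info("tissue mask: threshold %.1f coverage %.3f", mask.threshold, mask.coverage)
    plan = sample_patch_locations(
        mask,
        fixed,
        config.patches_per_level,
        levels=levels,
        patch_size=config.patch_size,
        seed=config.seed,
    )

    samples: list[OffsetSample] = []
    for lv in levels:
        psize = plan.patch_size_by_level[lv]
        n_ok = 0
        for origin in plan.locations[lv]:
            p_fixed = read_region(fixed, origin, lv, (psize, psize))
            p_float = read_region(
                floating, (origin[0] + pre[0], origin[1] + pre[1]), lv, (psize, psize)
            )
            s = register_patch_pair(
                p_fixed,
                p_float,
                rotation_enabled=config.rotation_enabled,
                rotation_max_deg=config.rotation_max_deg,
                score_floor=config.score_floor,
                subpixel=config.subpixel,
            )
            samples.append(s)
            n_ok += int(s.success)
        logger.info("level %d: %d/%d patch registrations succeeded", lv, n_ok, len(plan.locations[lv]))

    transform = estimate_global_transform(
        samples,
        scaling,
        initial=(float(pre[0]), float(pre[1])),
        weighting_mode=config.weighting_mode,
        regression_mode=config.regression_mode,
        kde_per_level=config.kde_per_level,
        kde_include_failures=config.kde_include_failures,
        kde_diagonal=config.kde_diagonal,
        use_theta_weights=config.rotation_enabled,
    )
    logger.info(
        "global transform: dx0=%.2f dy0=%.2f theta=%.3f slope=%.4f (%s, n=%d)",
        transform.dx0, transform.dy0, transform.theta, transform.slope_m,
        transform.quality_flag, transform.n_samples_used,
    )
    return transform, samples


def samples_to_frame(samples: list[OffsetSample]) -> pd.DataFrame:
    """Per-patch offset samples as a tidy DataFrame (one row per patch)."""
    return pd.DataFrame([s.as_row() for s in samples])
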