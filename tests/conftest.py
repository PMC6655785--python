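"""Shared fixtures: one small synthetic re-stained pair plus texture helpers.

All fixtures are generated programmatically at test time; nothing is read
from checked-in data.
"""

from __future__ import annotations

import numpy as np
import pytest

import slidealign as sa

# one small pair shared across the suite: 1024^2 level 0, 1:4:16:32 pyramid,
# level-0 truth (64, -32), default noise and blank fraction
PAIR_SPEC = sa.SyntheticSpec(
    level0_size=(1024, 1024), true_dx0=64.0, true_dy0=-32.0, seed=42
)


@pytest.fixture(scope="session")
def pair_paths(tmp_path_factory) -> tuple[str, str, str]:
    out = tmp_path_factory.mktemp("pair")
    return sa.generate_pair(PAIR_SPEC, out)


@pytest.fixture(scope="session")
def pair(pair_paths):
    fixed = sa.open_pyramid(pair_paths[0])
    floating = sa.open_pyramid(pair_paths[1])
    yield fixed, floating
    fixed.close()
    floating.close()


@pytest.fixture(scope="session")
def fixed_level0(pair) -> np.ndarray:
    return pair[0].level_array(0)


def tissue_crop(level0: np.ndarray, rng: np.random.Generator, n: int = 256) -> np.ndarray:
    """Grayscale n×n crop of the level-0 plane centred on tissue (non-white)."""
    h, w = level0.shape[:2]
    for _ in range(200):
        y = int(rng.integers(0, h - n))
        x = int(rng.integers(0, w - n))
        block = level0[y : y + n, x : x + n]
        gray = block.astype(np.float64) @ np.array([0.299, 0.587, 0.114])
        if gray.mean() < 235 and gray.std() > 10:  # mostly tissue, textured
            return gray
    raise RuntimeError("no textured crop found")
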