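"""Pyramidal slide access with a single coordinate convention.

Whole-slide images are stored as multi-resolution pyramids: level 0 is the
full-resolution scan and level ``k`` is the same scene downsampled by an
integer factor (``1:4:16:32`` is a common layout).  Every other module in
this package addresses pixels in the **level-0 frame**: a region is requested
by its level-0 top-left corner plus a level-local size, matching the
convention of the mainstream WSI readers.  Coordinates are 0-based with
``x`` = column and ``y`` = row, and rectangles are half-open.

Reads past the slide boundary are padded with white (blank glass) and
flagged, so random patch sampling near tissue edges never raises.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile

__all__ = [
    "PyramidLevel",
    "PyramidImage",
    "Patch",
    "open_pyramid",
    "read_region",
    "get_thumbnail",
]

BACKGROUND = 255  # blank glass in brightfield scans is near-white


@dataclass(frozen=True)
class PyramidLevel:
    """One resolution level of a pyramid."""

    index: int
    width: int
    height: int
    downsample: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"level {self.index}: non-positive dimensions")
        if self.downsample <= 0:
            raise ValueError(f"level {self.index}: downsample must be > 0")


@dataclass(frozen=True)
class Patch:
    """A pixel block read from one level, addressed in level-0 coordinates.

    ``pixels`` is H×W×3 uint8; ``origin_l0`` is the level-0 (x, y) of the
    top-left corner; ``size`` is the (w, h) requested in level-local pixels.
    ``padded`` is True when part of the request fell outside the slide and
    was filled with background white.
    """

    pixels: np.ndarray
    level: int
    origin_l0: tuple[int, int]
    size: tuple[int, int]
    padded: bool = False

    def __post_init__(self) -> None:
        w, h = self.size
        if self.pixels.shape[:2] != (h, w):
            raise ValueError("pixel array does not match requested size")


class PyramidImage:
    """A multi-level image with per-level downsample factors.

    Backed either by a multi-page TIFF on disk (pages sorted by decreasing
    resolution) or by in-memory arrays.  Level arrays are read lazily and
    cached, so opening a gigapixel file is cheap until level 0 is touched.
    """

    def __init__(
        self,
        levels: list[PyramidLevel],
        *,
        source: str | None = None,
        arrays: list[np.ndarray] | None = None,
        pixel_size_um: float | None = None,
    ) -> None:
        if len(levels) < 2:
            raise ValueError("a pyramid needs at least 2 levels")
        if [lv.index for lv in levels] != list(range(len(levels))):
            raise ValueError("levels must be sorted with indices 0..L-1")
        ds = [lv.downsample for lv in levels]
        if any(b <= a for a, b in zip(ds, ds[1:])):
            raise ValueError("downsample must strictly increase with level")
        if pixel_size_um is not None and pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.levels = levels
        self.source = source
        self.pixel_size_um = pixel_size_um
        self._arrays: dict[int, np.ndarray] = (
            dict(enumerate(arrays)) if arrays is not None else {}
        )
        self._tif: tifffile.TiffFile | None = None

    @classmethod
    def from_arrays(
        cls, arrays: list[np.ndarray], pixel_size_um: float | None = None
    ) -> "PyramidImage":
        """Build an in-memory pyramid; downsamples inferred from widths."""
        w0 = arrays[0].shape[1]
        levels = [
            PyramidLevel(i, a.shape[1], a.shape[0], _infer_downsample(w0, a.shape[1]))
            for i, a in enumerate(arrays)
        ]
        return cls(levels, arrays=list(arrays), pixel_size_um=pixel_size_um)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_array(self, level: int) -> np.ndarray:
        """Full pixel plane of one level (lazy-loaded, cached)."""
        if level not in self._arrays:
            if self._tif is None:
                raise RuntimeError("no backing store for this level")
            arr = self._tif.pages[level].asarray()
            self._arrays[level] = _as_rgb(arr)
        return self._arrays[level]

    def close(self) -> None:
        if self._tif is not None:
            self._tif.close()
            self._tif = None
        self._arrays.clear()

    def __enter__(self) -> "PyramidImage":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def _infer_downsample(w0: int, wk: int) -> float:
    ratio = w0 / wk
    rounded = round(ratio)
    # integer truncation during pyramid construction allows ±1 px per level
    return float(rounded) if abs(w0 / max(rounded, 1) - wk) <= 1 else ratio


def _as_rgb(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return np.ascontiguousarray(arr)


def open_pyramid(path: str | os.PathLike) -> PyramidImage:
    """Open a pyramidal (multi-page) TIFF as a :class:`PyramidImage`.

    Downsample factors are recovered from page dimensions relative to the
    first (largest) page.  Raises ``IOError`` for unreadable paths and
    ``ValueError`` for single-level images.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"cannot open pyramid: no such file: {path}")
    try:
        tif = tifffile.TiffFile(path)
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise IOError(f"cannot open pyramid {path}: {exc}") from exc
    pages = tif.pages
    if len(pages) < 2:
        tif.close()
        raise ValueError(f"{path}: single-level image is not a supported pyramid")
    w0 = pages[0].imagewidth
    levels = [
        PyramidLevel(i, p.imagewidth, p.imagelength, _infer_downsample(w0, p.imagewidth))
        for i, p in enumerate(pages)
    ]
    pixel_size = _pixel_size_um(pages[0])
    img = PyramidImage(levels, source=path, pixel_size_um=pixel_size)
    img._tif = tif
    return img


def _pixel_size_um(page) -> float | None:
    # TIFF resolution tags: pixels per unit; unit 3 = centimetre
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags.get("ResolutionUnit")
        num, den = xres if isinstance(xres, tuple) else (xres, 1)
        if num == 0:
            return None
        per_px = den / num
        if unit is not None and getattr(unit.value, "value", unit.value) == 3:
            return per_px * 1e4  # cm -> um
        return None
    except (KeyError, TypeError, ZeroDivisionError):
        return None


def read_region(
    img: PyramidImage,
    origin_l0: tuple[int, int],
    level: int,
    size: tuple[int, int],
) -> Patch:
    """Read a ``size``-shaped block whose top-left is ``origin_l0 / downsample``.

    Out-of-bounds area is filled with background white and the patch is
    flagged ``padded``.
    """
    if not 0 <= level < img.n_levels:
        raise IndexError(f"level {level} out of range 0..{img.n_levels - 1}")
    w, h = size
    if w <= 0 or h <= 0:
        raise ValueError("size must be positive")
    lv = img.levels[level]
    x0 = int(round(origin_l0[0] / lv.downsample))
    y0 = int(round(origin_l0[1] / lv.downsample))
    plane = img.level_array(level)
    out = np.full((h, w, 3), BACKGROUND, dtype=np.uint8)
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x0 + w, lv.width), min(y0 + h, lv.height)
    padded = (sx0, sy0) != (x0, y0) or (sx1, sy1) != (x0 + w, y0 + h)
    if sx1 > sx0 and sy1 > sy0:
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = plane[sy0:sy1, sx0:sx1]
    else:
        padded = True
    return Patch(out, level, tuple(origin_l0), (w, h), padded)


def get_thumbnail(img: PyramidImage) -> Patch:
    """Whole image at the lowest-resolution level."""
    top = img.n_levels - 1
    lv = img.levels[top]
    plane = _as_rgb(img.level_array(top)).astype(np.uint8, copy=False)
    return Patch(plane, top, (0, 0), (lv.width, lv.height))
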