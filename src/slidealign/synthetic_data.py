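"""Synthetic re-stained WSI pairs with known ground-truth transforms.

Re-staining keeps the tissue glued to the same glass: the two scans show the
*same* cell field under different colour models, displaced by a global
translation (plus at most a small rotation).  The generator renders one
shared field — elliptical nuclei over textured cytoplasm on white glass —
twice:

* **fixed**, H&E-like: purple nuclei on pink, strongly textured cytoplasm
  (both nucleus and cytoplasm take up stain → dense detail);
* **floating**, IHC-like: a pale counterstain with brown DAB chromogen on a
  sparse positive fraction of the nuclei only (sparse detail, different hue
  and contrast).

The rigid transform is applied to the continuous field before rasterisation,
so subpixel ground truths are meaningful.  Texture-poor "blank" zones (no
nuclei, flat cytoplasm) are injected to exercise patch-registration failure,
and i.i.d. Gaussian noise is added independently per image.  Pyramid levels
are block means of level 0, written as multi-page TIFF plus a truth JSON.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = ["SyntheticSpec", "generate_pair", "generate_cohort", "build_pyramid"]

_STRIP = 512  # rows rendered per block; caps peak memory on big slides

# colour models (RGB, 8-bit): H&E = dense dual colour, IHC = sparse positive
HE_CYTOPLASM = np.array([235.0, 170.0, 200.0])
HE_NUCLEUS = np.array([90.0, 60.0, 140.0])
IHC_COUNTERSTAIN = np.array([228.0, 226.0, 238.0])
IHC_NEGATIVE_NUCLEUS = np.array([175.0, 180.0, 215.0])
IHC_POSITIVE_NUCLEUS = np.array([125.0, 80.0, 38.0])
GLASS = np.array([255.0, 255.0, 255.0])


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one re-stained pair.

    ``cell_density`` is nuclei per 10⁴ level-0 px² (≈ 625 µm² at 0.25 µm/px);
    ``blank_region_fraction`` is the fraction of tissue rendered texture-poor;
    ``noise_sigma`` is the per-channel Gaussian noise s.d. in 8-bit units.
    """

    level0_size: tuple[int, int] = (2048, 2048)
    downsamples: tuple[int, ...] = (1, 4, 16, 32)
    true_dx0: float = 0.0
    true_dy0: float = 0.0
    true_theta: float = 0.0
    cell_density: float = 2.0
    ihc_positive_fraction: float = 0.3
    blank_region_fraction: float = 0.2
    noise_sigma: float = 5.0
    tissue_fraction: float = 0.6
    pixel_size_um: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.level0_size
        ds = self.downsamples
        if ds[0] != 1 or any(b <= a for a, b in zip(ds, ds[1:])):
            raise ValueError("downsamples must start at 1 and strictly increase")
        if w % ds[-1] or h % ds[-1]:
            raise ValueError("level-0 size must be divisible by the max downsample")
        for name in ("ihc_positive_fraction", "blank_region_fraction", "tissue_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if max(abs(self.true_dx0), abs(self.true_dy0)) > min(w, h) / 4:
            raise ValueError("shift exceeds 1/4 of the level-0 size")


class _SmoothField:
    """A smooth random scalar field over the level-0 plane, evaluable anywhere."""

    def __init__(self, rng: np.random.Generator, grid: int, size: tuple[int, int], smooth: float):
        g = rng.normal(size=(grid, grid))
        g = ndimage.gaussian_filter(g, smooth, mode="wrap")
        g -= g.min()
        peak = g.max()
        self.grid = g / peak if peak > 0 else g
        self.sx = (grid - 1) / size[0]
        self.sy = (grid - 1) / size[1]

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        coords = np.vstack([(y * self.sy).ravel(), (x * self.sx).ravel()])
        out = ndimage.map_coordinates(self.grid, coords, order=1, mode="nearest")
        return out.reshape(x.shape)

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.grid, q))


@dataclass
class _Scene:
    tissue: _SmoothField
    tissue_thr: float
    texture: _SmoothField
    blank: _SmoothField
    blank_thr: float
    nuclei: np.ndarray  # columns: cx, cy, a, b, phi, shade, positive
    center: tuple[float, float]


def _build_scene(spec: SyntheticSpec) -> _Scene:
    w, h = spec.level0_size
    rng = np.random.default_rng([spec.seed, 0])
    tissue = _SmoothField(rng, 64, (w, h), smooth=6.0)
    tissue_thr = tissue.quantile(1.0 - spec.tissue_fraction)
    texture = _SmoothField(rng, 512, (w, h), smooth=1.5)
    # blank (texture-poor) zones are rendered at a coarse scale so that a
    # zone can swallow whole patches, the failure mode seen on real slides
    blank = _SmoothField(rng, 8, (w, h), smooth=1.0)
    blank_thr = blank.quantile(1.0 - spec.blank_region_fraction)

    n_target = int(spec.cell_density * w * h / 1e4)
    # oversample, then keep nuclei landing on non-blank tissue
    n_draw = max(int(n_target / max(spec.tissue_fraction, 1e-6) * 1.6), n_target)
    cx = rng.uniform(0, w, n_draw)
    cy = rng.uniform(0, h, n_draw)
    keep = (tissue(cx, cy) >= tissue_thr) & (blank(cx, cy) < blank_thr)
    cx, cy = cx[keep][:n_target], cy[keep][:n_target]
    n = cx.size
    a = rng.uniform(9.0, 16.0, n)
    b = a * rng.uniform(0.55, 1.0, n)
    phi = rng.uniform(0, np.pi, n)
    shade = rng.uniform(0.75, 1.0, n)
    positive = rng.random(n) < spec.ihc_positive_fraction
    nuclei = np.column_stack([cx, cy, a, b, phi, shade, positive.astype(float)])
    return _Scene(tissue, tissue_thr, texture, blank, blank_thr, nuclei, (w / 2, h / 2))


def _inverse_transform(spec: SyntheticSpec, scene: _Scene, x, y):
    """Map floating-frame coords to fixed-frame (field) coords."""
    if spec.true_theta == 0.0 and spec.true_dx0 == 0.0 and spec.true_dy0 == 0.0:
        return x, y
    cx0, cy0 = scene.center
    xs = x - spec.true_dx0 - cx0
    ys = y - spec.true_dy0 - cy0
    if spec.true_theta != 0.0:
        t = np.radians(-spec.true_theta)
        xs, ys = xs * np.cos(t) - ys * np.sin(t), xs * np.sin(t) + ys * np.cos(t)
    return xs + cx0, ys + cy0


def _forward_points(spec: SyntheticSpec, scene: _Scene, px, py):
    """Map fixed-frame points into the floating frame."""
    cx0, cy0 = scene.center
    xs, ys = px - cx0, py - cy0
    if spec.true_theta != 0.0:
        t = np.radians(spec.true_theta)
        xs, ys = xs * np.cos(t) - ys * np.sin(t), xs * np.sin(t) + ys * np.cos(t)
    return xs + cx0 + spec.true_dx0, ys + cy0 + spec.true_dy0


def _render(spec: SyntheticSpec, scene: _Scene, stain: str, noise_rng: np.random.Generator) -> np.ndarray:
    w, h = spec.level0_size
    floating = stain == "ihc"
    out = np.empty((h, w, 3), dtype=np.uint8)

    if floating:
        ncx, ncy = _forward_points(spec, scene, scene.nuclei[:, 0], scene.nuclei[:, 1])
        nphi = scene.nuclei[:, 4] + np.radians(spec.true_theta)
    else:
        ncx, ncy = scene.nuclei[:, 0], scene.nuclei[:, 1]
        nphi = scene.nuclei[:, 4]
    na, nb = scene.nuclei[:, 2], scene.nuclei[:, 3]
    nshade, npos = scene.nuclei[:, 5], scene.nuclei[:, 6] > 0.5
    rmax = np.maximum(na, nb) + 2.0

    for y0 in range(0, h, _STRIP):
        y1 = min(y0 + _STRIP, h)
        yy, xx = np.mgrid[y0:y1, 0:w].astype(np.float64)
        fx, fy = (_inverse_transform(spec, scene, xx, yy)) if floating else (xx, yy)
        tis = scene.tissue(fx, fy) >= scene.tissue_thr
        blank = scene.blank(fx, fy) >= scene.blank_thr
        tex = scene.texture(fx, fy)
        tex = np.where(blank, 0.5, tex)  # texture-poor zones render flat

        strip = np.broadcast_to(GLASS, (y1 - y0, w, 3)).copy()
        if floating:
            mod = 0.97 + 0.06 * (tex - 0.5)
            base = IHC_COUNTERSTAIN
        else:
            mod = 0.88 + 0.35 * (tex - 0.5)
            base = HE_CYTOPLASM
        strip[tis] = np.clip(base * mod[tis, None], 0, 255)

        sel = np.flatnonzero((ncy + rmax >= y0) & (ncy - rmax < y1))
        for j in sel:
            _draw_nucleus(
                strip, y0, ncx[j], ncy[j], na[j], nb[j], nphi[j],
                _nucleus_color(floating, npos[j], nshade[j]),
            )
        if spec.noise_sigma > 0:
            strip = strip + noise_rng.normal(0.0, spec.noise_sigma, strip.shape)
        out[y0:y1] = np.clip(np.round(strip), 0, 255).astype(np.uint8)
    return out


def _nucleus_color(floating: bool, positive: bool, shade: float) -> np.ndarray:
    if not floating:
        return HE_NUCLEUS * shade
    return (IHC_POSITIVE_NUCLEUS if positive else IHC_NEGATIVE_NUCLEUS) * shade


def _draw_nucleus(strip, y0, cx, cy, a, b, phi, color):
    h, w = strip.shape[:2]
    R = max(a, b) + 2.0
    x_lo, x_hi = int(np.floor(cx - R)), int(np.ceil(cx + R)) + 1
    y_lo, y_hi = int(np.floor(cy - R)), int(np.ceil(cy + R)) + 1
    x_lo, x_hi = max(x_lo, 0), min(x_hi, w)
    y_lo, y_hi = max(y_lo - y0, 0), min(y_hi - y0, h)
    if x_lo >= x_hi or y_lo >= y_hi:
        return
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi].astype(np.float64)
    u = xx - cx
    v = yy + y0 - cy
    ur = u * np.cos(phi) + v * np.sin(phi)
    vr = -u * np.sin(phi) + v * np.cos(phi)
    rho = np.sqrt((ur / a) ** 2 + (vr / b) ** 2)
    alpha = np.clip((1.0 - rho) * min(a, b), 0.0, 1.0)[..., None]  # ~1 px soft edge
    block = strip[y_lo:y_hi, x_lo:x_hi]
    block[:] = block * (1.0 - alpha) + color * alpha


def build_pyramid(level0: np.ndarray, downsamples: tuple[int, ...]) -> list[np.ndarray]:
    """Block-mean pyramid of an H×W×3 uint8 plane."""
    levels = [level0]
    for d in downsamples[1:]:
        h, w = level0.shape[0] // d, level0.shape[1] // d
        blocks = level0.astype(np.float64).reshape(h, d, w, d, 3).mean(axis=(1, 3))
        levels.append(np.clip(np.round(blocks), 0, 255).astype(np.uint8))
    return levels


def _write_pyramid(path: str, levels: list[np.ndarray], pixel_size_um: float) -> None:
    px_per_cm = 1e4 / pixel_size_um
    with tifffile.TiffWriter(path) as tw:
        for lv in levels:
            ratio = levels[0].shape[1] / lv.shape[1]
            tw.write(
                lv,
                photometric="rgb",
                resolution=(px_per_cm / ratio, px_per_cm / ratio),
                resolutionunit="CENTIMETER",
                compression=None,
            )


def generate_pair(spec: SyntheticSpec, out_dir: str | os.PathLike, prefix: str = "pair") -> tuple[str, str, str]:
    """Render and write one fixed/floating pyramid pair plus its truth JSON.

    Returns ``(fixed_path, floating_path, truth_path)``.  Output is fully
    determined by ``spec`` (same spec twice → byte-identical files).
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    scene = _build_scene(spec)
    fixed = _render(spec, scene, "he", np.random.default_rng([spec.seed, 1]))
    floating = _render(spec, scene, "ihc", np.random.default_rng([spec.seed, 2]))
    fixed_path = os.path.join(out_dir, f"{prefix}_fixed.tiff")
    floating_path = os.path.join(out_dir, f"{prefix}_floating.tiff")
    truth_path = os.path.join(out_dir, f"{prefix}_truth.json")
    _write_pyramid(fixed_path, build_pyramid(fixed, spec.downsamples), spec.pixel_size_um)
    _write_pyramid(floating_path, build_pyramid(floating, spec.downsamples), spec.pixel_size_um)
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "dx0": spec.true_dx0,
                "dy0": spec.true_dy0,
                "theta_deg": spec.true_theta,
                "seed": spec.seed,
                "spec": asdict(spec),
            },
            fh,
            indent=2,
        )
    return fixed_path, floating_path, truth_path


def generate_cohort(
    base_spec: SyntheticSpec,
    n_pairs: int,
    out_dir: str | os.PathLike,
    difficulty_grid: dict[str, list] | None = None,
) -> str:
    """Write ``n_pairs`` pairs varying difficulty over a seeded grid.

    ``difficulty_grid`` maps SyntheticSpec field names to value lists cycled
    across pairs; by default shift, cell density, positive fraction and blank
    fraction are varied from seeded draws.  Returns the manifest CSV path.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng([base_spec.seed, 99])
    w, h = base_spec.level0_size
    rows = []
    for i in range(n_pairs):
        overrides: dict = {"seed": base_spec.seed + 1000 + i}
        if difficulty_grid:
            for key, values in difficulty_grid.items():
                overrides[key] = values[i % len(values)]
        else:
            overrides["true_dx0"] = float(rng.integers(-w // 8, w // 8 + 1))
            overrides["true_dy0"] = float(rng.integers(-h // 8, h // 8 + 1))
            overrides["cell_density"] = float(rng.uniform(1.0, 3.0))
            overrides["ihc_positive_fraction"] = float(rng.uniform(0.15, 0.5))
            overrides["blank_region_fraction"] = float(rng.uniform(0.0, 0.35))
        spec_i = SyntheticSpec(**{**asdict(base_spec), **overrides})
        fixed_p, float_p, truth_p = generate_pair(spec_i, out_dir, prefix=f"pair{i:03d}")
        rows.append(
            {
                "pair_id": f"pair{i:03d}",
                "fixed_path": fixed_p,
                "floating_path": float_p,
                "truth_path": truth_p,
                "true_dx0": spec_i.true_dx0,
                "true_dy0": spec_i.true_dy0,
                "true_theta_deg": spec_i.true_theta,
            }
        )
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
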