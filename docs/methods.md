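# Methods

## Problem and model

Two whole-slide scans of the *same* physical section, stained twice
(destain/re-stain), are related by a rigid transform with no scale change:
the tissue is fixed to the glass, the scanner magnification is identical,
and mounting differences amount to a translation (Δx, Δy) in level-0 pixels
plus at most a few degrees of rotation θ. The estimator treats translation
as primary and rotation as an optional refinement (off by default).

Each WSI is a pyramid: level 0 at full resolution, level k downsampled by a
fixed integer factor (the supported layout is arbitrary strictly increasing
factors; the common case is 1:4:16:32). All coordinates in the package are
level-0-referenced (x = column, y = row, 0-based, half-open rectangles);
region sizes are level-local. Out-of-bounds reads pad with white —
blank glass — and are flagged, never raised.

## Pipeline

1. **Thumbnail pre-shift.** Phase correlation of the two lowest-resolution
   planes, scaled by the thumbnail downsample, gives a coarse global offset;
   it is snapped to the coarsest-level pixel grid so that pre-shifted patch
   reads are exact at every level. Per-patch correlation then only resolves
   a small residual, far from the wrap-around ambiguity at ±patch/2. If the
   thumbnails cannot be registered the pre-shift falls back to zero with a
   warning.
2. **Tissue masking and sampling.** Tissue is darker than glass, so a
   brightness threshold on the grayscale thumbnail (Otsu by default,
   fallback 220/255) localises content; components under 0.1% of the
   thumbnail are dropped as debris. Patch origins lie on a half-patch-stride
   grid per level, restricted to footprints ≥ 50% inside the mask, and are
   drawn uniformly without replacement with an RNG stream keyed by
   (seed, level) — changing one level's request does not perturb another's
   draw. Defaults: the three coarsest levels, 30 patches per level,
   512-px patches (clamped to the level size). The defaults suit gigapixel
   slides; for desk-scale synthetic slides (≤ 4096² level 0) a 256-px patch
   keeps ~30 usable level-1 origins and is what the test suite uses there.
3. **Patch registration.** Grayscale luminance → mean removal → Hann window
   → normalized cross-power spectrum (whitened with ε = 10⁻¹⁵·max to keep
   division finite) → inverse transform → integer peak mapped to
   [−N/2, N/2) → subpixel refinement. The default refinement evaluates the
   correlation surface on a 1/64-px grid around the peak by a local matrix
   DFT; a 3-point quadratic fit is available (`subpixel="quadratic"`) but
   carries ~0.1 px bias on whitened surfaces, which the level-0
   extrapolation would multiply by up to the full downsample factor — the
   reason the upsampled evaluation is the default.
   The similarity score is the correlation peak clipped to [0, 1]. A
   registration is *successful* when the score clears
   max(0.05, 3·√(2·ln(hw)/hw)): the second term tracks how the null
   (unrelated-patch) peak grows as patches shrink; both terms were
   calibrated on empirical null/matched score distributions. Failed samples
   stay in the pool and are excluded from the KDE pool by default
   (configurable).
4. **Rotation (optional).** Log-polar resampling of the high-pass-emphasised
   spectral magnitudes turns rotation into an angle-axis shift recovered by
   phase correlation, restricted to ±5° (re-staining leaves no room for
   more) with the log-radius shift pinned to ≤1 bin (scale fixed at 1). The
   floating patch is derotated before translation estimation. Accuracy on
   textured patches is ~0.02° typical, <0.3° worst-case at 720 angular bins.
5. **KDE consensus weighting.** Scaled to level 0, all offsets should
   coincide; each sample's confidence is the pooled bivariate Gaussian KDE
   density at its own location, normalized so the maximum is 1. Bandwidth:
   Scott factor h = n^(−1/(d+4)) applied to the sample covariance,
   H = h²Σ̂ (a diagonal h²σ̂²I variant is available). Degenerate pools — one
   sample, or zero variance — carry no disagreement and get uniform weight
   1. Pooled (all-levels) weighting is the default; per-level densities are
   a config alternative. When rotation is enabled a separable 1-D KDE over
   θ multiplies in; rotation is near-zero and weakly coupled to translation
   in this regime, so a joint 3-D KDE buys nothing.
6. **Hierarchical regression.** The regression cost weights each sample by
   Rₗ·f̂, where Rₗ is the pixel-pitch ratio of level l to the next finer
   level (0.25, 0.25, 0.5 for 1:4:16:32; derived generically for other
   layouts). The through-origin residual is squared — an unsquared residual
   is unbounded below and has no minimizer — giving the closed form
   m = Σwxy/Σwx². When essentially all weighted energy sits on the y axis
   (near-vertical truth) the axes are swapped and the inverse slope fitted.
   The line alone does not determine a point: the estimate is the weighted
   projection of the pooled offsets onto the unit direction (1, m)/‖(1, m)‖,
   which uses m exactly as a direction constraint and reduces to the
   weighted mean for collinear samples. A plain weighted mean
   (`regression_mode="weighted_mean"`) is kept for comparison. The thumbnail
   pre-shift is added back at the end; θ is the weighted circular mean.
   With no successful samples the pipeline returns the pre-shift flagged
   `degraded`.

## Synthetic study conditions

The generator emulates the re-staining scenario rather than stain physics:

* one seeded cell field — elliptical nuclei (9–16 px semi-major axis at
  0.25 µm/px, i.e. ~5–8 µm, density default 2 nuclei per 10⁴ px²) over a
  smooth cytoplasm texture inside a smooth tissue blob (default 60% of the
  slide) on white glass;
* **fixed** rendition: H&E-like — purple nuclei, strongly modulated pink
  cytoplasm; **floating**: IHC-like — pale counterstain, faint negative
  nuclei, brown DAB on a positive fraction (default 0.3) only. Same
  geometry, different hue and contrast, as with real stain pairs;
* the rigid transform is applied to the continuous field before
  rasterization, so subpixel truths are exact; shifts above ¼ of the slide
  are rejected (they would break the wrap-around bound);
* texture-poor zones (default 20% of tissue) are drawn from a coarse random
  field (~W/8 blob scale) large enough to swallow whole patches — flat
  cytoplasm, no nuclei — reproducing the real patch-failure mode;
* i.i.d. Gaussian noise (default σ = 5/255), independent between the two
  renditions; pyramid levels are block means of level 0.

What the generator does **not** emulate: stain deconvolution physics,
scanner illumination gradients, focus variation, tissue folds or coverslip
artefacts, and local deformation. Passing tests therefore demonstrate the
estimator's statistical behaviour (consensus weighting, cross-level fusion,
failure robustness) under controlled conditions, not vendor-file handling or
robustness to every real-world artefact.

## Numerical choices and degenerate inputs

* Whitening ε = 10⁻¹⁵ of the spectrum maximum; all-zero spectra and
  constant patches return failure rather than raising.
* Signed shifts live in [−N/2, N/2); the thumbnail pre-shift keeps residuals
  far from the boundary.
* Subpixel grid 1/64 px over ±1.5 px around the integer peak.
* Singular sample covariance in the KDE falls back to an isotropic
  bandwidth; zero variance falls back to uniform weights.
* Slope fit: axis swap only when Σwx² ≤ 10⁻⁹·Σwy²; both sums zero → m = 0.
* Ties in grid argmaxes resolve to the first (lowest-index) cell.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run at desk scale by design: a
shared 1024² pair for unit tests, 4096² for the noise-free exactness check
(truth (100, −40), error < 0.1 px), and 8192² with 20% blank area and σ = 5
noise for the headline robustness check (truth (96, −64), error < 2 px,
default configuration). Estimator-level comparisons (KDE vs pooled mean,
breakdown vs outlier fraction) run on simulated offset pools of 30 samples
× 3 levels over 100 seeded trials, where truth is exact by construction.

## Known limitations

* Only multi-page TIFF pyramids are read; vendor WSI formats would need an
  external reader behind the same `PyramidImage` interface.
* Rotation estimation assumes square patches and angles within ±5°; larger
  angles alias in the restricted search window.
* The score floor is calibrated for brightfield-like noise statistics;
  heavily compressed or quantized inputs may need a different floor.
* A single global transform is estimated; slides with genuine local
  deformation (serial sections) violate the model and are out of scope.
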