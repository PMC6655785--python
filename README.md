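# slidealign

Robust rigid co-registration of **re-stained** histological whole-slide
images (WSIs).

When one tissue section is stained (e.g. H&E), scanned, destained and
stained again (e.g. IHC), the tissue never moves relative to the glass: the
two gigapixel scans differ by a global translation (Δx, Δy) and at most a
minimal rotation θ. Aligning them enables subcellular co-localization of
morphology (H&E) with protein expression (IHC). Direct registration at full
resolution is fragile — the stains differ in hue, contrast and local detail,
and many patches are texture-poor — while errors made at the coarse pyramid
levels are magnified up to the full downsample factor when propagated to
level 0.

`slidealign` addresses this with three ingredients:

1. **Patch-based Fourier registration.** For patches f₁ (fixed) and f₂
   (floating) with f₂(x, y) = f₁(x − Δx, y − Δy), the normalized cross-power
   spectrum F₁\*F₂ / |F₁\*F₂| = e^(−j2π(ξΔx + ηΔy)) is a pure phase ramp;
   its inverse transform is an impulse at (Δx, Δy). Patches are sampled from
   the three coarsest pyramid levels inside a brightness-thresholded tissue
   mask, after a coarse pre-shift from thumbnail correlation.
2. **KDE consensus weighting.** Similarity scores do not reliably flag
   failed registrations across stains, but failures do not agree with each
   other. Each level-0-scaled offset (xᵢ, yᵢ) is weighted by a bivariate
   Gaussian kernel density estimate f̂(xᵢ, yᵢ) with Scott's-rule bandwidth
   h = n^(−1/(d+4)) (equal on both axes, H = h²Σ̂), normalized to [0, 1].
3. **Hierarchical resolution regression.** Offsets at a level with
   downsample D correspond to D·(dx, dy) at level 0 — so scaled offsets from
   all levels must coincide, and y-vs-x offsets lie on a line through the
   origin. The slope m minimizing Σₗ Σᵢ Rₗ · f̂(xᵢₗ, yᵢₗ) · (yᵢₗ − m·xᵢₗ)²
   (Rₗ = resolution ratio of level l to the next finer level, {0.25, 0.25,
   0.5} for a 1:4:16:32 pyramid) has the closed form m = Σwxy / Σwx²; the
   weighted projection of the pooled offsets onto the fitted direction gives
   the final level-0 transform.

Because public re-stained WSI cohorts are not available, the package ships a
first-class synthetic generator: one shared cell field rendered twice (dense
dual-color H&E-like vs sparse-positive IHC-like), with a known continuous
rigid transform, texture-poor zones that provoke patch failures, and additive
noise — so the whole pipeline is testable end to end with exact ground truth.

## Worked example

Generate a 2048² synthetic pair whose true level-0 shift is (96, −64), then
register it:

```bash
cat > spec.json <<'EOF'
{"level0_size": [2048, 2048], "true_dx0": 96, "true_dy0": -64, "seed": 3}
EOF
slidealign simulate spec.json --out-dir sim
slidealign register sim/pair_fixed.tiff sim/pair_floating.tiff \
    --out-dir run --patch-size 256 --patches-per-level 12
```

prints

```json
{
  "dx0": 96.00107810448205,
  "dy0": -64.0,
  "theta_deg": 0.0,
  "slope_m": 0.0,
  "n_samples": 9,
  "quality_flag": "ok"
}
```

`dx0`/`dy0` is the estimated level-0 translation — here within 0.002 px of
the truth (96, −64). `slope_m` is the fitted cross-level regression slope of
the *residual* offsets after the coarse thumbnail pre-shift (the pre-shift
already captured the displacement, so the residual slope is ~0);
`n_samples` counts successful patch registrations. `run/samples.csv` holds
every per-patch offset with its score, and `run/run_config.json` the resolved
configuration. The same pipeline is available in Python:

```python
import slidealign as sa

fixed = sa.open_pyramid("sim/pair_fixed.tiff")
floating = sa.open_pyramid("sim/pair_floating.tiff")
transform, samples = sa.register_pair(fixed, floating, sa.RunConfig())
print(transform.dx0, transform.dy0, transform.theta)
```

`slidealign evaluate manifest.csv estimates.csv` scores a cohort of runs
against ground truth by Euclidean level-0 distance.

## Scope

Rigid (translation + small rotation) registration only: re-stained sections
share the glass, so scale, affine and deformable models are out of scope, as
are serial-section workflows that need them. Keypoint detection (SIFT etc.)
is not re-implemented; `filter_matches_by_slope` refines any external
matcher's output by keeping matches whose connecting lines share the modal
direction. See `docs/methods.md` for the model, parameter defaults and
limitations.
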