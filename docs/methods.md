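# Methods

## Design overview

`palzsim` implements a desk-scale re-creation of a simulation study of
attenuation-correction error in brain FDG-PET. All arithmetic happens on
one fixed template lattice (default 46 × 55 × 46 voxels at 4 mm, a
half-resolution MNI-like grid; a 91 × 109 × 91 / 2 mm configuration is
available). The chain is: generate a synthetic cohort and reference
database → smooth (12 mm FWHM) → fit a per-voxel age regression on the
references → multiply every subject image by every error field → rescore
each product from the intensity-normalization step onward → summarize
diagnostic accuracy, score differences and agreement.

The phantom geometry is deliberately schematic — an ellipsoidal brain
(semi-axes 80 % of the half field of view) with a cortical shell carved
into labelled patches — because the scoring mathematics only ever
inspects masks, never anatomy. The AD-related mask occupies ≈ 30 % of the
brain mask. That fraction is not arbitrary: writing the brain-average
error as the mask-fraction-weighted mean of the AD and non-AD regional
averages, the calibration targets (−1.37 % brain, −0.86 % AD, −1.59 %
non-AD) are mutually consistent only when the AD mask is ≈ 30 % of the
brain, so the geometry realizes the proportion the regional statistics
imply. The AD-preserved normalization region is a superior cortical patch
plus an inferior, infratentorial-analogue blob, disjoint from the AD mask.

## Uptake model

A subject image is

```
u(v) = baseline(v) · (1 + β_age·(age − 72.5)) · (1 − effect(v)) · (1 + b(v)) + ε(v)
```

* `baseline`: 1.0 in gray-matter labels, 0.25 in the white-matter-like
  core, 0 outside the brain.
* `β_age = −0.003 / year`: a global age-related decline. Because it is
  spatially uniform it cancels exactly under intensity normalization;
  the fitted voxel slopes are therefore near zero and the age regression
  machinery is exercised rather than load-bearing. The noise-free
  generator inversion tests check it on raw volumes.
* `effect`: fractional hypometabolism confined to the AD mask — 0.20 for
  AD, 0.6 × and 0.2 × that for MCI converters and stables, 0 for NC.
* `b(v)`: per-subject between-subject biological variability — white
  noise smoothed to 24 mm FWHM, rescaled to brain-mask SD 0.10 and
  brain-centred. This field is the dominant contribution to the reference
  residual SD because, unlike the measurement noise, it survives the
  12 mm scoring filter. Without it the residual SD collapses to ~0.004
  in normalized units, every error-map-induced shift becomes tens of
  per-voxel t-units, AD t-sums fall below −11089 and the PET score is
  undefined for most pairs; with it, baseline healthy t-sums are O(10³)
  and per-map mean score shifts land at the published order (−0.07).
  The default 0.10 is a realistic regional variability for normalized
  FDG uptake.
* `ε(v)`: measurement noise — white Gaussian, SD 0.05, smoothed to 6 mm.

Ages are uniform on [55, 90] by default (spreading leverage for the
regression-recovery tests); a truncated normal (76.0, 6.3) option matches
the emulated cohort's age distribution. Setting both noise SDs to zero
yields the exact closed-form generator used by the inversion oracles.

## Error fields

Each synthetic error map is

```
e(v) = 1 + g + r(v) + o(region(v))   inside the brain,  e = 1 outside,
```

clipped to [0.7, 1.3]. `g ~ N(−0.0137, 0.0198)` is one draw per map;
`r(v)` is white noise smoothed to 20 mm, rescaled to within-map brain SD
0.02; `o` is +0.0051 on the AD mask and −0.0022 elsewhere in the brain.
Both `r` and `o` are centred to zero mean over the brain mask, so each
map's brain-average error equals `g` exactly (up to clipping, which the
default amplitudes never reach). The across-map mean ± SD of the
brain-average error is therefore `−1.37 % ± 1.98 %` by construction, and
the AD-mask mean sits `0.0073 · (1 − f_AD) ≈ +0.51` percentage points
above it at the phantom's AD fraction `f_AD ≈ 0.30` — reproducing the
−0.86 % vs −1.59 % regional split. The 20 mm correlation length of `r`
is a free choice (the spatial autocorrelation of real MRAC error is not
published); it only spreads per-map regional means and does not move the
calibrated expectations.

Measured-pair error maps (ratio of an MRAC to a CTAC reconstruction) are
supported through the same `ErrorMap` container: the raw ratio is guarded
against near-zero denominators (voxels below 5 % of the brain-mean CTAC
value are set to 1 and counted), resampled to the template with the
transform estimated for the CTAC image, smoothed 12 mm, and brain-masked
with fill value 1. The shipped study uses the synthetic mode.

## Scoring

The t-value denominator defaults to the single-new-observation prediction
form `s_v · sqrt(1 + 1/n + (age − ā)²/Sxx)`, appropriate when one scan is
compared against a fitted regression database; a plain `s_v` variant is
selectable. The AD t-sum is the signed sum over the AD mask — negative
(hyper-normal) voxels subtract — keeping the logarithmic score defined
for hyper-normal scans; clipping negatives at zero is available as an
option. Voxels with zero residual SD contribute t = 0 and are counted in
a diagnostic. The PET-score denominator 11089 is a cohort-derived
constant and is configurable.

The cross simulation evaluates only the AD-mask and preserved-mask
voxels (the only voxels that enter a score), which reduces each of the
9541 pair evaluations to O(10⁴) operations; a test verifies the fast
path agrees with scoring full volumes to 1e-10. Per-pair intensity
re-normalization is applied after error multiplication, so a spatially
constant error changes no score — the error acts only through the ratio
of its AD-mask mean to its preserved-mask mean.

## Evaluation

Classification is positive at score ≥ cutoff (boundary counts as
positive; the convention is otherwise arbitrary and is pinned for
reproducibility). Confidence intervals for proportions are Wilson score
intervals, chosen for sane behaviour at extreme rates; the interval is
clamped to contain the point estimate against float rounding at k = 0 or
k = n. Error maps are ranked by accuracy, ties broken by sensitivity then
map id; the across-map "average/worst/best" aggregates are per-metric
extremes, and the best/worst-3 selection for Bland–Altman agreement uses
the same ranking. The institution comparison is a Welch (unequal
variance) two-sample t-test on per-map mean score differences.

## Registration

Spatial normalization is a 12-parameter affine (3 translations, 3
rotations, 3 scales, 3 shears about the fixed-volume centre) minimizing
mean squared intensity difference, optimized gradient-free (Powell) over
a two-level pyramid (8 mm smoothing with 2× subsampling, then full
resolution). A mono-modal MSE cost suffices because both images in every
within-pipeline registration are PET-like. Nonlinear warping is out of
scope: synthetic subjects are generated directly in template space, so
registration is exercised only by deliberately perturbed test inputs,
where 20 random rigid+scale perturbations (≤10 mm, ≤10°, ≤5 %) are
recovered to under one voxel at brain voxels. Zero-overlap inputs are
flagged as non-converged rather than raised.

## Determinism and problem sizes

One seed governs a run; it is fanned out through named substreams
(subjects, reference, error maps) so stages are independently
reproducible, and reruns produce bit-identical CSVs. The default study —
203 subjects × 47 maps plus a 60-subject reference on the 4 mm lattice —
completes in well under a minute on one CPU; the test suite's
registration-recovery property dominates its ~1.5 minute runtime.

## What the synthetic data does and does not show

The generator reproduces the *structure* the analysis depends on: cohort
composition, group-ordered hypometabolism, age decline, and error fields
whose regional statistics match the published MRAC error pattern. It does
not emulate anatomy, partial-volume or scanner point-spread effects,
dose/scan-duration differences (the two institutions differ only by
label), or the heavy-tailed biological heterogeneity of real cohorts.
Group separation is consequently much cleaner than in real data —
synthetic diagnostic accuracies approach 1.0 and should not be compared
with accuracies measured on real cohorts. What carries over is the
*relative* effect of attenuation-correction error: its direction (score
underestimation when non-AD regions are more underestimated than AD
regions), its approximate magnitude (mean PET-score shift ≈ −0.07), and
its insensitivity to institution.
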