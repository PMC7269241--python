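"""Automated Alzheimer's-discrimination scoring (PALZ-style).

The score of a spatially normalized, smoothed FDG-PET image is computed in
four steps:

1. **Intensity normalization** — divide every voxel by the mean uptake in
   a mask of "AD-preserved" voxels, regions whose metabolism is typically
   spared in Alzheimer's disease.
2. **Expected values** — a per-voxel linear regression of normalized
   uptake on age, fit once on a reference database of healthy controls,
   predicts the expected uptake for the patient's age.
3. **Voxel-wise t-values** — the deviation of the observed uptake below
   its expectation, scaled by the reference residual standard deviation
   inflated for the prediction of a single new observation:

       t_v = (a_v + b_v*age - u_v) / (s_v * sqrt(1 + 1/n + (age-abar)^2/Sxx))

   Positive t means hypometabolism (observed below expected).
4. **AD t-sum and PET score** — the t-values are summed over a predefined
   mask of AD-related voxels, and the sum is mapped to the logarithmic
   PET score ``log2(ad_t_sum / 11089 + 1)``, where 11089 is the 95 %
   prediction limit of the AD t-sum in healthy controls established in the
   NEST-DD multi-centre trial.  A score of 1.0 therefore corresponds
   exactly to that prediction limit and is the decision cutoff for AD
   versus normal; 0.79 is the cutoff used to predict conversion from mild
   cognitive impairment to AD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocessing import gaussian_smooth, resample, AffineTransform
from .volume import VolumeGrid

__all__ = [
    "AD_T_SUM_PREDICTION_LIMIT",
    "ScoringOptions",
    "ReferenceModel",
    "ScoreResult",
    "intensity_normalize",
    "fit_reference_model",
    "t_map",
    "ad_t_sum",
    "pet_score",
    "score_subject",
]

log = logging.getLogger(__name__)

#: 95 % prediction limit of the AD t-sum in healthy controls (NEST-DD trial);
#: denominator of the PET-score transform.  Cohort-derived, hence overridable
#: through :class:`ScoringOptions`.
AD_T_SUM_PREDICTION_LIMIT: float = 11089.0


@dataclass
class ScoringOptions:
    """Tunable choices of the scoring pipeline.

    ``t_denominator`` selects between the prediction-interval denominator
    ``s_v * sqrt(1 + 1/n + (age-abar)^2/Sxx)`` (default, appropriate when a
    single new scan is compared against a regression database) and the
    plain residual denominator ``s_v``.  ``clip_negative_t`` optionally
    zeroes hyper-normal (negative-t) voxels before summation; by default
    the AD t-sum is the signed sum, which keeps the PET score defined for
    hyper-normal scans.
    """

    smoothing_fwhm_mm: float = 12.0
    t_denominator: str = "prediction"  # "prediction" | "residual"
    clip_negative_t: bool = False
    pet_score_denominator: float = AD_T_SUM_PREDICTION_LIMIT

    def __post_init__(self) -> None:
        if self.t_denominator not in ("prediction", "residual"):
            raise ValueError(f"unknown t_denominator {self.t_denominator!r}")
        if self.pet_score_denominator <= 0:
            raise ValueError("pet_score_denominator must be positive")


@dataclass
class ReferenceModel:
    """Per-voxel age-regression of normalized uptake in healthy controls.

    ``intercept`` (a_v), ``slope`` (b_v, per year) and ``residual_sd``
    (s_v) are volumes on the template lattice, defined on ``mask``;
    ``n`` reference subjects with mean age ``mean_age`` and age sum of
    squares ``age_ssq`` = sum (age_i - abar)^2.
    """

    intercept: VolumeGrid
    slope: VolumeGrid
    residual_sd: VolumeGrid
    n: int
    mean_age: float
    age_ssq: float
    mask: VolumeGrid
    age_range: tuple[float, float] = (55.0, 90.0)

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError(f"reference model needs n >= 10 subjects, got {self.n}")
        if self.age_ssq <= 0:
            raise ValueError("degenerate reference design: zero age variance")
        m = self.mask.mask_array()
        s = self.residual_sd.data[m]
        if np.any(s < 0):
            raise ValueError("negative residual SD in reference model")


@dataclass
class ScoreResult:
    """AD t-sum and PET score for one (subject, error-map) pair."""

    subject_id: str
    error_map_id: str
    ad_t_sum: float
    pet_score: float
    normalization_mean: float
    n_zero_sd_voxels: int = 0
    status: str = "ok"


def intensity_normalize(
    volume: VolumeGrid, preserved_mask: VolumeGrid
) -> tuple[VolumeGrid, float]:
    """Divide every voxel by the mean value within the AD-preserved mask.

    Returns the normalized volume and the divisor.  Any positive global
    rescaling of the input cancels exactly, which is what makes the PET
    score insensitive to injected dose and scanner calibration.
    """
    volume.require_same_grid(preserved_mask, "intensity_normalize")
    m = preserved_mask.mask_array()
    if not m.any():
        raise ValueError("preserved mask is empty")
    mean = float(volume.data[m].mean())
    if mean <= 0:
        raise ValueError(f"degenerate image: preserved-mask mean {mean} <= 0")
    return volume.with_data(volume.data / mean), mean


def fit_reference_model(
    normalized_volumes: list[VolumeGrid],
    ages,
    mask: VolumeGrid,
) -> ReferenceModel:
    """Ordinary least squares of normalized uptake on age, voxel by voxel.

    The volumes must already be smoothed and intensity normalized.  For
    each in-mask voxel v: slope b_v = Sxy/Sxx, intercept a_v = ybar - b_v
    * abar, residual SD s_v = sqrt(RSS_v / (n - 2)).
    """
    ages = np.asarray(ages, dtype=float)
    n = len(normalized_volumes)
    if n != ages.size:
        raise ValueError("volumes and ages differ in length")
    if n < 10:
        raise ValueError(f"need >= 10 reference subjects, got {n}")
    if np.allclose(ages, ages[0]):
        raise ValueError("degenerate design: all reference ages equal")
    for v in normalized_volumes[1:]:
        normalized_volumes[0].require_same_grid(v, "fit_reference_model")
    mask.require_same_grid(normalized_volumes[0], "fit_reference_model mask")

    m = mask.mask_array()
    y = np.stack([v.data[m] for v in normalized_volumes])  # (n, nvox)
    abar = float(ages.mean())
    d = ages - abar
    sxx = float(np.sum(d**2))
    slope = (d @ (y - y.mean(axis=0))) / sxx
    intercept = y.mean(axis=0) - slope * abar
    resid = y - (intercept[None, :] + np.outer(ages, slope))
    rss = np.sum(resid**2, axis=0)
    s = np.sqrt(np.maximum(rss, 0.0) / (n - 2))

    def full(vals: np.ndarray) -> VolumeGrid:
        out = np.zeros(mask.shape)
        out[m] = vals
        return mask.with_data(out)

    return ReferenceModel(
        intercept=full(intercept),
        slope=full(slope),
        residual_sd=full(s),
        n=n,
        mean_age=abar,
        age_ssq=sxx,
        mask=mask,
        age_range=(float(ages.min()), float(ages.max())),
    )


def _t_denominator_inflation(model: ReferenceModel, age: float, options: ScoringOptions) -> float:
    if options.t_denominator == "residual":
        return 1.0
    return float(
        np.sqrt(1.0 + 1.0 / model.n + (age - model.mean_age) ** 2 / model.age_ssq)
    )


def t_map(
    normalized_volume: VolumeGrid,
    age: float,
    model: ReferenceModel,
    options: ScoringOptions | None = None,
) -> VolumeGrid:
    """Voxel-wise t-values of a normalized image against the reference model.

    ``t_v = (expected_v - observed_v) / (s_v * inflation)`` on the model
    mask, 0 outside; positive t marks hypometabolism.  Voxels with zero
    residual SD get t = 0 and are counted in a debug-level diagnostic.
    Ages outside the reference range are allowed but logged, since the
    regression then extrapolates.
    """
    options = options or ScoringOptions()
    normalized_volume.require_same_grid(model.mask, "t_map")
    lo, hi = model.age_range
    if not (lo <= age <= hi):
        log.warning("t_map: age %.1f outside reference range [%.1f, %.1f]", age, lo, hi)
    m = model.mask.mask_array()
    expected = model.intercept.data[m] + model.slope.data[m] * age
    observed = normalized_volume.data[m]
    s = model.residual_sd.data[m]
    infl = _t_denominator_inflation(model, age, options)
    zero_sd = s == 0
    denom = np.where(zero_sd, 1.0, s * infl)
    t = np.where(zero_sd, 0.0, (expected - observed) / denom)
    n_zero = int(zero_sd.sum())
    if n_zero:
        log.debug("t_map: %d in-mask voxels with zero residual SD set to t=0", n_zero)
    out = np.zeros(model.mask.shape)
    out[m] = t
    return model.mask.with_data(out)


def ad_t_sum(
    t_values: VolumeGrid, ad_mask: VolumeGrid, clip_negative: bool = False
) -> float:
    """Sum of t-values over the AD-related voxel mask (signed by default)."""
    t_values.require_same_grid(ad_mask, "ad_t_sum")
    m = ad_mask.mask_array()
    if not m.any():
        raise ValueError("AD mask is empty")
    t = t_values.data[m]
    if clip_negative:
        t = np.clip(t, 0.0, None)
    return float(t.sum())


def pet_score(
    t_sum: float, denominator: float = AD_T_SUM_PREDICTION_LIMIT
) -> float:
    """PET score, ``log2(ad_t_sum / denominator + 1)``.

    Maps an AD t-sum equal to the healthy-control prediction limit to
    exactly 1.0, and 0 to 0.0.  Defined only for ``t_sum > -denominator``.
    """
    arg = t_sum / denominator + 1.0
    if arg <= 0:
        raise ValueError(
            f"PET score undefined: AD t-sum {t_sum} <= -{denominator}"
        )
    return float(np.log2(arg))


def score_subject(
    volume: VolumeGrid,
    age: float,
    model: ReferenceModel,
    template,
    options: ScoringOptions | None = None,
    subject_id: str = "subject",
    error_map_id: str = "none",
    already_normalized: bool = False,
    transform: AffineTransform | None = None,
) -> ScoreResult:
    """Run the full scoring pipeline on one volume.

    Pipeline: [affine spatial normalization if a ``transform`` is given]
    -> Gaussian smoothing -> intensity normalization -> t-map -> AD t-sum
    -> PET score.  With ``already_normalized=True`` the spatial steps
    (resampling and smoothing) are skipped: this is the simulation path,
    where error-perturbed images were smoothed upstream and must not be
    smoothed again.

    ``template`` provides ``preserved_mask`` and ``ad_mask`` volumes.
    """
    options = options or ScoringOptions()
    vol = volume
    if not already_normalized:
        if transform is not None:
            vol = resample(vol, transform, template.brain_mask)
        vol = gaussian_smooth(vol, options.smoothing_fwhm_mm)
    normalized, mean = intensity_normalize(vol, template.preserved_mask)
    t = t_map(normalized, age, model, options)
    m = model.mask.mask_array()
    n_zero = int(np.count_nonzero(model.residual_sd.data[m] == 0))
    t_sum = ad_t_sum(t, template.ad_mask, clip_negative=options.clip_negative_t)
    score = pet_score(t_sum, options.pet_score_denominator)
    return ScoreResult(
        subject_id=subject_id,
        error_map_id=error_map_id,
        ad_t_sum=t_sum,
        pet_score=score,
        normalization_mean=mean,
        n_zero_sd_voxels=n_zero,
    )
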