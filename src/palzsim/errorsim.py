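"""Attenuation-correction error maps and the cross-product simulation.

An *error map* is the voxel-wise ratio of a PET reconstruction using
atlas-based MR attenuation correction (MRAC) to the same raw data
reconstructed with CT-based attenuation correction (CTAC); values below 1
mark underestimated uptake.  Raw ratio maps are brought to the template
lattice, smoothed with the same 12 mm filter as the scoring pipeline, and
brain-masked (fill value 1 outside the brain).

Each error map is then imposed *multiplicatively* on each already
normalized-and-smoothed cohort image; no further spatial deformation or
filtering is applied at that point.  Scoring (intensity normalization,
t-map, AD t-sum, PET score) is rerun per perturbed image, so a spatially
constant error cancels exactly in the intensity-normalization step — only
the spatial structure of the error relative to the AD-preserved
normalization region moves the score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import palz
from .palz import ReferenceModel, ScoringOptions
from .preprocessing import AffineTransform, apply_mask, gaussian_smooth, resample
from .volume import VolumeGrid

__all__ = [
    "ErrorMap",
    "map_stats",
    "compute_error_map",
    "normalize_error_map",
    "apply_error",
    "run_cross_simulation",
]

log = logging.getLogger(__name__)


@dataclass
class ErrorMap:
    """A multiplicative MRAC/CTAC error field on the template lattice."""

    map_id: str
    institution: str
    field: VolumeGrid
    source: str = "synthetic"  # "measured-pair" | "synthetic"
    stats: dict = None  # spatial mean error (%) over brain / AD / non-AD

    def __post_init__(self) -> None:
        if self.source not in ("measured-pair", "synthetic"):
            raise ValueError(f"unknown error-map source {self.source!r}")
        if np.any(self.field.data <= 0) or np.any(self.field.data >= 2):
            raise ValueError("error-map values must lie in (0, 2)")


def map_stats(error_field: VolumeGrid, template) -> dict:
    """Spatial mean error, percent deviation from unity, per region.

    Regions are the whole brain mask, the AD-related mask, and the non-AD
    brain (brain minus AD mask).
    """
    brain = template.brain_mask.mask_array()
    ad = template.ad_mask.mask_array()
    non_ad = brain & ~ad
    e = error_field.data
    return {
        "brain": float((e[brain] - 1.0).mean() * 100.0),
        "ad": float((e[ad] - 1.0).mean() * 100.0),
        "non_ad": float((e[non_ad] - 1.0).mean() * 100.0),
    }


def compute_error_map(
    pet_mrac: VolumeGrid,
    pet_ctac: VolumeGrid,
    brain_mask: VolumeGrid,
    eps_frac: float = 0.05,
) -> tuple[VolumeGrid, int]:
    """Voxel-wise ratio MRAC / CTAC with a near-zero-denominator guard.

    The ratio is computed where the CTAC value exceeds ``eps_frac`` times
    the brain-mask mean of the CTAC image; elsewhere (and outside the
    brain mask) the map is set to 1.  Returns the raw error map and the
    count of in-mask voxels excluded by the guard.
    """
    pet_mrac.require_same_grid(pet_ctac, "compute_error_map")
    pet_mrac.require_same_grid(brain_mask, "compute_error_map mask")
    if not 0.0 < eps_frac < 0.5:
        raise ValueError(f"eps_frac must be in (0, 0.5), got {eps_frac}")
    brain = brain_mask.mask_array()
    ctac_mean = float(pet_ctac.data[brain].mean())
    if ctac_mean <= 0:
        raise ValueError("CTAC image has non-positive brain-mask mean")
    valid = brain & (pet_ctac.data > eps_frac * ctac_mean)
    ratio = np.ones(pet_mrac.shape)
    ratio[valid] = pet_mrac.data[valid] / pet_ctac.data[valid]
    n_excluded = int(np.count_nonzero(brain & ~valid))
    if n_excluded:
        log.info("compute_error_map: %d in-mask voxels excluded by ratio guard", n_excluded)
    return pet_mrac.with_data(ratio), n_excluded


def normalize_error_map(
    error_raw: VolumeGrid,
    ctac_to_template_transform: AffineTransform,
    template,
    fwhm_mm: float = 12.0,
    map_id: str = "map",
    institution: str = "InA",
    source: str = "measured-pair",
) -> ErrorMap:
    """Bring a raw error map to the template lattice.

    Resample with the transform estimated for the CTAC image, smooth with
    the scoring filter, apply the brain mask with fill value 1 (so the
    field is exactly neutral outside the brain), and record regional
    statistics.
    """
    resampled = resample(
        error_raw, ctac_to_template_transform, template.brain_mask, fill=1.0
    )
    smoothed = gaussian_smooth(resampled, fwhm_mm)
    masked = apply_mask(smoothed, template.brain_mask, fill=1.0)
    clipped = masked.with_data(np.clip(masked.data, 0.7, 1.3))
    return ErrorMap(
        map_id=map_id,
        institution=institution,
        field=clipped,
        source=source,
        stats=map_stats(clipped, template),
    )


def apply_error(norm_subject_volume: VolumeGrid, error_map: ErrorMap | VolumeGrid) -> VolumeGrid:
    """Impose an error map on a normalized subject image, voxel-wise.

    A plain product; deliberately no re-smoothing or renormalization here —
    intensity normalization happens downstream in the scoring step.
    """
    e = error_map.field if isinstance(error_map, ErrorMap) else error_map
    norm_subject_volume.require_same_grid(e, "apply_error")
    return norm_subject_volume.with_data(norm_subject_volume.data * e.data)


# ---------------------------------------------------------------------------
# Cross-product simulation
# ---------------------------------------------------------------------------

_SCORE_COLUMNS = [
    "subject_id",
    "error_map_id",
    "institution",
    "ad_t_sum",
    "pet_score",
    "normalization_mean",
    "status",
]


def run_cross_simulation(
    subjects,
    error_maps: list[ErrorMap],
    model: ReferenceModel,
    template,
    options: ScoringOptions | None = None,
    csv_path=None,
    include_baseline: bool = True,
) -> pd.DataFrame:
    """Score every (subject, error map) pair, plus per-subject baselines.

    ``subjects`` is a sequence of objects with ``record`` (``subject_id``,
    ``age``) and ``volume`` attributes; volumes must already be spatially
    normalized and smoothed.  For each pair the subject image is multiplied
    by the error field and rescored from the intensity-normalization step
    onward.  Baseline rows carry ``error_map_id == "none"``.

    The computation is restricted to the AD-related and AD-preserved masks
    (the only voxels that enter the score), which makes the full cohort x
    map product cheap; the arithmetic is identical to scoring full volumes
    through :func:`palzsim.palz.score_subject` with
    ``already_normalized=True``.  Rows are appended to ``csv_path``
    incrementally when given; any per-pair failure becomes a flagged row,
    not a crash.
    """
    options = options or ScoringOptions()
    ad = template.ad_mask.mask_array()
    pres = template.preserved_mask.mask_array()
    model_mask = model.mask.mask_array()
    if not np.all(model_mask[ad]):
        raise ValueError("AD mask must lie inside the reference-model mask")

    a_ad = model.intercept.data[ad]
    b_ad = model.slope.data[ad]
    s_ad = model.residual_sd.data[ad]
    zero_sd = s_ad == 0
    n_zero = int(zero_sd.sum())
    safe_s = np.where(zero_sd, 1.0, s_ad)

    e_fields = []
    for em in error_maps:
        em.field.require_same_grid(template.brain_mask, "run_cross_simulation")
        e_fields.append((em.map_id, em.institution, em.field.data[ad], em.field.data[pres]))

    rows: list[dict] = []
    writer_started = False

    def emit(row: dict) -> None:
        nonlocal writer_started
        rows.append(row)
        if csv_path is not None:
            pd.DataFrame([row], columns=_SCORE_COLUMNS).to_csv(
                csv_path, mode="a", header=not writer_started, index=False
            )
            writer_started = True

    def score_pair(u_ad, u_pres, age, subject_id, map_id, institution) -> None:
        try:
            norm = float(u_pres.mean())
            if norm <= 0:
                raise ValueError("non-positive normalization mean")
            infl = palz._t_denominator_inflation(model, age, options)
            expected = a_ad + b_ad * age
            t = np.where(zero_sd, 0.0, (expected - u_ad / norm) / (safe_s * infl))
            if options.clip_negative_t:
                t = np.clip(t, 0.0, None)
            t_sum = float(t.sum())
            score = palz.pet_score(t_sum, options.pet_score_denominator)
            emit(
                {
                    "subject_id": subject_id,
                    "error_map_id": map_id,
                    "institution": institution,
                    "ad_t_sum": t_sum,
                    "pet_score": score,
                    "normalization_mean": norm,
                    "status": "ok",
                }
            )
        except Exception as exc:  # flagged row, simulation continues
            log.warning("pair (%s, %s) failed: %s", subject_id, map_id, exc)
            emit(
                {
                    "subject_id": subject_id,
                    "error_map_id": map_id,
                    "institution": institution,
                    "ad_t_sum": np.nan,
                    "pet_score": np.nan,
                    "normalization_mean": np.nan,
                    "status": f"error: {exc}",
                }
            )

    if n_zero:
        log.debug("run_cross_simulation: %d AD-mask voxels with zero residual SD", n_zero)

    subject_arrays = []
    for subj in subjects:
        subj.volume.require_same_grid(template.brain_mask, "run_cross_simulation")
        subject_arrays.append(
            (subj.record.subject_id, float(subj.record.age), subj.volume.data[ad], subj.volume.data[pres])
        )

    if include_baseline:
        for sid, age, u_ad, u_pres in subject_arrays:
            score_pair(u_ad, u_pres, age, sid, "none", "none")

    for i, (map_id, institution, e_ad, e_pres) in enumerate(e_fields):
        for sid, age, u_ad, u_pres in subject_arrays:
            score_pair(u_ad * e_ad, u_pres * e_pres, age, sid, map_id, institution)
        log.info("run_cross_simulation: map %d/%d (%s) done", i + 1, len(e_fields), map_id)

    return pd.DataFrame(rows, columns=_SCORE_COLUMNS)
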