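"""Synthetic template-space phantom cohorts, reference database and
MRAC-like error fields.

This module stands in for data that cannot ship with the package: a
203-subject FDG-PET cohort (48 normal controls, 59 Alzheimer's patients,
96 with mild cognitive impairment of whom 33 converted to AD within 24
months) and 47 paired MRAC/CTAC reconstructions from two institutions (20
and 27 patients).  Everything is generated directly on the template
lattice, deterministically from a seed, with the statistical structure the
downstream analysis assumes:

* an ellipsoidal brain phantom with a cortical shell carved into AD-related,
  AD-preserved and infratentorial regions (schematic geometry — the scoring
  math only ever inspects masks, never anatomy);
* an age-dependent global decline of uptake and AD-pattern hypometabolism
  restricted to the AD-related mask, with MCI converters/stables at
  configurable fractions of the full AD effect;
* smooth multiplicative error fields whose population statistics are
  calibrated to the regional means observed for atlas-based MRAC: about
  -1.4 % over the whole brain, with AD-related voxels less underestimated
  (about -0.9 %) than the rest of the brain (about -1.6 %).

The error-field construction makes the calibration hold by design: each
map's brain average equals ``1 + g`` with ``g`` drawn once per map from
``Normal(error_global_mean, error_between_map_sd)``, because both the
random spatial component and the regional offsets are centred to zero mean
over the brain mask before being added.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errorsim import ErrorMap, map_stats
from .preprocessing import gaussian_smooth
from .volume import VolumeGrid

__all__ = [
    "ConfigError",
    "TemplateSpace",
    "SubjectRecord",
    "Subject",
    "SimStudyConfig",
    "StudyCohorts",
    "make_template",
    "sample_subject_volume",
    "build_reference_cohort",
    "sample_error_field",
    "make_cohorts",
]

GROUPS = ("NC", "AD", "MCI")
INSTITUTIONS = ("InA", "InB", "ADNI")

#: region-label codes of the phantom
LABEL_BACKGROUND = 0  # outside the brain, or deep white-matter-like core
LABEL_CORTEX = 1  # non-AD cortex
LABEL_AD = 2  # AD-related cortex
LABEL_PRESERVED = 3  # AD-preserved normalization region (superior patch)
LABEL_INFRATENTORIAL = 4  # infratentorial-analogue blob (also AD-preserved)


class ConfigError(ValueError):
    """A configuration that cannot produce a valid study."""


# ---------------------------------------------------------------------------
# Template phantom
# ---------------------------------------------------------------------------


@dataclass
class TemplateSpace:
    """The shared lattice plus the masks the scoring pipeline needs."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray
    brain_mask: VolumeGrid
    ad_mask: VolumeGrid
    preserved_mask: VolumeGrid
    region_labels: VolumeGrid

    def validate(self) -> None:
        brain = self.brain_mask.mask_array()
        ad = self.ad_mask.mask_array()
        pres = self.preserved_mask.mask_array()
        if not brain.any():
            raise ConfigError("brain mask is empty")
        if np.any(ad & ~brain) or np.any(pres & ~brain):
            raise ConfigError("ad/preserved masks must lie inside the brain mask")
        if np.any(ad & pres):
            raise ConfigError("ad_mask and preserved_mask overlap")
        if int(ad.sum()) < 100 or int(pres.sum()) < 100:
            raise ConfigError(
                f"masks too small: |ad|={int(ad.sum())}, |preserved|={int(pres.sum())} (need >= 100)"
            )
        # smoothing headroom: >= 2 voxels of margin to every grid face
        idx = np.argwhere(brain)
        lo = idx.min(axis=0)
        hi = np.asarray(self.grid_shape) - 1 - idx.max(axis=0)
        margin = int(min(lo.min(), hi.min()))
        if margin < 2:
            raise ConfigError(
                f"brain mask margin to grid boundary is {margin} voxels (need >= 2); "
                "grid too small for the phantom"
            )


def _centered_affine(grid_shape, voxel_size_mm) -> np.ndarray:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = voxel_size_mm
    affine[:3, 3] = -(np.asarray(grid_shape) - 1) / 2.0 * np.asarray(voxel_size_mm)
    return affine


def make_template(
    grid_shape=(46, 55, 46), voxel_size_mm=(4.0, 4.0, 4.0)
) -> TemplateSpace:
    """Deterministic geometric phantom of the scoring template.

    An ellipsoidal brain (semi-axes 80 % of the half field of view) with a
    cortical shell; within the shell, bilateral posterior/lateral patches
    form the AD-related mask, a superior/central patch plus an inferior
    infratentorial-analogue blob form the AD-preserved normalization
    region, and the remainder is non-AD cortex.  The AD-related mask
    occupies roughly 30 % of the brain, the proportion implied by the
    regional error statistics the generator is calibrated to.  Purely
    geometric and RNG-free: identical inputs give bit-identical masks.

    Default lattice is 46 x 55 x 46 at 4 mm (half-resolution MNI-like);
    pass ``(91, 109, 91)`` and 2 mm for the full-resolution analogue.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    voxel_size_mm = tuple(float(v) for v in voxel_size_mm)
    if any(g < 24 for g in grid_shape):
        raise ConfigError(f"grid_shape must be >= 24 per axis, got {grid_shape}")
    if any(not 1.0 <= v <= 6.0 for v in voxel_size_mm):
        raise ConfigError(f"voxel size must be in [1, 6] mm, got {voxel_size_mm}")

    affine = _centered_affine(grid_shape, voxel_size_mm)
    ref = VolumeGrid(np.zeros(grid_shape), affine)
    x, y, z = ref.world_coordinates()

    half_extent = np.asarray(grid_shape) * np.asarray(voxel_size_mm) / 2.0
    a, b, c = 0.8 * half_extent
    rho2 = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2
    brain = rho2 <= 1.0
    shell = brain & (rho2 >= 0.6**2)

    infra = brain & (z / c < -0.60)
    preserved_patch = shell & ~infra & (z / c > 0.50)
    ad = (
        shell
        & ~infra
        & ~preserved_patch
        & (np.abs(z / c) <= 0.50)
        & ((y / b < -0.35) | (np.abs(x / a) > 0.60))
    )
    cortex = shell & ~infra & ~preserved_patch & ~ad

    labels = np.zeros(grid_shape, dtype=np.int16)
    labels[cortex] = LABEL_CORTEX
    labels[ad] = LABEL_AD
    labels[preserved_patch] = LABEL_PRESERVED
    labels[infra] = LABEL_INFRATENTORIAL

    preserved = preserved_patch | infra

    template = TemplateSpace(
        grid_shape=grid_shape,
        voxel_size_mm=voxel_size_mm,
        affine=affine,
        brain_mask=VolumeGrid(brain, affine),
        ad_mask=VolumeGrid(ad, affine),
        preserved_mask=VolumeGrid(preserved, affine),
        region_labels=VolumeGrid(labels, affine),
    )
    template.validate()
    return template


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------


@dataclass
class SubjectRecord:
    """Metadata of one cohort subject."""

    subject_id: str
    age: float
    group: str  # NC | AD | MCI
    converted_24mo: bool = False
    institution: str = "ADNI"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.institution not in INSTITUTIONS:
            raise ValueError(f"unknown institution {self.institution!r}")
        if self.converted_24mo and self.group != "MCI":
            raise ValueError("converted_24mo is defined only for MCI subjects")


@dataclass
class Subject:
    record: SubjectRecord
    volume: VolumeGrid


@dataclass
class SimStudyConfig:
    """Study-defining parameters of the synthetic cohort and error fields.

    Cohort sizes default to the emulated study: 48 NC + 59 AD + 96 MCI
    (33 converters) scored subjects, 20 + 27 error maps from the two
    institutions, and a 60-subject healthy reference database for the
    age regression.  Error-field calibration defaults reproduce the
    regional error means of atlas-based MRAC (brain -1.37 %, AD mask
    -0.86 %, non-AD -1.59 %, between-map SD 1.98 %).
    """

    # cohort composition
    n_nc: int = 48
    n_ad: int = 59
    n_mci: int = 96
    n_mci_converters: int = 33
    n_error_maps_a: int = 20
    n_error_maps_b: int = 27
    n_reference: int = 60

    # uptake model
    ad_hypometabolism_fraction: float = 0.20
    mci_converter_fraction_of_ad_effect: float = 0.6
    mci_stable_fraction_of_ad_effect: float = 0.2
    age_slope_per_year: float = -0.003  # relative units / year
    reference_age: float = 72.5  # midpoint of the default age range
    voxel_noise_sd: float = 0.05
    noise_smoothing_fwhm_mm: float = 6.0
    # smooth multiplicative between-subject biological variability; unlike the
    # voxel noise it survives the 12 mm scoring filter and therefore sets the
    # scale of the reference residual SD, hence of every t-value
    between_subject_sd: float = 0.10
    between_subject_fwhm_mm: float = 24.0

    # ages
    age_min: float = 55.0
    age_max: float = 90.0
    age_distribution: str = "uniform"  # "uniform" | "normal"
    age_normal_mean: float = 76.0
    age_normal_sd: float = 6.3

    # error fields
    error_global_mean: float = -0.0137
    error_between_map_sd: float = 0.0198
    error_ad_offset: float = +0.0051
    error_nonad_offset: float = -0.0022
    error_within_map_sd: float = 0.02
    error_field_fwhm_mm: float = 20.0

    # lattice
    grid_shape: tuple[int, int, int] = (46, 55, 46)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)

    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_nc=self.n_nc,
            n_ad=self.n_ad,
            n_mci=self.n_mci,
            n_error_maps_a=self.n_error_maps_a,
            n_error_maps_b=self.n_error_maps_b,
            n_reference=self.n_reference,
        )
        for name, value in counts.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if not 0 <= self.n_mci_converters <= self.n_mci:
            raise ConfigError("n_mci_converters must be in [0, n_mci]")
        for name in (
            "ad_hypometabolism_fraction",
            "mci_converter_fraction_of_ad_effect",
            "mci_stable_fraction_of_ad_effect",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.error_field_fwhm_mm <= 0:
            raise ConfigError("error_field_fwhm_mm must be positive")
        if self.age_min >= self.age_max:
            raise ConfigError("age range is empty")
        if self.age_distribution not in ("uniform", "normal"):
            raise ConfigError(f"unknown age_distribution {self.age_distribution!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimStudyConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "voxel_size_mm" in d:
            d["voxel_size_mm"] = tuple(d["voxel_size_mm"])
        return cls(**d)


def _sample_ages(n: int, config: SimStudyConfig, rng: np.random.Generator) -> np.ndarray:
    if config.age_distribution == "uniform":
        return rng.uniform(config.age_min, config.age_max, size=n)
    # truncated normal by resampling; the default study uses uniform ages,
    # which spread leverage for the regression-recovery checks
    ages = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(config.age_normal_mean, config.age_normal_sd, size=n)
        keep = draw[(draw >= config.age_min) & (draw <= config.age_max)]
        take = min(len(keep), n - filled)
        ages[filled : filled + take] = keep[:take]
        filled += take
    return ages


def _effect_fraction(record: SubjectRecord, config: SimStudyConfig) -> float:
    if record.group == "AD":
        return config.ad_hypometabolism_fraction
    if record.group == "MCI":
        frac = (
            config.mci_converter_fraction_of_ad_effect
            if record.converted_24mo
            else config.mci_stable_fraction_of_ad_effect
        )
        return config.ad_hypometabolism_fraction * frac
    return 0.0


def sample_subject_volume(
    template: TemplateSpace,
    record: SubjectRecord,
    config: SimStudyConfig,
    rng: np.random.Generator,
) -> VolumeGrid:
    """One synthetic FDG-PET volume in template space.

    ``u(v) = baseline(v) * (1 + age_slope * (age - age_ref)) * (1 - effect(v))
    * (1 + beta(v)) + smoothed noise``, clipped at 0.  Baseline is 1.0 in
    every gray region label (cortex, AD, preserved, infratentorial), 0.25
    in the white-matter-like brain core, 0 outside the brain.  The AD
    effect is a fractional uptake reduction confined to the AD-related
    mask: the full ``ad_hypometabolism_fraction`` for AD subjects, the
    configured fractions of it for MCI converters and stables, none for
    NC.

    Two stochastic components model different things.  ``beta(v)`` is a
    per-subject smooth field (white noise smoothed to
    ``between_subject_fwhm_mm``, rescaled to brain-mask SD
    ``between_subject_sd`` and brain-centred): the between-subject
    biological variability of regional metabolism, which survives the
    scoring pipeline's 12 mm filter and therefore dominates the reference
    residual SD.  The additive voxel noise (SD ``voxel_noise_sd``,
    smoothed to ``noise_smoothing_fwhm_mm``) is measurement noise and is
    largely removed by smoothing.  Setting both SDs to 0 gives the exact
    deterministic generator used by the closed-form inversion checks.
    """
    if not config.age_min <= record.age <= config.age_max:
        raise ValueError(
            f"age {record.age} outside configured range "
            f"[{config.age_min}, {config.age_max}]"
        )
    labels = template.region_labels.data
    brain = template.brain_mask.mask_array()
    baseline = np.where(labels > 0, 1.0, np.where(brain, 0.25, 0.0))

    age_factor = 1.0 + config.age_slope_per_year * (record.age - config.reference_age)
    effect = np.where(
        template.ad_mask.mask_array(), _effect_fraction(record, config), 0.0
    )
    u = baseline * age_factor * (1.0 - effect)

    if config.between_subject_sd > 0:
        beta = gaussian_smooth(
            VolumeGrid(rng.normal(0.0, 1.0, size=template.grid_shape), template.affine),
            config.between_subject_fwhm_mm,
        ).data
        beta_sd = float(beta[brain].std())
        if beta_sd > 0:
            beta *= config.between_subject_sd / beta_sd
        beta -= beta[brain].mean()
        u = u * (1.0 + beta)

    if config.voxel_noise_sd > 0:
        noise = rng.normal(0.0, config.voxel_noise_sd, size=template.grid_shape)
        noise_vol = gaussian_smooth(
            VolumeGrid(noise, template.affine), config.noise_smoothing_fwhm_mm
        )
        u = u + noise_vol.data

    return VolumeGrid(np.clip(u, 0.0, None), template.affine)


def build_reference_cohort(
    template: TemplateSpace, config: SimStudyConfig, rng: np.random.Generator
) -> tuple[list[VolumeGrid], np.ndarray]:
    """The healthy-control reference database: volumes paired with ages."""
    if config.n_reference < 10:
        raise ConfigError(
            f"n_reference = {config.n_reference} < 10: age regression under-determined"
        )
    ages = _sample_ages(config.n_reference, config, rng)
    volumes = []
    for i, age in enumerate(ages):
        record = SubjectRecord(
            subject_id=f"ref-{i:03d}", age=float(age), group="NC", institution="ADNI"
        )
        volumes.append(sample_subject_volume(template, record, config, rng))
    return volumes, ages


def sample_error_field(
    template: TemplateSpace,
    institution: str,
    config: SimStudyConfig,
    rng: np.random.Generator,
) -> VolumeGrid:
    """One smooth multiplicative MRAC-like error field.

    ``e(v) = 1 + g + r(v) + o(region(v))`` inside the brain mask and
    exactly 1 outside, clipped to [0.7, 1.3]:

    * ``g ~ Normal(error_global_mean, error_between_map_sd)``, one draw per
      map — the between-map variation of the global underestimation;
    * ``r(v)``: white noise smoothed to ``error_field_fwhm_mm``, rescaled
      to within-map SD ``error_within_map_sd`` and centred over the brain;
    * ``o``: ``error_ad_offset`` on the AD mask, ``error_nonad_offset`` on
      the rest of the brain, centred over the brain so the offsets change
      regional contrast without moving the brain average.

    Because ``r`` and ``o`` are brain-centred, each map's brain-average
    error equals ``g`` (up to clipping), so the across-map mean and SD of
    the brain-average error reproduce the configured calibration directly.
    """
    if institution not in ("InA", "InB"):
        raise ValueError(f"institution must be InA or InB, got {institution!r}")
    brain = template.brain_mask.mask_array()
    ad = template.ad_mask.mask_array()

    g = rng.normal(config.error_global_mean, config.error_between_map_sd)

    white = rng.normal(0.0, 1.0, size=template.grid_shape)
    r = gaussian_smooth(
        VolumeGrid(white, template.affine), config.error_field_fwhm_mm
    ).data
    r_brain_sd = float(r[brain].std())
    if r_brain_sd > 0 and config.error_within_map_sd > 0:
        r = r * (config.error_within_map_sd / r_brain_sd)
    else:
        r = np.zeros_like(r)
    r -= r[brain].mean()

    o = np.where(ad, config.error_ad_offset, config.error_nonad_offset)
    o -= o[brain].mean()

    e = np.ones(template.grid_shape)
    e[brain] = 1.0 + g + r[brain] + o[brain]
    return VolumeGrid(np.clip(e, 0.7, 1.3), template.affine)


# ---------------------------------------------------------------------------
# Whole study
# ---------------------------------------------------------------------------


@dataclass
class StudyCohorts:
    template: TemplateSpace
    subjects: list[Subject]
    reference_volumes: list[VolumeGrid] = field(repr=False)
    reference_ages: np.ndarray = field(repr=False)
    error_maps: list[ErrorMap] = field(repr=False)


def make_cohorts(config: SimStudyConfig, rng=None) -> StudyCohorts:
    """Generate the full synthetic study from one seed.

    Three independent named substreams (subjects, reference, error maps)
    are spawned from the seed so each stage is reproducible on its own.
    Returns subject volumes with records (exactly ``n_mci_converters`` of
    the MCI flagged as converters), the reference cohort, and the tagged
    error maps.
    """
    config.validate()
    if rng is None:
        rng = np.random.SeedSequence(config.seed)
    if isinstance(rng, np.random.SeedSequence):
        ss_subjects, ss_reference, ss_errors = rng.spawn(3)
        rng_subjects = np.random.default_rng(ss_subjects)
        rng_reference = np.random.default_rng(ss_reference)
        rng_errors = np.random.default_rng(ss_errors)
    else:
        rng_subjects, rng_reference, rng_errors = rng.spawn(3)

    template = make_template(config.grid_shape, config.voxel_size_mm)

    records: list[SubjectRecord] = []
    for i in range(config.n_nc):
        records.append(SubjectRecord(f"nc-{i:03d}", 0.0, "NC"))
    for i in range(config.n_ad):
        records.append(SubjectRecord(f"ad-{i:03d}", 0.0, "AD"))
    for i in range(config.n_mci):
        records.append(
            SubjectRecord(
                f"mci-{i:03d}", 0.0, "MCI", converted_24mo=i < config.n_mci_converters
            )
        )
    ages = _sample_ages(len(records), config, rng_subjects)
    subjects = []
    for record, age in zip(records, ages):
        record.age = float(age)
        subjects.append(
            Subject(record, sample_subject_volume(template, record, config, rng_subjects))
        )

    reference_volumes, reference_ages = build_reference_cohort(
        template, config, rng_reference
    )

    error_maps: list[ErrorMap] = []
    for institution, count in (("InA", config.n_error_maps_a), ("InB", config.n_error_maps_b)):
        for i in range(count):
            fld = sample_error_field(template, institution, config, rng_errors)
            error_maps.append(
                ErrorMap(
                    map_id=f"{institution}-{i:02d}",
                    institution=institution,
                    field=fld,
                    source="synthetic",
                    stats=map_stats(fld, template),
                )
            )

    return StudyCohorts(
        template=template,
        subjects=subjects,
        reference_volumes=reference_volumes,
        reference_ages=reference_ages,
        error_maps=error_maps,
    )
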