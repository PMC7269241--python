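"""Study endpoints: regional error summaries, diagnostic accuracy at fixed
PET-score cutoffs, error-map ranking, Bland-Altman agreement and the
between-institution comparison.

Two classification tasks are evaluated.  Discrimination of AD from normal
controls uses the cutoff PET score = 1.0 (the healthy-control prediction
limit); prediction of conversion from MCI to AD within 24 months uses the
cutoff 0.79.  A score at or above the cutoff predicts the positive class.
Proportion confidence intervals are Wilson score intervals at the 95 %
level; the institution comparison is a Welch two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CUTOFF_AD_VS_NC",
    "CUTOFF_MCI_CONVERSION",
    "DiagnosticSummary",
    "BlandAltmanResult",
    "InstitutionComparison",
    "regional_error_summary",
    "score_differences",
    "diagnostic_metrics",
    "rank_error_maps",
    "bland_altman",
    "compare_institutions",
]

CUTOFF_AD_VS_NC: float = 1.0
CUTOFF_MCI_CONVERSION: float = 0.79

_METRICS = ("accuracy", "sensitivity", "specificity")


@dataclass
class DiagnosticSummary:
    """Confusion counts and metrics for one (task, error map, cutoff)."""

    task: str  # "AD_vs_NC" | "MCI_conversion"
    error_map_id: str  # map id or "original"
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    accuracy_ci: tuple[float, float]
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]

    def as_row(self) -> dict:
        return {
            "task": self.task,
            "error_map_id": self.error_map_id,
            "cutoff": self.cutoff,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy_ci_low": self.accuracy_ci[0],
            "accuracy_ci_high": self.accuracy_ci[1],
            "sensitivity_ci_low": self.sensitivity_ci[0],
            "sensitivity_ci_high": self.sensitivity_ci[1],
            "specificity_ci_low": self.specificity_ci[0],
            "specificity_ci_high": self.specificity_ci[1],
        }


@dataclass
class BlandAltmanResult:
    """Limits-of-agreement summary of paired simulated vs baseline scores."""

    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    n_pairs: int
    pair_means: np.ndarray
    pair_differences: np.ndarray


@dataclass
class InstitutionComparison:
    t_statistic: float
    p_value: float
    group_means: dict
    group_sds: dict
    group_ns: dict


def regional_error_summary(error_maps, template) -> pd.DataFrame:
    """Per-map spatial mean error (% deviation from 1) per region.

    Regions: whole brain mask, AD-related mask, and non-AD brain (brain
    minus AD mask).  The returned frame has one row per map plus a final
    ``"mean"`` and ``"sd"`` row across maps — the population statistics the
    error-field generator is calibrated against.
    """
    brain = template.brain_mask.mask_array()
    ad = template.ad_mask.mask_array()
    non_ad = brain & ~ad
    if not (brain.any() and ad.any() and non_ad.any()):
        raise ValueError("empty evaluation region")
    rows = []
    for em in error_maps:
        field = em.field if hasattr(em, "field") else em
        field.require_same_grid(template.brain_mask, "regional_error_summary")
        e = field.data
        rows.append(
            {
                "map_id": getattr(em, "map_id", f"map-{len(rows):02d}"),
                "institution": getattr(em, "institution", "unknown"),
                "brain_mean_pct": float((e[brain] - 1.0).mean() * 100.0),
                "ad_mean_pct": float((e[ad] - 1.0).mean() * 100.0),
                "non_ad_mean_pct": float((e[non_ad] - 1.0).mean() * 100.0),
            }
        )
    df = pd.DataFrame(rows)
    num = df[["brain_mean_pct", "ad_mean_pct", "non_ad_mean_pct"]]
    summary = pd.DataFrame(
        [
            {"map_id": "mean", "institution": "", **num.mean().to_dict()},
            {"map_id": "sd", "institution": "", **num.std(ddof=1).to_dict()},
        ]
    )
    return pd.concat([df, summary], ignore_index=True)


def score_differences(score_table: pd.DataFrame) -> pd.DataFrame:
    """Simulated-minus-baseline PET score per (subject, map) row.

    Requires a baseline row (``error_map_id == "none"``) for every subject.
    Returns the per-row differences; the per-map and overall mean +- SD
    aggregates are in the frame's ``attrs["per_map"]`` and
    ``attrs["overall"]``.
    """
    baselines = score_table[score_table["error_map_id"] == "none"]
    simulated = score_table[score_table["error_map_id"] != "none"].copy()
    base_by_subject = baselines.set_index("subject_id")["pet_score"]
    missing = set(simulated["subject_id"]) - set(base_by_subject.index)
    if missing:
        raise ValueError(f"missing baseline for subjects: {sorted(missing)[:5]}")
    simulated["baseline_pet_score"] = simulated["subject_id"].map(base_by_subject)
    simulated["score_difference"] = (
        simulated["pet_score"] - simulated["baseline_pet_score"]
    )
    per_map = (
        simulated.groupby("error_map_id")["score_difference"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    simulated.attrs["per_map"] = per_map
    simulated.attrs["overall"] = {
        "mean": float(simulated["score_difference"].mean()),
        "sd": float(simulated["score_difference"].std(ddof=1)),
        "n": int(len(simulated)),
    }
    return simulated


def _wilson_ci(k: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    # guard float rounding at the boundaries so the interval always
    # contains the point estimate k/n
    p = k / n
    return (min(float(lo), p), max(float(hi), p))


def diagnostic_metrics(
    scores,
    truth_labels,
    cutoff: float,
    task: str = "AD_vs_NC",
    error_map_id: str = "original",
) -> DiagnosticSummary:
    """Confusion counts and accuracy/sensitivity/specificity at a cutoff.

    ``truth_labels`` is boolean (True = positive class: AD for the
    discrimination task, converter for the prediction task).  Prediction is
    positive when ``score >= cutoff``.  Metrics whose denominator is zero
    are reported as NaN.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth_labels, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and labels differ in length")
    pred = scores >= cutoff
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    n_pos, n_neg, n = tp + fn, tn + fp, tp + fp + tn + fn

    def safe(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return DiagnosticSummary(
        task=task,
        error_map_id=error_map_id,
        cutoff=cutoff,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=safe(tp + tn, n),
        sensitivity=safe(tp, n_pos),
        specificity=safe(tn, n_neg),
        accuracy_ci=_wilson_ci(tp + tn, n),
        sensitivity_ci=_wilson_ci(tp, n_pos),
        specificity_ci=_wilson_ci(tn, n_neg),
    )


@dataclass
class RankedMaps:
    """Error maps ordered best-to-worst plus across-map aggregates."""

    order: list
    aggregates: pd.DataFrame  # rows: average/worst/best, columns: metrics

    def best(self, k: int = 3) -> list:
        return self.order[:k]

    def worst(self, k: int = 3) -> list:
        return self.order[-k:][::-1]


def rank_error_maps(summaries: list[DiagnosticSummary]) -> RankedMaps:
    """Order per-map summaries by accuracy (descending).

    Ties break by sensitivity (descending), then map id (lexicographic).
    The aggregate table carries the across-map average, minimum ("worst")
    and maximum ("best") of each metric — per-metric extremes, not one
    map's full row.
    """
    if not summaries:
        raise ValueError("no per-map summaries to rank")
    df = pd.DataFrame([s.as_row() for s in summaries])
    df = df.sort_values(
        by=["accuracy", "sensitivity", "error_map_id"],
        ascending=[False, False, True],
    )
    agg = pd.DataFrame(
        {
            "accuracy": [
                df["accuracy"].mean(),
                df["accuracy"].min(),
                df["accuracy"].max(),
            ],
            "sensitivity": [
                df["sensitivity"].mean(),
                df["sensitivity"].min(),
                df["sensitivity"].max(),
            ],
            "specificity": [
                df["specificity"].mean(),
                df["specificity"].min(),
                df["specificity"].max(),
            ],
        },
        index=["average", "worst", "best"],
    )
    return RankedMaps(order=df["error_map_id"].tolist(), aggregates=agg)


def bland_altman(baseline_scores, simulated_scores) -> BlandAltmanResult:
    """Agreement between paired baseline and simulated PET scores.

    Differences are simulated - baseline; limits of agreement are the mean
    difference +- 1.96 SD (SD with n-1 denominator).  The pair means and
    differences are returned as the plotting payload.
    """
    base = np.asarray(baseline_scores, dtype=float)
    sim = np.asarray(simulated_scores, dtype=float)
    if base.shape != sim.shape:
        raise ValueError(f"length mismatch: {base.shape} vs {sim.shape}")
    if base.size < 2:
        raise ValueError("need at least 2 pairs")
    d = sim - base
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_difference=mean_d,
        sd_difference=sd_d,
        loa_low=mean_d - 1.96 * sd_d,
        loa_high=mean_d + 1.96 * sd_d,
        n_pairs=int(base.size),
        pair_means=(base + sim) / 2.0,
        pair_differences=d,
    )


def compare_institutions(per_map_mean_diffs, institution_labels) -> InstitutionComparison:
    """Welch two-sample t-test on per-map mean score differences by site."""
    values = np.asarray(per_map_mean_diffs, dtype=float)
    labels = np.asarray(institution_labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two institutions, got {groups}")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each institution needs >= 2 maps")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return InstitutionComparison(
        t_statistic=float(t),
        p_value=float(p),
        group_means={groups[0]: float(a.mean()), groups[1]: float(b.mean())},
        group_sds={groups[0]: float(a.std(ddof=1)), groups[1]: float(b.std(ddof=1))},
        group_ns={groups[0]: int(len(a)), groups[1]: int(len(b))},
    )


def bland_altman_plot(result: BlandAltmanResult, title: str, path) -> None:
    """Render one Bland-Altman panel to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.pair_means, result.pair_differences, s=8, alpha=0.5)
    ax.axhline(result.mean_difference, color="k", lw=1)
    ax.axhline(result.loa_low, color="k", lw=1, ls="--")
    ax.axhline(result.loa_high, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of baseline and simulated PET score")
    ax.set_ylabel("simulated - baseline")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
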