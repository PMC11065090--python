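"""Cohort statistics: group comparisons, correlations with histology, ROC.

The study design compares three groups — active EoE (aEoE, PEC >= 15
eosinophils per high-power field with symptoms), inactive EoE (iEoE), and
non-EoE controls — with one-way ANOVA plus Tukey's honestly-significant-
difference pairwise comparisons, relates imaging readouts to histology
scores by Spearman rank correlation, and evaluates diagnostic accuracy of
the headline readout (mean pore area) by ROC analysis with a Youden-index
operating point.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "HPF_AREA_MM2",
    "EOEHSS_FEATURES",
    "HistopathologyScores",
    "GroupComparison",
    "RocReport",
    "total_eoehss",
    "anova_tukey",
    "spearman_correlations",
    "roc_analysis",
    "run_cohort_analysis",
    "scores_to_frame",
]

#: Area of one high-power field; gives PEC (eos/hpf) its physical meaning.
HPF_AREA_MM2 = 0.237

#: The eight ordinal histology features, each graded 0-3:
#: eosinophilic inflammation, basal zone hyperplasia, eosinophilic abscess,
#: eosinophil surface layering, dilated intercellular spaces, surface
#: epithelial alteration, dyskeratotic epithelial cells, lamina propria
#: fibrosis.
EOEHSS_FEATURES = ("ei", "bzh", "ea", "esl", "dis", "sea", "dec", "lpf")

GROUPS = ("aEoE", "iEoE", "nonEoE")


@dataclasses.dataclass
class HistopathologyScores:
    """PEC plus the eight EoEHSS feature grades for one sample."""

    sample_id: str
    group: str
    pec: int
    ei: int = 0
    bzh: int = 0
    ea: int = 0
    esl: int = 0
    dis: int = 0
    sea: int = 0
    dec: int = 0
    lpf: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.pec < 0 or self.pec != int(self.pec):
            raise ValueError("pec must be a nonnegative integer")
        for f in EOEHSS_FEATURES:
            v = getattr(self, f)
            if v not in (0, 1, 2, 3):
                raise ValueError(f"feature {f} must be an integer grade in 0..3")

    @property
    def total_eoehss(self) -> float:
        return total_eoehss(self)


def total_eoehss(scores: "HistopathologyScores | Sequence[float]") -> float:
    """Total histology grade: arithmetic mean of the assessed feature grades.

    Accepts a :class:`HistopathologyScores` or a sequence of grades; NaN
    entries count as unassessed and reduce the denominator.
    """
    if isinstance(scores, HistopathologyScores):
        vals = np.array([getattr(scores, f) for f in EOEHSS_FEATURES], float)
    else:
        vals = np.asarray(scores, float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no assessed features")
    return float(vals.mean())


def scores_to_frame(scores: Sequence[HistopathologyScores]) -> pd.DataFrame:
    rows = []
    for s in scores:
        row = {"sample_id": s.sample_id, "group": s.group, "pec": s.pec}
        row.update({f: getattr(s, f) for f in EOEHSS_FEATURES})
        row["total_eoehss"] = s.total_eoehss
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA + Tukey


@dataclasses.dataclass
class GroupComparison:
    """One metric's group comparison: omnibus ANOVA plus Tukey pairwise."""

    metric: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    f_statistic: float
    p_omnibus: float
    pairwise_p: dict[tuple[str, str], float]
    flags: tuple[str, ...] = ()


def anova_tukey(
    values: Sequence[float],
    groups: Sequence[str],
    metric: str = "metric",
    group_order: Sequence[str] | None = None,
) -> GroupComparison:
    """Classical one-way ANOVA with Tukey HSD adjusted pairwise p-values.

    Tukey adjustment uses the studentized-range distribution with the
    pooled within-group variance; adjusted p-values are always at least the
    unadjusted pairwise t-test p on the same contrast.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    names = list(group_order) if group_order is not None else list(dict.fromkeys(groups))
    arrays = [values[groups == g] for g in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for g, a in zip(names, arrays):
        if len(a) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    flags: list[str] = []
    if all(np.allclose(a.var(ddof=1), 0.0) for a in arrays):
        flags.append("zero_within_group_variance")
        f_stat, p_omni = float("nan"), float("nan")
        pair_p = {
            (names[i], names[j]): float("nan") if not np.allclose(arrays[i].mean(), arrays[j].mean()) else 1.0
            for i in range(len(names))
            for j in range(i + 1, len(names))
        }
    else:
        f_stat, p_omni = sps.f_oneway(*arrays)
        res = sps.tukey_hsd(*arrays)
        pair_p = {}
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pair_p[(names[i], names[j])] = float(res.pvalue[i, j])
        if values.var(ddof=0) == 0:  # identical everything
            f_stat, p_omni = 0.0, 1.0
    return GroupComparison(
        metric=metric,
        group_means={g: float(a.mean()) for g, a in zip(names, arrays)},
        group_sds={g: float(a.std(ddof=1)) for g, a in zip(names, arrays)},
        group_ns={g: int(len(a)) for g, a in zip(names, arrays)},
        f_statistic=float(f_stat),
        p_omnibus=float(p_omni),
        pairwise_p=pair_p,
        flags=tuple(flags),
    )


def comparison_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        row: dict = {"metric": c.metric, "F": c.f_statistic, "p_omnibus": c.p_omnibus}
        for g, m in c.group_means.items():
            row[f"mean_{g}"] = m
            row[f"sd_{g}"] = c.group_sds[g]
            row[f"n_{g}"] = c.group_ns[g]
        for (g1, g2), p in c.pairwise_p.items():
            row[f"p_{g1}_vs_{g2}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spearman correlations


def _spearman(x: np.ndarray, y: np.ndarray, method: str, rng: np.random.Generator | None):
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan"), ("constant_input",)
    r, p = sps.spearmanr(x, y)
    flags: tuple[str, ...] = ()
    if method == "permutation":
        rng = rng or np.random.default_rng(0)
        n_perm = 9999
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        perm_r = np.empty(n_perm)
        for i in range(n_perm):
            perm_r[i] = np.corrcoef(rx, rng.permutation(ry))[0, 1]
        p = (1 + np.sum(np.abs(perm_r) >= obs - 1e-12)) / (n_perm + 1)
        flags = ("permutation_p",)
    return float(r), float(p), flags


def spearman_correlations(
    metrics: pd.DataFrame,
    histo: pd.DataFrame,
    metric_cols: Sequence[str] | None = None,
    score_cols: Sequence[str] = ("pec", "bzh", "lpf", "total_eoehss"),
    method: str = "t",
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman r and p for each imaging readout x histology score pair.

    Both tables must carry ``sample_id``. ``method="t"`` uses the standard
    t-approximation for the p-value (adequate at this cohort size);
    ``method="permutation"`` draws a permutation null instead, offered for
    small n. Constant inputs yield NaN cells. Ties are handled with average
    ranks.
    """
    joined = metrics.merge(histo, on="sample_id", suffixes=("", "_histo"))
    if len(joined) < 4:
        raise ValueError("need at least 4 paired samples")
    if metric_cols is None:
        metric_cols = [
            c for c in metrics.columns if c not in ("sample_id", "group") and np.issubdtype(metrics[c].dtype, np.number)
        ]
    rng = np.random.default_rng(seed)
    rows = []
    for m in metric_cols:
        for s in score_cols:
            x = joined[m].to_numpy(float)
            y = joined[s].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            r, p, flags = _spearman(x[ok], y[ok], method, rng)
            rows.append({"metric": m, "score": s, "r": r, "p": p, "n": int(ok.sum()),
                         "flags": ";".join(flags)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROC


@dataclasses.dataclass
class RocReport:
    """ROC analysis of one metric for one two-group contrast."""

    contrast: str
    auc: float
    threshold: float
    sensitivity_pct: float
    specificity_pct: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_analysis(
    values: Sequence[float],
    labels: Sequence[bool],
    contrast: str = "",
    threshold_rule: str = "youden",
    greater_is_positive: bool = True,
) -> RocReport:
    """ROC curve, AUC, and an operating threshold.

    The operating threshold is the midpoint between adjacent distinct metric
    values maximizing Youden's J (sensitivity + specificity - 1); ties break
    toward higher specificity. ``threshold_rule="max_specificity"`` instead
    picks the highest-sensitivity point among those with perfect
    specificity.
    """
    v = np.asarray(values, float)
    y = np.asarray(labels, bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be non-empty")
    score = v if greater_is_positive else -v
    fpr, tpr, thr = _sk_roc_curve(y, score)
    roc_auc = float(_sk_auc(fpr, tpr))

    # candidate cuts: midpoints between adjacent distinct values (plus
    # outer sentinels)
    sv = np.unique(score)
    cuts = np.concatenate([[sv[0] - 1.0], (sv[:-1] + sv[1:]) / 2.0, [sv[-1] + 1.0]])
    pos = score[y]
    neg = score[~y]
    sens = np.array([(pos > c).mean() for c in cuts])
    spec = np.array([(neg <= c).mean() for c in cuts])
    if threshold_rule == "youden":
        j = sens + spec - 1.0
        best = np.flatnonzero(np.isclose(j, j.max()))
    elif threshold_rule == "max_specificity":
        perfect = np.flatnonzero(np.isclose(spec, spec.max()))
        best = perfect[np.argsort(-sens[perfect], kind="stable")][:1]
    else:
        raise ValueError(f"unknown threshold_rule {threshold_rule!r}")
    k = best[np.argmax(spec[best])]  # tie-break toward higher specificity
    cut = cuts[k] if greater_is_positive else -cuts[k]
    return RocReport(
        contrast=contrast,
        auc=roc_auc,
        threshold=float(cut),
        sensitivity_pct=100.0 * float(sens[k]),
        specificity_pct=100.0 * float(spec[k]),
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
    )


# ---------------------------------------------------------------------------
# full cohort analysis


MORPHOMETRY_METRICS = (
    "mean_fiber_width_um",
    "fiber_coverage_pct",
    "shg_tpef_ratio",
    "fb_ratio",
    "mean_pore_area_um2",
    "pore_density_per_mm2",
)


@dataclasses.dataclass
class CohortReport:
    """Bundle of group comparisons, correlations, and ROC reports."""

    comparisons: list[GroupComparison]
    correlations: pd.DataFrame
    rocs: list[RocReport]

    def comparisons_frame(self) -> pd.DataFrame:
        return comparison_to_frame(self.comparisons)

    def rocs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "contrast": r.contrast,
                    "auc": r.auc,
                    "threshold": r.threshold,
                    "sensitivity_pct": r.sensitivity_pct,
                    "specificity_pct": r.specificity_pct,
                }
                for r in self.rocs
            ]
        )


def run_cohort_analysis(
    results: pd.DataFrame,
    histo: pd.DataFrame,
    roc_metric: str = "mean_pore_area_um2",
    threshold_rule: str = "youden",
    spearman_method: str = "t",
    seed: int = 0,
) -> CohortReport:
    """Joint analysis of a per-sample results table and a histology table.

    Emits one :class:`GroupComparison` per morphometric readout, the
    Spearman correlation table against PEC/BZH/LPF/total EoEHSS, and ROC
    reports for the configured headline metric on the aEoE-vs-iEoE and
    aEoE-vs-nonEoE contrasts.
    """
    joined = results.merge(histo, on="sample_id", suffixes=("", "_histo"))
    if len(joined) != len(results):
        missing = set(results["sample_id"]) - set(histo["sample_id"])
        raise ValueError(f"unjoinable sample ids: {sorted(missing)}")
    if "group" not in joined.columns and "group_histo" in joined.columns:
        joined["group"] = joined["group_histo"]
    if "total_eoehss" not in joined.columns:
        joined["total_eoehss"] = joined[list(EOEHSS_FEATURES)].mean(axis=1)

    metrics_present = [m for m in MORPHOMETRY_METRICS if m in joined.columns]
    comparisons = [
        anova_tukey(joined[m].to_numpy(float), joined["group"].to_numpy(), metric=m,
                    group_order=[g for g in GROUPS if g in set(joined["group"])])
        for m in metrics_present
    ]
    correlations = spearman_correlations(
        joined[["sample_id"] + metrics_present],
        joined[["sample_id", "pec", "total_eoehss"] + list(EOEHSS_FEATURES)],
        metric_cols=metrics_present,
        method=spearman_method,
        seed=seed,
    )
    rocs = []
    for other in ("iEoE", "nonEoE"):
        sub = joined[joined["group"].isin(["aEoE", other])]
        if sub["group"].nunique() == 2:
            rocs.append(
                roc_analysis(
                    sub[roc_metric].to_numpy(float),
                    (sub["group"] == "aEoE").to_numpy(),
                    contrast=f"aEoE_vs_{other}",
                    threshold_rule=threshold_rule,
                )
            )
    return CohortReport(comparisons=comparisons, correlations=correlations, rocs=rocs)
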