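"""Imbalance-aware evaluation: confusion metrics, ROC/AUC, optimal ROC
point, external score columns, and train-vs-test cohort comparison.

Point metrics follow the conventions for rare binary outcomes:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP) with
0/0 defined as 0, F-score = harmonic mean of precision and sensitivity
(0 when TP = 0), and G-mean = sqrt(sensitivity · specificity). The ROC
curve places one vertex per distinct score (ties grouped) and the AUC is
the trapezoidal area, which equals the Mann-Whitney pairwise concordance
with ties counted one half.

Cohort comparison mirrors a baseline-characteristics table: numeric
variables are compared by two-group one-way ANOVA (the equal-variance
F-test), categorical/binary variables and the outcome by the chi-square
test of independence with Yates continuity correction on 2×2 tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CohortTable
from .errors import ValidationError
from .pattern import Pattern, condition_matrix, match_counts

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RocCurve",
    "confusion",
    "metrics_from_confusion",
    "roc_curve",
    "auc",
    "optimal_roc_point",
    "evaluate_pattern",
    "evaluate_scores",
    "compare_cohorts",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The point-metric panel, optionally with the threshold-free AUC."""

    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    g_mean: float
    auc: float | None = None
    threshold: float | None = None

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f_score": self.f_score,
            "g_mean": self.g_mean,
            "threshold": self.threshold,
        }


@dataclass(frozen=True)
class RocCurve:
    """ROC vertices, one per distinct score, endpoints (0,0) and (1,1).

    ``thresholds[i]`` is the score cutoff (predict positive when
    score ≥ threshold) realizing vertex i; the leading (0,0) vertex
    carries +inf. ``tp``/``fp`` are the raw counts at each vertex.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    n_pos: int
    n_neg: int


def _binary(arr, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if a.size == 0:
        raise ValidationError(f"{name} must be non-empty")
    return a.astype(bool)


def confusion(predictions, labels) -> ConfusionCounts:
    """Tabulate predictions against true labels."""
    p = _binary(predictions, "predictions")
    y = _binary(labels, "labels")
    if p.shape != y.shape:
        raise ValidationError("predictions and labels lengths differ")
    return ConfusionCounts(
        tp=int(np.sum(p & y)),
        fp=int(np.sum(p & ~y)),
        tn=int(np.sum(~p & ~y)),
        fn=int(np.sum(~p & y)),
    )


def metrics_from_confusion(
    c: ConfusionCounts, auc: float | None = None, threshold: float | None = None
) -> MetricsReport:
    """Point metrics from raw counts; degenerate denominators give 0."""
    if c.n < 1:
        raise ValidationError("empty confusion table")
    sens = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    spec = c.tn / (c.tn + c.fp) if c.tn + c.fp else 0.0
    prec = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    if c.tp > 0:
        f = 2.0 * prec * sens / (prec + sens)
    else:
        f = 0.0
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f_score=f,
        g_mean=math.sqrt(sens * spec),
        auc=auc,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# ROC


def roc_curve(scores, labels) -> RocCurve:
    """ROC curve with one vertex per distinct score (descending cutoffs)."""
    s = np.asarray(scores, dtype=float)
    y = _binary(labels, "labels")
    if s.shape != y.shape:
        raise ValidationError("scores and labels lengths differ")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes present")

    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    tp_cum = np.cumsum(y_sorted)
    fp_cum = np.cumsum(~y_sorted)
    # last index of each tie group = the vertex realized by cutoff s
    last = np.flatnonzero(np.r_[np.diff(s_sorted) != 0, True])

    tp = np.r_[0, tp_cum[last]]
    fp = np.r_[0, fp_cum[last]]
    thresholds = np.r_[np.inf, s_sorted[last]]
    return RocCurve(
        fpr=fp / n_neg,
        tpr=tp / n_pos,
        thresholds=thresholds,
        tp=tp,
        fp=fp,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def optimal_roc_point(curve: RocCurve) -> tuple[float, ConfusionCounts]:
    """ROC vertex maximizing Youden's J; ties go to higher specificity.

    Returns the realizing score cutoff and the confusion counts at it.
    """
    j = curve.tpr - curve.fpr
    # scan in increasing-fpr order; strict '>' keeps the earliest
    # (lowest-fpr, i.e. highest-specificity) maximizer
    best = 0
    for i in range(1, len(j)):
        if j[i] > j[best] + 1e-12:
            best = i
    tp = int(curve.tp[best])
    fp = int(curve.fp[best])
    counts = ConfusionCounts(
        tp=tp, fp=fp, tn=curve.n_neg - fp, fn=curve.n_pos - tp
    )
    return float(curve.thresholds[best]), counts


# ---------------------------------------------------------------------------
# model evaluation


def evaluate_pattern(pattern: Pattern, table: CohortTable) -> MetricsReport:
    """Point metrics at the pattern's threshold k plus match-fraction AUC."""
    counts = match_counts(pattern, table.data)
    preds = counts >= pattern.min_matches
    y = table.target.to_numpy()
    curve = roc_curve(counts / pattern.m, y)
    return metrics_from_confusion(
        confusion(preds, y), auc=auc(curve), threshold=float(pattern.min_matches)
    )


def evaluate_scores(
    scores,
    labels,
    cutoff: float | str = "optimal",
    comparator: str = ">=",
) -> MetricsReport:
    """Metrics for an externally computed risk-score column.

    ``cutoff`` may be a published numeric threshold or "optimal" for the
    Youden point of the score's own ROC curve. ``comparator`` selects
    whether score ≥ cutoff or score > cutoff counts as positive.
    """
    s = np.asarray(scores, dtype=float)
    y = _binary(labels, "labels")
    curve = roc_curve(s, y)
    a = auc(curve)
    if cutoff == "optimal":
        cut, counts = optimal_roc_point(curve)
        return metrics_from_confusion(counts, auc=a, threshold=cut)
    cut = float(cutoff)
    if comparator == ">=":
        preds = s >= cut
    elif comparator == ">":
        preds = s > cut
    else:
        raise ValidationError(f"comparator must be '>=' or '>', got {comparator!r}")
    return metrics_from_confusion(confusion(preds, y), auc=a, threshold=cut)


# ---------------------------------------------------------------------------
# cohort comparison


def _chi2_counts(counts: np.ndarray) -> tuple[float, float]:
    """Chi-square test of independence; Yates correction on 2×2 tables.

    Degenerate tables (a zero row/column margin, e.g. a constant variable)
    return statistic 0, p = 1.
    """
    tab = counts[(counts.sum(axis=1) > 0)][:, counts.sum(axis=0) > 0]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return 0.0, 1.0
    res = stats.chi2_contingency(tab, correction=True)
    return float(res.statistic), float(res.pvalue)


def compare_cohorts(train: CohortTable, test: CohortTable) -> pd.DataFrame:
    """Baseline-characteristics comparison of two cohorts.

    One row per schema variable plus the outcome. Numeric variables show
    "mean (SD)" and a one-way ANOVA p-value; categorical/binary variables
    and the outcome show "n (%)" of the positive (or per-level modal)
    category and a chi-square p-value.
    """
    if [s.name for s in train.schema] != [s.name for s in test.schema]:
        raise ValidationError("train and test schemas differ")

    rows = []
    for s in train.schema:
        a = train.data[s.name]
        b = test.data[s.name]
        if s.kind == "numeric":
            av = pd.to_numeric(a, errors="coerce").dropna().to_numpy(dtype=float)
            bv = pd.to_numeric(b, errors="coerce").dropna().to_numpy(dtype=float)
            if len(av) < 2 or len(bv) < 2:
                p = float("nan")
            else:
                p = float(stats.f_oneway(av, bv).pvalue)
            rows.append(
                {
                    "variable": s.name,
                    "kind": s.kind,
                    "train": f"{av.mean():.2f} ({av.std(ddof=1):.2f})",
                    "test": f"{bv.mean():.2f} ({bv.std(ddof=1):.2f})",
                    "p_value": p,
                    "test_name": "one-way ANOVA",
                }
            )
        else:
            levels = sorted(
                set(a.dropna().unique()) | set(b.dropna().unique()), key=str
            )
            counts = np.array(
                [
                    [int((a == lev).sum()) for lev in levels],
                    [int((b == lev).sum()) for lev in levels],
                ]
            )
            _, p = _chi2_counts(counts)
            disp = s.positive_category if s.positive_category in levels else (
                levels[0] if levels else None
            )
            if disp is None:
                tr_s = te_s = "0 (0.0%)"
            else:
                na = int((a == disp).sum())
                nb = int((b == disp).sum())
                tr_s = f"{na} ({100 * na / len(a):.1f}%)"
                te_s = f"{nb} ({100 * nb / len(b):.1f}%)"
            rows.append(
                {
                    "variable": s.name,
                    "kind": s.kind,
                    "train": tr_s,
                    "test": te_s,
                    "p_value": p,
                    "test_name": "chi-square",
                }
            )

    ya = train.target.to_numpy()
    yb = test.target.to_numpy()
    counts = np.array(
        [[int(ya.sum()), int((~ya).sum())], [int(yb.sum()), int((~yb).sum())]]
    )
    _, p = _chi2_counts(counts)
    rows.append(
        {
            "variable": train.target_name,
            "kind": "target",
            "train": f"{ya.sum()} ({100 * ya.mean():.1f}%)",
            "test": f"{yb.sum()} ({100 * yb.mean():.1f}%)",
            "p_value": p,
            "test_name": "chi-square",
        }
    )
    return pd.DataFrame(rows)
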