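"""Data-driven pattern discovery: candidate conditions, exhaustive
matching-threshold optimization, greedy forward search, and chi-square
association arcs between pattern variables.

The search is a deterministic greedy forward selection. Candidate
conditions come one per numeric variable (the maximal-information-gain
cutoff, oriented toward the side with the higher positive-class rate) and
one per observed category of each categorical/binary variable. At each
step every unused candidate is tentatively added, the matching threshold k
is re-optimized exhaustively over 1..m, and the candidate giving the best
training objective is kept; the search stops when the improvement falls
below ``min_improvement``, the candidate pool is exhausted, or the pattern
reaches ``max_conditions``. Ties in objective break toward the candidate
whose match indicator has the stronger chi-square association with the
target, then toward the lexicographically smaller variable name. A pattern
never contains two conditions on the same variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .categorize import best_split
from .core_data import CohortTable
from .errors import ValidationError
from .evaluate import confusion, metrics_from_confusion
from .pattern import Condition, HistoryEntry, Pattern, condition_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "DiscoveryConfig",
    "ArcResult",
    "generate_candidates",
    "optimize_threshold",
    "discover_pattern",
    "compute_arcs",
    "OBJECTIVES",
]


def _f_score(preds: np.ndarray, y: np.ndarray) -> float:
    tp = int(np.sum(preds & y))
    if tp == 0:
        return 0.0
    prec = tp / int(preds.sum())
    rec = tp / int(y.sum())
    return 2.0 * prec * rec / (prec + rec)


def _g_mean(preds: np.ndarray, y: np.ndarray) -> float:
    pos = int(y.sum())
    neg = y.size - pos
    sens = int(np.sum(preds & y)) / pos if pos else 0.0
    spec = int(np.sum(~preds & ~y)) / neg if neg else 0.0
    return float(np.sqrt(sens * spec))


#: Training objectives selectable in :class:`DiscoveryConfig`.
OBJECTIVES = {"f_score": _f_score, "g_mean": _g_mean}


@dataclass(frozen=True)
class DiscoveryConfig:
    """Knobs of the greedy search.

    objective:
        Training metric maximized ("f_score" default, or "g_mean").
    max_conditions:
        Cap on pattern size m (default 16, one per input variable of a
        typical cohort).
    min_improvement:
        Minimal objective gain required to keep growing; the default
        1e-6 accepts any strict improvement.
    seed:
        Reserved; the search itself is deterministic.
    """

    objective: str = "f_score"
    max_conditions: int = 16
    min_improvement: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ValidationError(
                f"objective must be one of {sorted(OBJECTIVES)}, got {self.objective!r}"
            )
        if self.max_conditions < 1:
            raise ValidationError("max_conditions must be >= 1")
        if self.min_improvement < 0:
            raise ValidationError("min_improvement must be >= 0")


@dataclass(frozen=True)
class ArcResult:
    """Chi-square association between two pattern variables' match
    indicators."""

    variable_a: str
    variable_b: str
    chi2: float
    p_value: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "pair": [self.variable_a, self.variable_b],
            "chi2": self.chi2,
            "p": self.p_value,
            "significant": self.significant,
        }


def _check_two_classes(table: CohortTable) -> np.ndarray:
    y = table.target.to_numpy()
    if y.all() or not y.any():
        raise ValidationError("training data must contain both outcome classes")
    return y


def generate_candidates(train: CohortTable) -> list[Condition]:
    """One oriented cutoff condition per numeric variable, one equality
    condition per observed category of categorical/binary variables.

    The numeric comparator points at the split side with the higher
    positive-class rate, so candidates read as risk conditions. Variables
    with no valid split (constant, or all-missing) are omitted.
    """
    y = _check_two_classes(train)
    out: list[Condition] = []
    for s in train.schema:
        col = train.data[s.name]
        if s.kind == "numeric":
            v = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            rule = best_split(v, y, variable=s.name)
            if rule is None:
                continue
            ok = ~np.isnan(v)
            left = ok & (v <= rule.cutoff)
            right = ok & (v > rule.cutoff)
            rate_left = y[left].mean() if left.any() else 0.0
            rate_right = y[right].mean() if right.any() else 0.0
            comparator = "<=" if rate_left >= rate_right else ">"
            out.append(Condition(s.name, comparator, rule.cutoff))
        else:
            for cat in sorted(col.dropna().unique(), key=str):
                out.append(Condition(s.name, "==", cat))
    return out


def _best_k(counts: np.ndarray, y: np.ndarray, m: int, objective) -> tuple[int, float]:
    """Exhaustive scan of k = 1..m; ties toward larger k (stricter)."""
    best_k, best_val = 1, -1.0
    for k in range(1, m + 1):
        val = objective(counts >= k, y)
        if val >= best_val - 1e-12:  # '>=' drifts ties to the larger k
            best_k = k
            best_val = max(best_val, val)
    return best_k, best_val


def optimize_threshold(
    conditions: list[Condition],
    train: CohortTable,
    objective: str = "f_score",
) -> int:
    """Best matching threshold k* for a fixed condition set on training data.

    Evaluates every k in 1..m and returns the maximizer; ties break toward
    the larger (stricter) k. If the objective is 0 for every k, returns m
    and logs a warning.
    """
    if not conditions:
        raise ValidationError("need at least one condition")
    y = train.target.to_numpy()
    counts = condition_matrix(conditions, train.data).sum(axis=1)
    obj = OBJECTIVES[objective]
    k, val = _best_k(counts, y, len(conditions), obj)
    if val <= 0.0:
        logger.warning(
            "objective %s is 0 for every threshold; returning k=m=%d",
            objective,
            len(conditions),
        )
        return len(conditions)
    return k


def _indicator_chi2(ind: np.ndarray, y: np.ndarray) -> float:
    tab = np.array(
        [
            [int(np.sum(ind & y)), int(np.sum(ind & ~y))],
            [int(np.sum(~ind & y)), int(np.sum(~ind & ~y))],
        ]
    )
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return 0.0
    return float(stats.chi2_contingency(tab, correction=True).statistic)


def discover_pattern(
    train: CohortTable,
    config: DiscoveryConfig | None = None,
    timestamp: str | None = None,
) -> Pattern:
    """Greedy forward pattern discovery on a training cohort (pre-mode).

    Returns the pattern with its optimized threshold, tagged ``pre`` and
    carrying the initial history entry with the training objective reached.
    """
    config = config or DiscoveryConfig()
    y = _check_two_classes(train)
    obj = OBJECTIVES[config.objective]

    candidates = generate_candidates(train)
    if not candidates:
        raise ValidationError("no candidate conditions could be generated")
    cols = condition_matrix(candidates, train.data)  # n × n_candidates
    assoc = [_indicator_chi2(cols[:, j], y) for j in range(len(candidates))]

    selected: list[int] = []
    counts = np.zeros(len(train), dtype=int)
    score = 0.0
    k = 1
    while len(selected) < config.max_conditions:
        used_vars = {candidates[j].variable for j in selected}
        best = None  # (score, chi2, -lex rank proxy, j, k)
        for j in range(len(candidates)):
            if j in selected or candidates[j].variable in used_vars:
                continue
            cand_counts = counts + cols[:, j]
            kj, val = _best_k(cand_counts, y, len(selected) + 1, obj)
            key = (val, assoc[j], candidates[j].variable)
            if best is None or _better(key, best[0]):
                best = (key, j, kj)
        if best is None:
            break
        (val, _, _), j, kj = best
        if val - score < config.min_improvement or val <= 0.0:
            break
        selected.append(j)
        counts = counts + cols[:, j]
        score, k = val, kj

    if not selected:
        raise ValidationError(
            "no condition achieved a positive training objective"
        )

    conditions = [candidates[j] for j in selected]
    pattern = Pattern(
        target_variable=train.target_name,
        target_class="Yes",
        conditions=conditions,
        min_matches=k,
        mode_tag="pre",
        history=[
            HistoryEntry(
                mode="pre",
                timestamp=timestamp,
                edits=(),
                m=len(conditions),
                k=k,
                objective=score,
                objective_name=config.objective,
            )
        ],
    )
    return pattern


def resume_greedy(
    pinned: list[Condition],
    train: CohortTable,
    config: DiscoveryConfig,
) -> tuple[list[Condition], int]:
    """Greedy growth on top of a pinned condition set (in-mode
    ``full_rediscovery``): the pinned conditions are kept verbatim and
    the forward search may append further candidates."""
    y = _check_two_classes(train)
    obj = OBJECTIVES[config.objective]
    conditions = list(pinned)
    counts = condition_matrix(conditions, train.data).sum(axis=1)
    k, score = _best_k(counts, y, len(conditions), obj)

    candidates = [
        c
        for c in generate_candidates(train)
        if c.variable not in {p.variable for p in conditions}
    ]
    cols = condition_matrix(candidates, train.data) if candidates else None
    assoc = (
        [_indicator_chi2(cols[:, j], y) for j in range(len(candidates))]
        if candidates
        else []
    )
    used: set[int] = set()
    while len(conditions) < config.max_conditions and candidates:
        best = None
        for j in range(len(candidates)):
            if j in used or candidates[j].variable in {
                c.variable for c in conditions
            }:
                continue
            kj, val = _best_k(counts + cols[:, j], y, len(conditions) + 1, obj)
            key = (val, assoc[j], candidates[j].variable)
            if best is None or _better(key, best[0]):
                best = (key, j, kj)
        if best is None:
            break
        (val, _, _), j, kj = best
        if val - score < config.min_improvement or val <= 0.0:
            break
        used.add(j)
        conditions.append(candidates[j])
        counts = counts + cols[:, j]
        score, k = val, kj
    return conditions, k


def _better(key, ref) -> bool:
    """Candidate ordering: objective, then chi-square association with the
    target, then lexicographically smaller variable name."""
    val, chi, var = key
    rval, rchi, rvar = ref
    if val > rval + 1e-12:
        return True
    if val < rval - 1e-12:
        return False
    if chi > rchi + 1e-12:
        return True
    if chi < rchi - 1e-12:
        return False
    return var < rvar


def compute_arcs(
    pattern: Pattern, table: CohortTable, alpha: float = 0.05
) -> list[ArcResult]:
    """Pairwise chi-square independence tests between the pattern's
    per-record condition-match indicators, over all supplied records.

    2×2 tables use Yates continuity correction; a degenerate table (an
    indicator constant over the cohort) yields statistic 0, p = 1.
    Patterns with fewer than two conditions have no arcs.
    """
    if pattern.m < 2:
        return []
    ind = condition_matrix(pattern.conditions, table.data)
    out = []
    for i in range(pattern.m):
        for j in range(i + 1, pattern.m):
            a, b = ind[:, i], ind[:, j]
            tab = np.array(
                [
                    [int(np.sum(a & b)), int(np.sum(a & ~b))],
                    [int(np.sum(~a & b)), int(np.sum(~a & ~b))],
                ]
            )
            if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
                chi2, p = 0.0, 1.0
            else:
                res = stats.chi2_contingency(tab, correction=True)
                chi2, p = float(res.statistic), float(res.pvalue)
            out.append(
                ArcResult(
                    variable_a=pattern.conditions[i].variable,
                    variable_b=pattern.conditions[j].variable,
                    chi2=chi2,
                    p_value=p,
                    significant=bool(p < alpha),
                )
            )
    return out
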