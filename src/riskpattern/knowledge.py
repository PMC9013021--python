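"""Clinician-in-the-loop pattern editing.

Two modes follow the data-driven discovery:

* **in-mode** — the clinician edits conditions (add/remove variables,
  change values or comparators) and the matching threshold k is
  re-optimized on the training data. Conditions the edit list did not
  touch are never revised, so the variable-value pairs the clinician
  accepted stay exactly as they were. An optional ``full_rediscovery``
  switch instead re-runs the greedy search with the edited conditions
  pinned.
* **post-mode** — the clinician overrides condition values and/or the
  threshold verbatim, with no access to any data; the operation is a pure
  function of the pattern and the edits.

Every application appends one history entry, so replaying the history
from the initial discovery reconstructs the final pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .categorize import best_split
from .core_data import CohortTable
from .discovery import DiscoveryConfig, _check_two_classes, optimize_threshold
from .errors import EditError, ValidationError
from .evaluate import MetricsReport, evaluate_pattern
from .pattern import Condition, HistoryEntry, Pattern

__all__ = ["PatternEdit", "HistoryEntry", "apply_in_mode", "apply_post_mode"]

ACTIONS = (
    "add_variable",
    "remove_variable",
    "set_value",
    "set_comparator",
    "set_min_matches",
)


@dataclass(frozen=True)
class PatternEdit:
    """One atomic pattern edit.

    ``payload`` is the new value for ``set_value``, the new comparator for
    ``set_comparator``, the new threshold for ``set_min_matches``, and for
    ``add_variable`` either a ``{"comparator": ..., "value": ...}`` mapping
    or None (in-mode only: derive the cutoff from the training data).
    """

    action: str
    variable: str | None = None
    payload: object = None

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise EditError(f"unknown edit action {self.action!r}")
        if self.action != "set_min_matches" and not self.variable:
            raise EditError(f"edit {self.action!r} requires a variable")

    def to_dict(self) -> dict:
        return {"action": self.action, "variable": self.variable, "payload": self.payload}

    @classmethod
    def from_dict(cls, d: Mapping) -> "PatternEdit":
        if "action" not in d:
            raise EditError("edit document missing 'action'")
        return cls(
            action=d["action"], variable=d.get("variable"), payload=d.get("payload")
        )


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def _check_condition_type(
    cond: Condition, schema_kinds: Mapping[str, str] | None
) -> None:
    if schema_kinds is None or cond.variable not in schema_kinds:
        return
    kind = schema_kinds[cond.variable]
    if kind == "numeric" and cond.comparator == "==":
        raise EditError(
            f"variable {cond.variable!r} is numeric; use '<=' or '>' with a number"
        )
    if kind != "numeric" and cond.comparator != "==":
        raise EditError(
            f"variable {cond.variable!r} is {kind}; use '==' with a category"
        )


def _default_condition(variable: str, train: CohortTable) -> Condition:
    """Data-derived condition for an added variable with no explicit value:
    the best information-gain cutoff (risk-oriented side) for numeric
    variables, the highest-positive-rate observed category otherwise."""
    spec = train.spec(variable)
    y = train.target.to_numpy()
    if spec.kind == "numeric":
        v = pd.to_numeric(train.data[variable], errors="coerce").to_numpy(dtype=float)
        rule = best_split(v, y, variable=variable)
        if rule is None:
            raise EditError(f"no informative cutoff found for {variable!r}")
        ok = ~np.isnan(v)
        left = ok & (v <= rule.cutoff)
        right = ok & (v > rule.cutoff)
        rate_left = y[left].mean() if left.any() else 0.0
        rate_right = y[right].mean() if right.any() else 0.0
        return Condition(
            variable, "<=" if rate_left >= rate_right else ">", rule.cutoff
        )
    col = train.data[variable]
    cats = sorted(col.dropna().unique(), key=str)
    if not cats:
        raise EditError(f"variable {variable!r} has no observed categories")
    best = max(cats, key=lambda c: (y[(col == c).to_numpy()].mean()
                                    if (col == c).any() else 0.0, str(c)))
    return Condition(variable, "==", best)


def _make_condition(variable, comparator, value) -> Condition:
    try:
        return Condition(variable, comparator, value)
    except ValidationError as exc:
        raise EditError(str(exc)) from exc


def _apply_condition_edits(
    pattern: Pattern,
    edits: Sequence[PatternEdit],
    *,
    allow_set_k: bool,
    schema_kinds: Mapping[str, str] | None,
    train: CohortTable | None,
) -> tuple[list[Condition], int | None]:
    """Apply edits to a copy of the condition list; returns (conditions,
    explicitly set k or None)."""
    conditions = list(pattern.conditions)
    explicit_k: int | None = None

    def index_of(var: str) -> int:
        for i, c in enumerate(conditions):
            if c.variable == var:
                return i
        raise EditError(f"pattern has no condition on variable {var!r}")

    for e in edits:
        if e.action == "set_min_matches":
            if not allow_set_k:
                raise EditError(
                    "set_min_matches is only legal in post-mode; in-mode "
                    "re-optimizes the threshold from the training data"
                )
            if not isinstance(e.payload, int):
                raise EditError("set_min_matches payload must be an integer")
            explicit_k = e.payload
            continue

        if schema_kinds is not None and e.variable not in schema_kinds:
            raise EditError(f"unknown variable {e.variable!r}")

        if e.action == "remove_variable":
            i = index_of(e.variable)
            if len(conditions) == 1:
                raise EditError("cannot remove the last condition of a pattern")
            del conditions[i]
        elif e.action == "add_variable":
            if any(c.variable == e.variable for c in conditions):
                raise EditError(f"pattern already has a condition on {e.variable!r}")
            if e.payload is None:
                if train is None:
                    raise EditError(
                        f"add_variable on {e.variable!r} without an explicit "
                        "value requires training data (in-mode)"
                    )
                cond = _default_condition(e.variable, train)
            else:
                if (
                    not isinstance(e.payload, Mapping)
                    or "comparator" not in e.payload
                    or "value" not in e.payload
                ):
                    raise EditError(
                        "add_variable payload must be "
                        "{'comparator': ..., 'value': ...} or null"
                    )
                cond = _make_condition(
                    e.variable, e.payload["comparator"], e.payload["value"]
                )
            _check_condition_type(cond, schema_kinds)
            conditions.append(cond)
        elif e.action == "set_value":
            i = index_of(e.variable)
            cond = _make_condition(e.variable, conditions[i].comparator, e.payload)
            _check_condition_type(cond, schema_kinds)
            conditions[i] = cond
        elif e.action == "set_comparator":
            i = index_of(e.variable)
            if e.payload not in ("<=", ">", "=="):
                raise EditError(f"invalid comparator {e.payload!r}")
            cond = _make_condition(e.variable, e.payload, conditions[i].value)
            _check_condition_type(cond, schema_kinds)
            conditions[i] = cond
    return conditions, explicit_k


def apply_in_mode(
    pattern: Pattern,
    edits: Sequence[PatternEdit],
    train: CohortTable,
    config: DiscoveryConfig | None = None,
    full_rediscovery: bool = False,
    timestamp: str | None = "auto",
) -> tuple[Pattern, MetricsReport]:
    """Interactive edit with data-driven threshold re-optimization.

    Applies the edits exactly as given (untouched conditions are never
    revised), re-optimizes the matching threshold on the training cohort,
    and returns the updated pattern (mode tag ``in``) together with its
    training metrics. With ``full_rediscovery`` the greedy search resumes
    on top of the edited conditions, possibly adding further variables.
    """
    config = config or DiscoveryConfig()
    _check_two_classes(train)
    kinds = {s.name: s.kind for s in train.schema}
    conditions, _ = _apply_condition_edits(
        pattern, edits, allow_set_k=False, schema_kinds=kinds, train=train
    )

    if full_rediscovery:
        from .discovery import resume_greedy

        conditions, k = resume_greedy(conditions, train, config)
    else:
        k = optimize_threshold(conditions, train, config.objective)

    updated = Pattern(
        target_variable=pattern.target_variable,
        target_class=pattern.target_class,
        conditions=conditions,
        min_matches=k,
        mode_tag="in",
        history=list(pattern.history),
        arcs=list(pattern.arcs),
    )
    metrics = evaluate_pattern(updated, train)
    entry = HistoryEntry(
        mode="in",
        timestamp=_now() if timestamp == "auto" else timestamp,
        edits=tuple(e.to_dict() for e in edits),
        m=updated.m,
        k=k,
        objective=getattr(metrics, config.objective),
        objective_name=config.objective,
    )
    updated.history.append(entry)
    return updated, metrics


def apply_post_mode(
    pattern: Pattern,
    edits: Sequence[PatternEdit],
    timestamp: str | None = "auto",
) -> Pattern:
    """Data-free refinement: overrides applied verbatim, no re-optimization.

    A pure function of (pattern, edits); the resulting threshold must stay
    within [1, m].
    """
    conditions, explicit_k = _apply_condition_edits(
        pattern, edits, allow_set_k=True, schema_kinds=None, train=None
    )
    k = explicit_k if explicit_k is not None else pattern.min_matches
    if not 1 <= k <= len(conditions):
        raise EditError(
            f"min_matches {k} outside [1, {len(conditions)}] after edits"
        )
    updated = Pattern(
        target_variable=pattern.target_variable,
        target_class=pattern.target_class,
        conditions=conditions,
        min_matches=k,
        mode_tag="post",
        history=list(pattern.history),
        arcs=list(pattern.arcs),
    )
    updated.history.append(
        HistoryEntry(
            mode="post",
            timestamp=_now() if timestamp == "auto" else timestamp,
            edits=tuple(e.to_dict() for e in edits),
            m=updated.m,
            k=k,
            objective=None,
            objective_name=None,
        )
    )
    return updated
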