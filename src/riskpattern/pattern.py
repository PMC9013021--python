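"""The pattern data model: conditions, k-of-m matching, ratio display,
and JSON serialization.

A pattern is a set of m variable-value conditions together with a minimum
match count k: a record is pattern-positive when it satisfies at least k of
the m conditions. The threshold is displayed to users as a matching ratio
(floor percent of k/m) and parsed back with a ceiling, so the printed ratio
and the stored count round-trip exactly for any pattern of up to 50
conditions. A missing value never satisfies a condition; "≤" is inclusive
and ">" exclusive, exactly as the conditions read.

The continuous score of a pattern on a record is its match fraction
(match count / m), an (m+1)-level score suitable for ROC analysis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PatternFormatError, ValidationError

__all__ = [
    "Condition",
    "HistoryEntry",
    "Pattern",
    "min_matches_from_ratio",
    "display_ratio",
    "match_count",
    "match_fraction",
    "predict",
    "condition_matrix",
    "match_counts",
    "serialize",
    "deserialize",
    "save_pattern",
    "load_pattern",
]

COMPARATORS = ("<=", ">", "==")


@dataclass(frozen=True)
class Condition:
    """One variable-value comparison, e.g. ``contrast_volume > 79.5``.

    Numeric variables use "<=" or ">" with a numeric threshold;
    binary/categorical variables use "==" with a category.
    """

    variable: str
    comparator: str
    value: float | str

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise ValidationError(
                f"comparator must be one of {COMPARATORS}, got {self.comparator!r}"
            )
        if self.comparator in ("<=", ">") and not isinstance(
            self.value, (int, float)
        ):
            raise ValidationError(
                f"condition on {self.variable!r}: numeric comparator "
                f"{self.comparator!r} requires a numeric value, got {self.value!r}"
            )

    def matches(self, value) -> bool:
        """Whether one record value satisfies this condition (missing → False)."""
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return False
        if self.comparator == "==":
            return value == self.value
        try:
            v = float(value)
        except (TypeError, ValueError):
            return False
        return v <= self.value if self.comparator == "<=" else v > self.value

    def __str__(self) -> str:
        op = {"<=": "≤", ">": ">", "==": "="}[self.comparator]
        return f"{self.variable} {op} {self.value}"


@dataclass(frozen=True)
class HistoryEntry:
    """One step of the pattern's life: discovery or an edit session.

    The first entry of any pattern is the data-driven discovery (mode
    "pre"); in-mode entries carry the training objective reached after
    threshold re-optimization, post-mode entries carry none (no data
    access).
    """

    mode: str
    timestamp: str | None
    edits: tuple = ()
    m: int = 0
    k: int = 0
    objective: float | None = None
    objective_name: str | None = None

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "timestamp": self.timestamp,
            "edits": [dict(e) for e in self.edits],
            "m": self.m,
            "k": self.k,
            "objective": self.objective,
            "objective_name": self.objective_name,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "HistoryEntry":
        return cls(
            mode=d["mode"],
            timestamp=d.get("timestamp"),
            edits=tuple(dict(e) for e in d.get("edits", [])),
            m=int(d.get("m", 0)),
            k=int(d.get("k", 0)),
            objective=d.get("objective"),
            objective_name=d.get("objective_name"),
        )


@dataclass
class Pattern:
    """A k-of-m rule pattern predicting a positive class of a binary target."""

    target_variable: str
    target_class: str
    conditions: list[Condition]
    min_matches: int
    mode_tag: str = "pre"
    history: list[HistoryEntry] = field(default_factory=list)
    arcs: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.conditions) < 1:
            raise ValidationError("a pattern needs at least one condition")
        vars_ = [c.variable for c in self.conditions]
        if len(set(vars_)) != len(vars_):
            raise ValidationError("pattern variables must be distinct")
        if not 1 <= self.min_matches <= len(self.conditions):
            raise ValidationError(
                f"min_matches must be in [1, {len(self.conditions)}], "
                f"got {self.min_matches}"
            )
        if self.mode_tag not in ("pre", "in", "post"):
            raise ValidationError(f"unknown mode_tag {self.mode_tag!r}")

    @property
    def m(self) -> int:
        return len(self.conditions)

    @property
    def k(self) -> int:
        return self.min_matches

    @property
    def matching_ratio_percent(self) -> int:
        """The displayed matching ratio, floor(100·k/m) percent."""
        return display_ratio(self.min_matches, self.m)

    def variables(self) -> list[str]:
        return [c.variable for c in self.conditions]

    def condition_for(self, variable: str) -> Condition | None:
        for c in self.conditions:
            if c.variable == variable:
                return c
        return None

    def __str__(self) -> str:
        conds = ", ".join(str(c) for c in self.conditions)
        return (
            f"[{self.target_variable} = {self.target_class}] {conds} "
            f"(match ≥ {self.k}/{self.m}, ratio {self.matching_ratio_percent}%)"
        )


# ---------------------------------------------------------------------------
# matching-ratio conventions
#
# Parsing uses a ceiling (ratio 18% on 11 conditions means "at least 2"),
# display uses a floor percent (2/11 prints as 18%); the pair round-trips
# for all m < 100. The stored k is authoritative; the percentage is
# cosmetic.


def min_matches_from_ratio(ratio: float, m: int) -> int:
    """Minimum match count implied by a matching ratio, k = ceil(ratio·m)."""
    if not 0.0 < ratio <= 1.0:
        raise ValidationError(f"ratio must be in (0, 1], got {ratio}")
    if m < 1:
        raise ValidationError(f"pattern size must be >= 1, got {m}")
    k = math.ceil(ratio * m - 1e-9)  # guard float excess on exact products
    return max(1, min(m, k))


def display_ratio(k: int, m: int) -> int:
    """Matching ratio displayed for k of m conditions: floor(100·k/m)."""
    if not 1 <= k <= m:
        raise ValidationError(f"k must be in [1, {m}], got {k}")
    return (100 * k) // m


# ---------------------------------------------------------------------------
# matching


def match_count(pattern: Pattern, record: Mapping) -> int:
    """Number of pattern conditions a record satisfies.

    Variables absent from the record count as missing; missing never
    matches.
    """
    return sum(c.matches(record.get(c.variable)) for c in pattern.conditions)


def match_fraction(pattern: Pattern, record: Mapping) -> float:
    """Match count normalized by pattern size — the pattern's ROC score."""
    return match_count(pattern, record) / pattern.m


def predict(pattern: Pattern, record: Mapping) -> bool:
    """Positive pattern match: at least k of the m conditions satisfied."""
    return match_count(pattern, record) >= pattern.min_matches


def condition_matrix(conditions: Sequence[Condition], data: pd.DataFrame) -> np.ndarray:
    """Boolean indicator matrix (n records × m conditions); missing → False."""
    n = len(data)
    out = np.zeros((n, len(conditions)), dtype=bool)
    for j, c in enumerate(conditions):
        if c.variable not in data.columns:
            continue
        col = data[c.variable]
        if c.comparator == "==":
            out[:, j] = (col == c.value).to_numpy(dtype=bool)
        else:
            v = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                cmp = v <= c.value if c.comparator == "<=" else v > c.value
            out[:, j] = cmp & ~np.isnan(v)
    return out


def match_counts(pattern: Pattern, data: pd.DataFrame) -> np.ndarray:
    """Vectorized match counts over a cohort data frame."""
    return condition_matrix(pattern.conditions, data).sum(axis=1)


# ---------------------------------------------------------------------------
# serialization


def serialize(pattern: Pattern) -> dict:
    """Pattern → JSON-ready dict (lossless, including history and arcs)."""
    return {
        "target": {
            "variable": pattern.target_variable,
            "positive_class": pattern.target_class,
        },
        "conditions": [
            {"variable": c.variable, "comparator": c.comparator, "value": c.value}
            for c in pattern.conditions
        ],
        "min_matches": pattern.min_matches,
        "matching_ratio_percent": pattern.matching_ratio_percent,
        "mode_tag": pattern.mode_tag,
        "history": [h.to_dict() for h in pattern.history],
        "arcs": [dict(a) for a in pattern.arcs],
    }


def _require(doc: Mapping, key: str, where: str = "pattern") -> object:
    if key not in doc:
        raise PatternFormatError(f"{where}: missing required field {key!r}")
    return doc[key]


def deserialize(doc: Mapping) -> Pattern:
    """JSON dict → Pattern; malformed documents name the offending field."""
    if not isinstance(doc, Mapping):
        raise PatternFormatError("pattern document must be a JSON object")
    target = _require(doc, "target")
    if not isinstance(target, Mapping):
        raise PatternFormatError("target: must be an object")
    conditions_doc = _require(doc, "conditions")
    conditions = []
    for i, c in enumerate(conditions_doc):
        where = f"conditions[{i}]"
        try:
            conditions.append(
                Condition(
                    variable=str(_require(c, "variable", where)),
                    comparator=str(_require(c, "comparator", where)),
                    value=_require(c, "value", where),
                )
            )
        except ValidationError as e:
            raise PatternFormatError(f"{where}: {e}") from e
    k = _require(doc, "min_matches")
    if not isinstance(k, int):
        raise PatternFormatError("min_matches: must be an integer")
    try:
        return Pattern(
            target_variable=str(_require(target, "variable", "target")),
            target_class=str(_require(target, "positive_class", "target")),
            conditions=conditions,
            min_matches=k,
            mode_tag=doc.get("mode_tag", "pre"),
            history=[HistoryEntry.from_dict(h) for h in doc.get("history", [])],
            arcs=[dict(a) for a in doc.get("arcs", [])],
        )
    except ValidationError as e:
        raise PatternFormatError(str(e)) from e


def save_pattern(pattern: Pattern, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(serialize(pattern), indent=2, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def load_pattern(path: str | Path) -> Pattern:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise PatternFormatError(f"{path}: not valid JSON ({e})") from e
    return deserialize(doc)
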