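"""Cohort table model: CSV I/O, chronological splitting, outcome labeling,
and 1:1 class resampling.

A cohort is an ordered table of patient records (rows in chronological
order) with mixed numeric/categorical predictors and a binary outcome.
Missing values are retained as-is — no imputation is performed; downstream
condition matching treats a missing value as a non-match.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

__all__ = [
    "VariableSpec",
    "CohortTable",
    "load_schema",
    "read_cohort",
    "chronological_split",
    "label_aki",
    "resample_balanced",
    "UMOL_PER_MGDL",
]

#: Serum creatinine unit conversion: 1 mg/dL = 88.4 μmol/L.
UMOL_PER_MGDL = 88.4

VALID_KINDS = ("numeric", "binary", "categorical")

_TRUE_TOKENS = {"1", "true", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "no", "n"}


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one predictor variable.

    Parameters
    ----------
    name:
        Column name, unique within a schema.
    kind:
        One of ``numeric``, ``binary``, ``categorical``.
    units:
        Free-text units (e.g. ``mL``, ``ml/min``, ``μmol/L``).
    positive_category:
        For binary variables, the category treated as the risk-bearing
        value (e.g. ``"Yes"``). Binary variables are stored categorically
        rather than as 0/1 so that conditions read the way clinicians
        write them ("urgent PCI = Yes").
    """

    name: str
    kind: str
    units: str = ""
    positive_category: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise SchemaError(
                f"variable {self.name!r}: kind must be one of {VALID_KINDS}, got {self.kind!r}"
            )
        if self.kind == "numeric" and self.positive_category is not None:
            raise SchemaError(
                f"variable {self.name!r}: positive_category is only valid for "
                "binary/categorical variables"
            )


@dataclass
class CohortTable:
    """An ordered cohort of patient records with a binary outcome.

    ``data`` holds predictor columns (object dtype for categorical/binary,
    float for numeric; NaN/None = missing). ``target`` is a boolean Series
    aligned with ``data``. Row position is the chronological order index.
    """

    schema: list[VariableSpec]
    data: pd.DataFrame
    target: pd.Series
    target_name: str = "outcome"

    def __post_init__(self) -> None:
        names = [s.name for s in self.schema]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")
        if len(self.data) != len(self.target):
            raise ValidationError("data and target lengths differ")
        if len(self.data) < 1:
            raise ValidationError("cohort must contain at least one record")
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise SchemaError(f"columns missing from data: {missing}")
        self.data = self.data.reset_index(drop=True)
        self.target = self.target.reset_index(drop=True).astype(bool)

    # -- basic views ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def order_index(self) -> np.ndarray:
        return np.arange(len(self.data))

    @property
    def n_positive(self) -> int:
        return int(self.target.sum())

    @property
    def prevalence(self) -> float:
        return float(self.target.mean())

    def spec(self, name: str) -> VariableSpec:
        for s in self.schema:
            if s.name == name:
                return s
        raise SchemaError(f"unknown variable {name!r}")

    def variable_names(self) -> list[str]:
        return [s.name for s in self.schema]

    def record(self, i: int) -> dict:
        """Row ``i`` as a variable→value mapping (NaN mapped to None)."""
        row = self.data.iloc[i]
        return {
            s.name: (None if _is_missing(row[s.name]) else row[s.name])
            for s in self.schema
        }

    def iter_records(self) -> Iterable[dict]:
        for i in range(len(self.data)):
            yield self.record(i)

    def subset(self, positions: Sequence[int] | np.ndarray) -> "CohortTable":
        idx = np.asarray(positions)
        return CohortTable(
            schema=list(self.schema),
            data=self.data.iloc[idx].reset_index(drop=True),
            target=self.target.iloc[idx].reset_index(drop=True),
            target_name=self.target_name,
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the cohort as a standard cohort CSV (empty cell = missing)."""
        out = self.data.copy()
        out[self.target_name] = np.where(self.target.to_numpy(), "Yes", "No")
        out.to_csv(path, index=False)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or v is pd.NA


# ---------------------------------------------------------------------------
# schema I/O


def load_schema(path: str | Path) -> list[VariableSpec]:
    """Read a variable schema from YAML or JSON.

    The document is a list of ``{name, kind, units, positive_category}``
    mappings (or a mapping with a ``variables`` key holding that list).
    """
    text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    if isinstance(doc, Mapping) and "variables" in doc:
        doc = doc["variables"]
    if not isinstance(doc, list):
        raise SchemaError(f"schema file {path}: expected a list of variable specs")
    specs = []
    for entry in doc:
        if not isinstance(entry, Mapping) or "name" not in entry or "kind" not in entry:
            raise SchemaError(f"schema file {path}: each entry needs 'name' and 'kind'")
        specs.append(
            VariableSpec(
                name=str(entry["name"]),
                kind=str(entry["kind"]),
                units=str(entry.get("units", "") or ""),
                positive_category=entry.get("positive_category"),
            )
        )
    return specs


def save_schema(schema: Sequence[VariableSpec], path: str | Path) -> None:
    doc = [
        {
            "name": s.name,
            "kind": s.kind,
            "units": s.units,
            "positive_category": s.positive_category,
        }
        for s in schema
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


# ---------------------------------------------------------------------------
# cohort CSV I/O


def parse_binary_series(raw: pd.Series, name: str) -> pd.Series:
    """Parse a column of yes/no-style tokens into booleans.

    Accepts 1/0, true/false, yes/no, y/n (case-insensitive). Any other
    non-empty token is a validation error.
    """
    s = raw.astype("string").str.strip().str.lower()
    out = np.empty(len(s), dtype=bool)
    for i, tok in enumerate(s):
        if tok is pd.NA or tok == "":
            raise ValidationError(f"column {name!r}: missing value in row {i + 1}")
        if tok in _TRUE_TOKENS:
            out[i] = True
        elif tok in _FALSE_TOKENS:
            out[i] = False
        else:
            raise ValidationError(
                f"column {name!r}: non-binary value {raw.iloc[i]!r} in row {i + 1}"
            )
    return pd.Series(out)


def read_cohort(
    path: str | Path,
    schema: Sequence[VariableSpec],
    target_name: str,
) -> CohortTable:
    """Read a cohort CSV.

    Rows are taken in file order as chronological order. Empty cells become
    missing values. Numeric columns are parsed as decimals; a non-parsable
    numeric cell is an error naming the row.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [s.name for s in schema if s.name not in raw.columns]
    if target_name not in raw.columns:
        missing_cols.append(target_name)
    if missing_cols:
        raise SchemaError(f"cohort file {path}: missing column(s) {missing_cols}")

    data = {}
    for s in schema:
        col = raw[s.name].str.strip()
        if s.kind == "numeric":
            parsed = pd.to_numeric(col.replace("", None), errors="coerce")
            bad = parsed.isna() & (col != "")
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
                raise ValidationError(
                    f"column {s.name!r}: cannot parse {col.iloc[row - 1]!r} "
                    f"as a number in row {row}"
                )
            data[s.name] = parsed.astype(float)
        else:
            data[s.name] = col.replace("", None).astype(object)

    target = parse_binary_series(raw[target_name], target_name)
    return CohortTable(
        schema=list(schema),
        data=pd.DataFrame(data),
        target=target,
        target_name=target_name,
    )


# ---------------------------------------------------------------------------
# operations


def chronological_split(
    table: CohortTable, train_fraction: float
) -> tuple[CohortTable, CohortTable]:
    """Split a cohort into consecutive train/test parts, no shuffling.

    The first ``floor(train_fraction * n)`` records by chronological order
    form the training cohort; the remainder form the test cohort.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(table)
    if n < 2:
        raise ValidationError("need at least 2 records to split")
    n_train = int(math.floor(train_fraction * n))
    n_train = max(1, min(n - 1, n_train))
    return table.subset(np.arange(n_train)), table.subset(np.arange(n_train, n))


def label_aki(baseline: float, peak: float) -> bool:
    """AKIN creatinine criterion for acute kidney injury.

    Positive iff the peak creatinine rose by at least 0.3 mg/dL over the
    baseline, or reached at least 1.5 times the baseline. Both inputs are
    in mg/dL; divide μmol/L values by :data:`UMOL_PER_MGDL` first.
    """
    if baseline <= 0:
        raise ValidationError(f"baseline creatinine must be positive, got {baseline}")
    if peak < 0:
        raise ValidationError(f"peak creatinine must be nonnegative, got {peak}")
    return (peak - baseline >= 0.3) or (peak >= 1.5 * baseline)


def label_aki_series(
    baseline: Sequence[float], peak: Sequence[float], units: str = "mg_dl"
) -> np.ndarray:
    """Vectorized :func:`label_aki` over paired creatinine columns."""
    b = np.asarray(baseline, dtype=float)
    p = np.asarray(peak, dtype=float)
    if units == "umol_l":
        b = b / UMOL_PER_MGDL
        p = p / UMOL_PER_MGDL
    elif units != "mg_dl":
        raise ValidationError(f"unknown creatinine units {units!r}")
    if np.any(b <= 0):
        raise ValidationError("baseline creatinine must be positive")
    if np.any(p < 0):
        raise ValidationError("peak creatinine must be nonnegative")
    return (p - b >= 0.3) | (p >= 1.5 * b)


def resample_balanced(table: CohortTable, direction: str, seed: int) -> CohortTable:
    """Resample to an exact 1:1 class ratio.

    ``up`` draws positives with replacement until they equal the negatives;
    ``down`` subsamples negatives without replacement to the positive count.
    Deterministic for a given seed.
    """
    y = table.target.to_numpy()
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("resampling needs both classes present")
    rng = np.random.default_rng(seed)
    if direction == "up":
        if len(pos) > len(neg):
            raise ValidationError("up-sampling expects positives to be the minority")
        extra = rng.choice(pos, size=len(neg) - len(pos), replace=True)
        idx = np.concatenate([neg, pos, extra])
    elif direction == "down":
        if len(neg) < len(pos):
            raise ValidationError("down-sampling expects negatives to be the majority")
        kept = rng.choice(neg, size=len(pos), replace=False)
        idx = np.concatenate([kept, pos])
    else:
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    return table.subset(np.sort(idx))
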