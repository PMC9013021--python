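import numpy as np
import pandas as pd
import pytest

from riskpattern.core_data import CohortTable, VariableSpec
from riskpattern.pattern import Condition, Pattern


def infer_kind(values) -> str:
    vals = [v for v in values if v is not None]
    if all(isinstance(v, (int, float)) for v in vals):
        return "numeric"
    if set(map(str, vals)) <= {"Yes", "No"}:
        return "binary"
    return "categorical"


def make_table(columns, target, kinds=None, target_name="outcome") -> CohortTable:
    """Build a CohortTable from plain lists; variable kinds inferred
    unless given."""
    kinds = kinds or {}
    schema = []
    data = {}
    for name, values in columns.items():
        kind = kinds.get(name, infer_kind(values))
        pos = "Yes" if kind == "binary" else None
        schema.append(VariableSpec(name=name, kind=kind, positive_category=pos))
        if kind == "numeric":
            data[name] = pd.array(
                [np.nan if v is None else float(v) for v in values], dtype=float
            )
        else:
            data[name] = pd.array(values, dtype=object)
    return CohortTable(
        schema=schema,
        data=pd.DataFrame(data),
        target=pd.Series([bool(t) for t in target]),
        target_name=target_name,
    )


@pytest.fixture
def published_pattern() -> Pattern:
    """The 11-condition pre-mode AKI pattern with the published cutoffs.

    The published narrative prints ten of the eleven conditions; the
    eleventh (here diabetes = Yes) pads the pattern to its stated size
    without touching any variable the probe records use.
    """
    return Pattern(
        target_variable="AKI",
        target_class="Yes",
        conditions=[
            Condition("lvef", "<=", 56.6),
            Condition("pre_peak_creatinine", ">", 160.0),
            Condition("gfr", "<=", 31.5),
            Condition("urgent_pci", "==", "Yes"),
            Condition("iabp", "==", "Yes"),
            Condition("contrast_volume", ">", 79.5),
            Condition("age", "<=", 58.5),
            Condition("hdl_c", "<=", 0.695),
            Condition("hypertension", "==", "Yes"),
            Condition("anemia", "==", "Yes"),
            Condition("diabetes", "==", "Yes"),
        ],
        min_matches=2,
    )
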