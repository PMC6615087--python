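"""Stage classification of cancer-registry TNM records.

Registry records carry an N status (nodal involvement) and an M status
(distant metastases), either of which may be missing — missingness is always
explicit, never coded as "M0". Classification uses N and M only (T plays no
role in the advanced / non-advanced distinction):

=========  =========  ========================
N status   M status   class
=========  =========  ========================
any        M1         advanced_IV
N_plus     M0         advanced_III
N_plus     missing    advanced_unstratifiable
N0         M0         non_advanced
N0         missing    not_classifiable
missing    M0/missing not_classifiable
=========  =========  ========================

Scenario analyses quantify how the missing classes move the rates: dropping
the not-classifiable records, relabelling them all non-advanced, or making
the extreme assumption that every advanced-but-unstratifiable record is
UICC stage IV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CLASSES",
    "SCENARIOS",
    "classify_tnm",
    "classify_records",
    "tabulate_classes",
    "apply_scenario",
]

CLASSES = (
    "non_advanced",
    "advanced_III",
    "advanced_IV",
    "advanced_unstratifiable",
    "not_classifiable",
)
SCENARIOS = (
    "as_observed",
    "drop_nonclassifiable",
    "nonclassifiable_as_nonadvanced",
    "unstratifiable_as_IV",
)

_N_VALUES = {"N0", "N_plus", "missing"}
_M_VALUES = {"M0", "M1", "missing"}


def classify_tnm(n_status: str, m_status: str) -> str:
    """Classify a single (N, M) pair; total on the two enumerations."""
    if n_status not in _N_VALUES:
        raise ValueError(f"invalid n_status {n_status!r}")
    if m_status not in _M_VALUES:
        raise ValueError(f"invalid m_status {m_status!r}")
    if m_status == "M1":
        return "advanced_IV"
    if n_status == "N_plus":
        return "advanced_III" if m_status == "M0" else "advanced_unstratifiable"
    if n_status == "N0" and m_status == "M0":
        return "non_advanced"
    return "not_classifiable"


def classify_records(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification; adds a ``cls`` column."""
    n = records["n_status"]
    m = records["m_status"]
    if not set(n.unique()) <= _N_VALUES:
        raise ValueError(f"invalid n_status values {set(n.unique()) - _N_VALUES}")
    if not set(m.unique()) <= _M_VALUES:
        raise ValueError(f"invalid m_status values {set(m.unique()) - _M_VALUES}")
    cls = np.select(
        [
            m == "M1",
            (n == "N_plus") & (m == "M0"),
            (n == "N_plus") & (m == "missing"),
            (n == "N0") & (m == "M0"),
        ],
        ["advanced_IV", "advanced_III", "advanced_unstratifiable", "non_advanced"],
        default="not_classifiable",
    )
    out = records.copy()
    out["cls"] = cls
    return out


def tabulate_classes(
    records: pd.DataFrame, by: tuple[str, ...] = ("diagnosis_year", "sex")
) -> pd.DataFrame:
    """Counts and within-stratum proportions of the five classes.

    Empty strata keep zero counts with proportions left as NaN.
    """
    if "cls" not in records.columns:
        records = classify_records(records)
    counts = (
        records.groupby([*by, "cls"], observed=False)
        .size()
        .unstack("cls", fill_value=0)
        .reindex(columns=list(CLASSES), fill_value=0)
    )
    total = counts.sum(axis=1)
    props = counts.div(total.where(total > 0), axis=0)
    counts = counts.add_prefix("n_")
    props = props.add_prefix("prop_")
    return pd.concat([counts, props], axis=1).reset_index()


def apply_scenario(classes: pd.DataFrame, scenario: str) -> pd.DataFrame:
    """Re-label classified records under one missing-data scenario."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    out = classes.copy()
    if scenario == "as_observed":
        return out
    if scenario == "drop_nonclassifiable":
        return out[out["cls"] != "not_classifiable"].reset_index(drop=True)
    if scenario == "nonclassifiable_as_nonadvanced":
        out.loc[out["cls"] == "not_classifiable", "cls"] = "non_advanced"
        return out
    out.loc[out["cls"] == "advanced_unstratifiable", "cls"] = "advanced_IV"
    return out
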