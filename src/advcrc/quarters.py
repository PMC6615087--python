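"""Calendar-quarter arithmetic.

German outpatient claims carry diagnoses at (year, quarter) granularity only,
so the cohort algorithms operate on a linear quarter index
``qindex = 4 * year + quarter - 1`` alongside exact dates for inpatient
records.
"""

from __future__ import annotations

import datetime as dt

import pandas as pd

__all__ = [
    "qindex",
    "qindex_of_date",
    "qindex_series",
    "quarter_of_month",
    "quarter_start",
    "quarter_end",
    "year_quarter",
]


def quarter_of_month(month: int) -> int:
    return (month - 1) // 3 + 1


def qindex(year: int, quarter: int) -> int:
    if quarter not in (1, 2, 3, 4):
        raise ValueError(f"quarter must be in 1..4, got {quarter}")
    return 4 * year + quarter - 1


def qindex_of_date(d: dt.date) -> int:
    return 4 * d.year + (d.month - 1) // 3


def qindex_series(dates: pd.Series) -> pd.Series:
    """Vectorized quarter index for a datetime64 column."""
    return dates.dt.year * 4 + (dates.dt.month - 1) // 3


def year_quarter(qidx: int) -> tuple[int, int]:
    year, q0 = divmod(qidx, 4)
    return year, q0 + 1


def quarter_start(qidx: int) -> dt.date:
    year, q0 = divmod(qidx, 4)
    return dt.date(year, 3 * q0 + 1, 1)


def quarter_end(qidx: int) -> dt.date:
    return quarter_start(qidx + 1) - dt.timedelta(days=1)
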