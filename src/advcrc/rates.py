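"""Crude and directly age-standardized incidence rates.

Direct standardization weights the observed age-band-specific rates
``c_b / n_b`` with a fixed standard age distribution:

    ASIR = 100,000 * sum_b w_b * c_b / n_b / sum_b w_b

Here the standard is the old European Standard Population (ESP) over the
canonical 18 five-year bands 0-4, 5-9, ..., 80-84, 85+. A band with neither
cases nor denominator contributes zero; cases without denominator are a
data error.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ESP_OLD_WEIGHTS",
    "N_BANDS",
    "AGE_BAND_LABELS",
    "age_band",
    "asir",
    "rate_table",
]

N_BANDS = 18

#: Old (1976) European Standard Population, per 100,000.
ESP_OLD_WEIGHTS = np.array(
    [8000, 7000, 7000, 7000, 7000, 7000, 7000, 7000, 7000, 7000,
     7000, 6000, 5000, 4000, 3000, 2000, 1000, 1000],
    dtype=float,
)

AGE_BAND_LABELS = tuple(
    [f"{5 * b}-{5 * b + 4}" for b in range(N_BANDS - 1)] + ["85+"]
)


def age_band(age):
    """Five-year age-band index 0..17 (85+ is terminal); vectorized.

    Raises on negative ages.
    """
    arr = np.asarray(age)
    if np.any(arr < 0):
        raise ValueError("age must be non-negative")
    bands = np.minimum(arr // 5, N_BANDS - 1).astype(int)
    if np.isscalar(age) or arr.ndim == 0:
        return int(bands)
    if isinstance(age, pd.Series):
        return pd.Series(bands, index=age.index)
    return bands


def asir(
    case_counts: Sequence[float],
    denominators: Sequence[float],
    weights: Sequence[float] = ESP_OLD_WEIGHTS,
) -> float:
    """Directly standardized rate per 100,000 from 18-band count vectors."""
    c = np.asarray(case_counts, dtype=float)
    n = np.asarray(denominators, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (c.shape == n.shape == w.shape == (N_BANDS,)):
        raise ValueError(f"expected three vectors of length {N_BANDS}")
    bad = (c > 0) & (n <= 0)
    if bad.any():
        raise ValueError(
            f"cases without denominator in age band(s) {np.flatnonzero(bad).tolist()}"
        )
    band_rates = np.divide(c, n, out=np.zeros(N_BANDS), where=n > 0)
    return float(1e5 * np.sum(w * band_rates) / np.sum(w))


def rate_table(
    cases: pd.DataFrame,
    denominators: pd.DataFrame,
    weights: Sequence[float] = ESP_OLD_WEIGHTS,
    stages: Iterable[str] | None = None,
    years: Iterable[int] | None = None,
    sexes: Iterable[str] = ("female", "male"),
) -> pd.DataFrame:
    """One row of counts, crude rate and ASIR per year x sex x stage.

    Parameters
    ----------
    cases
        One row per case with columns ``year``, ``sex``, ``stage``,
        ``age_band``.
    denominators
        Person counts per ``year`` x ``sex`` x ``age_band``. Every stratum
        implied by the requested grid must be present (zero rows included),
        otherwise a :class:`KeyError` names the missing stratum.
    """
    required = {"year", "sex", "stage", "age_band"}
    if not required.issubset(cases.columns):
        raise ValueError(f"cases must have columns {sorted(required)}")
    if years is None:
        years = sorted(cases["year"].unique())
    if stages is None:
        stages = sorted(cases["stage"].unique())

    denom_map = {
        key: grp.set_index("age_band")["person_count"]
        for key, grp in denominators.groupby(["year", "sex"])
    }
    case_counts = (
        cases.groupby(["year", "sex", "stage", "age_band"]).size().to_dict()
    )

    rows = []
    for year in years:
        for sex in sexes:
            if (year, sex) not in denom_map:
                raise KeyError(f"missing denominator stratum year={year} sex={sex}")
            denom = denom_map[(year, sex)].reindex(range(N_BANDS), fill_value=0)
            n_total = float(denom.sum())
            for stage in stages:
                c = np.array(
                    [
                        case_counts.get((year, sex, stage, b), 0)
                        for b in range(N_BANDS)
                    ],
                    dtype=float,
                )
                count = int(c.sum())
                crude = 1e5 * count / n_total if n_total > 0 else np.nan
                rows.append(
                    {
                        "year": year,
                        "sex": sex,
                        "stage": stage,
                        "case_count": count,
                        "person_denominator": int(n_total),
                        "crude_rate": crude,
                        "asir": asir(c, denom.to_numpy(), weights),
                    }
                )
    return pd.DataFrame(rows)
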