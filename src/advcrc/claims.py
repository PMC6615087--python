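"""Claims-based ascertainment and staging of incident colorectal cancer.

The algorithm mirrors how incident CRC is identified in German statutory
health-insurance claims:

1. **Cohort entry** — the first C18-C20 code of the index year. Outpatient
   codes qualify only with certainty "confirmed"; inpatient codes only in
   main or secondary discharge position (never admission diagnoses). Because
   outpatient codes are quarter-granular, an outpatient entry is dated to the
   first day of its quarter; if an inpatient CRC code falls in the same
   quarter, its exact date is used instead.
2. **Confirmation** — a second qualifying CRC code record in the entry
   quarter or the ``confirm_quarters`` (default 2) following quarters; the
   entry record itself does not self-confirm.
3. **Washout** — no CRC code with certainty "confirmed" or "status post"
   (outpatient) and no main/secondary inpatient CRC code during the
   4 x 365.25-day preobservation window before entry. Quarter-granular
   outpatient codes count when their quarter lies strictly before the entry
   quarter and overlaps the window.
4. **Continuity & age** — continuously insured (no single interruption of
   more than ``max_gap_days``) from 4 x 365.25 days before entry through
   December 31 of the index year, and at least ``min_age`` years old. The
   upper bound matches the denominator definition, so every case is counted
   in its denominator stratum.
5. **Staging** — any main/secondary inpatient or confirmed outpatient
   C78-C79 code in the entry quarter plus ``n_following_quarters`` following
   quarters assigns UICC IV; otherwise any C77 code in that window assigns
   UICC III; otherwise the case is non-advanced.

Ages are banded on attained age (calendar year minus birth year) so the
numerator and denominator share strata; the reported ``age_at_entry`` uses a
mid-year (July 1) birthday convention, the standard choice when claims carry
only a birth year.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import warnings

import numpy as np
import pandas as pd

from .quarters import qindex_series, quarter_start
from .rates import N_BANDS, age_band

__all__ = [
    "CodeLists",
    "eligible_persons",
    "identify_incident_cases",
    "stage_cases",
    "inpatient_evidence_summary",
    "medication_crosscheck",
    "crosscheck_percentage",
]

LOOKBACK_DAYS_PER_YEAR = 365.25

CASE_COLUMNS = [
    "person_id",
    "cohort_entry_date",
    "entry_year",
    "entry_quarter",
    "age_at_entry",
    "sex",
    "calendar_year",
]


@dataclasses.dataclass(frozen=True)
class CodeLists:
    """ICD-10 prefixes and therapy agent codes driving the algorithm."""

    crc_codes: frozenset[str] = frozenset({"C18", "C19", "C20"})
    lymph_only_codes: frozenset[str] = frozenset({"C77"})
    distant_codes: frozenset[str] = frozenset({"C78", "C79"})
    advanced_therapy_codes: frozenset[str] = frozenset(
        {"L01XC07", "L01XC21", "L01XX44", "L01XE21"}
    )

    def __post_init__(self) -> None:
        sets = [self.crc_codes, self.lymph_only_codes, self.distant_codes]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("diagnosis code sets must be pairwise disjoint")

    @staticmethod
    def _matches(codes: pd.Series, prefixes: frozenset[str]) -> pd.Series:
        return codes.str.startswith(tuple(prefixes))


def _lookback_start(entry: dt.date, lookback_years: int) -> dt.date:
    return entry - dt.timedelta(days=round(lookback_years * LOOKBACK_DAYS_PER_YEAR))


def _check_spell_integrity(spells: pd.DataFrame) -> None:
    if (spells["start_date"] > spells["end_date"]).any():
        raise ValueError("spell with start_date after end_date")
    s = spells.sort_values(["person_id", "start_date"], kind="mergesort")
    same = s["person_id"] == s["person_id"].shift()
    overlap = same & (s["start_date"] <= s["end_date"].shift())
    if overlap.any():
        bad = s.loc[overlap, "person_id"].iloc[0]
        raise ValueError(f"overlapping insurance spells for person {bad}")


def _insured_through(
    spells: pd.DataFrame, window_start: dt.date, window_end: dt.date, max_gap_days: int
) -> pd.Index:
    """person_ids continuously insured over [window_start, window_end].

    Coverage must begin on/before the window start and end on/after the
    window end; interruptions of at most ``max_gap_days`` days are tolerated.
    """
    ws, we = pd.Timestamp(window_start), pd.Timestamp(window_end)
    s = spells[(spells["end_date"] >= ws) & (spells["start_date"] <= we)]
    s = s.sort_values(["person_id", "start_date"], kind="mergesort")
    grp = s.groupby("person_id")
    first_start = grp["start_date"].min()
    last_end = grp["end_date"].max()
    same = s["person_id"] == s["person_id"].shift()
    gap_days = (s["start_date"] - s["end_date"].shift()).dt.days - 1
    gap_days = gap_days.where(same, 0)
    max_gap = gap_days.groupby(s["person_id"]).max().fillna(0)
    ok = (first_start <= ws) & (last_end >= we) & (max_gap <= max_gap_days)
    return ok.index[ok]


def eligible_persons(
    persons: pd.DataFrame,
    spells: pd.DataFrame,
    year: int,
    lookback_years: int = 4,
    max_gap_days: int = 15,
    min_age: int = 5,
) -> pd.DataFrame:
    """Denominator strata for one calendar year.

    A person counts in ``year`` when continuously insured (no interruption
    longer than ``max_gap_days``) from ``lookback_years`` before the
    reference date (December 31) through the reference date, and at least
    ``min_age`` years old. Returns person counts on the full
    sex x 18-age-band grid.
    """
    _check_spell_integrity(spells)
    ref = dt.date(year, 12, 31)
    insured = _insured_through(
        spells, _lookback_start(ref, lookback_years), ref, max_gap_days
    )
    sub = persons[persons["person_id"].isin(insured)].copy()
    sub["age"] = year - sub["birth_year"]
    sub = sub[(sub["age"] >= min_age) & (sub["age"] >= 0)]
    sub["age_band"] = age_band(sub["age"])
    counts = (
        sub.groupby(["sex", "age_band"], observed=False)
        .size()
        .reindex(
            pd.MultiIndex.from_product(
                [["female", "male"], range(N_BANDS)], names=["sex", "age_band"]
            ),
            fill_value=0,
        )
        .reset_index(name="person_count")
    )
    counts.insert(0, "year", year)
    return counts


def _qualifying_crc_records(bundle, code_lists: CodeLists) -> pd.DataFrame:
    """Long table of CRC code records usable for entry/confirmation.

    Columns: person_id, qidx, date (NaT for outpatient), setting, position,
    icd_code. Outpatient records require certainty 'confirmed'; inpatient
    records require main/secondary position.
    """
    out = bundle.outpatient
    out = out[
        CodeLists._matches(out["icd_code"], code_lists.crc_codes)
        & (out["certainty"] == "confirmed")
    ]
    out = pd.DataFrame(
        {
            "person_id": out["person_id"],
            "qidx": out["year"] * 4 + out["quarter"] - 1,
            "date": pd.NaT,
            "setting": "outpatient",
            "position": "",
            "icd_code": out["icd_code"],
        }
    )
    inp = bundle.inpatient
    inp = inp[
        CodeLists._matches(inp["icd_code"], code_lists.crc_codes)
        & inp["position"].isin(["main", "secondary"])
    ]
    inp = pd.DataFrame(
        {
            "person_id": inp["person_id"],
            "qidx": qindex_series(inp["date"]),
            "date": inp["date"],
            "setting": "inpatient",
            "position": inp["position"],
            "icd_code": inp["icd_code"],
        }
    )
    return pd.concat([out, inp], ignore_index=True)


def _washout_records(bundle, code_lists: CodeLists) -> pd.DataFrame:
    """CRC records that mark prevalent disease: confirmed or status-post
    outpatient codes and main/secondary inpatient codes."""
    out = bundle.outpatient
    out = out[
        CodeLists._matches(out["icd_code"], code_lists.crc_codes)
        & out["certainty"].isin(["confirmed", "status_post"])
    ]
    out = pd.DataFrame(
        {
            "person_id": out["person_id"],
            "qidx": out["year"] * 4 + out["quarter"] - 1,
            "date": pd.NaT,
            "setting": "outpatient",
        }
    )
    inp = bundle.inpatient
    inp = inp[
        CodeLists._matches(inp["icd_code"], code_lists.crc_codes)
        & inp["position"].isin(["main", "secondary"])
    ]
    inp = pd.DataFrame(
        {
            "person_id": inp["person_id"],
            "qidx": qindex_series(inp["date"]),
            "date": inp["date"],
            "setting": "inpatient",
        }
    )
    return pd.concat([out, inp], ignore_index=True)


def identify_incident_cases(
    bundle,
    year: int,
    code_lists: CodeLists | None = None,
    lookback_years: int = 4,
    confirm_quarters: int = 2,
    max_gap_days: int = 15,
    min_age: int = 5,
) -> pd.DataFrame:
    """Ascertain incident CRC cases with cohort entry in ``year``."""
    code_lists = code_lists or CodeLists()

    years_covered = set()
    if len(bundle.spells):
        years_covered = set(
            range(
                bundle.spells["start_date"].min().year,
                bundle.spells["end_date"].max().year + 1,
            )
        )
    if year not in years_covered:
        warnings.warn(f"year {year} outside data coverage; returning no cases")
        return pd.DataFrame(columns=CASE_COLUMNS)

    qual = _qualifying_crc_records(bundle, code_lists)
    wash = _washout_records(bundle, code_lists)
    qual_year = qual[qual["qidx"] // 4 == year]
    if qual_year.empty:
        return pd.DataFrame(columns=CASE_COLUMNS)

    person_attrs = bundle.persons.set_index("person_id")[["sex", "birth_year"]]
    qual_by_person = dict(tuple(qual.groupby("person_id")))
    wash_by_person = dict(tuple(wash.groupby("person_id")))
    candidate_ids = qual_year["person_id"].unique()
    spell_map: dict[str, list[tuple[dt.date, dt.date]]] = {}
    cand_set = set(candidate_ids)
    for pid, start, end in bundle.spells.itertuples(index=False):
        if pid in cand_set:
            spell_map.setdefault(pid, []).append((start.date(), end.date()))
    _check_spell_integrity(bundle.spells)

    rows = []
    for pid in candidate_ids:
        recs = qual_by_person[pid]
        in_year = recs[recs["qidx"] // 4 == year]
        q0 = int(in_year["qidx"].min())
        in_q0 = in_year[in_year["qidx"] == q0]
        inp_dates = in_q0.loc[in_q0["setting"] == "inpatient", "date"]
        if len(inp_dates):
            entry = inp_dates.min().date()
        else:
            entry = quarter_start(q0)

        # (a) confirmation: a second qualifying record in the window
        window = recs[(recs["qidx"] >= q0) & (recs["qidx"] <= q0 + confirm_quarters)]
        if len(window) < 2:
            continue

        # (b) washout over the preobservation period
        wstart = _lookback_start(entry, lookback_years)
        wend = entry - dt.timedelta(days=1)
        w = wash_by_person.get(pid)
        if w is not None and len(w):
            out_w = w[w["setting"] == "outpatient"]
            # quarter strictly before the entry quarter, overlapping window
            prev_hit = (
                (out_w["qidx"] < q0)
                & (out_w["qidx"] >= (wstart.year * 4 + (wstart.month - 1) // 3))
            ).any()
            inp_w = w[w["setting"] == "inpatient"]
            inp_hit = (
                (inp_w["date"] >= pd.Timestamp(wstart))
                & (inp_w["date"] <= pd.Timestamp(wend))
            ).any()
            if prev_hit or inp_hit:
                continue

        # (c) continuity from look-back start through December 31
        ref = dt.date(year, 12, 31)
        if not _window_covered(spell_map.get(pid, []), wstart, ref, max_gap_days):
            continue

        # (d) age
        birth_year = int(person_attrs.at[pid, "birth_year"])
        if year - birth_year < min_age:
            continue
        age_entry = year - birth_year - (1 if entry < dt.date(year, 7, 1) else 0)

        rows.append(
            {
                "person_id": pid,
                "cohort_entry_date": pd.Timestamp(entry),
                "entry_year": q0 // 4,
                "entry_quarter": q0 % 4 + 1,
                "age_at_entry": age_entry,
                "sex": person_attrs.at[pid, "sex"],
                "calendar_year": year,
            }
        )
    cases = pd.DataFrame(rows, columns=CASE_COLUMNS)
    return cases.sort_values("person_id", kind="mergesort").reset_index(drop=True)


def _window_covered(
    spells: list[tuple[dt.date, dt.date]],
    window_start: dt.date,
    window_end: dt.date,
    max_gap_days: int,
) -> bool:
    overlapping = sorted(
        (s, e) for s, e in spells if e >= window_start and s <= window_end
    )
    if not overlapping:
        return False
    if overlapping[0][0] > window_start or overlapping[-1][1] < window_end:
        return False
    prev_end = overlapping[0][1]
    for s, e in overlapping[1:]:
        if (s - prev_end).days - 1 > max_gap_days:
            return False
        prev_end = max(prev_end, e)
    return True


def _stage_code_records(bundle, code_lists: CodeLists) -> pd.DataFrame:
    """C77-C79 records that may stage a case (confirmed outpatient or
    main/secondary inpatient)."""
    prefixes = code_lists.lymph_only_codes | code_lists.distant_codes
    out = bundle.outpatient
    out = out[
        CodeLists._matches(out["icd_code"], prefixes)
        & (out["certainty"] == "confirmed")
    ]
    out = pd.DataFrame(
        {
            "person_id": out["person_id"],
            "qidx": out["year"] * 4 + out["quarter"] - 1,
            "setting": "outpatient",
            "icd_code": out["icd_code"],
        }
    )
    inp = bundle.inpatient
    inp = inp[
        CodeLists._matches(inp["icd_code"], prefixes)
        & inp["position"].isin(["main", "secondary"])
    ]
    inp = pd.DataFrame(
        {
            "person_id": inp["person_id"],
            "qidx": qindex_series(inp["date"]),
            "setting": "inpatient",
            "icd_code": inp["icd_code"],
        }
    )
    return pd.concat([out, inp], ignore_index=True)


def stage_cases(
    cases: pd.DataFrame,
    bundle,
    code_lists: CodeLists | None = None,
    n_following_quarters: int = 1,
) -> pd.DataFrame:
    """Assign {non_advanced, III, IV} from C77/C78-C79 codes in the staging
    window (entry quarter plus ``n_following_quarters`` following quarters).

    Any qualifying distant-metastasis code (C78-C79) forces UICC IV; else any
    lymph-node code (C77) gives UICC III; else non-advanced.
    """
    if n_following_quarters not in (0, 1, 2):
        raise ValueError(
            f"n_following_quarters must be 0, 1 or 2, got {n_following_quarters}"
        )
    code_lists = code_lists or CodeLists()
    staged = cases.copy()
    if staged.empty:
        staged["stage"] = pd.Series(dtype=str)
        staged["staging_window_quarters"] = pd.Series(dtype=int)
        return staged

    recs = _stage_code_records(bundle, code_lists)
    by_person = dict(tuple(recs.groupby("person_id")))
    distant = tuple(code_lists.distant_codes)
    stages = []
    for row in staged.itertuples(index=False):
        q0 = row.entry_year * 4 + row.entry_quarter - 1
        r = by_person.get(row.person_id)
        stage = "non_advanced"
        if r is not None:
            in_win = r[(r["qidx"] >= q0) & (r["qidx"] <= q0 + n_following_quarters)]
            if len(in_win):
                if in_win["icd_code"].str.startswith(distant).any():
                    stage = "IV"
                else:
                    stage = "III"
        stages.append(stage)
    staged["stage"] = stages
    staged["staging_window_quarters"] = n_following_quarters
    return staged


def inpatient_evidence_summary(
    staged_cases: pd.DataFrame, bundle, code_lists: CodeLists | None = None
) -> dict:
    """Evidence quality behind UICC IV assignments.

    Returns the proportion of stage-IV cases with at least one main/secondary
    inpatient C78-C79 code in their staging window, and - among the stage-IV
    cases without such a code - the proportion carrying two or more confirmed
    outpatient C78-C79 records there. Undefined proportions are ``None``.
    """
    code_lists = code_lists or CodeLists()
    iv = staged_cases[staged_cases["stage"] == "IV"]
    if iv.empty:
        return {
            "n_iv": 0,
            "prop_IV_with_inpatient_code": None,
            "prop_remaining_with_2plus_outpatient": None,
        }
    recs = _stage_code_records(bundle, code_lists)
    distant = tuple(code_lists.distant_codes)
    recs = recs[recs["icd_code"].str.startswith(distant)]
    by_person = dict(tuple(recs.groupby("person_id")))

    with_inp = 0
    remaining_2plus = 0
    n_remaining = 0
    for row in iv.itertuples(index=False):
        q0 = row.entry_year * 4 + row.entry_quarter - 1
        q1 = q0 + int(row.staging_window_quarters)
        r = by_person.get(row.person_id)
        in_win = r[(r["qidx"] >= q0) & (r["qidx"] <= q1)] if r is not None else None
        has_inp = in_win is not None and (in_win["setting"] == "inpatient").any()
        if has_inp:
            with_inp += 1
        else:
            n_remaining += 1
            n_out = 0 if in_win is None else int((in_win["setting"] == "outpatient").sum())
            if n_out >= 2:
                remaining_2plus += 1
    return {
        "n_iv": int(len(iv)),
        "prop_IV_with_inpatient_code": with_inp / len(iv),
        "prop_remaining_with_2plus_outpatient": (
            remaining_2plus / n_remaining if n_remaining else None
        ),
    }


def _round_half_away(x: float, ndigits: int = 0) -> float:
    import decimal

    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(
        decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def crosscheck_percentage(
    n_subsample: int,
    n_non_advanced: int,
    n_flagged: int,
    denominator: str = "subsample",
) -> float:
    """Flagged cases as a percentage (two decimals, half away from zero).

    ``denominator`` chooses between the full CRC subsample (default) and the
    non-advanced subset.
    """
    if n_subsample <= 0:
        raise ValueError("empty subsample")
    if denominator == "subsample":
        denom = n_subsample
    elif denominator == "non_advanced":
        denom = n_non_advanced
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom <= 0:
        raise ValueError("denominator is zero")
    return _round_half_away(100.0 * n_flagged / denom, 2)


def medication_crosscheck(
    staged_cases: pd.DataFrame,
    dispensations: pd.DataFrame,
    code_lists: CodeLists | None = None,
    window_days: int = 90,
    denominator: str = "subsample",
) -> dict:
    """Count non-advanced-classified cases that nevertheless received a
    therapy typically reserved for advanced CRC (bevacizumab-class agents)
    within ``window_days`` after cohort entry."""
    code_lists = code_lists or CodeLists()
    if staged_cases.empty:
        raise ValueError("empty subsample")
    non_adv = staged_cases[staged_cases["stage"] == "non_advanced"]
    disp = dispensations[
        dispensations["agent_code"].isin(code_lists.advanced_therapy_codes)
    ]
    by_person = dict(tuple(disp.groupby("person_id")))
    n_flagged = 0
    for row in non_adv.itertuples(index=False):
        d = by_person.get(row.person_id)
        if d is None:
            continue
        start = row.cohort_entry_date
        end = start + pd.Timedelta(days=window_days)
        if ((d["date"] >= start) & (d["date"] <= end)).any():
            n_flagged += 1
    return {
        "n_subsample": int(len(staged_cases)),
        "n_non_advanced": int(len(non_adv)),
        "n_flagged": n_flagged,
        "pct_of_subsample": crosscheck_percentage(
            len(staged_cases), len(non_adv), n_flagged, denominator
        ),
    }
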