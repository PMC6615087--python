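"""Independent per-person, per-rule interpreter of the cohort algorithm.

Deliberately naive: plain-Python loops over one person's records, day-level
coverage bitmaps for insurance continuity, no pandas group logic. Serves as
the oracle the vectorized pipeline is checked against on small fixtures.
"""

from __future__ import annotations

import datetime as dt

CRC = ("C18", "C19", "C20")
LYMPH = ("C77",)
DISTANT = ("C78", "C79")


def _q(year: int, quarter: int) -> int:
    return year * 4 + quarter - 1


def _q_of_date(d: dt.date) -> int:
    return d.year * 4 + (d.month - 1) // 3


def _q_first_day(q: int) -> dt.date:
    return dt.date(q // 4, (q % 4) * 3 + 1, 1)


def _q_last_day(q: int) -> dt.date:
    m = (q % 4) * 3 + 3
    y = q // 4
    if m == 12:
        return dt.date(y, 12, 31)
    return dt.date(y, m + 1, 1) - dt.timedelta(days=1)


def _person_rows(df, pid):
    return [row for row in df.itertuples(index=False) if row.person_id == pid]


def _covered_ok(spell_rows, start: dt.date, end: dt.date, max_gap: int) -> bool:
    """Day-bitmap walk: endpoints covered, no uncovered run > max_gap."""
    n = (end - start).days + 1
    cov = bytearray(n)
    for row in spell_rows:
        s = max(row.start_date.date(), start)
        e = min(row.end_date.date(), end)
        if s <= e:
            i0 = (s - start).days
            cov[i0 : (e - start).days + 1] = b"\x01" * ((e - s).days + 1)
    if not cov[0] or not cov[-1]:
        return False
    run = 0
    for b in cov:
        if b:
            run = 0
        else:
            run += 1
            if run > max_gap:
                return False
    return True


def naive_eligible(
    persons, spells, year, lookback_years=4, max_gap_days=15, min_age=5
):
    """Set of person_ids in the year's denominator."""
    ref = dt.date(year, 12, 31)
    start = ref - dt.timedelta(days=round(lookback_years * 365.25))
    by_pid = {}
    for row in spells.itertuples(index=False):
        by_pid.setdefault(row.person_id, []).append(row)
    out = set()
    for p in persons.itertuples(index=False):
        if year - p.birth_year < min_age:
            continue
        if _covered_ok(by_pid.get(p.person_id, []), start, ref, max_gap_days):
            out.add(p.person_id)
    return out


def naive_cases(
    bundle,
    year,
    lookback_years=4,
    confirm_quarters=2,
    max_gap_days=15,
    min_age=5,
    n_following_quarters=1,
):
    """List of (person_id, entry_date, stage) ascertained for the year."""
    persons = {p.person_id: p for p in bundle.persons.itertuples(index=False)}
    spells_by = {}
    for row in bundle.spells.itertuples(index=False):
        spells_by.setdefault(row.person_id, []).append(row)

    out_by, inp_by = {}, {}
    for row in bundle.outpatient.itertuples(index=False):
        out_by.setdefault(row.person_id, []).append(row)
    for row in bundle.inpatient.itertuples(index=False):
        inp_by.setdefault(row.person_id, []).append(row)

    results = []
    for pid, p in persons.items():
        # qualifying CRC records: (quarter, exact date or None)
        qual = []
        for r in out_by.get(pid, []):
            if r.icd_code.startswith(CRC) and r.certainty == "confirmed":
                qual.append((_q(r.year, r.quarter), None))
        for r in inp_by.get(pid, []):
            if r.icd_code.startswith(CRC) and r.position in ("main", "secondary"):
                qual.append((_q_of_date(r.date.date()), r.date.date()))
        in_year = [q for q in qual if q[0] // 4 == year]
        if not in_year:
            continue
        q0 = min(q for q, _ in in_year)
        inp_dates = [d for q, d in in_year if q == q0 and d is not None]
        entry = min(inp_dates) if inp_dates else _q_first_day(q0)

        n_window = sum(1 for q, _ in qual if q0 <= q <= q0 + confirm_quarters)
        if n_window < 2:
            continue

        wstart = entry - dt.timedelta(days=round(lookback_years * 365.25))
        wend = entry - dt.timedelta(days=1)
        prevalent = False
        for r in out_by.get(pid, []):
            if r.icd_code.startswith(CRC) and r.certainty in (
                "confirmed",
                "status_post",
            ):
                q = _q(r.year, r.quarter)
                if q < q0 and _q_last_day(q) >= wstart:
                    prevalent = True
        for r in inp_by.get(pid, []):
            if r.icd_code.startswith(CRC) and r.position in ("main", "secondary"):
                if wstart <= r.date.date() <= wend:
                    prevalent = True
        if prevalent:
            continue

        if not _covered_ok(
            spells_by.get(pid, []), wstart, dt.date(year, 12, 31), max_gap_days
        ):
            continue
        if year - p.birth_year < min_age:
            continue

        # staging
        stage = "non_advanced"
        has_distant = has_lymph = False
        for r in out_by.get(pid, []):
            q = _q(r.year, r.quarter)
            if q0 <= q <= q0 + n_following_quarters and r.certainty == "confirmed":
                if r.icd_code.startswith(DISTANT):
                    has_distant = True
                elif r.icd_code.startswith(LYMPH):
                    has_lymph = True
        for r in inp_by.get(pid, []):
            q = _q_of_date(r.date.date())
            if q0 <= q <= q0 + n_following_quarters and r.position in (
                "main",
                "secondary",
            ):
                if r.icd_code.startswith(DISTANT):
                    has_distant = True
                elif r.icd_code.startswith(LYMPH):
                    has_lymph = True
        if has_distant:
            stage = "IV"
        elif has_lymph:
            stage = "III"
        results.append((pid, entry, stage))
    return sorted(results)
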