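"""Synthetic claims and cancer-registry data with known ground truth.

The generator emulates the structure of German statutory-health-insurance
claims (GePaRD-like) and federal cancer-registry records as far as the
downstream algorithms are sensitive to it:

* outpatient diagnoses at (year, quarter) granularity with a mandatory
  certainty qualifier; inpatient discharge diagnoses with exact dates and a
  main/secondary/admission position;
* incident colorectal cancers (ICD-10 C18-C20) drawn per person-year from
  age-, sex-, and stage-specific rates, a configurable fraction re-dated
  before the analysis window to act as prevalent disease;
* an initial tumour code, a probabilistic confirmatory code within two
  quarters, quarterly follow-up codes thereafter, and - for advanced stages -
  secondary-neoplasm codes (C77 nodes, C78-C79 distant) emitted with
  configurable probability and quarter lag;
* antiangiogenic-therapy dispensations for stage IV disease;
* insurance interruptions;
* registry records whose N/M status is degraded by pathologist-only
  reporting, premature "M0" assignment in true stage IV, and independent
  missingness.

Every draw flows from a single mandatory seed; identical configurations give
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging

import numpy as np
import pandas as pd

from .config import STAGES, SimConfig
from .quarters import qindex, qindex_of_date, quarter_start
from .rates import age_band

__all__ = [
    "ClaimsBundle",
    "simulate_population",
    "simulate_events",
    "emit_claims",
    "emit_registry",
    "population_denominators",
    "simulate_bundle",
]

logger = logging.getLogger(__name__)

# per-stage stream ids so each generator stage has an independent substream
_POP, _EVENTS, _CLAIMS, _REGISTRY = 1, 2, 3, 4

CRC_CODES = ("C18.0", "C18.2", "C18.4", "C18.7", "C19", "C20")
LYMPH_CODES = ("C77.0", "C77.2", "C77.9")
DISTANT_CODES = ("C78.0", "C78.7", "C79.5", "C79.9")
THERAPY_CODES = ("L01XC07", "L01XC21", "L01XX44")  # bevacizumab-class agents
NOISE_CODES = ("I10.90", "E11.9", "J06.9", "M54.5", "K29.7")

OUTPATIENT_COLS = ["person_id", "year", "quarter", "icd_code", "certainty"]
INPATIENT_COLS = ["person_id", "date", "icd_code", "position"]
DISPENSATION_COLS = ["person_id", "date", "agent_code"]


@dataclasses.dataclass
class ClaimsBundle:
    """The five claims tables of one synthetic (or fixture) population."""

    persons: pd.DataFrame
    spells: pd.DataFrame
    outpatient: pd.DataFrame
    inpatient: pd.DataFrame
    dispensations: pd.DataFrame

    def table_names(self) -> tuple[str, ...]:
        return ("persons", "spells", "outpatient", "inpatient", "dispensations")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, stream])


def simulate_population(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw persons and their insurance spells.

    Each person is insured over the whole data window; with probability
    ``p_gap`` one interior interruption of ``gap_days_min..gap_days_max`` days
    splits the coverage into two spells.
    """
    rng = _rng(config, _POP)
    n = config.n_persons
    person_id = np.array([f"P{i:07d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    birth_year = config.first_year - rng.integers(
        config.min_age, config.max_age + 1, size=n
    )
    persons = pd.DataFrame(
        {"person_id": person_id, "sex": sex, "birth_year": birth_year}
    )

    range_start = pd.Timestamp(dt.date(config.first_year, 1, 1))
    range_end = pd.Timestamp(dt.date(config.last_year, 12, 31))
    total_days = (range_end - range_start).days + 1

    gap_len = rng.integers(config.gap_days_min, config.gap_days_max + 1, size=n)
    has_gap = rng.random(n) < config.p_gap
    # keep the interruption strictly interior (30-day margins); degenerate
    # windows fall back to no gap
    hi = total_days - gap_len - 30
    has_gap &= hi > 30
    gap_off = np.where(hi > 30, rng.integers(30, np.maximum(hi, 31)), 0)

    rows = {"person_id": [], "start_date": [], "end_date": []}
    day = pd.to_timedelta(1, "D")
    for i in np.flatnonzero(has_gap):
        g0 = range_start + pd.to_timedelta(int(gap_off[i]), "D")
        g1 = g0 + pd.to_timedelta(int(gap_len[i]) - 1, "D")
        rows["person_id"] += [person_id[i], person_id[i]]
        rows["start_date"] += [range_start, g1 + day]
        rows["end_date"] += [g0 - day, range_end]
    no_gap = ~has_gap
    rows["person_id"] += list(person_id[no_gap])
    rows["start_date"] += [range_start] * int(no_gap.sum())
    rows["end_date"] += [range_end] * int(no_gap.sum())

    spells = (
        pd.DataFrame(rows)
        .sort_values(["person_id", "start_date"], kind="mergesort")
        .reset_index(drop=True)
    )
    return persons, spells


def _stage_probs(persons: pd.DataFrame, year: int, config: SimConfig) -> np.ndarray:
    """Per-person annual event probability for each stage, shape (n, 3)."""
    ages = year - persons["birth_year"].to_numpy()
    bands = np.clip(ages // 5, 0, 17)
    mult = np.asarray(config.age_pattern)[bands]
    mult = np.where(ages < 0, 0.0, mult)  # not yet born
    mult = mult * np.where(
        persons["sex"].to_numpy() == "male", config.male_to_female_ratio, 1.0
    )
    base = np.array([config.incidence_per_100k[s] for s in STAGES]) / 1e5
    return np.outer(mult, base)


def simulate_events(persons: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Draw at most one colorectal-cancer event per person.

    Incident events arise per person-year over the analysis years at the
    configured age-/sex-/stage-specific rates. Prevalent disease is added on
    top: extra events among otherwise event-free persons, dated uniformly
    into the preobservation years, sized so that ``prevalent_fraction`` of
    all events is prevalent (the incident process keeps its configured rate).
    With ``prevalent_fraction = 1`` every drawn event is re-dated before the
    analysis window instead.
    """
    rng = _rng(config, _EVENTS)
    n = len(persons)
    years = config.analysis_years
    taken = np.zeros(n, dtype=bool)
    ev_year = np.full(n, -1)
    ev_stage = np.full(n, "", dtype=object)
    for year in years:
        probs = _stage_probs(persons, year, config)  # (n, 3)
        total = probs.sum(axis=1)
        u = rng.random(n)
        hit = (~taken) & (u < total)
        if hit.any():
            # conditional stage draw
            cum = np.cumsum(probs[hit], axis=1)
            v = rng.random(hit.sum()) * total[hit]
            stage_idx = (v[:, None] >= cum).sum(axis=1)
            ev_year[hit] = year
            ev_stage[hit] = np.asarray(STAGES, dtype=object)[stage_idx]
            taken |= hit
    idx = np.flatnonzero(taken)
    if idx.size == 0:
        return pd.DataFrame(
            {
                "person_id": pd.Series(dtype=str),
                "diagnosis_date": pd.Series(dtype="datetime64[ns]"),
                "true_stage": pd.Series(dtype=str),
                "prevalent_flag": pd.Series(dtype=bool),
            }
        )

    day_in_year = rng.integers(0, 365, size=idx.size)
    diag = (
        pd.to_datetime(pd.DataFrame({"year": ev_year[idx], "month": 1, "day": 1}))
        + pd.to_timedelta(day_in_year, "D")
    ).to_numpy()
    prevalent = np.zeros(idx.size, dtype=bool)

    pre_start = dt.date(config.first_year, 1, 1)
    pre_end = dt.date(config.first_analysis_year, 1, 1) - dt.timedelta(days=1)
    if pre_end < pre_start:  # no preobservation years simulated
        pre_start = dt.date(config.first_year - 1, 1, 1)
        pre_end = dt.date(config.first_year - 1, 12, 31)
    pre_span = (pre_end - pre_start).days + 1

    def _pre_dates(k: int) -> np.ndarray:
        off = rng.integers(0, pre_span, size=k)
        return pd.Timestamp(pre_start).to_numpy() + off.astype("timedelta64[D]")

    f = config.prevalent_fraction
    pids = persons["person_id"].to_numpy()[idx]
    stages_out = ev_stage[idx]
    if f >= 1.0:
        diag = _pre_dates(idx.size)
        prevalent[:] = True
    elif f > 0.0 and idx.size > 0:
        free = np.flatnonzero(~taken)
        n_prev = min(int(round(f / (1.0 - f) * idx.size)), free.size)
        if n_prev > 0:
            chosen = rng.choice(free, size=n_prev, replace=False)
            base = np.array(
                [config.incidence_per_100k[s] for s in STAGES], dtype=float
            )
            stage_p = base / base.sum() if base.sum() > 0 else np.full(3, 1 / 3)
            prev_stage = np.asarray(STAGES, dtype=object)[
                rng.choice(3, size=n_prev, p=stage_p)
            ]
            pids = np.concatenate([pids, persons["person_id"].to_numpy()[chosen]])
            stages_out = np.concatenate([stages_out, prev_stage])
            diag = np.concatenate([diag, _pre_dates(n_prev)])
            prevalent = np.concatenate([prevalent, np.ones(n_prev, dtype=bool)])

    events = pd.DataFrame(
        {
            "person_id": pids,
            "diagnosis_date": pd.Series(diag),
            "true_stage": stages_out,
            "prevalent_flag": prevalent,
        }
    )
    return (
        events.sort_values("person_id", kind="mergesort").reset_index(drop=True)
    )


def _random_day_in_quarter(
    rng: np.random.Generator, qidx_val: int, not_before: dt.date | None = None
) -> dt.date:
    start = quarter_start(qidx_val)
    end = quarter_start(qidx_val + 1) - dt.timedelta(days=1)
    if not_before is not None and not_before > start:
        start = not_before
    span = (end - start).days + 1
    return start + dt.timedelta(days=int(rng.integers(0, span)))


def emit_claims(
    persons: pd.DataFrame,
    spells: pd.DataFrame,
    events: pd.DataFrame,
    config: SimConfig,
) -> ClaimsBundle:
    """Translate true cancer events into claims codes.

    Events whose diagnosis date falls outside every insurance spell of the
    person leave no trace (logged, not an error).
    """
    rng = _rng(config, _CLAIMS)
    qmin = qindex(config.first_year, 1)
    qmax = qindex(config.last_year, 4)

    spell_map: dict[str, list[tuple[dt.date, dt.date]]] = {}
    ev_persons = set(events["person_id"])
    for pid, start, end in spells.itertuples(index=False):
        if pid in ev_persons:
            spell_map.setdefault(pid, []).append((start.date(), end.date()))

    out_rows: list[tuple] = []
    inp_rows: list[tuple] = []
    disp_rows: list[tuple] = []
    n_uncoded = 0

    def emit_out(pid: str, q: int, code: str, certainty: str) -> None:
        if qmin <= q <= qmax:
            year, q0 = divmod(q, 4)
            out_rows.append((pid, year, q0 + 1, code, certainty))

    def emit_inp(pid: str, date: dt.date, code: str, position: str) -> None:
        if config.first_year <= date.year <= config.last_year:
            inp_rows.append((pid, pd.Timestamp(date), code, position))

    lags = np.array([0, 1, 2])

    for row in events.itertuples(index=False):
        pid = row.person_id
        diag: dt.date = row.diagnosis_date.date()
        covered = any(s <= diag <= e for s, e in spell_map.get(pid, ()))
        if not covered:
            n_uncoded += 1
            continue
        q0 = qindex_of_date(diag)

        # initial tumour code
        code = str(rng.choice(CRC_CODES))
        if rng.random() < config.p_outpatient_initial:
            emit_out(pid, q0, code, "confirmed")
        else:
            emit_inp(pid, diag, code, "main")

        # confirmatory code within the entry quarter or the two following
        if rng.random() < config.p_confirmation_code:
            lag = int(rng.choice(lags, p=config.confirmation_lag_probs))
            q = q0 + lag
            ccode = str(rng.choice(CRC_CODES))
            if rng.random() < config.p_inpatient_confirmation:
                if q <= qmax:
                    d = _random_day_in_quarter(rng, q, diag if lag == 0 else None)
                    emit_inp(pid, d, ccode, "secondary")
            else:
                emit_out(pid, q, ccode, "confirmed")

        # quarterly follow-up coding of the known tumour
        for q in range(q0 + 1, qmax + 1):
            if rng.random() < config.p_followup_code:
                cert = "status_post" if rng.random() < 0.5 else "confirmed"
                emit_out(pid, q, str(rng.choice(CRC_CODES)), cert)

        # secondary-neoplasm codes
        stage = row.true_stage
        if stage == "III" and rng.random() < config.p_c77_emission:
            _emit_lymph(rng, config, pid, q0, diag, emit_out, emit_inp)
        if stage == "IV":
            if rng.random() < config.p_distant_emission:
                lag = int(rng.choice(lags, p=config.distant_lag_probs))
                q = q0 + lag
                dcode = str(rng.choice(DISTANT_CODES))
                if rng.random() < config.p_inpatient_metastasis_code:
                    if q <= qmax:
                        d = _random_day_in_quarter(rng, q, diag if lag == 0 else None)
                        pos = "main" if rng.random() < 0.5 else "secondary"
                        emit_inp(pid, d, dcode, pos)
                else:
                    emit_out(pid, q, dcode, "confirmed")
                    if rng.random() < config.p_second_outpatient_distant:
                        emit_out(pid, q, str(rng.choice(DISTANT_CODES)), "confirmed")
            if rng.random() < config.p_c77_given_iv:
                _emit_lymph(rng, config, pid, q0, diag, emit_out, emit_inp)
            if rng.random() < config.p_advanced_therapy:
                d = diag + dt.timedelta(
                    days=int(rng.integers(0, config.therapy_delay_max_days + 1))
                )
                if d.year <= config.last_year:
                    disp_rows.append(
                        (pid, pd.Timestamp(d), str(rng.choice(THERAPY_CODES)))
                    )

    if n_uncoded:
        logger.info("emit_claims: %d events outside insurance left uncoded", n_uncoded)

    outpatient = pd.DataFrame(out_rows, columns=OUTPATIENT_COLS)
    inpatient = pd.DataFrame(inp_rows, columns=INPATIENT_COLS)
    dispensations = pd.DataFrame(disp_rows, columns=DISPENSATION_COLS)

    # unrelated background diagnoses (do not interact with the algorithms)
    if config.noise_codes_per_person_year > 0 and len(persons) > 0:
        n_py = len(persons) * len(config.data_years)
        k = int(rng.poisson(config.noise_codes_per_person_year * n_py))
        if k:
            noise = pd.DataFrame(
                {
                    "person_id": persons["person_id"]
                    .to_numpy()[rng.integers(0, len(persons), k)],
                    "year": rng.integers(config.first_year, config.last_year + 1, k),
                    "quarter": rng.integers(1, 5, k),
                    "icd_code": np.array(NOISE_CODES)[
                        rng.integers(0, len(NOISE_CODES), k)
                    ],
                    "certainty": "confirmed",
                }
            )
            outpatient = pd.concat([outpatient, noise], ignore_index=True)

    inpatient["date"] = pd.to_datetime(inpatient["date"])
    dispensations["date"] = pd.to_datetime(dispensations["date"])

    outpatient = outpatient.sort_values(
        ["person_id", "year", "quarter", "icd_code"], kind="mergesort"
    ).reset_index(drop=True)
    inpatient = inpatient.sort_values(
        ["person_id", "date", "icd_code"], kind="mergesort"
    ).reset_index(drop=True)
    dispensations = dispensations.sort_values(
        ["person_id", "date"], kind="mergesort"
    ).reset_index(drop=True)

    return ClaimsBundle(
        persons=persons.reset_index(drop=True),
        spells=spells.reset_index(drop=True),
        outpatient=outpatient,
        inpatient=inpatient,
        dispensations=dispensations,
    )


def _emit_lymph(rng, config, pid, q0, diag, emit_out, emit_inp) -> None:
    lag = int(rng.choice([0, 1, 2], p=config.c77_lag_probs))
    q = q0 + lag
    code = str(rng.choice(LYMPH_CODES))
    if rng.random() < 0.5:
        emit_out(pid, q, code, "confirmed")
    else:
        if q <= qindex(config.last_year, 4):
            d = _random_day_in_quarter(rng, q, diag if lag == 0 else None)
            emit_inp(pid, d, code, "secondary")


def emit_registry(
    events: pd.DataFrame, persons: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Produce one registry record per reported event.

    A faithful record carries (N0, M0) for non-advanced, (N+, M0) for stage
    III, and (N+/N0, M1) for stage IV disease. Degradation, in order:
    pathologist-only reporting blanks both statuses; premature reporting turns
    a true-IV M1 into M0 with N kept as recorded; independent N and M
    missingness applies last.
    """
    rng = _rng(config, _REGISTRY)
    merged = events.merge(
        persons[["person_id", "sex", "birth_year"]], on="person_id", how="left"
    )
    n = len(merged)
    reported = rng.random(n) < config.reporting_completeness

    stage = merged["true_stage"].to_numpy()
    is_iv = stage == "IV"
    n_status = np.where(stage == "non_advanced", "N0", "N_plus").astype(object)
    iv_n0 = is_iv & (rng.random(n) >= config.p_n_plus_given_iv)
    n_status[iv_n0] = "N0"
    m_status = np.where(is_iv, "M1", "M0").astype(object)

    path_only = rng.random(n) < config.p_pathologist_only
    premature = (~path_only) & is_iv & (rng.random(n) < config.p_premature_m0)
    m_status[premature] = "M0"
    n_missing = (~path_only) & (rng.random(n) < config.p_n_missing)
    m_missing = (~path_only) & (rng.random(n) < config.p_m_missing)
    n_status[path_only | n_missing] = "missing"
    m_status[path_only | m_missing] = "missing"

    diag_year = merged["diagnosis_date"].dt.year.to_numpy()
    registry = pd.DataFrame(
        {
            "person_id": merged["person_id"],
            "sex": merged["sex"],
            "age_at_diagnosis": diag_year - merged["birth_year"].to_numpy(),
            "diagnosis_year": diag_year,
            "n_status": n_status,
            "m_status": m_status,
        }
    )[reported].reset_index(drop=True)
    registry.insert(0, "record_id", [f"R{i:07d}" for i in range(len(registry))])
    return registry


def population_denominators(persons: pd.DataFrame, years: list[int]) -> pd.DataFrame:
    """Population counts by year x sex x five-year age band (attained age)."""
    frames = []
    for year in years:
        ages = year - persons["birth_year"]
        alive = ages >= 0  # cohorts born after the data start
        df = pd.DataFrame(
            {"sex": persons["sex"][alive], "age_band": age_band(ages[alive])}
        )
        counts = (
            df.groupby(["sex", "age_band"], observed=False)
            .size()
            .reindex(
                pd.MultiIndex.from_product(
                    [["female", "male"], range(18)], names=["sex", "age_band"]
                ),
                fill_value=0,
            )
            .reset_index(name="person_count")
        )
        counts.insert(0, "year", year)
        frames.append(counts)
    return pd.concat(frames, ignore_index=True)


def simulate_bundle(
    config: SimConfig,
) -> tuple[ClaimsBundle, pd.DataFrame, pd.DataFrame]:
    """Run the whole generator: returns (bundle, events, registry)."""
    persons, spells = simulate_population(config)
    events = simulate_events(persons, config)
    bundle = emit_claims(persons, spells, events, config)
    registry = emit_registry(events, persons, config)
    return bundle, events, registry
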