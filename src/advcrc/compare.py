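"""Claims-vs-registry comparison analyses and the end-to-end pipeline.

Joins the two rate tables on year x sex x stage, computes absolute and
relative ASIR differences, summarizes first-to-last-year trends as integer
percent declines, runs the staging-window sensitivity analysis, and drives
simulate -> claims pipeline -> registry pipeline -> rates -> comparison as a
single reproducible run.
"""

from __future__ import annotations

import decimal
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as advio
from .claims import (
    CodeLists,
    eligible_persons,
    identify_incident_cases,
    inpatient_evidence_summary,
    medication_crosscheck,
    stage_cases,
)
from .config import SimConfig
from .rates import ESP_OLD_WEIGHTS, age_band, rate_table
from .registry import SCENARIOS, apply_scenario, classify_records, tabulate_classes
from .synthetic import population_denominators, simulate_bundle

__all__ = [
    "percent_change",
    "build_comparison",
    "trend_summary",
    "window_sensitivity",
    "claims_rate_table",
    "registry_rate_table",
    "run_all",
]

logger = logging.getLogger(__name__)

#: How registry classes map onto the claims stage labels for comparison.
REGISTRY_STAGE_MAP = {
    "non_advanced": "non_advanced",
    "advanced_III": "III",
    "advanced_IV": "IV",
}
ADVANCED_CLASSES = ("advanced_III", "advanced_IV", "advanced_unstratifiable")


def percent_change(rate_first: float, rate_last: float) -> int:
    """Integer percent decline 100 * (1 - last/first), half away from zero."""
    if rate_first <= 0:
        raise ValueError("rate_first must be positive")
    x = 100.0 * (1.0 - float(rate_last) / float(rate_first))
    return int(
        decimal.Decimal(repr(float(x))).quantize(
            decimal.Decimal(1), decimal.ROUND_HALF_UP
        )
    )


def build_comparison(
    claims_rates: pd.DataFrame, registry_rates: pd.DataFrame
) -> pd.DataFrame:
    """Join two rate tables and attach absolute / relative ASIR differences.

    Strata present on one side only are kept with not-available differences
    (and logged); a registry ASIR of zero leaves the relative difference
    not available.
    """
    key = ["year", "sex", "stage"]
    merged = claims_rates[key + ["asir"]].merge(
        registry_rates[key + ["asir"]],
        on=key,
        how="outer",
        suffixes=("_claims", "_registry"),
    )
    one_sided = merged["asir_claims"].isna() | merged["asir_registry"].isna()
    if one_sided.any():
        logger.warning(
            "build_comparison: %d strata present in one table only", one_sided.sum()
        )
    merged["abs_difference"] = merged["asir_claims"] - merged["asir_registry"]
    merged["relative_difference"] = np.where(
        merged["asir_registry"] > 0,
        100.0 * merged["abs_difference"] / merged["asir_registry"],
        np.nan,
    )
    return merged.sort_values(key, kind="mergesort").reset_index(drop=True)


def trend_summary(rates: pd.DataFrame) -> pd.DataFrame:
    """First-to-last-year ASIR decline per sex x stage, in integer percent."""
    rows = []
    for (sex, stage), grp in rates.groupby(["sex", "stage"]):
        grp = grp.dropna(subset=["asir"]).sort_values("year")
        if len(grp) < 2 or grp["asir"].iloc[0] <= 0:
            continue
        first, last = grp.iloc[0], grp.iloc[-1]
        rows.append(
            {
                "sex": sex,
                "stage": stage,
                "first_year": int(first["year"]),
                "last_year": int(last["year"]),
                "asir_first": first["asir"],
                "asir_last": last["asir"],
                "percent_decline": percent_change(first["asir"], last["asir"]),
            }
        )
    return pd.DataFrame(rows)


def _staged_with_bands(staged: pd.DataFrame) -> pd.DataFrame:
    out = staged.copy()
    out["year"] = out["calendar_year"]
    # attained age: aligns numerator bands with the Dec-31 denominator
    out["age_band"] = age_band(out["calendar_year"] - _birth_year_from(out))
    return out


def _birth_year_from(staged: pd.DataFrame) -> pd.Series:
    # age_at_entry uses the mid-year convention; recover birth year exactly
    before_july = staged["cohort_entry_date"] < pd.to_datetime(
        staged["calendar_year"].astype(str) + "-07-01"
    )
    return staged["calendar_year"] - staged["age_at_entry"] - before_july.astype(int)


def claims_pipeline(
    bundle,
    years: list[int],
    code_lists: CodeLists | None = None,
    n_following_quarters: int = 1,
    lookback_years: int = 4,
    confirm_quarters: int = 2,
    max_gap_days: int = 15,
    min_age: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run ascertainment + staging for each year; returns (staged, denoms)."""
    code_lists = code_lists or CodeLists()
    staged_frames, denom_frames = [], []
    for year in years:
        cases = identify_incident_cases(
            bundle,
            year,
            code_lists,
            lookback_years=lookback_years,
            confirm_quarters=confirm_quarters,
            max_gap_days=max_gap_days,
            min_age=min_age,
        )
        staged_frames.append(
            stage_cases(cases, bundle, code_lists, n_following_quarters)
        )
        denom_frames.append(
            eligible_persons(
                bundle.persons,
                bundle.spells,
                year,
                lookback_years=lookback_years,
                max_gap_days=max_gap_days,
                min_age=min_age,
            )
        )
    non_empty = [f for f in staged_frames if not f.empty]
    staged = pd.concat(non_empty or staged_frames[:1], ignore_index=True)
    denoms = pd.concat(denom_frames, ignore_index=True)
    return staged, denoms


def claims_rate_table(
    staged: pd.DataFrame,
    denominators: pd.DataFrame,
    weights=ESP_OLD_WEIGHTS,
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Rates per year x sex for the three stages plus the advanced aggregate."""
    cases = _staged_with_bands(staged)
    adv = cases[cases["stage"].isin(["III", "IV"])].copy()
    adv["stage"] = "advanced"
    cases = pd.concat([cases, adv], ignore_index=True)
    return rate_table(
        cases,
        denominators,
        weights,
        stages=["non_advanced", "III", "IV", "advanced"],
        years=years,
    )


def registry_rate_table(
    classified: pd.DataFrame,
    denominators: pd.DataFrame,
    weights=ESP_OLD_WEIGHTS,
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Rates per year x sex for the registry classes mapped to stage labels.

    ``advanced`` aggregates III, IV and the unstratifiable advanced records;
    ``not_classifiable`` is carried through as its own label.
    """
    cases = classified.copy()
    cases["year"] = cases["diagnosis_year"]
    cases["age_band"] = age_band(cases["age_at_diagnosis"])
    frames = []
    mapped = cases[cases["cls"].isin(REGISTRY_STAGE_MAP)].copy()
    mapped["stage"] = mapped["cls"].map(REGISTRY_STAGE_MAP)
    frames.append(mapped)
    adv = cases[cases["cls"].isin(ADVANCED_CLASSES)].copy()
    adv["stage"] = "advanced"
    frames.append(adv)
    nc = cases[cases["cls"] == "not_classifiable"].copy()
    nc["stage"] = "not_classifiable"
    frames.append(nc)
    non_empty = [f for f in frames if not f.empty]
    all_cases = pd.concat(non_empty or frames[:1], ignore_index=True)
    return rate_table(
        all_cases,
        denominators,
        weights,
        stages=["non_advanced", "III", "IV", "advanced", "not_classifiable"],
        years=years,
    )


def window_sensitivity(
    bundle,
    years: list[int],
    denominators: pd.DataFrame,
    code_lists: CodeLists | None = None,
    windows: tuple[int, ...] = (0, 1, 2),
    weights=ESP_OLD_WEIGHTS,
) -> pd.DataFrame:
    """Stage with each window and tabulate rates; checks that stage-IV case
    sets are nested as the window grows."""
    code_lists = code_lists or CodeLists()
    cases_by_year = {
        year: identify_incident_cases(bundle, year, code_lists) for year in years
    }
    frames = []
    prev_iv: set | None = None
    for w in sorted(windows):
        per_year = [
            stage_cases(cases_by_year[year], bundle, code_lists, w)
            for year in years
        ]
        non_empty = [f for f in per_year if not f.empty]
        staged = pd.concat(non_empty or per_year[:1], ignore_index=True)
        iv_set = set(
            staged.loc[staged["stage"] == "IV", ["person_id", "calendar_year"]]
            .itertuples(index=False, name=None)
        )
        if prev_iv is not None and not prev_iv <= iv_set:
            raise AssertionError("stage-IV case sets not nested across windows")
        prev_iv = iv_set
        rt = claims_rate_table(staged, denominators, weights, years=years)
        rt.insert(0, "staging_window_quarters", w)
        frames.append(rt)
    return pd.concat(frames, ignore_index=True)


def run_all(config: SimConfig, seed: int | None = None, out_dir=None) -> dict:
    """Full pipeline: simulate, ascertain, classify, standardize, compare.

    Returns a dict of result tables; when ``out_dir`` is given, every table
    is written as CSV next to a manifest recording the configuration.
    """
    if seed is not None:
        config = config.model_copy(update={"rng_seed": seed})

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate failing stage
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    bundle, events, registry = _stage("simulate", simulate_bundle, config)
    years = config.analysis_years
    code_lists = CodeLists()

    staged, denoms = _stage(
        "claims_pipeline", claims_pipeline, bundle, years, code_lists
    )
    claims_rates = _stage("claims_rates", claims_rate_table, staged, denoms, years=years)

    classified = _stage("registry_classify", classify_records, registry)
    classified = classified[classified["diagnosis_year"].isin(years)].reset_index(
        drop=True
    )
    class_tables = _stage("registry_tabulate", tabulate_classes, classified)
    pop_denoms = _stage(
        "population_denominators", population_denominators, bundle.persons, years
    )
    registry_rates = {}
    for scenario in SCENARIOS:
        relabelled = apply_scenario(classified, scenario)
        registry_rates[scenario] = _stage(
            f"registry_rates[{scenario}]",
            registry_rate_table,
            relabelled,
            pop_denoms,
            years=years,
        )

    comparison = _stage(
        "comparison", build_comparison, claims_rates, registry_rates["as_observed"]
    )
    trends = {
        "claims": trend_summary(claims_rates),
        "registry": trend_summary(registry_rates["as_observed"]),
    }
    sensitivity = _stage(
        "window_sensitivity", window_sensitivity, bundle, years, denoms, code_lists
    )
    evidence = _stage("inpatient_evidence", inpatient_evidence_summary, staged, bundle)
    crosscheck = (
        _stage(
            "medication_crosscheck",
            medication_crosscheck,
            staged,
            bundle.dispensations,
            code_lists,
        )
        if len(staged)
        else None
    )

    results = {
        "config": config,
        "bundle": bundle,
        "events": events,
        "registry": registry,
        "staged_cases": staged,
        "claims_denominators": denoms,
        "claims_rates": claims_rates,
        "registry_classified": classified,
        "registry_class_tables": class_tables,
        "registry_rates": registry_rates,
        "comparison": comparison,
        "trends": trends,
        "window_sensitivity": sensitivity,
        "inpatient_evidence": evidence,
        "medication_crosscheck": crosscheck,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        advio.write_bundle(bundle, out / "bundle")
        advio.write_table(events, out / "true_events.csv")
        advio.write_table(registry, out / "registry.csv")
        advio.write_table(staged, out / "staged_cases.csv")
        advio.write_table(denoms, out / "claims_denominators.csv")
        advio.write_table(claims_rates, out / "claims_rates.csv")
        advio.write_table(class_tables, out / "registry_class_tables.csv")
        for scenario, table in registry_rates.items():
            advio.write_table(table, out / f"registry_rates_{scenario}.csv")
        advio.write_table(comparison, out / "comparison.csv")
        advio.write_table(trends["claims"], out / "trend_claims.csv")
        advio.write_table(trends["registry"], out / "trend_registry.csv")
        advio.write_table(sensitivity, out / "window_sensitivity.csv")
        summaries = {
            "inpatient_evidence": evidence,
            "medication_crosscheck": crosscheck,
        }
        (out / "summaries.json").write_text(json.dumps(summaries, indent=2))
        advio.write_manifest(config, out / "manifest.yaml")

    return results
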