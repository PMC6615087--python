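"""Unit behaviour of the claims-cohort algorithm on hand-written fixtures:
denominator continuity boundaries, entry/confirmation/washout rules, staging
windows, inpatient-evidence summary, and the medication cross-check."""

import datetime as dt

import pandas as pd
import pytest

from advcrc import (
    CodeLists,
    crosscheck_percentage,
    eligible_persons,
    identify_incident_cases,
    inpatient_evidence_summary,
    medication_crosscheck,
    stage_cases,
)

from conftest import inpd, make_bundle, outp


def _eligible_count(persons, spells, year, **kw):
    return eligible_persons(persons, spells, year, **kw)["person_count"].sum()


class TestEligibility:
    def test_full_coverage_every_year(self):
        b = make_bundle()
        for year in range(2008, 2016):
            assert _eligible_count(b.persons, b.spells, year) == 1

    def test_16_day_gap_breaks_continuity(self):
        b = make_bundle(
            spells=[
                {"person_id": "A", "start_date": "2004-01-01", "end_date": "2010-06-01"},
                {"person_id": "A", "start_date": "2010-06-18", "end_date": "2015-12-31"},
            ]
        )
        assert _eligible_count(b.persons, b.spells, 2010) == 0
        assert _eligible_count(b.persons, b.spells, 2013) == 0
        # the gap falls out of the 4-year look-back window eventually
        assert _eligible_count(b.persons, b.spells, 2014) == 1
        assert _eligible_count(b.persons, b.spells, 2015) == 1

    def test_15_day_gap_is_tolerated(self):
        b = make_bundle(
            spells=[
                {"person_id": "A", "start_date": "2004-01-01", "end_date": "2010-06-01"},
                {"person_id": "A", "start_date": "2010-06-17", "end_date": "2015-12-31"},
            ]
        )
        for year in range(2008, 2016):
            assert _eligible_count(b.persons, b.spells, year) == 1

    def test_minimum_age(self):
        b = make_bundle(persons=[{"person_id": "A", "birth_year": 2006}])
        assert _eligible_count(b.persons, b.spells, 2010) == 0  # age 4
        assert _eligible_count(b.persons, b.spells, 2011) == 1  # age 5

    def test_overlapping_spells_raise(self):
        b = make_bundle(
            spells=[
                {"person_id": "A", "start_date": "2004-01-01", "end_date": "2010-06-01"},
                {"person_id": "A", "start_date": "2010-05-01", "end_date": "2015-12-31"},
            ]
        )
        with pytest.raises(ValueError, match="overlapping"):
            eligible_persons(b.persons, b.spells, 2010)


class TestIncidentAscertainment:
    def test_single_code_is_not_a_case(self):
        b = make_bundle(outpatient=[outp("A", 2014, 2)])
        assert identify_incident_cases(b, 2014).empty

    def test_confirmation_two_quarters_later_outer_boundary(self):
        b = make_bundle(
            outpatient=[outp("A", 2014, 2, "C20"), outp("A", 2014, 4, "C18.2")]
        )
        cases = identify_incident_cases(b, 2014)
        assert len(cases) == 1
        row = cases.iloc[0]
        assert row["entry_quarter"] == 2
        assert row["cohort_entry_date"] == pd.Timestamp("2014-04-01")

    def test_confirmation_three_quarters_later_fails(self):
        b = make_bundle(
            outpatient=[outp("A", 2014, 1, "C20"), outp("A", 2014, 4, "C18.2")]
        )
        assert identify_incident_cases(b, 2014).empty

    def test_status_post_in_washout_excludes(self):
        b = make_bundle(
            outpatient=[
                outp("A", 2011, 3, "C18.9", "status_post"),
                outp("A", 2014, 2, "C20"),
                outp("A", 2014, 3, "C18.2"),
            ]
        )
        assert identify_incident_cases(b, 2014).empty

    def test_old_code_outside_washout_window_is_ignored(self):
        # entry 2014-04-01; 4-year washout reaches back to ~2010-04; a code in
        # 2009 Q1 lies outside and must not mark the case prevalent
        b = make_bundle(
            outpatient=[
                outp("A", 2009, 1, "C18.9", "status_post"),
                outp("A", 2014, 2, "C20"),
                outp("A", 2014, 3, "C18.2"),
            ]
        )
        assert len(identify_incident_cases(b, 2014)) == 1

    def test_suspected_codes_never_qualify(self):
        b = make_bundle(
            outpatient=[
                outp("A", 2014, 2, "C18.2", "suspected"),
                outp("A", 2014, 3, "C18.2", "suspected"),
            ]
        )
        assert identify_incident_cases(b, 2014).empty

    def test_admission_diagnoses_never_qualify(self):
        b = make_bundle(
            inpatient=[
                inpd("A", "2014-05-10", position="admission"),
                inpd("A", "2014-06-10", position="admission"),
            ]
        )
        assert identify_incident_cases(b, 2014).empty

    def test_inpatient_entry_uses_exact_date(self):
        b = make_bundle(
            inpatient=[inpd("A", "2014-05-10", "C18.4", "main")],
            outpatient=[outp("A", 2014, 2)],
        )
        cases = identify_incident_cases(b, 2014)
        assert len(cases) == 1
        assert cases.iloc[0]["cohort_entry_date"] == pd.Timestamp("2014-05-10")

    def test_year_outside_coverage_warns_and_returns_empty(self):
        b = make_bundle(outpatient=[outp("A", 2014, 2), outp("A", 2014, 3)])
        with pytest.warns(UserWarning, match="outside data coverage"):
            assert identify_incident_cases(b, 2030).empty

    def test_case_requires_continuity_through_lookback(self):
        # insured only from 2013: less than 4 years before a 2014 entry
        b = make_bundle(
            spells=[
                {"person_id": "A", "start_date": "2013-01-01", "end_date": "2015-12-31"}
            ],
            outpatient=[outp("A", 2014, 2), outp("A", 2014, 3)],
        )
        assert identify_incident_cases(b, 2014).empty

    def test_age_at_entry_mid_year_convention(self):
        b = make_bundle(
            persons=[{"person_id": "A", "birth_year": 1950}],
            outpatient=[outp("A", 2014, 1), outp("A", 2014, 2)],
        )
        # entry 2014-01-01 is before July 1 -> 63, not 64
        assert identify_incident_cases(b, 2014).iloc[0]["age_at_entry"] == 63


def _case_bundle(extra_out=(), extra_inp=()):
    return make_bundle(
        outpatient=[outp("A", 2014, 2, "C20"), outp("A", 2014, 3, "C18.2")]
        + list(extra_out),
        inpatient=list(extra_inp),
    )


class TestStaging:
    def _staged(self, bundle, window=1):
        cases = identify_incident_cases(bundle, 2014)
        return stage_cases(cases, bundle, n_following_quarters=window)

    def test_c77_and_c79_in_window_give_iv(self):
        b = _case_bundle(
            extra_out=[outp("A", 2014, 2, "C77.0"), outp("A", 2014, 3, "C79.5")]
        )
        assert self._staged(b).iloc[0]["stage"] == "IV"

    def test_window_length_changes_stage(self):
        # distant code two quarters after entry: missed by the default
        # 3-6-month window, caught by the extended one
        b = _case_bundle(extra_out=[outp("A", 2014, 4, "C79.5")])
        assert self._staged(b, window=1).iloc[0]["stage"] == "non_advanced"
        assert self._staged(b, window=2).iloc[0]["stage"] == "IV"

    def test_no_stage_codes_give_non_advanced(self):
        assert self._staged(_case_bundle()).iloc[0]["stage"] == "non_advanced"

    def test_c77_only_gives_iii(self):
        b = _case_bundle(extra_inp=[inpd("A", "2014-05-02", "C77.9", "secondary")])
        assert self._staged(b).iloc[0]["stage"] == "III"

    def test_suspected_and_admission_stage_codes_ignored(self):
        b = _case_bundle(
            extra_out=[outp("A", 2014, 2, "C78.0", "suspected")],
            extra_inp=[inpd("A", "2014-05-02", "C79.5", "admission")],
        )
        assert self._staged(b).iloc[0]["stage"] == "non_advanced"

    def test_invalid_window_rejected(self):
        b = _case_bundle()
        cases = identify_incident_cases(b, 2014)
        with pytest.raises(ValueError, match="n_following_quarters"):
            stage_cases(cases, b, n_following_quarters=3)


class TestInpatientEvidence:
    def test_saturated_inpatient_evidence(self):
        b = _case_bundle(extra_inp=[inpd("A", "2014-05-02", "C78.7", "main")])
        staged = stage_cases(identify_incident_cases(b, 2014), b)
        res = inpatient_evidence_summary(staged, b)
        assert res["prop_IV_with_inpatient_code"] == 1.0
        assert res["prop_remaining_with_2plus_outpatient"] is None

    def test_outpatient_only_case(self):
        b = _case_bundle(
            extra_out=[outp("A", 2014, 2, "C79.5"), outp("A", 2014, 3, "C79.9")]
        )
        staged = stage_cases(identify_incident_cases(b, 2014), b)
        res = inpatient_evidence_summary(staged, b)
        assert res["prop_IV_with_inpatient_code"] == 0.0
        assert res["prop_remaining_with_2plus_outpatient"] == 1.0

    def test_no_iv_cases_not_available(self):
        b = _case_bundle()
        staged = stage_cases(identify_incident_cases(b, 2014), b)
        res = inpatient_evidence_summary(staged, b)
        assert res["prop_IV_with_inpatient_code"] is None

    def test_inpatient_emission_probability_recovered(self):
        from advcrc import SimConfig, claims_pipeline, simulate_bundle
        import numpy as np

        p = 0.85
        cfg = SimConfig.perfect_coding(
            n_persons=20_000,
            rng_seed=21,
            p_inpatient_metastasis_code=p,
            incidence_per_100k={"non_advanced": 0, "III": 0, "IV": 400},
            age_pattern=(0.0,) + (1.0,) * 17,
        )
        bundle, _, _ = simulate_bundle(cfg)
        staged, _ = claims_pipeline(bundle, cfg.analysis_years)
        res = inpatient_evidence_summary(staged, bundle)
        n = res["n_iv"]
        assert n > 300
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(res["prop_IV_with_inpatient_code"] - p) < 3 * sd


class TestMedicationCrosscheck:
    def test_toy_subsample_arithmetic(self):
        assert crosscheck_percentage(10, 4, 4) == 40.0
        assert crosscheck_percentage(10, 4, 4, denominator="non_advanced") == 100.0

    def test_no_dispensations_null_case(self):
        b = _case_bundle()
        staged = stage_cases(identify_incident_cases(b, 2014), b)
        res = medication_crosscheck(staged, b.dispensations)
        assert res["n_flagged"] == 0
        assert res["pct_of_subsample"] == 0.0

    def test_flagging_respects_window(self):
        b = make_bundle(
            outpatient=[outp("A", 2014, 2, "C20"), outp("A", 2014, 3, "C18.2")],
            dispensations=[("A", "2014-05-01", "L01XC07")],
        )
        staged = stage_cases(identify_incident_cases(b, 2014), b)
        assert medication_crosscheck(staged, b.dispensations)["n_flagged"] == 1
        # same dispensation outside a narrow window
        assert (
            medication_crosscheck(staged, b.dispensations, window_days=10)["n_flagged"]
            == 0
        )

    def test_empty_subsample_is_an_error(self):
        b = _case_bundle()
        staged = stage_cases(identify_incident_cases(b, 2014), b).iloc[0:0]
        with pytest.raises(ValueError, match="empty"):
            medication_crosscheck(staged, b.dispensations)


def test_disjoint_code_lists_enforced():
    with pytest.raises(ValueError, match="disjoint"):
        CodeLists(crc_codes=frozenset({"C18", "C77"}))


def test_washout_soundness_on_simulated_cohort(sim_default):
    """No ascertained case carries any confirmed/status-post CRC code in the
    4-year look-back before its entry (re-scan of the raw tables)."""
    cfg, bundle, events, registry = sim_default
    out = bundle.outpatient
    crc_out = out[
        out["icd_code"].str.startswith(("C18", "C19", "C20"))
        & out["certainty"].isin(["confirmed", "status_post"])
    ]
    cases = identify_incident_cases(bundle, 2012)
    for row in cases.itertuples(index=False):
        entry = row.cohort_entry_date.date()
        wstart = entry - dt.timedelta(days=1461)
        q0 = row.entry_year * 4 + row.entry_quarter - 1
        mine = crc_out[crc_out["person_id"] == row.person_id]
        qidx = mine["year"] * 4 + mine["quarter"] - 1
        in_washout = (qidx < q0) & (qidx >= wstart.year * 4 + (wstart.month - 1) // 3)
        assert not in_washout.any()


def test_cases_are_counted_in_their_denominator_stratum(sim_default):
    from advcrc.rates import age_band

    cfg, bundle, events, registry = sim_default
    year = 2012
    cases = identify_incident_cases(bundle, year)
    denoms = eligible_persons(bundle.persons, bundle.spells, year)
    birth = bundle.persons.set_index("person_id")["birth_year"]
    n_cases = (
        cases.assign(age_band=lambda d: age_band(year - birth.loc[d["person_id"]].to_numpy()))
        .groupby(["sex", "age_band"])
        .size()
    )
    denom_map = denoms.set_index(["sex", "age_band"])["person_count"]
    for (sex, band), n in n_cases.items():
        assert denom_map.loc[(sex, band)] >= n
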