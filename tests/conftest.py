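import pandas as pd
import pytest

from advcrc.synthetic import ClaimsBundle

PERSON_DEFAULTS = {"person_id": "A", "sex": "male", "birth_year": 1950}


def make_bundle(
    persons=None, spells=None, outpatient=(), inpatient=(), dispensations=()
) -> ClaimsBundle:
    """Build a tiny hand-written bundle; sensible defaults for one person
    insured 2004-2015."""
    if persons is None:
        persons = [dict(PERSON_DEFAULTS)]
    persons = pd.DataFrame([{**PERSON_DEFAULTS, **p} for p in persons])
    if spells is None:
        spells = [
            {"person_id": pid, "start_date": "2004-01-01", "end_date": "2015-12-31"}
            for pid in persons["person_id"]
        ]
    spells = pd.DataFrame(spells)
    spells["start_date"] = pd.to_datetime(spells["start_date"])
    spells["end_date"] = pd.to_datetime(spells["end_date"])

    out = pd.DataFrame(
        list(outpatient),
        columns=["person_id", "year", "quarter", "icd_code", "certainty"],
    )
    inp = pd.DataFrame(
        list(inpatient), columns=["person_id", "date", "icd_code", "position"]
    )
    inp["date"] = pd.to_datetime(inp["date"])
    disp = pd.DataFrame(
        list(dispensations), columns=["person_id", "date", "agent_code"]
    )
    disp["date"] = pd.to_datetime(disp["date"])
    return ClaimsBundle(
        persons=persons,
        spells=spells,
        outpatient=out,
        inpatient=inp,
        dispensations=disp,
    )


def outp(pid, year, quarter, code="C18.2", certainty="confirmed"):
    return (pid, year, quarter, code, certainty)


def inpd(pid, date, code="C18.2", position="main"):
    return (pid, date, code, position)


@pytest.fixture(scope="session")
def sim_default():
    """A moderately sized simulated dataset under default parameters."""
    from advcrc import SimConfig, simulate_bundle

    cfg = SimConfig(n_persons=10_000, rng_seed=123)
    bundle, events, registry = simulate_bundle(cfg)
    return cfg, bundle, events, registry
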