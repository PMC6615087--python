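"""CSV persistence for the claims/registry tables (ISO-8601 dates) and the
run manifest recording the simulation configuration."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .config import SimConfig
from .synthetic import ClaimsBundle

__all__ = [
    "write_table",
    "write_bundle",
    "read_bundle",
    "write_manifest",
    "read_manifest",
]

_DATE_COLS = {"start_date", "end_date", "date", "cohort_entry_date", "diagnosis_date"}


def write_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in _DATE_COLS & set(out.columns):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in _DATE_COLS & set(df.columns):
        df[col] = pd.to_datetime(df[col])
    return df


def write_bundle(bundle: ClaimsBundle, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in bundle.table_names():
        write_table(getattr(bundle, name), directory / f"{name}.csv")


def read_bundle(directory) -> ClaimsBundle:
    directory = Path(directory)
    tables = {
        name: read_table(directory / f"{name}.csv")
        for name in ("persons", "spells", "outpatient", "inpatient", "dispensations")
    }
    return ClaimsBundle(**tables)


def write_manifest(config: SimConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"sim_config": config.model_dump(mode="json")}, fh, sort_keys=False
        )


def read_manifest(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return SimConfig(**raw["sim_config"])
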