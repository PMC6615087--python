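"""Simulation configuration.

:class:`SimConfig` holds every parameter of the synthetic claims / registry
generator: population size and demography, annual stage-specific colorectal
cancer (CRC) incidence, claims coding behaviour (initial, confirmatory,
follow-up, and metastasis codes with quarter lags), insurance-gap structure,
and the cancer-registry reporting mechanisms (pathologist-only notifications,
premature M0, independent N/M missingness).

The defaults describe a statutory-health-insurance-like population observed
2004-2015 with analyses starting after a four-year preobservation period.
Stage-specific reference incidences are chosen to resemble German CRC rates
(advanced disease around 20 per 100,000 person-years, distant metastases
making up the larger share); coding probabilities are illustrative, since no
published sensitivity/specificity exists for these codes in German claims.
"""

from __future__ import annotations

from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = ["SimConfig", "STAGES", "Stage"]

Stage = Literal["non_advanced", "III", "IV"]
STAGES: tuple[str, ...] = ("non_advanced", "III", "IV")

#: Default relative incidence by five-year age band (0-4 ... 85+), shaped like
#: the steep age gradient of colorectal cancer. The reference band (multiplier
#: 1.0) is 55-59.
DEFAULT_AGE_PATTERN: tuple[float, ...] = (
    0.0, 0.0, 0.0, 0.01, 0.02, 0.04, 0.07, 0.12, 0.2, 0.35,
    0.6, 1.0, 1.6, 2.4, 3.4, 4.5, 5.5, 6.0,
)

class SimConfig(BaseModel):
    """All knobs of the synthetic cohort generator (seed mandatory)."""

    model_config = {"extra": "forbid"}

    # population
    n_persons: int = Field(default=100_000, gt=0)
    first_year: int = 2004
    last_year: int = 2015
    preobservation_years: int = Field(default=4, ge=0)
    female_fraction: float = Field(default=0.52, ge=0.0, le=1.0)
    # attained age in first_year; may be negative so that cohorts born after
    # the data start keep the youngest age bands populated in later years
    min_age: int = 5
    max_age: int = Field(default=90, ge=0)

    # disease process: reference rate per 100,000 person-years (female, band
    # 55-59); actual rates scale by age_pattern and male_to_female_ratio
    incidence_per_100k: dict[str, float] = Field(
        default_factory=lambda: {"non_advanced": 38.0, "III": 9.0, "IV": 21.0}
    )
    age_pattern: tuple[float, ...] = DEFAULT_AGE_PATTERN
    male_to_female_ratio: float = Field(default=1.4, gt=0.0)
    prevalent_fraction: float = Field(default=0.15, ge=0.0, le=1.0)

    # claims coding of the primary tumour (C18-C20)
    p_outpatient_initial: float = Field(default=0.6, ge=0.0, le=1.0)
    p_confirmation_code: float = Field(default=0.95, ge=0.0, le=1.0)
    confirmation_lag_probs: tuple[float, float, float] = (0.6, 0.3, 0.1)
    p_inpatient_confirmation: float = Field(default=0.3, ge=0.0, le=1.0)
    p_followup_code: float = Field(default=0.6, ge=0.0, le=1.0)  # per later quarter

    # claims coding of nodal involvement / distant metastases (C77 / C78-C79)
    p_c77_emission: float = Field(default=0.9, ge=0.0, le=1.0)      # true stage III
    c77_lag_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)
    p_c77_given_iv: float = Field(default=0.5, ge=0.0, le=1.0)      # nodes also coded in IV
    p_distant_emission: float = Field(default=0.95, ge=0.0, le=1.0)  # true stage IV
    distant_lag_probs: tuple[float, float, float] = (0.6, 0.3, 0.1)
    p_inpatient_metastasis_code: float = Field(default=0.87, ge=0.0, le=1.0)
    p_second_outpatient_distant: float = Field(default=0.67, ge=0.0, le=1.0)

    # advanced-line systemic therapy for true stage IV
    p_advanced_therapy: float = Field(default=0.6, ge=0.0, le=1.0)
    therapy_delay_max_days: int = Field(default=90, ge=0)

    # nuisance structure
    noise_codes_per_person_year: float = Field(default=0.2, ge=0.0)
    p_gap: float = Field(default=0.1, ge=0.0, le=1.0)
    gap_days_min: int = Field(default=1, ge=1)
    gap_days_max: int = Field(default=60, ge=1)

    # cancer-registry reporting mechanisms
    reporting_completeness: float = Field(default=0.95, ge=0.0, le=1.0)
    p_pathologist_only: float = Field(default=0.25, ge=0.0, le=1.0)
    p_premature_m0: float = Field(default=0.2, ge=0.0, le=1.0)
    p_n_missing: float = Field(default=0.05, ge=0.0, le=1.0)
    p_m_missing: float = Field(default=0.05, ge=0.0, le=1.0)
    p_n_plus_given_iv: float = Field(default=0.75, ge=0.0, le=1.0)

    rng_seed: int = Field(ge=0, lt=2**31)

    @field_validator("incidence_per_100k")
    @classmethod
    def _check_incidence(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(STAGES)
        if unknown:
            raise ValueError(f"incidence_per_100k: unknown stages {sorted(unknown)}")
        missing = set(STAGES) - set(v)
        if missing:
            raise ValueError(f"incidence_per_100k: missing stages {sorted(missing)}")
        for stage, rate in v.items():
            if rate < 0:
                raise ValueError(f"incidence_per_100k[{stage}] must be >= 0, got {rate}")
        return v

    @field_validator("age_pattern")
    @classmethod
    def _check_age_pattern(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if len(v) != 18:
            raise ValueError(f"age_pattern must have 18 entries, got {len(v)}")
        if any(x < 0 for x in v):
            raise ValueError("age_pattern entries must be >= 0")
        return v

    @field_validator("confirmation_lag_probs", "c77_lag_probs", "distant_lag_probs")
    @classmethod
    def _check_lag_probs(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(p < 0 for p in v):
            raise ValueError("lag probabilities must be >= 0")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"lag probabilities must sum to 1, got {sum(v)}")
        return v

    @model_validator(mode="after")
    def _check_ranges(self) -> "SimConfig":
        if self.first_year > self.last_year:
            raise ValueError("first_year must not exceed last_year")
        if self.min_age > self.max_age:
            raise ValueError("min_age must not exceed max_age")
        if self.min_age < self.first_year - self.last_year:
            raise ValueError("min_age implies birth years beyond last_year")
        if self.gap_days_min > self.gap_days_max:
            raise ValueError("gap_days_min must not exceed gap_days_max")
        return self

    # -- derived windows -------------------------------------------------

    @property
    def first_analysis_year(self) -> int:
        """First year with a full preobservation period behind it."""
        return min(self.first_year + self.preobservation_years, self.last_year)

    @property
    def analysis_years(self) -> list[int]:
        return list(range(self.first_analysis_year, self.last_year + 1))

    @property
    def data_years(self) -> list[int]:
        return list(range(self.first_year, self.last_year + 1))

    # -- convenience constructors ----------------------------------------

    @classmethod
    def perfect_coding(cls, **overrides) -> "SimConfig":
        """A noise-free configuration under which the claims algorithm and the
        registry both recover every incident case exactly.

        Every diagnosis is confirmed in its entry quarter, metastasis and
        nodal codes carry no quarter lag, prevalent tumours keep emitting
        follow-up codes (so the washout always sees them), insurance has no
        gaps, the registry reports everyone faithfully, and no registry
        missingness mechanism is active.
        """
        base = dict(
            p_outpatient_initial=0.6,
            p_confirmation_code=1.0,
            confirmation_lag_probs=(1.0, 0.0, 0.0),
            p_inpatient_confirmation=0.0,
            p_followup_code=1.0,
            p_c77_emission=1.0,
            c77_lag_probs=(1.0, 0.0, 0.0),
            p_c77_given_iv=0.0,
            p_distant_emission=1.0,
            distant_lag_probs=(1.0, 0.0, 0.0),
            p_inpatient_metastasis_code=1.0,
            p_second_outpatient_distant=0.0,
            p_advanced_therapy=1.0,
            noise_codes_per_person_year=0.0,
            p_gap=0.0,
            reporting_completeness=1.0,
            p_pathologist_only=0.0,
            p_premature_m0=0.0,
            p_n_missing=0.0,
            p_m_missing=0.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
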