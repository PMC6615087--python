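n_persons: 100000
first_year: 2004
last_year: 2015
preobservation_years: 4
female_fraction: 0.52
min_age: 5
max_age: 90
incidence_per_100k:
  non_advanced: 38.0
  III: 9.0
  IV: 21.0
age_pattern:
- 0.0
- 0.0
- 0.0
- 0.01
- 0.02
- 0.04
- 0.07
- 0.12
- 0.2
- 0.35
- 0.6
- 1.0
- 1.6
- 2.4
- 3.4
- 4.5
- 5.5
- 6.0
male_to_female_ratio: 1.4
prevalent_fraction: 0.15
p_outpatient_initial: 0.6
p_confirmation_code: 0.95
confirmation_lag_probs:
- 0.6
- 0.3
- 0.1
p_inpatient_confirmation: 0.3
p_followup_code: 0.6
p_c77_emission: 0.9
c77_lag_probs:
- 0.7
- 0.2
- 0.1
p_c77_given_iv: 0.5
p_distant_emission: 0.95
distant_lag_probs:
- 0.6
- 0.3
- 0.1
p_inpatient_metastasis_code: 0.87
p_second_outpatient_distant: 0.67
p_advanced_therapy: 0.6
therapy_delay_max_days: 90
noise_codes_per_person_year: 0.2
p_gap: 0.1
gap_days_min: 1
gap_days_max: 60
reporting_completeness: 0.95
p_pathologist_only: 0.25
p_premature_m0: 0.2
p_n_missing: 0.05
p_m_missing: 0.05
p_n_plus_given_iv: 0.75
rng_seed: 12345
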