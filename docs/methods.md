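# Methods

`advcrc` estimates age-standardized incidence rates (ASIRs) of advanced
colorectal cancer (CRC) from two kinds of sources — longitudinal
health-insurance claims and cancer-registry TNM records — and compares them.
Because real German claims (GePaRD-like) and registry (ZfKD-like) data are
access-restricted, the package ships a synthetic-data generator with known
ground truth; every stage of the analysis is exercised against that truth.

## Claims-based case ascertainment

German claims carry outpatient diagnoses only at (year, quarter) resolution,
with a mandatory certainty qualifier (confirmed / suspected / status post /
excluded), and inpatient discharge diagnoses with exact dates and a
main / secondary / admission position. The algorithm, per index year:

1. **Cohort entry** is the first CRC code (ICD-10 C18–C20) of the year.
   Outpatient codes qualify only when coded "confirmed"; inpatient codes only
   in main or secondary position (admission diagnoses are never used).
2. **Confirmation**: a second qualifying CRC code record must appear in the
   entry quarter or the two following quarters. The entry record itself does
   not self-confirm; each table row is one record, and identical duplicate
   rows are deliberately not collapsed (a repeat coding *is* the
   confirmation signal in quarter-granular claims).
3. **Washout**: any CRC code coded "confirmed" or "status post" (outpatient)
   or any main/secondary inpatient CRC code during the four-year
   preobservation window before entry marks the tumour prevalent and drops
   the person.
4. **Continuity and age**: continuous insurance (no single interruption of
   more than 15 days) from four years before entry through December 31 of
   the index year, and age ≥ 5 years.
5. **Staging**: within the entry quarter plus a configurable number of
   following quarters (default 1, sensitivity 0 and 2), any qualifying
   C78–C79 code (distant metastases) assigns UICC IV; otherwise any C77 code
   (lymph-node involvement) assigns UICC III; otherwise the case is
   non-advanced. Qualifying stage codes are main/secondary inpatient or
   confirmed outpatient records. The three labels form an exhaustive,
   mutually exclusive partition, and the stage-IV case set can only grow
   with the window.

### Date conventions

* A look-back of *k* years is `round(k * 365.25)` days (1461 for the default
  four years), ending the day before cohort entry.
* An outpatient entry is dated to the first day of its quarter; if an
  inpatient CRC code falls in the same quarter its exact (earliest) date is
  used. Ties on the same day resolve inpatient-main > inpatient-secondary >
  outpatient, then lexicographically by code.
* A quarter-granular outpatient code counts as inside the washout window
  when its quarter lies **strictly before the entry quarter** and overlaps
  the window. Requiring mere overlap with the look-back interval would let a
  case's own entry-quarter confirmation codes mark it prevalent whenever the
  entry date falls mid-quarter, contradicting the confirmation rule; the
  strict form is the only self-consistent reading.
* Continuity is checked over the union window [entry − 1461 d, Dec 31].
  This implies both the four-year pre-entry look-back and the denominator's
  own continuity condition, which guarantees numerator ⊆ denominator.
* `age_at_entry` uses a mid-year (July 1) birthday convention, the standard
  choice when claims carry only a birth year. Age **banding** for rates,
  however, uses attained age (calendar year − birth year) for cases and
  denominators alike, so that each case sits in exactly the denominator
  stratum it is counted against; banding entries by mid-year age would let a
  first-half-year case fall one band below its December-31 denominator band.

### Denominators

A person counts in year *Y* when continuously insured (gap ≤ 15 days) from
four years before December 31 of *Y* through that date, and aged ≥ 5. The
December-31 reference date is a fixed convention chosen for reproducibility.

## Registry TNM classification

Registry records carry an N status (N0 / N+ / missing) and an M status
(M0 / M1 / missing); missingness is always explicit ("MX" and absent values
both map to missing upstream of the classifier, which stays a pure function
of the recorded values). T is ignored: the advanced / non-advanced
distinction rests on nodes and metastases only.

| N        | M       | class                    |
|----------|---------|--------------------------|
| any      | M1      | advanced_IV              |
| N+       | M0      | advanced_III             |
| N+       | missing | advanced_unstratifiable  |
| N0       | M0      | non_advanced             |
| N0       | missing | not_classifiable         |
| missing  | M0/missing | not_classifiable      |

Both partially observed negative patterns — (N0, M missing) and
(N missing, M0) — are assigned not_classifiable rather than guessed finer.

Missing-data scenarios re-label classified records: `as_observed` (identity),
`drop_nonclassifiable` (removes exactly the not-classifiable records,
denominators untouched), `nonclassifiable_as_nonadvanced`, and the extreme
`unstratifiable_as_IV`. Re-labelling conserves record counts except for the
drop scenario; advanced totals are invariant under `unstratifiable_as_IV`.

## Direct age standardization

With case counts c_b and person denominators n_b over the 18 canonical
five-year bands (0–4, …, 80–84, 85+) and the old (1976) European Standard
Population weights w = (8000, 7000 ×10, 6000, 5000, 4000, 3000, 2000, 1000,
1000) per 100,000:

    ASIR = 100000 · Σ_b w_b (c_b / n_b) / Σ_b w_b

A band with neither cases nor denominator contributes zero; cases without a
denominator raise an error. Uniform band rates r return exactly r, and a
denominator proportional to the standard makes the ASIR equal the crude
rate. Rates are kept at full precision internally and displayed to one
decimal; percent declines, 100·(1 − last/first), are rounded half away from
zero to integer percent.

## The synthetic generator

The generator emulates exactly the features the algorithms are sensitive to:

* **Population**: `n_persons` (default 100,000) with a configurable female
  fraction (0.52) and attained ages uniform on [`min_age`, `max_age`]
  (default 5–90) at the data start (2004); insurance covers 2004–2015 with
  one interior interruption (probability 0.1, length 1–60 days). `min_age`
  may be negative, which simply means cohorts born after the data start —
  used where every age band must stay populated across the analysis years.
* **Disease**: at most one CRC per person, drawn per person-year over the
  analysis years (2008–2015) from stage-specific reference rates per
  100,000 (defaults 38 / 9 / 21 for non-advanced / III / IV at the 55–59
  reference band, male-to-female ratio 1.4) scaled by a CRC-like age
  gradient. Prevalent disease is added on top: extra events among event-free
  persons, dated uniformly into 2004–2007 and sized so the configured
  fraction (0.15) of all events is prevalent — the incident process keeps
  its configured rate. There is no secular trend and no mortality; spells
  simply end.
* **Coding**: an initial C18–C20 code (outpatient confirmed with
  probability 0.6, else inpatient main, on the exact date); a confirmatory
  code with probability 0.95 at a quarter lag of 0/1/2 (0.6/0.3/0.1);
  quarterly follow-up codes (0.6 per quarter, confirmed or status-post) that
  keep prevalent tumours visible to the washout; for stage III a C77 code
  (0.9, lags 0.7/0.2/0.1); for stage IV a C78–C79 code (0.95, lags
  0.6/0.3/0.1) that is an inpatient discharge diagnosis with probability
  0.87 — calibrated to the observed share of stage-IV cases with inpatient
  metastasis evidence — plus optional second outpatient metastasis codes
  (0.67), nodal codes (0.5) and a bevacizumab-class dispensation (0.6,
  ≤ 90 days after diagnosis). Background non-cancer codes arrive at 0.2 per
  person-year. No published sensitivity or specificity exists for these
  codes in German claims, so the coding probabilities are illustrative
  choices of plausible magnitude, not calibrated values.
* **Registry**: each event is reported with probability 0.95. A faithful
  record carries (N0, M0), (N+, M0) or (N+/N0, M1) according to the true
  stage (N+ with probability 0.75 in stage IV). Degradation, in order:
  pathologist-only reporting (0.25) blanks both statuses; premature
  reporting (0.2) records a true-IV tumour as M0 with N kept correct —
  exactly the mechanism that moves distant-metastasis disease into the
  registry's stage-III column; independent N and M missingness (0.05 each)
  applies last. The defaults put the not-classifiable share near the
  30–35 % range reported for German registry data.

Everything flows from one mandatory seed (independent substreams per stage),
so identical configurations give byte-identical CSV output.

### What passing tests do and do not show

The generator reproduces the *structural* features of claims and registry
data (quarter granularity, certainty flags, washout-relevant follow-up
coding, stage-dependent metastasis coding, TNM missingness mechanisms). It
does not model mortality, multiple primaries, secular incidence trends,
geographic or insurer heterogeneity, or realistic code-level noise
(miscoded CRC in cancer-free persons). Recovery results on synthetic data
therefore validate the pipeline's logic and arithmetic, not the clinical
accuracy of any particular code list on real data.

## Verification design

* **Oracle equivalence**: an independent, rule-literal per-person
  interpreter (plain loops, day-level coverage bitmaps) is kept in the test
  suite and must agree exactly with the vectorized pipeline on dozens of
  randomized 200-person populations with aggressive gap, lag and
  missingness settings.
* **Exact recovery**: under a perfect-coding configuration (confirmation
  probability 1, zero lags, no gaps, follow-up coding 1, faithful registry)
  the ascertained case set equals the true non-prevalent event set, with
  true stages, and claims-based and registry-based ASIRs coincide exactly.
* **Rate recovery**: with a flat advanced-CRC incidence of 20 per 100,000,
  all 18 bands populated in every analysis year (negative `min_age`) and
  the pediatric exclusion lifted (`min_age=0` in the pipeline call, so the
  0–4 band can carry its flat rate), the pooled claims ASIR is unbiased for
  20 and is checked within 3 Poisson standard errors at 100,000 persons.
  Without those two provisions the target is structurally unattainable:
  bands with zero denominator contribute zero rate, not the flat rate.
* **Mechanism direction**: with premature-M0 probability 0.3 and
  pathologist-only probability 0.1 on an otherwise perfect simulation
  (60,000 persons, 2008–2011), the registry's stage-IV ASIR falls below and
  its stage-III ASIR rises above the claims values in every year.
* Sampling-distribution checks (gap fractions, event counts, quarter-lag
  frequencies, missingness shares) use closed-form binomial / Poisson /
  multinomial 3-standard-deviation bands.

Problem sizes in the test suite and acceptance script (200-person fixtures;
50,000–100,000-person experiments; 4–8 analysis years) were chosen so the
statistical checks have comfortable margins while a full run stays in the
minutes range on one CPU.

## Known limitations

* C77–C79 codes carry no link to the primary tumour; in patients with
  multiple cancers the algorithm may stage a CRC with another tumour's
  metastases. Multiple primaries are out of scope here.
* Affected distant lymph nodes are indistinguishable from regional ones in
  ICD-10 coding and are treated as regional (stage III), as in the source
  algorithms.
* The medication cross-check reports its percentage against the full CRC
  subsample by default (`denominator="subsample"`); the non-advanced-only
  denominator is available behind a flag, since either convention is
  defensible.
* Staging-window sensitivity varies only the staging scan; cohort entry is
  never re-derived per window.
* No confidence intervals are attached to ASIRs, and the new (2013) ESP is
  not bundled — alternative weights can be passed explicitly.
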