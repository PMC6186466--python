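# Methods

## Model

The package implements a prevalence-based cost-of-illness model for stroke:
all costs attributable to cases treated during one calendar year, split into
direct and indirect components and reported per subtype (ischemic, I63;
hemorrhagic, I61) and for all stroke.

The unit of analysis is a claim line: one outpatient visit or one inpatient
admission episode, carrying the patient's subtype, gender, 10-year age band,
facility type, inpatient days, and the covered and medication amounts in
KRW. Patient-level quantities (cohort counts, assistive-device costs,
per-case denominators) are derived by deduplicating on the opaque patient
id; visit-level quantities (disposition and facility tallies,
transportation) count claim lines. A patient appearing with both subtypes is
permitted and counts once in each subtype's patient tally.

Cost components:

| component | formula | unit inputs |
| --- | --- | --- |
| inpatient / outpatient | Σ covered_cost by disposition | claims only |
| non-covered | r_in · covered_in + r_out · covered_out | ratios (from an out-of-pocket survey, not claims) |
| medication | Σ medication_cost | claims only |
| assistive devices | cpi(base, 2010→ref) · patients | 241 512 KRW/yr at 2010 prices |
| transportation | fare · outpatient visit-claims | 21 000 KRW round trip |
| caregiver | cpi(rate, base→ref) · inpatient days | daily rate at its base year |
| morbidity loss | Σ_a (days_a + f·visits_a) · (income_a / divisor) · emp_a | f = 1/3 day per visit, divisor 365 |
| mortality loss | Σ_a deaths_a · lostyears_a · income_a · emp_a | separate vital-statistics table |

Income is zero for every age band entirely below `working_age_min` (20) or
at/above `retirement_age` (70). "No income between 1 and 19" is implemented
as no income below 20 — taking the wording literally would leave age 0 with
income, which cannot be meant.

CPI adjustment uses the index-ratio convention, amount ·
CPI[to]/CPI[from], which is equivalent to chaining annual inflation rates
when the index is consistent and is easier to validate (identity at equal
years, exact inverse on the round trip).

### Premature-death loss: two conventions

`mortality_loss(mode="product")` (default) is the plain four-factor
multiplication above — the convention the reference analysis states. It
knowingly prices *all* lost years at the income of the age band at death,
including years that extend past retirement.

`mode="present_value"` is the standard human-capital refinement: a
year-by-year earnings stream starting at the band midpoint age (5, 15, …,
75; 85 for 80+), using the income and employment of whichever band each
future year falls in, truncated at retirement, with a fractional final year
and discounting by `discount_rate` (default 0). At zero discount, with lost
years that stay inside one band and below retirement, the two modes
coincide exactly — a tested equivalence. Which convention the original
analysis used is not recoverable from its published tables; both are
provided and neither is asserted as "the" published one.

Per-case cost is (grand total − premature-death loss) / patients, in
million KRW to one decimal: deaths are not treatment cases, so their loss
is excluded from the numerator while the denominator counts treated
patients.

## Rounding and the published-table tolerances

All internal arithmetic is unrounded KRW; rounding (half-up, via `Decimal`,
matching how the published cells print) happens only at render time. The
published 2015 tables were rounded cell by cell to the million *before*
being summed, so their printed subtotals disagree with their own cells by a
few million (e.g. 57 387 + 8 924 = 66 311 vs a printed 66 312). When the
package reconstructs a subtotal from k printed cells, the reconstruction is
therefore checked within 0.5·k million KRW — the exact worst case of
per-cell rounding, fixed a priori, not an empirical fit. Component-row
shares recomputed from the ledger agree with the printed shares within 0.01
percentage points. Two printed cells are internally inconsistent with their
own ledger and are checked against the ledger-implied values instead: the
hemorrhagic per-case cost (printed 18.5; the ledger implies 18.3) and the
cohort table's gender percents (transposed relative to the counts; the
arithmetic, 277 641/515 848 = 53.82 % male, is followed). The published
"4.5 times higher" for death loss vs work loss (the ledger implies 4.24) is
likewise not reproduced.

The all-stroke column of the breakdown is always the elementwise sum of the
two subtype columns, never an independent aggregate, so the ledger
invariants (direct_medical = its five rows, grand = direct + indirect,
all = ischemic + hemorrhagic) hold exactly at full precision on every run.

## Synthetic cohort generator

The generator emulates the structure of the non-public 2015 national claims
extract. Defaults **are** the 2015 study conditions and are not tuning
knobs:

- **Category mixes** — subtype, gender, age band, facility probabilities
  equal the published cohort counts divided by their column totals.
- **Claim volumes** — every patient draws outpatient visits from a
  zero-truncated Poisson (ischemic mean 5.90, hemorrhagic 8.06 per year —
  the visit-claim counts implied by dividing the published transportation
  rows by the 21 000 KRW fare); a patient is hospitalized with probability
  0.2511 (admissions per patient in the published disposition counts) and
  then draws inpatient days from a zero-truncated negative binomial
  (dispersion 1.2; means 31.7 / 86.9 days per admission, implied by the
  caregiver rows at the default daily rate).
- **Costs** — gamma per claim line (shape 1.5), with subtype-specific means
  chosen so each covered and medication component matches its published row
  in expectation.
- **Deaths** — Poisson counts per (subtype, band), independent of the claim
  stream (the mortality input is a separate vital-statistics source).
  Working-age death counts were derived once by inverting the published
  premature-death rows against the default income/employment/lost-years
  tables; 70+ counts reflect the old-age skew of stroke mortality and carry
  no income. Lost years per band come from the 2015 Korean complete life
  table at band midpoints.

Reproducibility: a single `numpy.random.default_rng(seed)` stream consumed
in a fixed order (patient attributes → visit counts → inpatient days →
inpatient-claim facilities/costs → outpatient-claim facilities/costs →
deaths). The insertion order is part of the contract; identical config and
seed give byte-identical CSVs. Episodes never span a year boundary.

### What the generator does not emulate

- The published cohort table counts 472 371 outpatient "visits", while its
  own transportation row implies ≈3.16 million outpatient visit-claims;
  these cannot both hold. The generator follows the claim-level volumes
  (they drive every cost), so its disposition/facility *shares* do not
  reproduce the published visit-level shares; calibration checks cover
  subtype/gender/age only.
- The published work-loss (morbidity) rows are not recoverable from the
  stated 1/3-day rule plus public 2015 income and employment statistics —
  the income tables actually used were never published. The package
  computes morbidity loss from its stated rule; under the default
  parameters the simulated morbidity component is accordingly smaller than
  the published row, and the simulated cost structure shifts a few points
  toward direct costs. Passing tests demonstrate the arithmetic and the
  calibrated direct-cost/death-loss structure, not a reconstruction of the
  unpublished income tables.
- No readmission correlation, within-year progression, secondary
  diagnoses, or long-term-care insurance costs; no diagnosis codes beyond
  the two subtypes.

## Default economic parameters

| parameter | default | basis |
| --- | --- | --- |
| round_trip_fare | 21 000 KRW/visit | published unit cost |
| assistive_device_annual_base | 241 512 KRW/yr @2010 | published unit cost |
| caregiver_daily_rate_base | 60 000 KRW/day @2010 (shipped set; required field otherwise) | 2010 hospital-caregiver model-project range; no printed value exists |
| noncovered ratios | 0.17617 both dispositions | implied by the published ledger: 354 489/(1 898 241+114 285) |
| cpi_index | {2010: 100.0, 2015: 109.8} | official index; the assistive row implies ≈109.3, a 0.5 % gap left as is |
| annual_income / employment_rate | rounded 2015 national labour statistics per band | public statistics |
| outpatient_day_fraction | 1/3 | stated rule |
| daily_wage_divisor | 365 | calendar-day convention; configurable (e.g. 250 working days) |
| working ages | [20, 70) | stated rule |
| discount_rate | 0 | keeps product and present-value modes consistent |
| krw_per_usd | 1090.14 | implied by the published KRW/USD total pair |

## Problem sizes and numerical choices

The test suite exercises cohorts of 200–10 000 patients (the 10 000-patient
cohort backs the 3-standard-error calibration checks); the acceptance
script simulates 20 000 patients (~128 000 claim lines, a few seconds) —
per-patient structure, shares and per-case costs are scale-free, so larger
cohorts only shrink Monte-Carlo noise. Zero-truncated draws use inverse-CDF
sampling on (P(0), 1], keeping them vectorised and reproducible. Costs are
rounded to whole KRW at generation (real claim amounts are integers).
Degenerate inputs are defined, not special-cased: empty claims give zero
components and a summary with percents omitted; an all-zero ledger column
has undefined (None) shares; a zero ratio or zero employment gives exact
zeros.

## Known limitations

Morbidity loss uses whole-population employment rates, not stroke-specific
ones; lost years are not adjusted for disability level; the model is
annual, not lifetime; only claims-listed service users are covered. These
mirror the scope of the reference analysis. The non-covered ratios are
parameters, not estimated from microdata, and the single stroke-level
default slightly redistributes the non-covered component between subtypes
relative to the published (survey-based) split.
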