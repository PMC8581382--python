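# Methods

This note documents the procedures the package implements, the defaults
it ships, the design choices that were genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Ascertainment model

Coded events from two linked sources are matched, exactly and
case-sensitively, against a user-supplied code list. Dementia codes carry
a specificity tier: *high-specificity* codes (e.g. "unspecified
dementia") indicate a diagnosis on their own; *low-specificity* codes
(e.g. "delirium superimposed on dementia") only do so in combination.
The criteria, applied per source inside the study window
(2007-01-01 … 2019-05-31, inclusive at both ends):

- primary care (Read/SNOMED CT): ≥ 1 high-specificity code, **or** two
  *different* low-specificity codes — interpreted as two distinct
  (terminology, code) pairs on any dates, same-day allowed;
- specialist (ICD-10): ≥ 1 dementia code from the mental and
  behavioural chapter (F00–F03).

The combined first date is the minimum of the per-source first dates and
anchors every downstream window ("index date"). Eligibility requires age
at the combined first date ≥ 65, where age is the calendar-year
difference from year of birth (primary-care extracts supply year of
birth only, so mid-year refinements are not attempted).

Open choices, resolved as follows:

- **"Two different codes"** is read as code-distinctness, not
  occasion-distinctness: the same low-specificity code recorded twice
  never qualifies. Case counts of distinct codes per patient in such
  data (median around two) make the code-distinct reading natural.
- **First primary-care date** defaults to the earliest dementia-domain
  code of any tier, even when the qualifying second low-specificity code
  came later; the alternative ("date criteria first satisfied") is the
  `first_date_rule="criteria_met"` switch. Both are implemented and
  tested against a brute-force oracle.
- The age gate is applied to the **combined** first date, not per-source
  dates.
- A low+high pair qualifies through the high code alone; exact duplicate
  event rows are dropped before counting (they cannot create eligibility
  under code-distinctness anyway).

Restrictions for sensitivity analyses: borough residence; ≥ 1
face-to-face or telephone primary-care consultation in the 2 years up to
and including the index date; first documentation on or before
2015-12-31.

## Covariates

All lookbacks anchor at the index date. Boundary conventions (both
config-exposed): consultation counting uses the half-open window
`(index − 2y, index]` — a consultation on the index date plausibly *is*
the diagnostic encounter — while comorbidity and smoking codes must fall
*strictly before* the index date, since they describe the pre-diagnosis
state.

- **Consultations**: face-to-face + telephone count over 2 years;
  categories none / average-or-less / above-average relative to the
  cohort median (lower median for even n). The median is recomputed from
  the data by default; `median_override` pins it (23 in replication
  runs) so thresholds match a fixed reference.
- **Care home**: any care-home-flagged consultation within a 2-year
  lookback (default) or at any time prior (`unlimited`); the two
  published definitions conflict, so both exist and reports record which
  was used. The comparison table uses the unlimited variant.
- **Modified Charlson index**: Quan weights summed over *distinct*
  conditions (repeat codes count once), dementia itself structurally
  excluded at code-list validation; "high" means a score of 4+.
- **Smoking**: former if any former-smoker code, or if both current- and
  never-smoker documentation exist; else current beats never; no codes →
  missing.
- **Ethnicity**: the 16-class coding condensed to White British
  (reference), White non-British, Black, Asian, Mixed, Other.
- **Deprivation**: IMD quintile 1 via a user-supplied LSOA→quintile
  lookup.
- **Subtype**: most recent specialist ICD-10 diagnosis where one exists
  (unspecified stays unspecified); otherwise the most frequent
  subtype-specific primary-care code, ties broken by most recent tagged
  code then fixed tag order (logged); no subtype-specific codes →
  unspecified.
- **Medication**: AChEI or memantine prescription within
  `[index, min(index + 4y, 2019-05-31)]`. The comparison row restricts
  both denominators to members whose index date leaves a full 4-year
  window before the censor date — the published restricted denominators
  are not defined explicitly, and this is the package's
  operationalisation.
- **Mortality**: death within the same censored 4-year window; death
  before the index date is a fatal data-quality error.

## Statistics

Wilson score intervals for proportions and Katz log-method intervals for
prevalence ratios, both without continuity correction and with computed
(not hard-coded) normal quantiles. "Binomial method" descriptions of
ratio CIs are ambiguous; the Katz method is adopted because it
reproduces all nine published comparison intervals to two decimals from
the printed numerators and denominators (asserted in tests). The two
compared cohorts overlap (they share the both-sources stratum) but are
treated as independent for CI purposes, as the published intervals
imply. Chi-squared tests are Pearson tests on the non-missing table.
Display rounding is half-away-from-zero, to the nearest percentage point
except below 10% (one decimal); internal values are never rounded.
Missing categories are tabulated explicitly and excluded from percentage
denominators. The stratified tables flag a non-reference cell with `+`/`-`
when its Wilson CI excludes the both-sources stratum point estimate; the
original annotations are not defined anywhere, so this operationalisation
is stated in the report footer. No multiple-testing adjustment is applied
(the comparisons are pre-specified).

## Synthetic-data generator

A single scalar frailty latent `f ~ N(0,1)` per patient drives
everything that must co-vary: presence of each Charlson condition
(per-condition logistic), negative-binomial consultation counts,
care-home residence, 4-year mortality, and — crucially — *differential
documentation*: `P(primary doc | f) = σ(a_p + b_p f)` with `b_p > 0` and
`P(specialist doc | f) = σ(a_s + b_s f)` with `b_s < 0`, independent
given `f`. This is the simplest mechanism that makes the specialist
cohort systematically less frail than the primary-care cohort; richer
causal structure is deliberately out of scope.

**Calibration.** Defaults are solved at config-construction time
(64-node Gauss–Hermite quadrature + Newton root finding, deterministic,
~10 ms): documentation intercepts are chosen so the expected union
composition is 3,859 primary : 4,266 specialist : 2,886 both per 5,239
(hence expected overlap 55.09%); each covariate's (baseline, slope) pair
is chosen to hit its published marginal prevalence and
specialist:primary prevalence ratio — care home 0.73, high comorbidity
0.87, high consultation 0.91, mortality 0.98, medication 0.85 — and the
probability that primary-care coding is subtype-specific is solved from
the Alzheimer's ratio (≈1.04). With slopes `±0.35` this system is
exactly identified. `expected_summaries` recomputes all expectations
from any config, so parameter-recovery tests compare simulation against
closed forms, not against hard-coded numbers.

Other defaults: 20,000 patients per cohort; case probability 5.4% (the
published share of over-65s with documented dementia); years of birth
uniform on 1918–1950; index dates uniform in the window; 75% of
primary-documented cases qualify via a high-specificity code, the rest
via two distinct low-specificity codes; subtype distribution
(60.4% Alzheimer's/mixed among the specialist sample, remainder split
vascular/other/unspecified); missingness 14.2% ethnicity, 12.4% smoking,
2.1% LSOA; medication probability logistic in primary documentation and
Alzheimer's subtype, so medication recipients are almost always coded in
primary care; a 10% rate of unlisted filler codes exercises the
silent-ignore path.

**What the generator does *not* emulate**: realistic coding sequences or
free text, terminology-version churn, seasonality, migration in and out
of the catchment, correlated missingness, false-positive dementia codes,
and any ethnicity/sex/age association with frailty or documentation
(their expected prevalence ratios are exactly 1). Passing
parameter-recovery tests therefore shows that the pipeline measures what
the generative model encodes — not that the published real-data tables
would be reproduced, which is impossible without the original extracts.

## Problem sizes and numerics

The parameter-recovery study uses 20 cohorts of 20,000 patients
(~1,000 documented cases each), comparing the mean measured overlap and
each prevalence ratio against the analytic expectation within three
Monte-Carlo standard errors; it completes in well under a minute.
Interval-coverage checks use 10,000 simulated binomials at n = 100, and
chi-squared size checks 5,000 null 2×2 tables at n = 500. The
brute-force phenotyping oracle (verbatim subset enumeration of the
criteria) is compared with the vectorised engine on 1,000 random
micro-cohorts of up to 8 patients with boundary dates, duplicates and
unlisted codes.

Degenerate inputs: empty event tables yield empty cohorts; events with
unknown patient ids are dropped with a warning; patients with missing
year of birth are excluded with a warning; a zero reference numerator
makes a prevalence ratio undefined (error), and a zero first numerator
yields a 0 point estimate with a substitution upper bound flagged
approximate; zero chi-squared marginals are fatal with the offending
row/column named.

## Known limitations

- Exact string matching only; no SNOMED hierarchy expansion and no
  Read→SNOMED mapping — both terminologies must appear as rows of the
  input list.
- Free-text (NLP) ascertainment and general-hospital sources are out of
  scope.
- The synthetic calibration targets published *marginals and ratios*;
  joint distributions beyond the frailty mechanism are not matched.
- IMD quintiles are taken from a lookup file; deriving them from raw
  rank data is out of scope.
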