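# ehrlink

Dual-source electronic-health-record (EHR) case ascertainment and
concordance analysis for dementia, with a calibrated synthetic linked-EHR
generator.

## The problem

Database studies of dementia usually ascertain cases from a single source
— either primary-care coded records (Read/SNOMED CT) or a specialist
mental-health provider's records (ICD-10 diagnoses). Neither source is
complete, and the *kind* of patient each source misses differs: frail,
complex patients tend to be coded in primary care but never referred,
while relatively fit patients may carry only a specialist diagnosis. This
package implements, as a tested and reusable pipeline, the analysis that
quantifies this: specificity-tiered code-list phenotyping of two linked
sources, derivation of the standard covariates (modified Charlson
comorbidity index with Quan weights, consultation rates, care-home
residence, smoking, condensed ethnicity, deprivation, dementia subtype,
medication, mortality), concordance tables stratified by documentation
group, and prevalence-ratio comparison of the two overlapping cohorts.

It is written for epidemiologists working with linked primary-care /
specialist extracts, and for methodologists studying ascertainment bias.
Because real extracts of this kind cannot be shared, a first-class
synthetic-data module generates linked cohorts with known ground truth
and analytically calibrated expectations, so every pipeline stage is
testable end to end.

## The methods at the core

**Phenotyping rule.** A patient is a documented case in primary care if,
inside the study window (2007-01-01 to 2019-05-31), they have one code
from the *high-specificity* dementia list, or two *different* codes from
the *low-specificity* list. One ICD-10 dementia code (F00–F03) suffices
in the specialist source. The index date is the earliest dementia code
across both sources, and eligibility requires age ≥ 65 at that date.

**Statistics.** Proportions get Wilson score intervals

$$\tilde p \pm \frac{z}{1+z^2/n}\sqrt{\hat p(1-\hat p)/n + z^2/4n^2},
\qquad \tilde p = \frac{x + z^2/2}{n + z^2},$$

and ratios of proportions between the two overlapping cohorts get Katz
log-method intervals

$$\exp\!\Big(\ln \mathrm{PR} \pm z\sqrt{\tfrac{1-p_1}{x_1} + \tfrac{1-p_2}{x_2}}\Big).$$

Stratified tables are compared with Pearson chi-squared tests (no
continuity correction).

**Synthetic generator.** A scalar frailty latent `f ~ N(0,1)` jointly
drives comorbidity, consultations, care-home residence, mortality, and
*differential documentation* (logistic documentation models with
opposite-signed frailty slopes for the two sources). Default parameters
are solved by quadrature so the expected union composition and the
expected specialist:primary prevalence ratios match the published
reference values; `expected_summaries` returns the closed-form
expectations for parameter-recovery checks.

## Worked example

```python
from ehrlink import overlap_from_counts, prevalence_ratio, wilson_ci, format_percent
from ehrlink.synthetic import default_config, generate
from ehrlink.replication import measure_bundle

ov = overlap_from_counts(n_both=2886, n_specialist_only=1380, n_primary_only=973)
print(f"union {ov.n_union}; both {format_percent(ov.n_both / ov.n_union)}; "
      f"primary also specialist {format_percent(ov.n_both / ov.n_primary)}; "
      f"specialist also primary {format_percent(ov.n_both / ov.n_specialist)}")
pr = prevalence_ratio(270, 4266, 334, 3859)   # care-home residence
print(f"care home PR {pr.pr:.2f} (95% CI {pr.lo:.2f}-{pr.hi:.2f})")
ci = wilson_ci(2886, 5239)
print(f"both-sources share {ci.p:.4f} (95% CI {ci.lo:.4f}-{ci.hi:.4f})")

cfg = default_config(seed=42, n_patients=20_000)
m = measure_bundle(generate(cfg))
print(f"synthetic cohort union {m['n_union']}; overlap {m['overlap_pct']:.1f}%; "
      f"care home PR {m['pr_care_home']:.2f}")
```

prints

```
union 5239; both 55%; primary also specialist 75%; specialist also primary 68%
care home PR 0.73 (95% CI 0.63-0.85)
both-sources share 0.5509 (95% CI 0.5374-0.5643)
synthetic cohort union 930; overlap 55.1%; care home PR 0.76
```

The first three lines are worked-example arithmetic on published counts:
of 5,239 documented cases, 55% were found by both sources, and people
ascertained through the specialist database are markedly less likely to
live in a care home than those ascertained through primary-care codes
(PR 0.73). The last line runs the *whole pipeline* — phenotyping,
covariates, comparison — on one synthetic 20,000-patient cohort; the
measured overlap (55.1%) sits on the generator's analytic expectation
(55.09%) and the care-home PR fluctuates around its calibrated 0.73
within Monte-Carlo noise.

A CLI wraps the same functionality:

```sh
ehrlink synth --out data/ --seed 1 --n-patients 20000
ehrlink run --config config.yaml --out reports/
```

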