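"""Synthetic linked two-source EHR cohorts with known ground truth.

Real extracts behind this kind of concordance study cannot be shared, so
the generator emits the four pipeline input tables (patients, coded
events, consultations, prescriptions) plus a ground-truth table, with the
statistical structure the analysis assumes:

* a scalar latent **frailty** ``f ~ N(0, 1)`` per patient jointly drives
  comorbidity, consultation rate, care-home residence, mortality and
  *differential documentation*: higher frailty raises the probability of
  primary-care dementia documentation and lowers the probability of
  specialist documentation (logistic models with opposite-signed slopes);
* true dementia cases get dementia codes in each source per the
  documentation model — primary-care cases via one high-specificity code
  or two distinct low-specificity codes, specialist cases via ICD-10;
* medication recipients are (by construction) almost always documented
  in primary care.

Default parameters are **calibrated analytically** (Gauss–Hermite
quadrature over the frailty latent + root finding) so that the expected
documented-union composition matches the published marginals
(primary 3,859 : specialist 4,266 : both 2,886 per 5,239) and the
expected specialist:primary prevalence ratios match the published values
for care home (0.73), high comorbidity (0.87), high consultation (0.91),
mortality (0.98), medication (0.85) and Alzheimer's subtype (~1.04).
:func:`expected_summaries` returns those closed-form expectations so
simulation output can be checked against them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import nbinom as nbinom_dist

from .codelib import (
    CodeEntry,
    CodeList,
    Domain,
    DrugClass,
    SmokingTag,
    Specificity,
    SubtypeTag,
    Terminology,
    build_codelist,
)

# published marginal composition of the documented union, used as the
# default calibration target (counts per 5,239)
UNION_N = 5239
PRIMARY_N = 3859
SPECIALIST_N = 4266
BOTH_N = 2886

_CAL_TARGETS = {
    "care_home": (0.0723, 0.73),       # (marginal among union, specialist:primary PR)
    "charlson_high": (0.1174, 0.87),
    "consult_high": (0.5129, 0.91),
    "mortality": (0.2636, 0.98),
    "medication": (0.2872, 0.85),
}
_ALZ_SPEC_FRACTION = 2577 / 4266       # Alzheimer's/mixed share of the specialist cohort
_ALZ_PR = (2577 / 4266) / (2249 / 3859)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _gh_nodes(n: int = 64):
    """Gauss–Hermite nodes/weights rescaled for a standard normal latent."""
    x, w = np.polynomial.hermite_e.hermegauss(n)
    return x, w / w.sum()


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

CHARLSON_CONDITIONS = [
    # (condition, Quan weight, baseline prevalence)
    ("congestive_heart_failure", 2, 0.10),
    ("copd", 1, 0.15),
    ("rheumatic_disease", 1, 0.04),
    ("mild_liver_disease", 2, 0.02),
    ("hemiplegia", 2, 0.03),
    ("renal_disease", 1, 0.10),
    ("cancer", 2, 0.12),
    ("severe_liver_disease", 4, 0.005),
    ("metastatic_cancer", 6, 0.02),
    ("aids_hiv", 4, 0.002),
    ("diabetes_complicated", 1, 0.08),
]

ETHNICITY16_WEIGHTS = {
    "White British": 0.44,
    "White Irish": 0.04,
    "Any other White background": 0.13,
    "Black Caribbean": 0.14,
    "Black African": 0.10,
    "Any other Black background": 0.03,
    "Indian": 0.02,
    "Pakistani": 0.01,
    "Bangladeshi": 0.01,
    "Any other Asian background": 0.02,
    "White and Black Caribbean": 0.01,
    "White and Black African": 0.01,
    "White and Asian": 0.005,
    "Any other mixed background": 0.015,
    "Chinese": 0.005,
    "Any other ethnic group": 0.015,
}


@dataclass
class GeneratorConfig:
    """All tunable parameters of the synthetic-cohort generator."""

    n_patients: int = 20_000
    seed: int = 0
    # demographics
    yob_min: int = 1918
    yob_max: int = 1950
    p_female: float = 0.60
    p_dementia: float = 0.054
    # documentation model: P(doc | frailty f) = sigmoid(intercept + slope * f)
    doc_primary_intercept: float = 0.9
    doc_primary_slope: float = 0.35
    doc_specialist_intercept: float = 1.2
    doc_specialist_slope: float = -0.35
    p_primary_high_path: float = 0.75   # share documented via a high-specificity code
    # subtype
    p_subtype: tuple = (0.604, 0.25, 0.046, 0.10)  # ALZ, VASC, OTHER, UNSPEC
    p_subtype_coded_primary: float = 0.86
    # care home
    care_home_intercept: float = -2.9
    care_home_slope: float = 0.6
    # comorbidity (per-condition baseline logit shift + common frailty slope)
    charlson_shift: float = 0.0
    charlson_slope: float = 0.4
    # consultations: count ~ NegBin(mean = exp(c0 + c1 f), size r)
    consult_intercept: float = 3.1
    consult_slope: float = 0.3
    consult_dispersion: float = 4.0
    consult_threshold: int = 23
    # mortality within 4-year follow-up
    mortality_intercept: float = -1.05
    mortality_slope: float = 0.05
    # medication: P = sigmoid(g0 + g1 * primary_documented + g2 * alzheimers)
    medication_intercept: float = -3.0
    medication_primary_effect: float = 1.8
    medication_alz_effect: float = 0.8
    # missingness and noise
    p_missing_ethnicity: float = 0.142
    p_missing_smoking: float = 0.124
    p_missing_lsoa: float = 0.021
    smoking_dist: tuple = (0.37, 0.46, 0.17)  # never, former, current (when recorded)
    noise_code_rate: float = 0.10
    # window
    window_start: date = date(2007, 1, 1)
    window_end: date = date(2019, 5, 31)
    censor_date: date = date(2019, 5, 31)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        probs = [
            self.p_female, self.p_dementia, self.p_primary_high_path,
            self.p_subtype_coded_primary, self.p_missing_ethnicity,
            self.p_missing_smoking, self.p_missing_lsoa, self.noise_code_rate,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.p_subtype) - 1.0) > 1e-9:
            raise ValueError("subtype probabilities must sum to 1")
        if self.p_dementia > 0:
            x, w = _gh_nodes()
            pp = _sigmoid(self.doc_primary_intercept + self.doc_primary_slope * x)
            ps = _sigmoid(self.doc_specialist_intercept + self.doc_specialist_slope * x)
            if float(w @ (pp + ps - pp * ps)) < 1e-12:
                raise ValueError(
                    "infeasible: zero documentation probability with p_dementia > 0"
                )


@dataclass
class SyntheticCohortBundle:
    patients: pd.DataFrame
    events: pd.DataFrame
    consultations: pd.DataFrame
    prescriptions: pd.DataFrame
    ground_truth: pd.DataFrame
    imd_lookup: pd.DataFrame
    codelist: CodeList
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# synthetic code list (illustrative, exercises every enum value)
# ---------------------------------------------------------------------------

def synthetic_codelist() -> CodeList:
    """Small illustrative code list used by the generator and the fixtures."""
    E = CodeEntry
    T, S, ST, SM, DC = Terminology, Specificity, SubtypeTag, SmokingTag, DrugClass
    entries = [
        # dementia, primary care, high specificity (subtype-tagged)
        E(T.READ, "Eu00.", "Alzheimer's disease dementia", Domain.DEMENTIA, S.HIGH, ST.ALZHEIMERS_MIXED),
        E(T.READ, "Eu01.", "Vascular dementia", Domain.DEMENTIA, S.HIGH, ST.VASCULAR),
        E(T.READ, "Eu02z", "Other specified dementia", Domain.DEMENTIA, S.HIGH, ST.OTHER_SPECIFIED),
        E(T.READ, "E00..", "Senile dementia, unspecified", Domain.DEMENTIA, S.HIGH, ST.UNSPECIFIED),
        E(T.SNOMED, "26929004", "Alzheimer's disease", Domain.DEMENTIA, S.HIGH, ST.ALZHEIMERS_MIXED),
        E(T.SNOMED, "429998004", "Vascular dementia", Domain.DEMENTIA, S.HIGH, ST.VASCULAR),
        E(T.SNOMED, "52448006", "Dementia", Domain.DEMENTIA, S.HIGH, ST.UNSPECIFIED),
        # dementia, primary care, low specificity
        E(T.READ, "Eu041", "Delirium superimposed on dementia", Domain.DEMENTIA, S.LOW),
        E(T.READ, "1B1A.", "Memory loss symptom", Domain.DEMENTIA, S.LOW),
        E(T.SNOMED, "386805003", "Mild memory disturbance", Domain.DEMENTIA, S.LOW),
        E(T.SNOMED, "248603002", "Cognitive decline", Domain.DEMENTIA, S.LOW),
        # dementia, specialist ICD-10 (F00-F03)
        E(T.ICD10, "F00", "Dementia in Alzheimer's disease", Domain.DEMENTIA, S.HIGH, ST.ALZHEIMERS_MIXED),
        E(T.ICD10, "F00.2", "Alzheimer's dementia, mixed type", Domain.DEMENTIA, S.HIGH, ST.ALZHEIMERS_MIXED),
        E(T.ICD10, "F01", "Vascular dementia", Domain.DEMENTIA, S.HIGH, ST.VASCULAR),
        E(T.ICD10, "F02", "Dementia in other diseases", Domain.DEMENTIA, S.HIGH, ST.OTHER_SPECIFIED),
        E(T.ICD10, "F03", "Unspecified dementia", Domain.DEMENTIA, S.HIGH, ST.UNSPECIFIED),
    ]
    # comorbidity codes, one Read + one SNOMED per condition
    for i, (cond, weight, _) in enumerate(CHARLSON_CONDITIONS):
        entries.append(
            E(T.READ, f"Q{i:02d}..", cond.replace("_", " "), Domain.COMORBIDITY,
              condition=cond, weight=weight)
        )
        entries.append(
            E(T.SNOMED, f"90{i:02d}0001", cond.replace("_", " "), Domain.COMORBIDITY,
              condition=cond, weight=weight)
        )
    entries += [
        E(T.READ, "137R.", "Current smoker", Domain.SMOKING, smoking_tag=SM.CURRENT),
        E(T.READ, "137S.", "Ex-smoker", Domain.SMOKING, smoking_tag=SM.FORMER),
        E(T.READ, "1372.", "Never smoked tobacco", Domain.SMOKING, smoking_tag=SM.NEVER),
        E(T.SNOMED, "77176002", "Smoker", Domain.SMOKING, smoking_tag=SM.CURRENT),
        E(T.SNOMED, "401201003", "Cholinesterase inhibitor therapy", Domain.MEDICATION, drug_class=DC.ACHEI),
        E(T.SNOMED, "407745005", "Memantine therapy", Domain.MEDICATION, drug_class=DC.MEMANTINE),
        E(T.READ, "9S1..", "Ethnicity: White British", Domain.ETHNICITY),
        E(T.READ, "9S2..", "Ethnicity: Black Caribbean", Domain.ETHNICITY),
    ]
    return build_codelist(entries, name="synthetic-illustrative", version="1")


_HIGH_BY_SUBTYPE = {
    0: [("READ", "Eu00."), ("SNOMED", "26929004")],        # ALZHEIMERS_MIXED
    1: [("READ", "Eu01."), ("SNOMED", "429998004")],       # VASCULAR
    2: [("READ", "Eu02z")],                                # OTHER_SPECIFIED
    3: [("READ", "E00.."), ("SNOMED", "52448006")],        # UNSPECIFIED
}
_LOW_CODES = [("READ", "Eu041"), ("READ", "1B1A."), ("SNOMED", "386805003"), ("SNOMED", "248603002")]
_ICD_BY_SUBTYPE = {0: "F00", 1: "F01", 2: "F02", 3: "F03"}
_SUBTYPE_NAMES = ["ALZHEIMERS_MIXED", "VASCULAR", "OTHER_SPECIFIED", "UNSPECIFIED"]


# ---------------------------------------------------------------------------
# analytic expectations and calibration
# ---------------------------------------------------------------------------

def _charlson_high_prob(cfg: GeneratorConfig, f: np.ndarray) -> np.ndarray:
    """P(modified Charlson >= 4 | frailty) by exact DP over conditions."""
    state = np.zeros((5, f.size))
    state[0] = 1.0
    for cond, weight, base in CHARLSON_CONDITIONS:
        logit = np.log(base / (1 - base)) + cfg.charlson_shift
        p = _sigmoid(logit + cfg.charlson_slope * f)
        new = np.zeros_like(state)
        for s in range(5):
            ns = min(4, s + weight)
            new[s] += state[s] * (1.0 - p)
            new[ns] += state[s] * p
        state = new
    return state[4]


def _consult_high_prob(cfg: GeneratorConfig, f: np.ndarray) -> np.ndarray:
    mu = np.exp(cfg.consult_intercept + cfg.consult_slope * f)
    r = cfg.consult_dispersion
    return nbnom_sf(cfg.consult_threshold - 1, r, r / (r + mu))


def nbnom_sf(k, r, p):
    return nbinom_dist.sf(k, r, p)


def _medication_bars(cfg: GeneratorConfig) -> tuple[float, float]:
    """Mean medication probability given primary documentation status."""
    pi = np.asarray(cfg.p_subtype)
    alz = np.array([1.0, 0.0, 0.0, 0.0])
    m1 = float(pi @ _sigmoid(cfg.medication_intercept + cfg.medication_primary_effect + cfg.medication_alz_effect * alz))
    m0 = float(pi @ _sigmoid(cfg.medication_intercept + cfg.medication_alz_effect * alz))
    return m1, m0


def expected_summaries(cfg: GeneratorConfig, n_nodes: int = 64) -> dict:
    """Closed-form (quadrature) expectations implied by a generator config.

    Returns the expected overlap composition of the documented union and
    the expected specialist:primary prevalence ratio for each compared
    characteristic, integrating over the frailty latent.
    """
    f, w = _gh_nodes(n_nodes)
    pp = _sigmoid(cfg.doc_primary_intercept + cfg.doc_primary_slope * f)
    ps = _sigmoid(cfg.doc_specialist_intercept + cfg.doc_specialist_slope * f)
    both = pp * ps
    union = pp + ps - both
    E = lambda g: float(w @ g)  # noqa: E731

    e_un, e_pp, e_ps, e_both = E(union), E(pp), E(ps), E(both)
    out = {
        "overlap_pct": 100.0 * e_both / e_un,
        "pct_primary_of_union": 100.0 * e_pp / e_un,
        "pct_specialist_of_union": 100.0 * e_ps / e_un,
        "union_rate": e_un,
    }

    def pr_and_marginal(x):
        spec = E(x * ps) / e_ps
        prim = E(x * pp) / e_pp
        marg = E(x * union) / e_un
        return spec / prim, marg

    for name, x in [
        ("care_home", _sigmoid(cfg.care_home_intercept + cfg.care_home_slope * f)),
        ("charlson_high", _charlson_high_prob(cfg, f)),
        ("consult_high", _consult_high_prob(cfg, f)),
        ("mortality", _sigmoid(cfg.mortality_intercept + cfg.mortality_slope * f)),
    ]:
        pr, marg = pr_and_marginal(x)
        out[f"pr_{name}"] = pr
        out[f"marginal_{name}"] = marg

    m1, m0 = _medication_bars(cfg)
    med_spec = E(ps * (pp * m1 + (1 - pp) * m0)) / e_ps
    med_prim = m1
    out["pr_medication"] = med_spec / med_prim
    out["marginal_medication"] = E(pp * m1 + (1 - pp) * ps * m0) / e_un

    # Alzheimer's/mixed among the full cohort denominators: specialist-
    # documented members resolve to the true subtype; primary-only members
    # resolve only when subtype-specific codes were used.
    pi_alz = cfg.p_subtype[0]
    q = cfg.p_subtype_coded_primary
    w_both = e_both / e_pp
    out["pr_alzheimers"] = 1.0 / (w_both + q * (1.0 - w_both))
    out["marginal_alzheimers"] = pi_alz * (
        e_both + E(ps * (1 - pp)) + q * E(pp * (1 - ps))
    ) / e_un
    out["spec_alzheimers"] = pi_alz
    return out


def calibrate_default_config(seed: int = 0, n_patients: int = 20_000) -> GeneratorConfig:
    """Solve the default parameters against the published calibration targets.

    Documentation intercepts are solved so that the expected union
    composition is 3,859 : 4,266 : 2,886 per 5,239; each covariate's
    (baseline, frailty-slope) pair is solved to hit its published
    marginal prevalence and specialist:primary prevalence ratio.
    Deterministic; runs in well under a second.
    """
    cfg = GeneratorConfig(seed=seed, n_patients=n_patients)
    f, w = _gh_nodes()
    E = lambda g: float(w @ g)  # noqa: E731

    t_prim, t_spec = PRIMARY_N / UNION_N, SPECIALIST_N / UNION_N

    def doc_resid(ab):
        pp = _sigmoid(ab[0] + cfg.doc_primary_slope * f)
        ps = _sigmoid(ab[1] + cfg.doc_specialist_slope * f)
        un = E(pp + ps - pp * ps)
        return [E(pp) / un - t_prim, E(ps) / un - t_spec]

    sol = optimize.root(doc_resid, x0=[0.9, 1.2])
    if not sol.success:
        raise RuntimeError("documentation-model calibration failed")
    cfg.doc_primary_intercept, cfg.doc_specialist_intercept = map(float, sol.x)

    pp = _sigmoid(cfg.doc_primary_intercept + cfg.doc_primary_slope * f)
    ps = _sigmoid(cfg.doc_specialist_intercept + cfg.doc_specialist_slope * f)
    un = pp + ps - pp * ps
    e_pp, e_ps, e_un = E(pp), E(ps), E(un)

    def solve_pair(update, x0, target_marg, target_pr):
        def resid(params):
            c = update(params)
            return [
                E(c * un) / e_un - target_marg,
                (E(c * ps) / e_ps) / (E(c * pp) / e_pp) - target_pr,
            ]
        sol = optimize.root(resid, x0=x0)
        if not sol.success:
            raise RuntimeError("covariate calibration failed")
        return [float(v) for v in sol.x]

    marg, pr = _CAL_TARGETS["care_home"]
    cfg.care_home_intercept, cfg.care_home_slope = solve_pair(
        lambda p: _sigmoid(p[0] + p[1] * f), [-2.6, 0.8], marg, pr
    )
    marg, pr = _CAL_TARGETS["mortality"]
    cfg.mortality_intercept, cfg.mortality_slope = solve_pair(
        lambda p: _sigmoid(p[0] + p[1] * f), [-1.0, 0.05], marg, pr
    )
    marg, pr = _CAL_TARGETS["charlson_high"]

    def charlson_update(p):
        c = replace(cfg, charlson_shift=p[0], charlson_slope=p[1])
        return _charlson_high_prob(c, f)

    cfg.charlson_shift, cfg.charlson_slope = solve_pair(charlson_update, [0.0, 0.35], marg, pr)

    marg, pr = _CAL_TARGETS["consult_high"]

    def consult_update(p):
        c = replace(cfg, consult_intercept=p[0], consult_slope=p[1])
        return _consult_high_prob(c, f)

    cfg.consult_intercept, cfg.consult_slope = solve_pair(consult_update, [3.1, 0.25], marg, pr)

    marg, pr = _CAL_TARGETS["medication"]

    def med_resid(p):
        c = replace(cfg, medication_intercept=p[0], medication_primary_effect=p[1])
        m1, m0 = _medication_bars(c)
        med_spec = E(ps * (pp * m1 + (1 - pp) * m0)) / e_ps
        med_marg = E(pp * m1 + (1 - pp) * ps * m0) / e_un
        return [med_marg - marg, med_spec / m1 - pr]

    sol = optimize.root(med_resid, x0=[-2.8, 1.8])
    if not sol.success:
        raise RuntimeError("medication calibration failed")
    cfg.medication_intercept, cfg.medication_primary_effect = map(float, sol.x)

    # Alzheimer's: share of subtype-specific primary coding solved from the PR
    w_both = E(pp * ps) / e_pp
    cfg.p_subtype_coded_primary = float((1.0 / _ALZ_PR - w_both) / (1.0 - w_both))
    pi_alz = _ALZ_SPEC_FRACTION
    rest = 1.0 - pi_alz
    cfg.p_subtype = (pi_alz, rest * 0.631, rest * 0.116, rest * 0.253)

    cfg.validate()
    return cfg


def default_config(seed: int = 0, n_patients: int = 20_000) -> GeneratorConfig:
    """The calibrated default generator configuration (study conditions)."""
    return calibrate_default_config(seed=seed, n_patients=n_patients)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _rand_dates(rng, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Uniform integer day offsets between per-element date bounds (inclusive)."""
    span = np.maximum((hi - lo).astype("timedelta64[D]").astype(int), 0)
    off = (rng.random(lo.size) * (span + 1)).astype(int)
    return lo + off.astype("timedelta64[D]")


def generate(cfg: GeneratorConfig) -> SyntheticCohortBundle:
    """Generate one synthetic linked-EHR bundle; deterministic given the seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    codelist = synthetic_codelist()

    pid = np.array([f"P{i:06d}" for i in range(n)])
    yob = rng.integers(cfg.yob_min, cfg.yob_max + 1, size=n)
    sex = np.where(rng.random(n) < cfg.p_female, "F", "M")
    frailty = rng.standard_normal(n)
    is_case = rng.random(n) < cfg.p_dementia

    pp = _sigmoid(cfg.doc_primary_intercept + cfg.doc_primary_slope * frailty)
    ps = _sigmoid(cfg.doc_specialist_intercept + cfg.doc_specialist_slope * frailty)
    doc_p = is_case & (rng.random(n) < pp)
    doc_s = is_case & (rng.random(n) < ps)
    documented = doc_p | doc_s

    win_lo = np.datetime64(cfg.window_start)
    win_hi = np.datetime64(cfg.window_end)
    censor = np.datetime64(cfg.censor_date)
    span_days = (win_hi - win_lo).astype(int)
    t0 = win_lo + (rng.random(n) * (span_days + 1)).astype(int).astype("timedelta64[D]")

    subtype = rng.choice(4, size=n, p=np.asarray(cfg.p_subtype))
    age_at_t0 = t0.astype("datetime64[Y]").astype(int) + 1970 - yob

    # ethnicity / lsoa / smoking status
    eth_labels = list(ETHNICITY16_WEIGHTS)
    eth_w = np.asarray(list(ETHNICITY16_WEIGHTS.values()))
    eth = np.array(eth_labels)[rng.choice(len(eth_labels), size=n, p=eth_w / eth_w.sum())]
    eth = np.where(rng.random(n) < cfg.p_missing_ethnicity, "", eth)
    lsoa_pool = np.array([f"E0100{i:04d}" for i in range(10)])
    lsoa = lsoa_pool[rng.integers(0, 10, size=n)]
    lsoa = np.where(rng.random(n) < cfg.p_missing_lsoa, "", lsoa)
    smoking_state = rng.choice(3, size=n, p=np.asarray(cfg.smoking_dist))  # 0 never 1 former 2 current
    smoking_missing = rng.random(n) < cfg.p_missing_smoking

    # frailty-driven covariates (materialised for documented cases)
    care_home = rng.random(n) < _sigmoid(cfg.care_home_intercept + cfg.care_home_slope * frailty)
    dies = rng.random(n) < _sigmoid(cfg.mortality_intercept + cfg.mortality_slope * frailty)
    mu = np.exp(cfg.consult_intercept + cfg.consult_slope * frailty)
    r = cfg.consult_dispersion
    consult_count = rng.negative_binomial(r, r / (r + mu))
    alz = subtype == 0
    p_med = _sigmoid(
        cfg.medication_intercept
        + cfg.medication_primary_effect * doc_p.astype(float)
        + cfg.medication_alz_effect * alz.astype(float)
    )
    medicated = documented & (rng.random(n) < p_med)
    subtype_coded = (rng.random(n) < cfg.p_subtype_coded_primary) & (subtype != 3)

    events = _emit_events(cfg, rng, pid, doc_p, doc_s, t0, subtype, subtype_coded, win_hi)
    consultations = _emit_consultations(cfg, rng, pid, documented, t0, consult_count, care_home, win_lo, win_hi)
    prescriptions = _emit_prescriptions(cfg, rng, pid, medicated, t0, censor, win_lo, win_hi)

    death_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    idx_die = np.flatnonzero(documented & dies)
    if idx_die.size:
        hi = np.minimum(t0[idx_die] + np.timedelta64(4 * 365, "D"), censor)
        death_date[idx_die] = _rand_dates(rng, t0[idx_die], hi)

    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "year_of_birth": yob,
            "sex": sex,
            "ethnicity16": eth,
            "lsoa": lsoa,
            "lambeth_resident": rng.random(n) < 0.84,
            "death_date": [str(d)[:10] if not np.isnat(d) else "" for d in death_date],
        }
    )
    # smoking codes (primary-care coded events before index, documented cases)
    smoke_events = _emit_smoking(cfg, rng, pid, documented, smoking_missing, smoking_state, t0)
    comorb_events = _emit_comorbidity(cfg, rng, pid, documented, frailty, t0)
    events = pd.concat([events, smoke_events, comorb_events], ignore_index=True)
    events = events.sort_values(["patient_id", "event_date", "code"], kind="mergesort", ignore_index=True)

    imd = pd.DataFrame({"lsoa": lsoa_pool, "quintile": [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]})
    truth = pd.DataFrame(
        {
            "patient_id": pid,
            "frailty": frailty,
            "true_dementia": is_case,
            "doc_primary": doc_p,
            "doc_specialist": doc_s,
            "true_index_date": [str(d)[:10] for d in t0],
            "age_at_index": age_at_t0,
            "subtype": np.array(_SUBTYPE_NAMES)[subtype],
            "care_home": care_home,
            "dies_in_followup": dies & documented,
            "consult_count": consult_count,
            "medicated": medicated,
        }
    )
    return SyntheticCohortBundle(
        patients=patients,
        events=events,
        consultations=consultations,
        prescriptions=prescriptions,
        ground_truth=truth,
        imd_lookup=imd,
        codelist=codelist,
        config=cfg,
    )


def _emit_events(cfg, rng, pid, doc_p, doc_s, t0, subtype, subtype_coded, win_hi):
    rows: list[tuple] = []
    idx_doc = np.flatnonzero(doc_p | doc_s)
    for i in idx_doc:
        p = pid[i]
        base = t0[i]
        both = doc_p[i] and doc_s[i]
        primary_first = bool(doc_p[i]) if not both else bool(rng.random() < 0.5)
        delay = np.timedelta64(int(rng.integers(30, 366)), "D")
        t_p = base if primary_first or not doc_s[i] else min(base + delay, win_hi)
        t_s = base if (not primary_first) or not doc_p[i] else min(base + delay, win_hi)
        st = int(subtype[i])
        if doc_s[i]:
            icd = _ICD_BY_SUBTYPE[st]
            rows.append((p, "SPECIALIST", "ICD10", icd, t_s))
            for _ in range(int(rng.integers(0, 3))):
                extra = min(t_s + np.timedelta64(int(rng.integers(1, 700)), "D"), win_hi)
                rows.append((p, "SPECIALIST", "ICD10", icd, extra))
        if doc_p[i]:
            coded_st = st if subtype_coded[i] else 3
            high_pool = _HIGH_BY_SUBTYPE[coded_st]
            if rng.random() < cfg.p_primary_high_path:
                term, code = high_pool[int(rng.integers(0, len(high_pool)))]
                rows.append((p, "PRIMARY", term, code, t_p))
                for _ in range(int(rng.integers(0, 3))):
                    extra = min(t_p + np.timedelta64(int(rng.integers(1, 700)), "D"), win_hi)
                    term2, code2 = high_pool[int(rng.integers(0, len(high_pool)))]
                    rows.append((p, "PRIMARY", term2, code2, extra))
            else:
                j, k = rng.choice(len(_LOW_CODES), size=2, replace=False)
                t2 = min(t_p + np.timedelta64(int(rng.integers(0, 400)), "D"), win_hi)
                rows.append((p, "PRIMARY", *_LOW_CODES[j], t_p))
                rows.append((p, "PRIMARY", *_LOW_CODES[k], t2))
                if subtype_coded[i]:
                    term, code = high_pool[int(rng.integers(0, len(high_pool)))]
                    t3 = min(t_p + np.timedelta64(int(rng.integers(1, 500)), "D"), win_hi)
                    rows.append((p, "PRIMARY", term, code, t3))
        if rng.random() < cfg.noise_code_rate:  # unlisted filler code, ignored downstream
            rows.append((p, "PRIMARY", "READ", "ZZZ99", t_p if doc_p[i] else t_s))
    return _event_frame(rows)


def _event_frame(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "source", "terminology", "code", "event_date"])
    df["event_date"] = pd.to_datetime(df["event_date"]).dt.strftime("%Y-%m-%d")
    return df


def _emit_smoking(cfg, rng, pid, documented, missing, state, t0):
    rows = []
    for i in np.flatnonzero(documented & ~missing):
        d = t0[i] - np.timedelta64(int(rng.integers(30, 8 * 365)), "D")
        if state[i] == 0:
            rows.append((pid[i], "PRIMARY", "READ", "1372.", d))
        elif state[i] == 2:
            code = ("READ", "137R.") if rng.random() < 0.7 else ("SNOMED", "77176002")
            rows.append((pid[i], "PRIMARY", *code, d))
        else:  # former: explicit ex-smoker code, or current + never documentation
            if rng.random() < 0.5:
                rows.append((pid[i], "PRIMARY", "READ", "137S.", d))
            else:
                rows.append((pid[i], "PRIMARY", "READ", "137R.", d))
                d2 = t0[i] - np.timedelta64(int(rng.integers(30, 8 * 365)), "D")
                rows.append((pid[i], "PRIMARY", "READ", "1372.", d2))
    return _event_frame(rows)


def _emit_comorbidity(cfg, rng, pid, documented, frailty, t0):
    rows = []
    idx = np.flatnonzero(documented)
    for ci, (cond, weight, base) in enumerate(CHARLSON_CONDITIONS):
        logit = np.log(base / (1 - base)) + cfg.charlson_shift
        present = rng.random(idx.size) < _sigmoid(logit + cfg.charlson_slope * frailty[idx])
        for j in idx[present]:
            d = t0[j] - np.timedelta64(int(rng.integers(1, 8 * 365)), "D")
            code = (f"Q{ci:02d}..", "READ") if rng.random() < 0.6 else (f"90{ci:02d}0001", "SNOMED")
            rows.append((pid[j], "PRIMARY", code[1], code[0], d))
    return _event_frame(rows)


def _emit_consultations(cfg, rng, pid, documented, t0, counts, care_home, win_lo, win_hi):
    rows = []
    two_years = np.timedelta64(2 * 365, "D")
    for i in np.flatnonzero(documented):
        k = int(counts[i])
        lo = t0[i] - two_years + np.timedelta64(1, "D")
        span = (t0[i] - lo).astype(int)
        for _ in range(k):
            d = lo + np.timedelta64(int(rng.integers(0, span + 1)), "D")
            mode = "FACE_TO_FACE" if rng.random() < 0.7 else "TELEPHONE"
            rows.append((pid[i], d, mode, False))
        if care_home[i]:
            d = lo + np.timedelta64(int(rng.integers(0, span + 1)), "D")
            rows.append((pid[i], d, "OTHER", True))
    # light background consultations for undocumented patients
    idx_other = np.flatnonzero(~documented)
    n_bg = rng.poisson(0.5, size=idx_other.size)
    span_days = (win_hi - win_lo).astype(int)
    for i, k in zip(idx_other, n_bg):
        for _ in range(int(k)):
            d = win_lo + np.timedelta64(int(rng.integers(0, span_days + 1)), "D")
            rows.append((pid[i], d, "FACE_TO_FACE", False))
    df = pd.DataFrame(rows, columns=["patient_id", "date", "mode", "care_home"])
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    return df.sort_values(["patient_id", "date"], kind="mergesort", ignore_index=True)


def _emit_prescriptions(cfg, rng, pid, medicated, t0, censor, win_lo, win_hi):
    rows = []
    four_years = np.timedelta64(4 * 365, "D")
    for i in np.flatnonzero(medicated):
        hi = min(t0[i] + four_years, censor)
        span = (hi - t0[i]).astype(int)
        d = t0[i] + np.timedelta64(int(rng.integers(0, span + 1)), "D")
        cls = "ACHEI" if rng.random() < 0.8 else "MEMANTINE"
        rows.append((pid[i], d, cls))
    # non-dementia prescriptions as noise
    n_noise = rng.poisson(0.2, size=pid.size)
    span_days = (win_hi - win_lo).astype(int)
    for i, k in enumerate(n_noise):
        for _ in range(int(k)):
            d = win_lo + np.timedelta64(int(rng.integers(0, span_days + 1)), "D")
            rows.append((pid[i], d, "OTHER"))
    df = pd.DataFrame(rows, columns=["patient_id", "date", "drug_class"])
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    return df.sort_values(["patient_id", "date"], kind="mergesort", ignore_index=True)


def write_bundle(bundle: SyntheticCohortBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle's tables (and code list) as CSV files."""
    from .codelib import write_codelist

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("patients", "events", "consultations", "prescriptions", "ground_truth", "imd_lookup"):
        path = out / f"{name}.csv"
        getattr(bundle, name).to_csv(path, index=False)
        paths[name] = path
    paths["codelist"] = out / "codelist.csv"
    write_codelist(bundle.codelist, paths["codelist"])
    return paths
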