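"""Covariate derivation for cohort members, anchored at the index date.

The index date is a patient's first recorded dementia documentation
across both sources. All lookback windows anchor there:

* GP consultations (face-to-face or telephone) are counted over the
  half-open two-year window ``(index - 2y, index]`` and categorised
  against the cohort median (none / average-or-less / above-average).
* Care-home residence is any care-home-flagged consultation in a
  two-year lookback by default, or at any time prior under the
  unlimited-lookback variant.
* The modified Charlson comorbidity index sums Quan weights over the
  *distinct* chronic conditions (dementia itself excluded) coded in
  primary care strictly before the index date.
* Smoking, ethnicity condensation (16 classes to 6), IMD quintile-1
  deprivation, dementia subtype (specialist most-recent diagnosis where
  available, else the most frequent subtype-specific primary-care code),
  dementia medication (AChEI or memantine within 4 years post-index,
  censored 2019-05-31) and mortality within the same follow-up window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .codelib import CodeList, Domain, SmokingTag, SubtypeTag, Terminology
from .phenotype import CodedEvent, Source

logger = logging.getLogger(__name__)

CENSOR_DATE = date(2019, 5, 31)
FOLLOWUP_YEARS = 4
CONSULT_LOOKBACK_YEARS = 2


class ConsultCategory(str, Enum):
    ABOVE_AVERAGE = "ABOVE_AVERAGE"
    AVERAGE_OR_LESS = "AVERAGE_OR_LESS"
    NONE = "NONE"


class Smoking(str, Enum):
    NEVER = "NEVER"
    FORMER = "FORMER"
    CURRENT = "CURRENT"
    MISSING = "MISSING"


class Ethnicity6(str, Enum):
    WHITE_BRITISH = "WHITE_BRITISH"
    WHITE_NON_BRITISH = "WHITE_NON_BRITISH"
    BLACK = "BLACK"
    ASIAN = "ASIAN"
    MIXED = "MIXED"
    OTHER = "OTHER"
    MISSING = "MISSING"


class AgeGroup(str, Enum):
    AGE_65_74 = "65_74"
    AGE_75_84 = "75_84"
    AGE_85_PLUS = "85_PLUS"


CHARLSON_CATEGORIES = ["0", "1", "2_3", "4_5", "6_PLUS"]
CHARLSON_HIGH_THRESHOLD = 4

#: 16-class ethnicity labels condensed to the six analysis classes;
#: White British is kept unchanged as the reference class.
ETHNICITY16_TO_6 = {
    "White British": Ethnicity6.WHITE_BRITISH,
    "White Irish": Ethnicity6.WHITE_NON_BRITISH,
    "Any other White background": Ethnicity6.WHITE_NON_BRITISH,
    "White and Black Caribbean": Ethnicity6.MIXED,
    "White and Black African": Ethnicity6.MIXED,
    "White and Asian": Ethnicity6.MIXED,
    "Any other mixed background": Ethnicity6.MIXED,
    "Indian": Ethnicity6.ASIAN,
    "Pakistani": Ethnicity6.ASIAN,
    "Bangladeshi": Ethnicity6.ASIAN,
    "Any other Asian background": Ethnicity6.ASIAN,
    "Asian British": Ethnicity6.ASIAN,
    "Black Caribbean": Ethnicity6.BLACK,
    "Black African": Ethnicity6.BLACK,
    "Black British": Ethnicity6.BLACK,
    "Any other Black background": Ethnicity6.BLACK,
    "Chinese": Ethnicity6.OTHER,
    "Any other ethnic group": Ethnicity6.OTHER,
}


@dataclass(frozen=True)
class Consultation:
    patient_id: str
    date: date
    mode: str  # FACE_TO_FACE | TELEPHONE | OTHER
    care_home: bool = False


@dataclass(frozen=True)
class Prescription:
    patient_id: str
    date: date
    drug_class: str  # ACHEI | MEMANTINE | OTHER


def _years_before(d: date, years: int) -> date:
    try:
        return d.replace(year=d.year - years)
    except ValueError:  # 29 Feb
        return d.replace(year=d.year - years, day=28)


def _years_after(d: date, years: int) -> date:
    try:
        return d.replace(year=d.year + years)
    except ValueError:
        return d.replace(year=d.year + years, day=28)


def consultation_features(
    consultations: Sequence[Consultation], index_date: date, median: int
) -> tuple[int, ConsultCategory]:
    """Count face-to-face/telephone consultations in (index-2y, index]; categorise.

    ``ABOVE_AVERAGE`` means at or above the cohort median; zero
    consultations form their own category.
    """
    if median < 1:
        raise ValueError("median must be >= 1")
    lo = _years_before(index_date, CONSULT_LOOKBACK_YEARS)
    count = sum(
        1
        for c in consultations
        if c.mode in ("FACE_TO_FACE", "TELEPHONE") and lo < c.date <= index_date
    )
    if count == 0:
        cat = ConsultCategory.NONE
    elif count >= median:
        cat = ConsultCategory.ABOVE_AVERAGE
    else:
        cat = ConsultCategory.AVERAGE_OR_LESS
    return count, cat


def compute_median_consultations(counts: Sequence[int]) -> int:
    """Lower median of per-patient consultation counts over the whole cohort."""
    if len(counts) == 0:
        raise ValueError("empty cohort")
    s = sorted(counts)
    return int(s[(len(s) - 1) // 2])


def care_home_flag(
    consultations: Sequence[Consultation],
    index_date: date,
    lookback_years: Optional[int] = CONSULT_LOOKBACK_YEARS,
) -> bool:
    """Any care-home-flagged consultation in the lookback window ending at index.

    ``lookback_years=None`` means unlimited lookback (any time prior).
    """
    lo = None if lookback_years is None else _years_before(index_date, lookback_years)
    return any(
        c.care_home and c.date <= index_date and (lo is None or c.date > lo)
        for c in consultations
    )


def charlson_score(
    events: Sequence[CodedEvent], codelist: CodeList, index_date: date
) -> int:
    """Modified Charlson comorbidity index, Quan weights, dementia excluded.

    Sums weights over *distinct* conditions coded strictly before the
    index date; repeat codes for one condition count once.
    """
    conditions: dict[str, int] = {}
    for ev in events:
        if ev.source is not Source.PRIMARY or ev.event_date >= index_date:
            continue
        entry = codelist.lookup(ev.terminology, ev.code)
        if entry is None or entry.domain is not Domain.COMORBIDITY:
            continue
        conditions[entry.condition] = max(conditions.get(entry.condition, 0), entry.weight)
    return sum(conditions.values())


def charlson_category(score: int) -> str:
    if score <= 0:
        return "0"
    if score == 1:
        return "1"
    if score <= 3:
        return "2_3"
    if score <= 5:
        return "4_5"
    return "6_PLUS"


def smoking_status(
    events: Sequence[CodedEvent], codelist: CodeList, index_date: date
) -> Smoking:
    """Smoking status from codes strictly before the index date.

    Former smoking is assigned on any former-smoker code, or when both
    current-smoker and never-smoker documentation exist.
    """
    tags = set()
    for ev in events:
        if ev.event_date >= index_date:
            continue
        entry = codelist.lookup(ev.terminology, ev.code)
        if entry is None or entry.domain is not Domain.SMOKING:
            continue
        tags.add(entry.smoking_tag)
    tags.discard(SmokingTag.NONE)
    if not tags:
        return Smoking.MISSING
    if SmokingTag.FORMER in tags or {SmokingTag.CURRENT, SmokingTag.NEVER} <= tags:
        return Smoking.FORMER
    if SmokingTag.CURRENT in tags:
        return Smoking.CURRENT
    return Smoking.NEVER


def condense_ethnicity(ethnicity16: Optional[str]) -> Ethnicity6:
    """Condense the 16-class ethnicity coding into the six analysis classes."""
    if ethnicity16 is None or (isinstance(ethnicity16, float) and np.isnan(ethnicity16)) or ethnicity16 == "":
        return Ethnicity6.MISSING
    try:
        return ETHNICITY16_TO_6[ethnicity16]
    except KeyError:
        raise ValueError(f"unknown 16-class ethnicity label {ethnicity16!r}") from None


def imd_flag(lsoa: Optional[str], imd_lookup: Mapping[str, int]):
    """True iff the patient's LSOA maps to IMD quintile 1 (most deprived).

    Returns the string ``"MISSING"`` when the LSOA is absent or unmapped.
    """
    if lsoa is None or lsoa == "" or (isinstance(lsoa, float) and np.isnan(lsoa)):
        return "MISSING"
    q = imd_lookup.get(lsoa)
    if q is None:
        return "MISSING"
    return q == 1

_PRIMARY_SUBTYPE_TAGS = (
    SubtypeTag.ALZHEIMERS_MIXED,
    SubtypeTag.VASCULAR,
    SubtypeTag.OTHER_SPECIFIED,
)


def resolve_subtype(
    specialist_events: Sequence[CodedEvent],
    primary_events: Sequence[CodedEvent],
    codelist: CodeList,
) -> SubtypeTag:
    """Dementia subtype with specialist precedence.

    The most recent specialist (ICD-10) dementia diagnosis decides where
    one exists; otherwise the most frequent subtype-specific primary-care
    code is taken, with ties broken by the most recent tagged code and
    then fixed tag order. Unspecified when the specialist diagnosis is
    unspecified or no subtype-specific primary codes exist.
    """
    spec = []
    for ev in specialist_events:
        entry = codelist.lookup(ev.terminology, ev.code)
        if entry is not None and entry.domain is Domain.DEMENTIA:
            spec.append((ev.event_date, entry.subtype_tag))
    if spec:
        spec.sort(key=lambda t: t[0])
        tag = spec[-1][1]
        return tag if tag is not SubtypeTag.NONE else SubtypeTag.UNSPECIFIED

    counts: dict[SubtypeTag, int] = {}
    latest: dict[SubtypeTag, date] = {}
    for ev in primary_events:
        entry = codelist.lookup(ev.terminology, ev.code)
        if entry is None or entry.domain is not Domain.DEMENTIA:
            continue
        tag = entry.subtype_tag
        if tag not in _PRIMARY_SUBTYPE_TAGS:
            continue
        counts[tag] = counts.get(tag, 0) + 1
        if tag not in latest or ev.event_date > latest[tag]:
            latest[tag] = ev.event_date
    if not counts:
        return SubtypeTag.UNSPECIFIED
    order = {t: i for i, t in enumerate(_PRIMARY_SUBTYPE_TAGS)}
    # ties: most recent tagged code, then fixed tag order
    winner = max(counts, key=lambda t: (counts[t], latest[t], -order[t]))
    if sum(1 for t in counts if counts[t] == counts[winner]) > 1:
        logger.debug("subtype tie broken by recency/tag order: %s", counts)
    return winner


def medication_flag(
    prescriptions: Sequence[Prescription],
    index_date: date,
    censor_date: date = CENSOR_DATE,
) -> bool:
    """AChEI or memantine prescribed within 4 years post-index (censored)."""
    hi = min(_years_after(index_date, FOLLOWUP_YEARS), censor_date)
    return any(
        p.drug_class in ("ACHEI", "MEMANTINE") and index_date <= p.date <= hi
        for p in prescriptions
    )


def mortality_flag(
    death_date: Optional[date],
    index_date: date,
    censor_date: date = CENSOR_DATE,
) -> bool:
    """Death within 4 years of first dementia documentation (censored)."""
    if death_date is None:
        return False
    if death_date < index_date:
        raise ValueError("death before first dementia documentation: data-quality error")
    hi = min(_years_after(index_date, FOLLOWUP_YEARS), censor_date)
    return index_date <= death_date <= hi


def age_group(age: int) -> AgeGroup:
    if age >= 85:
        return AgeGroup.AGE_85_PLUS
    if age >= 75:
        return AgeGroup.AGE_75_84
    return AgeGroup.AGE_65_74


def prevalence_denominator(patients: pd.DataFrame, reference_date: date = date(2013, 5, 24)) -> int:
    """Population aged 65+ at the reference date (median diagnosis date)."""
    if patients.empty:
        return 0
    yob = pd.to_numeric(patients["year_of_birth"], errors="coerce")
    return int(((reference_date.year - yob) >= 65).sum())


# ---------------------------------------------------------------------------
# whole-cohort derivation
# ---------------------------------------------------------------------------

def derive_covariates(
    cohort: pd.DataFrame,
    patients: pd.DataFrame,
    events: pd.DataFrame,
    consultations: pd.DataFrame,
    prescriptions: pd.DataFrame,
    codelist: CodeList,
    imd_lookup: Mapping[str, int] | None = None,
    median_override: Optional[int] = None,
    care_home_lookback_years: Optional[int] = CONSULT_LOOKBACK_YEARS,
    censor_date: date = CENSOR_DATE,
) -> pd.DataFrame:
    """Derive the full covariate table for an ascertained cohort.

    One row per cohort member with every tabulated characteristic. The
    consultation median is recomputed from the cohort unless
    ``median_override`` pins it (replication runs).
    """
    from .phenotype import CodedEvent as CE  # local alias

    imd_lookup = imd_lookup or {}
    pats = patients.drop_duplicates("patient_id").set_index("patient_id")

    ev_by_pat: dict[str, list[CodedEvent]] = {}
    for row in events.itertuples(index=False):
        d = _as_date(row.event_date)
        ev_by_pat.setdefault(str(row.patient_id), []).append(
            CE(
                patient_id=str(row.patient_id),
                source=Source(row.source),
                terminology=Terminology(row.terminology),
                code=str(row.code),
                event_date=d,
            )
        )
    cons_by_pat: dict[str, list[Consultation]] = {}
    for row in consultations.itertuples(index=False):
        d = _as_date(row.date)
        cons_by_pat.setdefault(str(row.patient_id), []).append(
            Consultation(str(row.patient_id), d, str(row.mode), bool(row.care_home))
        )
    rx_by_pat: dict[str, list[Prescription]] = {}
    for row in prescriptions.itertuples(index=False):
        d = _as_date(row.date)
        rx_by_pat.setdefault(str(row.patient_id), []).append(
            Prescription(str(row.patient_id), d, str(row.drug_class))
        )

    rows = []
    counts = []
    for rec in cohort.itertuples(index=False):
        pid = str(rec.patient_id)
        index_date = _as_date(rec.first_date_combined)
        pat = pats.loc[pid]
        evs = ev_by_pat.get(pid, [])
        prim = [e for e in evs if e.source is Source.PRIMARY]
        spec = [e for e in evs if e.source is Source.SPECIALIST]
        cons = cons_by_pat.get(pid, [])
        rx = rx_by_pat.get(pid, [])
        count, _ = consultation_features(cons, index_date, median=1)
        counts.append(count)
        score = charlson_score(prim, codelist, index_date)
        death = _none_if_na(pat.get("death_date"))
        death = None if death is None else _as_date(death)
        rows.append(
            {
                "patient_id": pid,
                "stratum": rec.stratum,
                "age_at_first": int(rec.age_at_first),
                "age_group": age_group(int(rec.age_at_first)).value,
                "sex": str(pat["sex"]),
                "ethnicity6": condense_ethnicity(_none_if_na(pat.get("ethnicity16"))).value,
                "imd_q1": imd_flag(_none_if_na(pat.get("lsoa")), imd_lookup),
                "smoking": smoking_status(prim, codelist, index_date).value,
                "consult_count": count,
                "care_home": care_home_flag(cons, index_date, care_home_lookback_years),
                "charlson": score,
                "charlson_cat": charlson_category(score),
                "charlson_high": score >= CHARLSON_HIGH_THRESHOLD,
                "died_in_followup": mortality_flag(death, index_date, censor_date),
                "full_followup": _years_after(index_date, FOLLOWUP_YEARS) <= censor_date,
                "subtype": resolve_subtype(spec, prim, codelist).value,
                "medicated": medication_flag(rx, index_date, censor_date),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    median = median_override if median_override is not None else compute_median_consultations(counts)
    out["consult_cat"] = [
        ConsultCategory.NONE.value
        if c == 0
        else (ConsultCategory.ABOVE_AVERAGE.value if c >= median else ConsultCategory.AVERAGE_OR_LESS.value)
        for c in out["consult_count"]
    ]
    out.attrs["consult_median"] = median
    return out


def _as_date(d) -> date:
    if isinstance(d, date) and not hasattr(d, "hour"):
        return d
    if isinstance(d, str):
        return date.fromisoformat(d)
    return pd.Timestamp(d).date()


def _none_if_na(v):
    if v is None:
        return None
    if isinstance(v, float) and np.isnan(v):
        return None
    if isinstance(v, str) and v == "":
        return None
    if pd.isna(v):
        return None
    return v
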