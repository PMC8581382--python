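"""Dementia case ascertainment from linked primary-care and specialist records.

A patient is counted as a documented dementia case when, inside the study
window (2007-01-01 to 2019-05-31, inclusive at both ends):

* **specialist source** — at least one ICD-10 dementia code (mental and
  behavioural disorder chapter, F00–F03) is recorded; or
* **primary-care source** — either one code from the high-specificity
  dementia list, or two *different* codes (distinct (terminology, code)
  pairs, any dates) from the low-specificity list, with Read or SNOMED
  terminology.

Eligibility additionally requires the first recorded dementia date — the
earlier of the per-source first dates — to fall at age 65 or more, with
age computed as calendar-year difference from year of birth.

The per-patient operations (:func:`ascertain_primary`,
:func:`ascertain_specialist`, :func:`combine_and_gate`) state the
criteria directly; :func:`build_cohort` is the vectorised equivalent for
whole extracts and is tested for equality against a brute-force oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from datetime import date
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .codelib import CodeList, Domain, Specificity, Terminology

logger = logging.getLogger(__name__)

#: how the first primary-care dementia date is defined when eligibility
#: rests on two low-specificity codes: "earliest_code" dates the case at
#: the first dementia-domain code of any tier (the default); "criteria_met"
#: dates it at the moment the criteria were first satisfied.
FIRST_DATE_RULES = ("earliest_code", "criteria_met")


class Stratum(str, Enum):
    BOTH = "BOTH"
    SPECIALIST_ONLY = "SPECIALIST_ONLY"
    PRIMARY_ONLY = "PRIMARY_ONLY"
    NONE = "NONE"


class Source(str, Enum):
    PRIMARY = "PRIMARY"
    SPECIALIST = "SPECIALIST"


class RestrictionMode(str, Enum):
    NONE = "NONE"
    RESIDENCE = "RESIDENCE"
    PRIOR_CONSULTATION = "PRIOR_CONSULTATION"
    PRE2016 = "PRE2016"


@dataclass(frozen=True)
class StudyWindow:
    start: date = date(2007, 1, 1)
    end: date = date(2019, 5, 31)
    min_age: int = 65

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("StudyWindow: start must precede end")
        if self.min_age < 0:
            raise ValueError("StudyWindow: min_age must be >= 0")

    def contains(self, d: date) -> bool:
        return self.start <= d <= self.end


@dataclass(frozen=True)
class Patient:
    patient_id: str
    year_of_birth: Optional[int]
    sex: str = "F"
    ethnicity16: Optional[str] = None
    lsoa: Optional[str] = None
    lambeth_resident: bool = True
    death_date: Optional[date] = None


@dataclass(frozen=True)
class CodedEvent:
    patient_id: str
    source: Source
    terminology: Terminology
    code: str
    event_date: date

    def __post_init__(self) -> None:
        primary_term = self.terminology in (Terminology.READ, Terminology.SNOMED)
        if (self.source is Source.PRIMARY) != primary_term:
            raise ValueError(
                f"{self.patient_id}: terminology {self.terminology.value} "
                f"inconsistent with source {self.source.value}"
            )


@dataclass(frozen=True)
class AscertainmentResult:
    patient_id: str
    in_primary: bool
    in_specialist: bool
    first_date_primary: Optional[date]
    first_date_specialist: Optional[date]
    first_date_combined: Optional[date]
    age_at_first: Optional[int]
    eligible: bool
    stratum: Stratum


def _dementia_matches(
    events: Iterable[CodedEvent], codelist: CodeList, window: StudyWindow
):
    """Yield (event, entry) for in-window dementia-domain matches; dedup exact rows."""
    seen = set()
    for ev in events:
        key = (ev.patient_id, ev.source, ev.terminology, ev.code, ev.event_date)
        if key in seen:
            continue
        seen.add(key)
        if not window.contains(ev.event_date):
            logger.debug("event outside window ignored: %s", ev)
            continue
        entry = codelist.lookup(ev.terminology, ev.code)
        if entry is None or entry.domain is not Domain.DEMENTIA:
            continue
        yield ev, entry


def ascertain_primary(
    events: Sequence[CodedEvent],
    codelist: CodeList,
    window: StudyWindow,
    first_date_rule: str = "earliest_code",
) -> tuple[bool, Optional[date]]:
    """Primary-care ascertainment for one patient.

    Documented iff, among in-window dementia matches, there is at least
    one high-specificity code or two distinct low-specificity
    (terminology, code) pairs. Codes absent from the list are ignored.
    """
    if first_date_rule not in FIRST_DATE_RULES:
        raise ValueError(f"unknown first_date_rule {first_date_rule!r}")
    for ev in events:
        if ev.source is not Source.PRIMARY:
            raise ValueError(f"{ev.patient_id}: non-primary event passed to ascertain_primary")
    high_dates: list[date] = []
    low_first: dict[tuple[Terminology, str], date] = {}
    all_dates: list[date] = []
    for ev, entry in _dementia_matches(events, codelist, window):
        all_dates.append(ev.event_date)
        if entry.specificity is Specificity.HIGH:
            high_dates.append(ev.event_date)
        elif entry.specificity is Specificity.LOW:
            key = (ev.terminology, ev.code)
            if key not in low_first or ev.event_date < low_first[key]:
                low_first[key] = ev.event_date
    qualified = bool(high_dates) or len(low_first) >= 2
    if not qualified:
        return False, None
    if first_date_rule == "earliest_code":
        return True, min(all_dates)
    # criteria_met: earliest date at which a HIGH code existed or a second
    # distinct LOW code had appeared
    candidates = []
    if high_dates:
        candidates.append(min(high_dates))
    if len(low_first) >= 2:
        candidates.append(sorted(low_first.values())[1])
    return True, min(candidates)


def ascertain_specialist(
    events: Sequence[CodedEvent], codelist: CodeList, window: StudyWindow
) -> tuple[bool, Optional[date]]:
    """Specialist ascertainment: any in-window ICD-10 dementia code."""
    for ev in events:
        if ev.source is not Source.SPECIALIST:
            raise ValueError(f"{ev.patient_id}: non-specialist event passed to ascertain_specialist")
    dates = [ev.event_date for ev, _ in _dementia_matches(events, codelist, window)]
    if not dates:
        return False, None
    return True, min(dates)


def combine_and_gate(
    primary: tuple[bool, Optional[date]],
    specialist: tuple[bool, Optional[date]],
    patient: Patient,
    window: StudyWindow,
) -> AscertainmentResult:
    """Combine per-source results and apply the minimum-age criterion."""
    in_p, d_p = primary
    in_s, d_s = specialist
    if in_p and in_s:
        stratum = Stratum.BOTH
    elif in_p:
        stratum = Stratum.PRIMARY_ONLY
    elif in_s:
        stratum = Stratum.SPECIALIST_ONLY
    else:
        stratum = Stratum.NONE
    present = [d for d in (d_p, d_s) if d is not None]
    first = min(present) if present else None
    age = None
    eligible = False
    if first is not None:
        if patient.year_of_birth is None:
            warnings.warn(f"{patient.patient_id}: missing year of birth; excluded")
        else:
            age = first.year - patient.year_of_birth
            eligible = stratum is not Stratum.NONE and age >= window.min_age
    return AscertainmentResult(
        patient_id=patient.patient_id,
        in_primary=in_p,
        in_specialist=in_s,
        first_date_primary=d_p,
        first_date_specialist=d_s,
        first_date_combined=first,
        age_at_first=age,
        eligible=eligible,
        stratum=stratum,
    )


# ---------------------------------------------------------------------------
# vectorised whole-extract path
# ---------------------------------------------------------------------------

_COHORT_COLUMNS = [
    "patient_id",
    "in_primary",
    "in_specialist",
    "first_date_primary",
    "first_date_specialist",
    "first_date_combined",
    "age_at_first",
    "eligible",
    "stratum",
]


def _empty_cohort() -> pd.DataFrame:
    return pd.DataFrame(columns=_COHORT_COLUMNS)


def build_cohort(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    codelist: CodeList,
    window: StudyWindow | None = None,
    first_date_rule: str = "earliest_code",
    keep_ineligible: bool = False,
) -> pd.DataFrame:
    """Ascertain every patient in an extract and apply the age gate.

    ``patients`` needs columns ``patient_id, year_of_birth``; ``events``
    needs ``patient_id, source, terminology, code, event_date``. Events
    whose patient_id is unknown are dropped with a warning. Returns one
    row per eligible patient (all patients with ``keep_ineligible``),
    deterministic and order-invariant in the inputs.
    """
    window = window or StudyWindow()
    if first_date_rule not in FIRST_DATE_RULES:
        raise ValueError(f"unknown first_date_rule {first_date_rule!r}")
    if patients.empty:
        return _empty_cohort()
    pats = patients.drop_duplicates("patient_id").set_index("patient_id")

    ev = events.copy()
    if not ev.empty:
        unknown = ~ev["patient_id"].isin(pats.index)
        if unknown.any():
            warnings.warn(f"{int(unknown.sum())} events with unknown patient_id dropped")
            ev = ev[~unknown]
    if ev.empty:
        agg = pd.DataFrame(
            columns=["first_p", "first_s", "in_p", "in_s"], index=pd.Index([], name="patient_id")
        )
    else:
        ev = ev.drop_duplicates(["patient_id", "source", "terminology", "code", "event_date"])
        dates = pd.to_datetime(ev["event_date"])
        in_win = (dates >= pd.Timestamp(window.start)) & (dates <= pd.Timestamp(window.end))
        ev = ev.assign(event_date=dates)[in_win]
        # join to the dementia sub-list
        dem = pd.DataFrame(
            [
                {"terminology": e.terminology.value, "code": e.code, "specificity": e.specificity.value}
                for e in codelist.subset(Domain.DEMENTIA)
            ]
        )
        if dem.empty:
            ev = ev.iloc[0:0]
        else:
            ev = ev.merge(dem, on=["terminology", "code"], how="inner")
        agg = _aggregate_matches(ev, first_date_rule)

    res = pats.join(agg, how="left")
    res["in_p"] = res["in_p"].eq(True)
    res["in_s"] = res["in_s"].eq(True)
    first_p = pd.to_datetime(res["first_p"], errors="coerce")
    first_s = pd.to_datetime(res["first_s"], errors="coerce")
    combined = pd.concat([first_p, first_s], axis=1).min(axis=1)

    stratum = np.select(
        [
            res["in_p"] & res["in_s"],
            res["in_p"],
            res["in_s"],
        ],
        [Stratum.BOTH.value, Stratum.PRIMARY_ONLY.value, Stratum.SPECIALIST_ONLY.value],
        default=Stratum.NONE.value,
    )
    yob = pd.to_numeric(res["year_of_birth"], errors="coerce")
    n_missing_yob = int((yob.isna() & combined.notna()).sum())
    if n_missing_yob:
        warnings.warn(f"{n_missing_yob} documented patients excluded: missing year of birth")
    age = combined.dt.year - yob
    eligible = (
        (stratum != Stratum.NONE.value) & combined.notna() & yob.notna() & (age >= window.min_age)
    )
    out = pd.DataFrame(
        {
            "patient_id": res.index,
            "in_primary": res["in_p"].to_numpy(),
            "in_specialist": res["in_s"].to_numpy(),
            "first_date_primary": first_p.to_numpy(),
            "first_date_specialist": first_s.to_numpy(),
            "first_date_combined": combined.to_numpy(),
            "age_at_first": age.to_numpy(),
            "eligible": np.asarray(eligible),
            "stratum": stratum,
        }
    ).sort_values("patient_id", kind="mergesort", ignore_index=True)
    if keep_ineligible:
        return out
    return out[out["eligible"]].reset_index(drop=True)


def _aggregate_matches(ev: pd.DataFrame, first_date_rule: str) -> pd.DataFrame:
    """Per-patient documentation flags and first dates from matched events."""
    if ev.empty:
        return pd.DataFrame(
            columns=["first_p", "first_s", "in_p", "in_s"], index=pd.Index([], name="patient_id")
        )
    prim = ev[ev["source"] == Source.PRIMARY.value]
    spec = ev[ev["source"] == Source.SPECIALIST.value]

    in_s = spec.groupby("patient_id").size() > 0
    first_s = spec.groupby("patient_id")["event_date"].min()

    high = prim[prim["specificity"] == Specificity.HIGH.value]
    low = prim[prim["specificity"] == Specificity.LOW.value]
    has_high = high.groupby("patient_id").size() > 0
    n_low_distinct = (
        low.drop_duplicates(["patient_id", "terminology", "code"]).groupby("patient_id").size()
        if not low.empty
        else pd.Series(dtype=int)
    )
    in_p = (
        pd.concat([has_high.rename("h"), (n_low_distinct >= 2).rename("l")], axis=1)
        .eq(True)
        .any(axis=1)
    )
    in_p = in_p[in_p]
    if first_date_rule == "earliest_code":
        first_p = prim.groupby("patient_id")["event_date"].min().reindex(in_p.index)
    else:
        first_high = high.groupby("patient_id")["event_date"].min()
        if low.empty:
            second_low = pd.Series(dtype="datetime64[ns]")
        else:
            lf = (
                low.groupby(["patient_id", "terminology", "code"])["event_date"]
                .min()
                .reset_index()
                .sort_values(["patient_id", "event_date"], kind="mergesort")
            )
            second_low = lf.groupby("patient_id").nth(1).set_index("patient_id")["event_date"]
        first_p = (
            pd.concat([first_high.rename("h"), second_low.rename("l")], axis=1)
            .min(axis=1)
            .reindex(in_p.index)
        )
    agg = pd.concat(
        [
            first_p.rename("first_p"),
            first_s.rename("first_s"),
            in_p.rename("in_p"),
            in_s[in_s].rename("in_s"),
        ],
        axis=1,
    )
    agg.index.name = "patient_id"
    agg["in_p"] = agg["in_p"].eq(True)
    agg["in_s"] = agg["in_s"].eq(True)
    # a patient qualifies in primary only when in_p; drop stray first dates
    agg.loc[~agg["in_p"].astype(bool), "first_p"] = pd.NaT
    return agg


def apply_restrictions(
    cohort: pd.DataFrame,
    patients: pd.DataFrame,
    consultations: pd.DataFrame | None,
    mode: RestrictionMode | str,
) -> pd.DataFrame:
    """Sensitivity-analysis restrictions of the ascertained cohort.

    ``RESIDENCE`` keeps borough residents; ``PRIOR_CONSULTATION`` keeps
    patients with at least one face-to-face or telephone primary-care
    consultation in the 2 years up to and including the first dementia
    date; ``PRE2016`` keeps first documentation on or before 2015-12-31.
    """
    mode = RestrictionMode(mode)
    if mode is RestrictionMode.NONE:
        return cohort.copy()
    if mode is RestrictionMode.RESIDENCE:
        resident = patients.set_index("patient_id")["lambeth_resident"].astype(bool)
        keep = cohort["patient_id"].map(resident).fillna(False).astype(bool)
        return cohort[keep].reset_index(drop=True)
    if mode is RestrictionMode.PRE2016:
        keep = pd.to_datetime(cohort["first_date_combined"]) <= pd.Timestamp(2015, 12, 31)
        return cohort[keep].reset_index(drop=True)
    # PRIOR_CONSULTATION
    if consultations is None:
        raise ValueError("PRIOR_CONSULTATION restriction needs a consultations table")
    cons = consultations[consultations["mode"].isin(["FACE_TO_FACE", "TELEPHONE"])]
    cons = cons.assign(date=pd.to_datetime(cons["date"]))
    idx = cohort.set_index("patient_id")["first_date_combined"]
    merged = cons.merge(
        idx.rename("index_date"), left_on="patient_id", right_index=True, how="inner"
    )
    merged["index_date"] = pd.to_datetime(merged["index_date"])
    lo = merged["index_date"] - pd.DateOffset(years=2)
    ok = merged[(merged["date"] > lo) & (merged["date"] <= merged["index_date"])]
    keep = cohort["patient_id"].isin(ok["patient_id"].unique())
    return cohort[keep].reset_index(drop=True)
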