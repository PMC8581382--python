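"""Brute-force ascertainment oracle: the inclusion criteria applied verbatim.

Independent of the library's engine: it enumerates singleton and pair
subsets of a patient's in-window dementia matches and asks, literally,
"is there one high-specificity code, or two different low-specificity
codes?". Intended for micro-cohorts only (quadratic in events).
"""

from datetime import date
from itertools import combinations

from ehrlink.codelib import Domain, Specificity
from ehrlink.phenotype import Source, Stratum


def _matches(events, codelist, window):
    out = []
    seen = set()
    for ev in events:
        key = (ev.source, ev.terminology, ev.code, ev.event_date)
        if key in seen:
            continue
        seen.add(key)
        if not (window.start <= ev.event_date <= window.end):
            continue
        entry = codelist.lookup(ev.terminology, ev.code)
        if entry is not None and entry.domain is Domain.DEMENTIA:
            out.append((ev, entry))
    return out


def oracle_patient(patient, events, codelist, window, first_date_rule="earliest_code"):
    """Return (in_primary, first_p, in_specialist, first_s, stratum, age, eligible)."""
    prim = _matches([e for e in events if e.source is Source.PRIMARY], codelist, window)
    spec = _matches([e for e in events if e.source is Source.SPECIALIST], codelist, window)

    in_p = False
    # one high-specificity code suffices
    for ev, entry in prim:
        if entry.specificity is Specificity.HIGH:
            in_p = True
    # ... or two different low-specificity codes
    for (e1, n1), (e2, n2) in combinations(prim, 2):
        if (
            n1.specificity is Specificity.LOW
            and n2.specificity is Specificity.LOW
            and (e1.terminology, e1.code) != (e2.terminology, e2.code)
        ):
            in_p = True
    first_p = None
    if in_p:
        if first_date_rule == "earliest_code":
            first_p = min(ev.event_date for ev, _ in prim)
        else:
            dates = []
            highs = [ev.event_date for ev, n in prim if n.specificity is Specificity.HIGH]
            if highs:
                dates.append(min(highs))
            pair_dates = []
            for (e1, n1), (e2, n2) in combinations(prim, 2):
                if (
                    n1.specificity is Specificity.LOW
                    and n2.specificity is Specificity.LOW
                    and (e1.terminology, e1.code) != (e2.terminology, e2.code)
                ):
                    pair_dates.append(max(e1.event_date, e2.event_date))
            if pair_dates:
                dates.append(min(pair_dates))
            first_p = min(dates)

    in_s = len(spec) > 0
    first_s = min((ev.event_date for ev, _ in spec), default=None)

    if in_p and in_s:
        stratum = Stratum.BOTH
    elif in_p:
        stratum = Stratum.PRIMARY_ONLY
    elif in_s:
        stratum = Stratum.SPECIALIST_ONLY
    else:
        stratum = Stratum.NONE
    present = [d for d in (first_p, first_s) if d is not None]
    combined = min(present) if present else None
    age = None
    eligible = False
    if combined is not None and patient.year_of_birth is not None:
        age = combined.year - patient.year_of_birth
        eligible = stratum is not Stratum.NONE and age >= window.min_age
    return {
        "in_primary": in_p,
        "first_date_primary": first_p,
        "in_specialist": in_s,
        "first_date_specialist": first_s,
        "first_date_combined": combined,
        "stratum": stratum.value,
        "age_at_first": age,
        "eligible": eligible,
    }
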