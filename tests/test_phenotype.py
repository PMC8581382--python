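from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from ehrlink.phenotype import (
    Patient,
    RestrictionMode,
    StudyWindow,
    apply_restrictions,
    ascertain_primary,
    ascertain_specialist,
    build_cohort,
    combine_and_gate,
)

from .conftest import events_frame, make_event
from .oracle import oracle_patient


class TestPrimaryAscertainment:
    def test_one_high_code_qualifies(self, codelist, window):
        events = [make_event("p", "PRIMARY", "READ", "Eu02.", "2010-03-01")]
        assert ascertain_primary(events, codelist, window) == (True, date(2010, 3, 1))

    def test_single_low_code_insufficient(self, codelist, window):
        events = [make_event("p", "PRIMARY", "READ", "LOW1.", "2010-03-01")]
        assert ascertain_primary(events, codelist, window) == (False, None)

    def test_same_low_code_twice_insufficient(self, codelist, window):
        events = [
            make_event("p", "PRIMARY", "READ", "LOW1.", "2010-03-01"),
            make_event("p", "PRIMARY", "READ", "LOW1.", "2012-06-01"),
        ]
        assert ascertain_primary(events, codelist, window) == (False, None)

    def test_two_distinct_low_codes_qualify_from_earliest(self, codelist, window):
        events = [
            make_event("p", "PRIMARY", "READ", "LOW2.", "2012-01-01"),
            make_event("p", "PRIMARY", "READ", "LOW1.", "2011-05-01"),
        ]
        assert ascertain_primary(events, codelist, window) == (True, date(2011, 5, 1))

    def test_two_distinct_low_codes_same_day_qualify(self, codelist, window):
        events = [
            make_event("p", "PRIMARY", "READ", "LOW1.", "2011-05-01"),
            make_event("p", "PRIMARY", "SNOMED", "111000", "2011-05-01"),
        ]
        assert ascertain_primary(events, codelist, window) == (True, date(2011, 5, 1))

    def test_criteria_met_rule_dates_at_second_low_code(self, codelist, window):
        events = [
            make_event("p", "PRIMARY", "READ", "LOW1.", "2011-05-01"),
            make_event("p", "PRIMARY", "READ", "LOW2.", "2012-01-01"),
        ]
        ok, d = ascertain_primary(events, codelist, window, first_date_rule="criteria_met")
        assert (ok, d) == (True, date(2012, 1, 1))

    def test_low_then_high_dates_at_earliest_code(self, codelist, window):
        events = [
            make_event("p", "PRIMARY", "READ", "LOW1.", "2009-01-01"),
            make_event("p", "PRIMARY", "READ", "Eu00.", "2013-01-01"),
        ]
        assert ascertain_primary(events, codelist, window) == (True, date(2009, 1, 1))
        ok, d = ascertain_primary(events, codelist, window, first_date_rule="criteria_met")
        assert (ok, d) == (True, date(2013, 1, 1))

    def test_out_of_window_and_unknown_codes_ignored(self, codelist, window):
        events = [
            make_event("p", "PRIMARY", "READ", "Eu02.", "2006-12-31"),
            make_event("p", "PRIMARY", "READ", "Eu02.", "2019-06-01"),
            make_event("p", "PRIMARY", "READ", "NOTLISTED", "2010-01-01"),
        ]
        assert ascertain_primary(events, codelist, window) == (False, None)

    def test_window_boundaries_inclusive(self, codelist, window):
        for d in ("2007-01-01", "2019-05-31"):
            events = [make_event("p", "PRIMARY", "READ", "Eu02.", d)]
            assert ascertain_primary(events, codelist, window)[0] is True


class TestSpecialistAscertainment:
    def test_one_icd_code_qualifies(self, codelist, window):
        events = [make_event("p", "SPECIALIST", "ICD10", "F03", "2013-06-10")]
        assert ascertain_specialist(events, codelist, window) == (True, date(2013, 6, 10))

    def test_no_dementia_codes(self, codelist, window):
        assert ascertain_specialist([], codelist, window) == (False, None)

    def test_first_date_is_min_regardless_of_order(self, codelist, window):
        events = [
            make_event("p", "SPECIALIST", "ICD10", "F01", "2014-02-01"),
            make_event("p", "SPECIALIST", "ICD10", "F00", "2012-08-15"),
        ]
        assert ascertain_specialist(events, codelist, window)[1] == date(2012, 8, 15)


class TestCombineAndGate:
    def test_age_eligible(self, window):
        pat = Patient("p", 1940)
        res = combine_and_gate((True, date(2010, 7, 1)), (False, None), pat, window)
        assert res.age_at_first == 70 and res.eligible

    def test_under_age_excluded(self, window):
        pat = Patient("p", 1950)
        res = combine_and_gate((True, date(2010, 7, 1)), (False, None), pat, window)
        assert res.age_at_first == 60 and not res.eligible

    def test_combined_first_date_is_min(self, window):
        pat = Patient("p", 1930)
        res = combine_and_gate(
            (True, date(2012, 1, 1)), (True, date(2010, 1, 1)), pat, window
        )
        assert res.first_date_combined == date(2010, 1, 1)
        assert res.stratum.value == "BOTH"

    def test_missing_yob_warns_and_excludes(self, window):
        pat = Patient("p", None)
        with pytest.warns(UserWarning, match="year of birth"):
            res = combine_and_gate((True, date(2010, 1, 1)), (False, None), pat, window)
        assert not res.eligible and res.age_at_first is None


def _micro_cohort(rng, codelist, window, n_patients=None):
    """Random micro-cohort stressing boundaries, duplicates and unknown codes."""
    pool = [
        ("PRIMARY", "READ", "Eu02."),
        ("PRIMARY", "READ", "Eu00."),
        ("PRIMARY", "READ", "LOW1."),
        ("PRIMARY", "READ", "LOW2."),
        ("PRIMARY", "SNOMED", "111000"),
        ("PRIMARY", "READ", "JUNK1"),
        ("SPECIALIST", "ICD10", "F00"),
        ("SPECIALIST", "ICD10", "F03"),
        ("SPECIALIST", "ICD10", "X99"),
    ]
    boundary_dates = [
        window.start - timedelta(days=1),
        window.start,
        window.end,
        window.end + timedelta(days=1),
    ]
    n = n_patients or rng.integers(1, 9)
    patients, events = [], []
    for i in range(n):
        pid = f"p{i}"
        yob = int(rng.choice([1915, 1938, 1949, 1952]))
        patients.append(Patient(pid, yob))
        for _ in range(rng.integers(0, 7)):
            src, term, code = pool[rng.integers(0, len(pool))]
            if rng.random() < 0.25:
                d = boundary_dates[rng.integers(0, 4)]
            else:
                d = window.start + timedelta(days=int(rng.integers(0, 4535)))
            events.append(make_event(pid, src, term, code, d))
        if rng.random() < 0.2 and events:  # exact duplicate row
            events.append(events[-1])
    return patients, events


@pytest.mark.parametrize("first_date_rule", ["earliest_code", "criteria_met"])
def test_engine_matches_bruteforce_oracle(codelist, window, first_date_rule):
    """Vectorised engine equals the verbatim-criteria oracle on random micro-cohorts."""
    rng = np.random.default_rng(20107)
    for _ in range(60):
        patients, events = _micro_cohort(rng, codelist, window)
        pats_df = pd.DataFrame(
            {"patient_id": [p.patient_id for p in patients], "year_of_birth": [p.year_of_birth for p in patients]}
        )
        got = build_cohort(
            pats_df, events_frame(events), codelist, window,
            first_date_rule=first_date_rule, keep_ineligible=True,
        ).set_index("patient_id")
        for pat in patients:
            want = oracle_patient(
                pat,
                [e for e in events if e.patient_id == pat.patient_id],
                codelist,
                window,
                first_date_rule,
            )
            row = got.loc[pat.patient_id]
            assert bool(row["in_primary"]) == want["in_primary"]
            assert bool(row["in_specialist"]) == want["in_specialist"]
            assert row["stratum"] == want["stratum"]
            assert bool(row["eligible"]) == want["eligible"]
            for col in ("first_date_primary", "first_date_specialist", "first_date_combined"):
                expect = want[col]
                if expect is None:
                    assert pd.isna(row[col])
                else:
                    assert pd.Timestamp(row[col]).date() == expect


def test_order_invariance_and_monotonicity(codelist, window):
    rng = np.random.default_rng(99)
    patients, events = _micro_cohort(rng, codelist, window, n_patients=8)
    pats_df = pd.DataFrame(
        {"patient_id": [p.patient_id for p in patients], "year_of_birth": [p.year_of_birth for p in patients]}
    )
    base = build_cohort(pats_df, events_frame(events), codelist, window, keep_ineligible=True)
    shuffled = events_frame(events).sample(frac=1.0, random_state=3).reset_index(drop=True)
    assert build_cohort(pats_df, shuffled, codelist, window, keep_ineligible=True).equals(base)

    # adding a dementia event never removes anyone and never delays first dates
    extra = events + [make_event("p0", "SPECIALIST", "ICD10", "F00", "2008-02-01")]
    grown = build_cohort(pats_df, events_frame(extra), codelist, window, keep_ineligible=True)
    before = set(base[base["eligible"]]["patient_id"])
    after = set(grown[grown["eligible"]]["patient_id"])
    assert before <= after | {"p0"}
    merged = base.merge(grown, on="patient_id", suffixes=("_a", "_b"))
    both_dated = merged.dropna(subset=["first_date_combined_a", "first_date_combined_b"])
    assert (both_dated["first_date_combined_b"] <= both_dated["first_date_combined_a"]).all()


def test_strata_partition_identity(codelist, window):
    rng = np.random.default_rng(5)
    patients, events = _micro_cohort(rng, codelist, window, n_patients=20)
    pats_df = pd.DataFrame(
        {"patient_id": [p.patient_id for p in patients], "year_of_birth": [p.year_of_birth for p in patients]}
    )
    cohort = build_cohort(pats_df, events_frame(events), codelist, window)
    counts = cohort["stratum"].value_counts()
    n_both = counts.get("BOTH", 0)
    assert n_both + counts.get("SPECIALIST_ONLY", 0) + counts.get("PRIMARY_ONLY", 0) == len(cohort)
    assert n_both + counts.get("PRIMARY_ONLY", 0) == int(cohort["in_primary"].sum())
    assert n_both + counts.get("SPECIALIST_ONLY", 0) == int(cohort["in_specialist"].sum())


def test_empty_event_table_gives_empty_cohort(codelist, window):
    pats = pd.DataFrame({"patient_id": ["a", "b"], "year_of_birth": [1940, 1930]})
    empty = pd.DataFrame(columns=["patient_id", "source", "terminology", "code", "event_date"])
    assert build_cohort(pats, empty, codelist, window).empty


def test_unknown_patient_events_dropped_with_warning(codelist, window):
    pats = pd.DataFrame({"patient_id": ["a"], "year_of_birth": [1940]})
    events = events_frame(
        [
            make_event("a", "PRIMARY", "READ", "Eu02.", "2010-01-01"),
            make_event("ghost", "PRIMARY", "READ", "Eu02.", "2010-01-01"),
        ]
    )
    with pytest.warns(UserWarning, match="unknown patient_id"):
        cohort = build_cohort(pats, events, codelist, window)
    assert list(cohort["patient_id"]) == ["a"]


class TestRestrictions:
    @pytest.fixture()
    def cohort_and_inputs(self, codelist, window):
        pats = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c"],
                "year_of_birth": [1935, 1936, 1937],
                "lambeth_resident": [True, False, True],
            }
        )
        events = events_frame(
            [
                make_event("a", "PRIMARY", "READ", "Eu02.", "2010-01-01"),
                make_event("b", "PRIMARY", "READ", "Eu02.", "2015-12-31"),
                make_event("c", "SPECIALIST", "ICD10", "F03", "2016-02-01"),
            ]
        )
        cons = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c"],
                "date": [pd.Timestamp("2009-02-01"), pd.Timestamp("2012-01-01"), pd.Timestamp("2016-01-15")],
                "mode": ["TELEPHONE", "FACE_TO_FACE", "OTHER"],
                "care_home": [True, False, False],
            }
        )
        return build_cohort(pats, events, codelist, window), pats, cons

    def test_none_is_identity(self, cohort_and_inputs):
        cohort, pats, cons = cohort_and_inputs
        assert apply_restrictions(cohort, pats, cons, "NONE").equals(cohort)

    def test_residence_keeps_residents(self, cohort_and_inputs):
        cohort, pats, cons = cohort_and_inputs
        kept = apply_restrictions(cohort, pats, cons, RestrictionMode.RESIDENCE)
        assert set(kept["patient_id"]) == {"a", "c"}

    def test_prior_consultation_counts_care_home_telephone(self, cohort_and_inputs):
        cohort, pats, cons = cohort_and_inputs
        kept = apply_restrictions(cohort, pats, cons, "PRIOR_CONSULTATION")
        # a: telephone (care-home flagged) 11 months before index -> kept
        # b: consultation > 2 years before index; c: OTHER mode -> dropped
        assert set(kept["patient_id"]) == {"a"}

    def test_pre2016_drops_late_first_documentation(self, cohort_and_inputs):
        cohort, pats, cons = cohort_and_inputs
        kept = apply_restrictions(cohort, pats, cons, "PRE2016")
        assert set(kept["patient_id"]) == {"a", "b"}

    def test_unknown_mode_fatal(self, cohort_and_inputs):
        cohort, pats, cons = cohort_and_inputs
        with pytest.raises(ValueError):
            apply_restrictions(cohort, pats, cons, "BOGUS")
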