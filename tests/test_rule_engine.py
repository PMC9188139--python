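"""Inclusion paths, exclusions, control criteria, and status assignment."""

import datetime as dt
import itertools

import pytest

from adhdpheno.config import default_config
from adhdpheno.model import DiagnosisEvent
from adhdpheno.rule_engine import (
    assign_status,
    count_distinct_days,
    evaluate_adhd,
    evaluate_case_exclusion,
    evaluate_comorbidity,
    evaluate_control,
)
from adhdpheno.text_mining import find_keyword_hits

from _helpers import make_cohort, random_micro_cohort
from _oracles import bf_status

CFG = default_config()


def _hits(record):
    hits = []
    for note in record.notes:
        for cid in CFG.condition_ids:
            hits.extend(find_keyword_hits(note, CFG.rules[cid], CFG.therapy_keywords))
    return hits


def decide(cohort, pid, cid):
    record = cohort.record(pid)
    rule = CFG.rules[cid]
    if cid == "ADHD":
        return evaluate_adhd(record, rule, _hits(record))
    return evaluate_comorbidity(record, rule, _hits(record))


# -- count_distinct_days ----------------------------------------------------

def test_count_distinct_days_collapses_duplicates():
    evs = [DiagnosisEvent("P", dt.date(2015, 3, 1), "ICD9", "314.01"),
           DiagnosisEvent("P", dt.date(2015, 3, 1), "ICD9", "314.00"),
           DiagnosisEvent("P", dt.date(2015, 3, 9), "ICD9", "314.01")]
    assert count_distinct_days(evs) == 2
    assert count_distinct_days([]) == 0
    assert count_distinct_days([dt.date(2015, 1, i) for i in range(1, 6)]) == 5


# -- ADHD paths -------------------------------------------------------------

def test_adhd_two_diagnosis_days():
    c = make_cohort([("P1", "2008-01-15")],
                    diagnoses=[("P1", "2014-02-03", "ICD9", "314.01"),
                               ("P1", "2014-06-01", "ICD9", "314.01")])
    d = decide(c, "P1", "ADHD")
    assert d.is_case and d.qualifying_path == "two_dx_days"


def test_adhd_same_day_dx_and_med_insufficient():
    c = make_cohort([("P1", "2008-01-15")],
                    diagnoses=[("P1", "2014-02-03", "ICD9", "314.01")],
                    medications=[("P1", "2014-02-03", "methylphenidate", "cns stimulants")])
    assert not decide(c, "P1", "ADHD").is_case


def test_adhd_dx_and_med_on_separate_days():
    c = make_cohort([("P1", "2008-01-15")],
                    diagnoses=[("P1", "2014-02-03", "ICD9", "314.01")],
                    medications=[("P1", "2014-02-04", "methylphenidate", "cns stimulants")])
    d = decide(c, "P1", "ADHD")
    assert d.is_case and d.qualifying_path == "dx_plus_med_separate_days"


def test_adhd_excluded_drug_class_never_counts():
    c = make_cohort([("P1", "2008-01-15")],
                    medications=[("P1", f"2014-02-0{i}", "clonidine", "cardiovascular agents")
                                 for i in (1, 3, 5)])
    assert not decide(c, "P1", "ADHD").is_case


def test_adhd_diagnosis_before_age_four_does_not_count():
    # first code at 3y10m is discarded; one countable day is not enough
    c = make_cohort([("P1", "2008-06-01")],
                    diagnoses=[("P1", "2012-04-01", "ICD9", "314.01"),
                               ("P1", "2013-07-01", "ICD9", "314.01")])
    d = decide(c, "P1", "ADHD")
    assert not d.is_case
    assert d.dx_days == [dt.date(2013, 7, 1)]


def test_adhd_medication_only_record_qualifies():
    c = make_cohort([("P1", "2008-01-15")],
                    medications=[("P1", "2014-02-03", "methylphenidate", "cns stimulants"),
                                 ("P1", "2014-05-07", "methylphenidate", "cns stimulants")])
    d = decide(c, "P1", "ADHD")
    assert d.is_case and d.qualifying_path == "two_med_days"


def test_adhd_abstraction_paths():
    base = [("P1", "2008-01-15")]
    med = [("P1", "2014-02-03", "methylphenidate", "cns stimulants")]
    note = [("P1", "2014-03-01", "assessment consistent with adhd")]
    d = decide(make_cohort(base, medications=med, notes=note), "P1", "ADHD")
    assert d.is_case and d.qualifying_path == "med_plus_abstraction"
    dx = [("P1", "2014-02-03", "ICD10", "F90.0")]
    d = decide(make_cohort(base, diagnoses=dx, notes=note), "P1", "ADHD")
    assert d.is_case and d.qualifying_path == "dx_plus_abstraction"


# -- comorbidity criteria ---------------------------------------------------

def test_depression_gap_inside_window():
    c = make_cohort([("P1", "2005-01-15")],
                    diagnoses=[("P1", "2016-01-01", "ICD9", "296.20"),
                               ("P1", "2016-02-15", "ICD9", "296.20")])
    assert decide(c, "P1", "major_depression").is_case  # 45-day gap


def test_depression_gap_below_window():
    c = make_cohort([("P1", "2005-01-15")],
                    diagnoses=[("P1", "2016-01-01", "ICD9", "296.20"),
                               ("P1", "2016-01-15", "ICD9", "296.20")])
    assert not decide(c, "P1", "major_depression").is_case  # 14-day gap


def test_depression_any_pair_may_satisfy_window():
    days = ["2016-01-01", "2016-01-10", "2016-05-01"]
    c = make_cohort([("P1", "2005-01-15")],
                    diagnoses=[("P1", day, "ICD9", "296.20") for day in days])
    d = decide(c, "P1", "major_depression")
    assert d.is_case
    # brute-force pair oracle
    dates = [dt.date.fromisoformat(x) for x in days]
    gaps = [abs((a - b).days) for a, b in itertools.combinations(dates, 2)]
    assert any(30 <= g <= 180 for g in gaps)


def test_anxiety_benzodiazepines_never_count():
    c = make_cohort([("P1", "2005-01-15")],
                    medications=[("P1", f"2016-0{i}-01", "lorazepam", "benzodiazepines")
                                 for i in (1, 2, 3)])
    assert not decide(c, "P1", "anxiety").is_case


def test_anxiety_medication_path():
    c = make_cohort([("P1", "2005-01-15")],
                    medications=[("P1", "2016-01-01", "sertraline", "psychotherapeutic agents"),
                                 ("P1", "2016-03-01", "sertraline", "psychotherapeutic agents")])
    d = decide(c, "P1", "anxiety")
    assert d.is_case and d.qualifying_path == "two_med_days"


def test_autism_two_visit_days():
    c = make_cohort([("P1", "2005-01-15")],
                    diagnoses=[("P1", "2015-03-01", "ICD10", "F84.0"),
                               ("P1", "2015-03-01", "ICD9", "299.00"),
                               ("P1", "2016-03-01", "ICD10", "F84.0")])
    assert decide(c, "P1", "autism").is_case


# -- exclusions and controls ------------------------------------------------

def test_exclusionary_code_overrides_case():
    c = make_cohort([("P1", "2008-01-15")],
                    diagnoses=[("P1", "2014-02-03", "ICD9", "314.01"),
                               ("P1", "2014-06-01", "ICD9", "314.01"),
                               ("P1", "2015-01-01", "ICD9", "191.9")])
    excluded, reasons = evaluate_case_exclusion(c.record("P1"), CFG.case_exclusion)
    assert excluded and reasons == ["191"]  # normalized prefix form
    statuses = assign_status(c, CFG)
    row = statuses.iloc[0]
    assert row["status"] == "excluded" and not row["adhd"]


def test_no_excluded_codes_empty_reasons():
    c = make_cohort([("P1", "2008-01-15")],
                    diagnoses=[("P1", "2014-02-03", "ICD9", "314.01")])
    excluded, reasons = evaluate_case_exclusion(c.record("P1"), CFG.case_exclusion)
    assert not excluded and reasons == []


def test_two_excluded_codes_two_reasons():
    c = make_cohort([("P1", "2008-01-15")],
                    diagnoses=[("P1", "2014-02-03", "ICD9", "191.9"),
                               ("P1", "2014-06-01", "ICD10", "S06.9")])
    excluded, reasons = evaluate_case_exclusion(c.record("P1"), CFG.case_exclusion)
    assert excluded and len(reasons) == 2


@pytest.mark.parametrize(
    "birth,events,expected",
    [
        ("2007-06-01", (), True),                                        # age 9, clean
        ("2009-06-01", (), False),                                       # age 7, clean
        ("2006-06-01", (("P1", "2015-01-01", "ICD9", "315.1"),), True),  # LD allowed
        ("2004-06-01", (("P1", "2015-01-01", "ICD9", "300.00"),), False),  # anxiety mention
    ],
)
def test_control_criteria(birth, events, expected):
    c = make_cohort([("P1", birth)], diagnoses=list(events))
    assert evaluate_control(c.record("P1"), CFG.control_exclusion) is expected


def test_control_mention_in_note_disqualifies():
    c = make_cohort([("P1", "2005-06-01")],
                    notes=[("P1", "2015-01-01", "patient does not have adhd")])
    assert not evaluate_control(c.record("P1"), CFG.control_exclusion)


# -- status assignment ------------------------------------------------------

def test_three_patient_fixture_statuses():
    c = make_cohort(
        [("CASE", "2008-01-15"), ("CTRL", "2006-05-02"), ("YOUNG", "2011-08-09")],
        diagnoses=[("CASE", "2014-02-03", "ICD9", "314.01"),
                   ("CASE", "2014-06-01", "ICD9", "314.01")],
    )
    statuses = assign_status(c, CFG).set_index("patient_id")
    assert statuses.loc["CASE", "status"] == "case"
    assert statuses.loc["CTRL", "status"] == "control"
    assert statuses.loc["YOUNG", "status"] == "excluded"


def test_anxiety_only_case_has_adhd_false():
    c = make_cohort([("P1", "2005-01-15")],
                    diagnoses=[("P1", "2015-01-01", "ICD9", "300.00"),
                               ("P1", "2015-06-01", "ICD9", "300.00")])
    row = assign_status(c, CFG).iloc[0]
    assert row["status"] == "case" and row["anxiety"] and not row["adhd"]
    assert not row["comorbid_adhd"]


def test_adhd_plus_autism_is_comorbid():
    c = make_cohort([("P1", "2005-01-15")],
                    diagnoses=[("P1", "2014-02-03", "ICD9", "314.01"),
                               ("P1", "2014-06-01", "ICD9", "314.01"),
                               ("P1", "2015-03-01", "ICD10", "F84.0"),
                               ("P1", "2016-03-01", "ICD10", "F84.0")])
    row = assign_status(c, CFG).iloc[0]
    assert row["status"] == "case" and row["adhd"] and row["autism"]
    assert row["comorbid_adhd"]


# -- properties on random micro-cohorts ------------------------------------

def test_partition_identity_random_cohorts():
    for seed in (1, 2, 3):
        cohort = random_micro_cohort(120, seed)
        statuses = assign_status(cohort, CFG)
        counts = statuses["status"].value_counts()
        assert counts.sum() == len(cohort)
        assert set(statuses["status"]).issubset({"case", "control", "excluded"})
        # a case has >=1 flag, a control none
        cases = statuses[statuses["status"] == "case"]
        controls = statuses[statuses["status"] == "control"]
        conds = CFG.condition_ids
        assert cases[conds].any(axis=1).all()
        assert not controls[conds].any(axis=1).any()


def test_exclusion_precedence_is_absolute():
    """Adding an exclusionary code never creates a case or control."""
    cohort = random_micro_cohort(80, 4)
    extra = [(pid, "2016-06-01", "ICD9", "191.9") for pid in cohort.patient_ids]
    poisoned = make_cohort(
        [(r.patient_id, r.birth_date.isoformat(), r.sex) for r in cohort.patients.itertuples()],
        diagnoses=[(t.patient_id, t.event_date.isoformat(), t.code_system, t.code)
                   for t in cohort.diagnoses.itertuples()] + extra,
        medications=[(t.patient_id, t.event_date.isoformat(), t.drug_name, t.drug_class)
                     for t in cohort.medications.itertuples()],
        notes=[(t.patient_id, t.event_date.isoformat(), t.text)
               for t in cohort.notes.itertuples()],
    )
    statuses = assign_status(poisoned, CFG)
    assert (statuses["status"] == "excluded").all()


def test_monotonicity_of_qualifying_evidence():
    """Adding a qualifying diagnosis day never flips a case to non-case."""
    cohort = random_micro_cohort(80, 5)
    before = assign_status(cohort, CFG).set_index("patient_id")
    extra = [(pid, "2016-06-02", "ICD9", "314.01") for pid in cohort.patient_ids]
    boosted = make_cohort(
        [(r.patient_id, r.birth_date.isoformat(), r.sex) for r in cohort.patients.itertuples()],
        diagnoses=[(t.patient_id, t.event_date.isoformat(), t.code_system, t.code)
                   for t in cohort.diagnoses.itertuples()] + extra,
        medications=[(t.patient_id, t.event_date.isoformat(), t.drug_name, t.drug_class)
                     for t in cohort.medications.itertuples()],
        notes=[(t.patient_id, t.event_date.isoformat(), t.text)
               for t in cohort.notes.itertuples()],
    )
    after = assign_status(boosted, CFG).set_index("patient_id")
    was_case = before.index[before["status"] == "case"]
    assert (after.loc[was_case, "status"] == "case").all()


def test_engine_matches_brute_force_small():
    """Spot check of the subset-enumeration oracle (full run in acceptance)."""
    cohort = random_micro_cohort(150, 6)
    statuses = assign_status(cohort, CFG).set_index("patient_id")
    for pid in cohort.patient_ids[:150]:
        record = cohort.record(pid)
        status, flags = bf_status(record, CFG)
        assert statuses.loc[pid, "status"] == status, pid
        for cid in CFG.condition_ids:
            assert bool(statuses.loc[pid, cid]) == flags[cid], (pid, cid)


def test_gap_window_misconfiguration_rejected():
    from adhdpheno.config import ConditionRule

    with pytest.raises(ValueError):
        ConditionRule(condition_id="bipolar", gap_window_days=(30, 180), min_distinct_days=1)
    with pytest.raises(ValueError):
        ConditionRule(condition_id="bipolar", gap_window_days=(180, 30))
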