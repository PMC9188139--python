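"""Independent brute-force evaluators used as oracles for the rule engine.

These enumerate event subsets and paths literally (itertools over event
pairs), sharing no code with the engine's set-based evaluation.
"""

from __future__ import annotations

import datetime as dt
import itertools
import re

from adhdpheno.codes import normalize_code, normalize_prefix
from adhdpheno.config import PhenotypeConfig
from adhdpheno.model import PatientRecord


def _age_completed_years(birth: dt.date, on: dt.date) -> int:
    years = on.year - birth.year
    if (on.month, on.day) < (birth.month, birth.day):
        years -= 1
    return years


def _matches(code: str, prefixes) -> bool:
    n = normalize_code(code)
    return any(n.startswith(normalize_prefix(p)) for p in prefixes)


def _keyword_in(text: str, term: str) -> bool:
    return re.search(r"(?<!\w)" + re.escape(term) + r"(?!\w)", text or "",
                     re.IGNORECASE) is not None


def bf_condition_hits(record: PatientRecord, rule) -> set[str]:
    """Abstraction hit kinds for one condition, recomputed from raw notes."""
    kinds = set()
    for note in record.notes:
        for term in rule.phenotype_keywords:
            if _keyword_in(note.text, term):
                kinds.add("phenotype")
        for term in rule.medication_names:
            if _keyword_in(note.text, term):
                kinds.add("medication")
    return kinds


def bf_is_case(record: PatientRecord, rule, excluded_classes=("cardiovascular agents", "analgesics")) -> bool:
    """Brute-force qualification: enumerate all event pairs/subsets per path."""
    prefixes = rule.icd9_prefixes + rule.icd10_prefixes
    dx = []
    for ev in record.diagnoses:
        if not _matches(ev.code, prefixes):
            continue
        if rule.min_age_years_at_event is not None:
            if _age_completed_years(record.patient.birth_date, ev.event_date) < rule.min_age_years_at_event:
                continue
        dx.append(ev)
    meds = [
        ev for ev in record.medications
        if ev.drug_name in rule.medication_names
        and ev.drug_name not in rule.excluded_medication_names
        and ev.drug_class not in excluded_classes
    ]
    has_abs = bool(bf_condition_hits(record, rule))

    # path 1: a subset of min_distinct_days diagnosis events on pairwise
    # distinct days (with a gap-window pair when required)
    if rule.gap_window_days is None:
        for combo in itertools.combinations(dx, rule.min_distinct_days):
            if len({e.event_date for e in combo}) == rule.min_distinct_days:
                return True
    else:
        lo, hi = rule.gap_window_days
        enough_days = False
        for combo in itertools.combinations(dx, rule.min_distinct_days):
            if len({e.event_date for e in combo}) == rule.min_distinct_days:
                enough_days = True
        if enough_days:
            for e1, e2 in itertools.combinations(dx, 2):
                gap = abs((e1.event_date - e2.event_date).days)
                if gap and lo <= gap <= hi:
                    return True
    # paths 2-3 (medication criterion)
    if rule.medication_criterion_enabled:
        for e1, e2 in itertools.combinations(meds, 2):
            if e1.event_date != e2.event_date:
                return True
        for e1 in dx:
            for e2 in meds:
                if e1.event_date != e2.event_date:
                    return True
    # paths 4-5 (abstraction)
    if meds and has_abs:
        return True
    if dx and has_abs:
        return True
    return False


def bf_case_excluded(record: PatientRecord, exclusion) -> bool:
    prefixes = exclusion.excluded_icd9_prefixes + exclusion.excluded_icd10_prefixes
    return any(_matches(ev.code, prefixes) for ev in record.diagnoses)


def bf_is_control(record: PatientRecord, control) -> bool:
    min_age = control.min_age_years if control.min_age_years is not None else 8
    if _age_completed_years(record.patient.birth_date, record.patient.extraction_date) < min_age:
        return False
    prefixes = control.excluded_icd9_prefixes + control.excluded_icd10_prefixes
    if any(_matches(ev.code, prefixes) for ev in record.diagnoses):
        return False
    for ev in record.medications:
        if ev.drug_name in control.excluded_medication_names:
            return False
        if ev.drug_class in control.excluded_drug_classes:
            return False
    for note in record.notes:
        if any(_keyword_in(note.text, term) for term in control.excluded_keywords):
            return False
    return True


def bf_status(record: PatientRecord, config: PhenotypeConfig) -> tuple[str, dict[str, bool]]:
    """Full status assembly: flags, exclusion precedence, control check."""
    excluded_classes = tuple(config.case_exclusion.excluded_drug_classes)
    flags = {
        cid: bf_is_case(record, config.rules[cid], excluded_classes)
        for cid in config.condition_ids
    }
    if config.tourette_counts_as_tic and flags.get("tourette"):
        flags["tic_disorder"] = True
    if any(flags.values()):
        if bf_case_excluded(record, config.case_exclusion):
            return "excluded", {c: False for c in flags}
        return "case", flags
    if bf_is_control(record, config.control_exclusion):
        return "control", flags
    return "excluded", {c: False for c in flags}
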