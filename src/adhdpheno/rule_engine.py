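"""Per-condition inclusion criteria, case exclusions, and control selection.

Case qualification is multi-source: a patient qualifies for a condition when
any of five evidence paths holds, each requiring more than one "hit" across
distinct calendar days so that a single stray code or order cannot create a
case.  The paths, in reporting order:

1. ``two_dx_days``                — >= *min_distinct_days* distinct diagnosis
   days (subject to the 30–180-day pair window where configured);
2. ``two_med_days``               — >= 2 distinct qualifying medication days;
3. ``dx_plus_med_separate_days``  — >= 1 diagnosis day and >= 1 medication day
   on different calendar days;
4. ``med_plus_abstraction``       — >= 1 medication day plus an abstraction hit;
5. ``dx_plus_abstraction``        — >= 1 diagnosis day plus an abstraction hit.

Paths 2–3 require the condition's medication criterion to be enabled
(ADHD, anxiety, schizophrenia, bipolar).  Medication orders filed under an
excluded pharmacologic class ("cardiovascular agents", "analgesics") or an
excluded drug list (benzodiazepines for anxiety) never count, per event.
Case exclusion (etiologically distinct diagnoses) takes precedence over any
qualification.  Controls are subjects aged >= 8 with no psychiatric or
neurological codes, medications, or mentions; learning-disability and
mild/moderate intellectual-disability codes do not disqualify a control.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .codes import normalize_prefix
from .config import ConditionRule, ExclusionRule, PhenotypeConfig
from .model import Cohort, PatientRecord
from .text_mining import find_keyword_hits, scan_notes, AbstractionHit

QUALIFYING_PATHS = (
    "two_dx_days",
    "two_med_days",
    "dx_plus_med_separate_days",
    "med_plus_abstraction",
    "dx_plus_abstraction",
    "none",
)

STATUSES = ("case", "control", "excluded")

#: default per-event pharmacologic-class exclusion applied to medication
#: evidence (clonidine and similar agents ordered for non-psychiatric
#: indications).
DEFAULT_EXCLUDED_DRUG_CLASSES = ("cardiovascular agents", "analgesics")


@dataclass(frozen=True)
class EvidenceChannels:
    """Which evidence sources the engine may use (ablation mask)."""

    diagnoses: bool = True
    medications: bool = True
    note_phenotype: bool = True
    note_medication: bool = True


ALL_CHANNELS = EvidenceChannels()


@dataclass
class PhenotypeDecision:
    """Per-patient, per-condition decision with its evidence trail."""

    patient_id: str
    condition_id: str
    is_case: bool
    qualifying_path: str
    dx_days: list[dt.date] = field(default_factory=list)
    med_days: list[dt.date] = field(default_factory=list)
    abstraction_kinds: list[str] = field(default_factory=list)


def count_distinct_days(events: Iterable) -> int:
    """Number of unique calendar dates in a dated event list.

    Accepts events carrying an ``event_date`` attribute, or plain dates.
    """
    dates = {getattr(e, "event_date", e) for e in events}
    return len(dates)


def _age_years(birth: dt.date, on: dt.date) -> int:
    return on.year - birth.year - ((on.month, on.day) < (birth.month, birth.day))


def _gap_window_satisfied(days: Iterable[dt.date], window: tuple[int, int]) -> bool:
    lo, hi = window
    days = sorted(set(days))
    return any(
        lo <= (days[j] - days[i]).days <= hi
        for i in range(len(days))
        for j in range(i + 1, len(days))
    )


def _decide(
    patient_id: str,
    rule: ConditionRule,
    dx_days: frozenset,
    med_days: frozenset,
    abstraction_kinds: list[str],
    channels: EvidenceChannels = ALL_CHANNELS,
) -> PhenotypeDecision:
    """Evaluate the five paths over pre-extracted qualifying evidence."""
    dx = dx_days if channels.diagnoses else frozenset()
    med = med_days if channels.medications else frozenset()
    has_abs = bool(abstraction_kinds)

    path = "none"
    dx_ok = len(dx) >= rule.min_distinct_days and (
        rule.gap_window_days is None or _gap_window_satisfied(dx, rule.gap_window_days)
    )
    if dx_ok:
        path = "two_dx_days"
    elif rule.medication_criterion_enabled and len(med) >= 2:
        path = "two_med_days"
    elif rule.medication_criterion_enabled and dx and med and len(dx | med) >= 2:
        path = "dx_plus_med_separate_days"
    elif med and has_abs:
        path = "med_plus_abstraction"
    elif dx and has_abs:
        path = "dx_plus_abstraction"

    return PhenotypeDecision(
        patient_id=patient_id,
        condition_id=rule.condition_id,
        is_case=path != "none",
        qualifying_path=path,
        dx_days=sorted(dx),
        med_days=sorted(med),
        abstraction_kinds=abstraction_kinds if path.endswith("abstraction") else [],
    )


# --------------------------------------------------------------------------
# per-patient operations (record-level API)


def _record_dx_days(record: PatientRecord, rule: ConditionRule) -> frozenset:
    prefixes = tuple(rule.all_prefixes)
    days = set()
    for ev in record.diagnoses:
        if not ev.code.startswith(prefixes):
            continue
        if rule.min_age_years_at_event is not None:
            if record.patient.birth_date is None:
                raise ValueError(f"{record.patient.patient_id}: birth_date required for age check")
            if _age_years(record.patient.birth_date, ev.event_date) < rule.min_age_years_at_event:
                continue
        days.add(ev.event_date)
    return frozenset(days)


def _record_med_days(
    record: PatientRecord,
    rule: ConditionRule,
    excluded_drug_classes: Iterable[str],
) -> frozenset:
    allowed = set(rule.medication_names) - set(rule.excluded_medication_names)
    excluded_classes = {c.lower() for c in excluded_drug_classes}
    return frozenset(
        ev.event_date
        for ev in record.medications
        if ev.drug_name in allowed and ev.drug_class not in excluded_classes
    )


def _hit_kinds(abstraction_hits: Iterable[AbstractionHit], condition_id: str) -> list[str]:
    kinds = sorted(
        {h.hit_kind for h in abstraction_hits
         if h.condition_id == condition_id and h.hit_kind in ("phenotype", "medication")}
    )
    return kinds


def evaluate_adhd(
    record: PatientRecord,
    rule: ConditionRule,
    abstraction_hits: Iterable[AbstractionHit] = (),
    excluded_drug_classes: Iterable[str] = DEFAULT_EXCLUDED_DRUG_CLASSES,
    channels: EvidenceChannels = ALL_CHANNELS,
) -> PhenotypeDecision:
    """Evaluate ADHD qualification for one patient.

    Diagnosis events before the patient's fourth birthday do not count
    (``rule.min_age_years_at_event``); medication orders filed under an
    excluded pharmacologic class do not count.
    """
    if record.patient.birth_date is None:
        raise ValueError("birth_date required to apply the minimum-age criterion")
    dx = _record_dx_days(record, rule)
    med = _record_med_days(record, rule, excluded_drug_classes)
    kinds = _mask_kinds(_hit_kinds(abstraction_hits, rule.condition_id), channels)
    return _decide(record.patient.patient_id, rule, dx, med, kinds, channels)


def evaluate_comorbidity(
    record: PatientRecord,
    rule: ConditionRule,
    abstraction_hits: Iterable[AbstractionHit] = (),
    excluded_drug_classes: Iterable[str] = DEFAULT_EXCLUDED_DRUG_CLASSES,
    channels: EvidenceChannels = ALL_CHANNELS,
) -> PhenotypeDecision:
    """Evaluate one non-ADHD condition for one patient."""
    dx = _record_dx_days(record, rule)
    med = _record_med_days(record, rule, excluded_drug_classes)
    kinds = _mask_kinds(_hit_kinds(abstraction_hits, rule.condition_id), channels)
    return _decide(record.patient.patient_id, rule, dx, med, kinds, channels)


def _mask_kinds(kinds: list[str], channels: EvidenceChannels) -> list[str]:
    out = []
    if channels.note_phenotype and "phenotype" in kinds:
        out.append("phenotype")
    if channels.note_medication and "medication" in kinds:
        out.append("medication")
    return out


def evaluate_case_exclusion(
    record: PatientRecord, exclusion: ExclusionRule
) -> tuple[bool, list[str]]:
    """Check the case-level exclusionary-diagnosis rule for one patient.

    Returns ``(excluded, reasons)`` where reasons lists every matched
    exclusion prefix (distinct, sorted).
    """
    reasons = sorted(
        {p for p in exclusion.all_prefixes
         for ev in record.diagnoses if ev.code.startswith(p)}
    )
    return bool(reasons), reasons


def evaluate_control(record: PatientRecord, control_rule: ExclusionRule) -> bool:
    """True if the patient qualifies as a psychiatric-negative control.

    Age at the record's extraction date must be at least
    ``control_rule.min_age_years`` (8 by default); no diagnosis may match a
    control-exclusion prefix, no medication may be in the excluded
    psychiatric/neurological medication union or an excluded drug class, and
    no note may mention an excluded keyword.
    """
    min_age = control_rule.min_age_years if control_rule.min_age_years is not None else 8
    if _age_years(record.patient.birth_date, record.patient.extraction_date) < min_age:
        return False
    prefixes = tuple(control_rule.all_prefixes)
    if prefixes and any(ev.code.startswith(prefixes) for ev in record.diagnoses):
        return False
    excluded_names = set(control_rule.excluded_medication_names)
    excluded_classes = set(control_rule.excluded_drug_classes)
    for ev in record.medications:
        if ev.drug_name in excluded_names or ev.drug_class in excluded_classes:
            return False
    if control_rule.excluded_keywords:
        probe = ConditionRule(condition_id="ADHD",
                              phenotype_keywords=control_rule.excluded_keywords)
        for note in record.notes:
            if find_keyword_hits(note, probe):
                return False
    return True


# --------------------------------------------------------------------------
# cohort-level evaluation


@dataclass
class CohortEvidence:
    """Pre-extracted qualifying evidence for a whole cohort.

    Built once; evaluation under different channel masks (ablation) reuses it.
    """

    patient_ids: list[str]
    ages_at_extraction: dict[str, int]
    dx_days: dict[str, dict[str, frozenset]]          # condition -> patient -> dates
    med_days: dict[str, dict[str, frozenset]]
    abs_phenotype: dict[str, set]                     # condition -> patients
    abs_medication: dict[str, set]
    therapy_patients: set
    case_exclusion_reasons: dict[str, list[str]]      # patient -> matched prefixes
    control_flags: dict[str, list[str]]               # patient -> disqualifier tags
    hits: pd.DataFrame


def _event_ages(events: pd.DataFrame, patients: pd.DataFrame) -> pd.Series:
    merged = events.merge(patients[["patient_id", "birth_date"]], on="patient_id", how="left")
    ev = pd.to_datetime(merged["event_date"])
    bd = pd.to_datetime(merged["birth_date"])
    before_birthday = (ev.dt.month < bd.dt.month) | (
        (ev.dt.month == bd.dt.month) & (ev.dt.day < bd.dt.day)
    )
    return (ev.dt.year - bd.dt.year - before_birthday.astype(int)).set_axis(events.index)


def _group_dates(df: pd.DataFrame) -> dict[str, frozenset]:
    if df.empty:
        return {}
    return {
        pid: frozenset(grp)
        for pid, grp in df.groupby("patient_id")["event_date"]
    }


def _keyword_patients(notes: pd.DataFrame, keywords: list[str]) -> set:
    if notes.empty or not keywords:
        return set()
    pattern = re.compile(
        r"(?<!\w)(?:" + "|".join(re.escape(k) for k in keywords) + r")(?!\w)",
        re.IGNORECASE,
    )
    mask = notes["text"].fillna("").map(lambda t: bool(pattern.search(t)))
    return set(notes.loc[mask, "patient_id"])


def build_cohort_evidence(
    cohort: Cohort,
    config: PhenotypeConfig,
    hits: Optional[pd.DataFrame] = None,
) -> CohortEvidence:
    """Extract qualifying evidence for every patient and condition."""
    patients = cohort.patients
    if patients["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in cohort")
    diagnoses = cohort.diagnoses
    medications = cohort.medications

    if hits is None:
        if config.notes_count_as_abstraction and not cohort.notes.empty:
            hits = scan_notes(cohort.notes, config)
        else:
            from .text_mining import HIT_COLUMNS
            hits = pd.DataFrame(columns=HIT_COLUMNS)

    ext = pd.to_datetime(patients["extraction_date"])
    bd = pd.to_datetime(patients["birth_date"])
    before_birthday = (ext.dt.month < bd.dt.month) | (
        (ext.dt.month == bd.dt.month) & (ext.dt.day < bd.dt.day)
    )
    ages = dict(zip(patients["patient_id"],
                    (ext.dt.year - bd.dt.year - before_birthday.astype(int)).astype(int)))

    dx_ages = _event_ages(diagnoses, patients) if not diagnoses.empty else pd.Series(dtype=int)

    excluded_classes = set(config.case_exclusion.excluded_drug_classes)

    dx_days: dict[str, dict[str, frozenset]] = {}
    med_days: dict[str, dict[str, frozenset]] = {}
    abs_phenotype: dict[str, set] = {}
    abs_medication: dict[str, set] = {}
    for cid in config.condition_ids:
        rule = config.rules[cid]
        if diagnoses.empty:
            dx_days[cid] = {}
        else:
            mask = diagnoses["code"].str.startswith(tuple(rule.all_prefixes))
            if rule.min_age_years_at_event is not None:
                mask &= dx_ages >= rule.min_age_years_at_event
            dx_days[cid] = _group_dates(diagnoses[mask])
        if medications.empty or not rule.medication_names:
            med_days[cid] = {}
        else:
            allowed = set(rule.medication_names) - set(rule.excluded_medication_names)
            mmask = medications["drug_name"].isin(allowed) & ~medications["drug_class"].isin(
                excluded_classes
            )
            med_days[cid] = _group_dates(medications[mmask])
        chits = hits[(hits["condition_id"] == cid)]
        abs_phenotype[cid] = set(chits.loc[chits["hit_kind"] == "phenotype", "patient_id"])
        abs_medication[cid] = set(chits.loc[chits["hit_kind"] == "medication", "patient_id"])
    therapy_patients = set(hits.loc[hits["hit_kind"] == "therapy", "patient_id"])

    # case exclusion: record every matched prefix per patient
    case_reasons: dict[str, list[str]] = {}
    if not diagnoses.empty:
        for prefix in config.case_exclusion.all_prefixes:
            hit_pids = diagnoses.loc[diagnoses["code"].str.startswith(prefix), "patient_id"]
            for pid in set(hit_pids):
                case_reasons.setdefault(pid, []).append(prefix)
    for pid in case_reasons:
        case_reasons[pid] = sorted(set(case_reasons[pid]))

    # control disqualifiers
    control = config.control_exclusion
    control_flags: dict[str, list[str]] = {}
    min_age = control.min_age_years if control.min_age_years is not None else 8
    for pid, age in ages.items():
        if age < min_age:
            control_flags.setdefault(pid, []).append("below_control_min_age")
    if not diagnoses.empty and control.all_prefixes:
        flagged = diagnoses.loc[
            diagnoses["code"].str.startswith(tuple(control.all_prefixes)), "patient_id"
        ]
        for pid in set(flagged):
            control_flags.setdefault(pid, []).append("psychiatric_or_excluded_code")
    if not medications.empty:
        mmask = medications["drug_name"].isin(set(control.excluded_medication_names))
        if control.excluded_drug_classes:
            mmask |= medications["drug_class"].isin(set(control.excluded_drug_classes))
        for pid in set(medications.loc[mmask, "patient_id"]):
            control_flags.setdefault(pid, []).append("psychiatric_medication")
    for pid in _keyword_patients(cohort.notes, control.excluded_keywords):
        control_flags.setdefault(pid, []).append("psychiatric_keyword_mention")

    return CohortEvidence(
        patient_ids=patients["patient_id"].tolist(),
        ages_at_extraction=ages,
        dx_days=dx_days,
        med_days=med_days,
        abs_phenotype=abs_phenotype,
        abs_medication=abs_medication,
        therapy_patients=therapy_patients,
        case_exclusion_reasons=case_reasons,
        control_flags=control_flags,
        hits=hits,
    )


_EMPTY: frozenset = frozenset()


def decide_condition(
    evidence: CohortEvidence,
    config: PhenotypeConfig,
    patient_id: str,
    condition_id: str,
    channels: EvidenceChannels = ALL_CHANNELS,
) -> PhenotypeDecision:
    """Evaluate one condition for one patient from pre-built evidence."""
    rule = config.rules[condition_id]
    kinds = []
    if channels.note_phenotype and patient_id in evidence.abs_phenotype[condition_id]:
        kinds.append("phenotype")
    if channels.note_medication and patient_id in evidence.abs_medication[condition_id]:
        kinds.append("medication")
    return _decide(
        patient_id,
        rule,
        evidence.dx_days[condition_id].get(patient_id, _EMPTY),
        evidence.med_days[condition_id].get(patient_id, _EMPTY),
        kinds,
        channels,
    )


def evaluate_cohort(
    evidence: CohortEvidence,
    config: PhenotypeConfig,
    channels: EvidenceChannels = ALL_CHANNELS,
) -> tuple[pd.DataFrame, dict]:
    """Assign case/control/excluded status to every patient.

    Returns ``(statuses, decisions)``: the ``cohort_status`` table, and the
    per-(patient, condition) decision map for conditions the patient
    qualified for (evidence trails).

    Condition flags are reported post-exclusion: a patient removed by a
    case exclusion carries all-false flags and the triggering prefixes in
    ``exclusion_reasons``.
    """
    cids = config.condition_ids
    rows = []
    decisions: dict[tuple[str, str], PhenotypeDecision] = {}
    for pid in evidence.patient_ids:
        flags = {}
        for cid in cids:
            d = decide_condition(evidence, config, pid, cid, channels)
            flags[cid] = d.is_case
            if d.is_case:
                decisions[(pid, cid)] = d
        if config.tourette_counts_as_tic and flags.get("tourette"):
            flags["tic_disorder"] = True
        any_case = any(flags.values())
        excl_reasons = evidence.case_exclusion_reasons.get(pid, [])
        if any_case and excl_reasons:
            status = "excluded"
            flags = {c: False for c in cids}
            reasons = excl_reasons
        elif any_case:
            status = "case"
            reasons = []
        elif not evidence.control_flags.get(pid):
            status = "control"
            reasons = []
        else:
            status = "excluded"
            flags = {c: False for c in cids}
            reasons = evidence.control_flags[pid]
        adhd = flags.get("ADHD", False)
        rows.append(
            {
                "patient_id": pid,
                "status": status,
                "adhd": adhd,
                "comorbid_adhd": adhd and any(flags[c] for c in cids if c != "ADHD"),
                **{c: flags[c] for c in cids},
                "exclusion_reasons": ";".join(reasons),
            }
        )
    statuses = pd.DataFrame(rows)
    return statuses, decisions


def assign_status(
    cohort: Cohort,
    config: PhenotypeConfig,
    hits: Optional[pd.DataFrame] = None,
    channels: EvidenceChannels = ALL_CHANNELS,
    return_decisions: bool = False,
):
    """End-to-end status assignment for a cohort (builds evidence, evaluates).

    Every patient receives exactly one status: ``case`` (at least one
    condition qualification and no case exclusion), ``control``
    (psychiatric-negative, age >= 8), or ``excluded``.
    """
    evidence = build_cohort_evidence(cohort, config, hits)
    statuses, decisions = evaluate_cohort(evidence, config, channels)
    if return_decisions:
        return statuses, decisions
    return statuses
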