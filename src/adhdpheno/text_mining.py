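"""Keyword search over free-text note abstractions.

Deliberately simple matching: case-insensitive whole-phrase hits on word
boundaries, no stemming, no fuzzy matching, and — importantly — no negation
handling.  "patient does not have ADHD" therefore yields an (incorrect)
phenotype hit; the multi-hit inclusion criteria upstream are what compensate
for this known limitation of plain keyword search.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .config import ConditionRule, PhenotypeConfig
from .model import NoteAbstraction

HIT_KINDS = ("phenotype", "medication", "therapy")

HIT_COLUMNS = ["patient_id", "event_date", "hit_kind", "condition_id", "matched_term"]


@dataclass(frozen=True)
class AbstractionHit:
    """One matched term in one note."""

    patient_id: str
    hit_kind: str
    condition_id: Optional[str]  # None for therapy hits
    matched_term: str
    event_date: dt.date


def _phrase_pattern(term: str) -> re.Pattern:
    # word-boundary on both sides of the whole phrase; "ADHDlike" must not
    # match the keyword "adhd".
    return re.compile(r"(?<!\w)" + re.escape(term) + r"(?!\w)", re.IGNORECASE)


def find_keyword_hits(
    note: NoteAbstraction,
    rule: ConditionRule,
    therapy_keywords: Iterable[str] = (),
) -> list[AbstractionHit]:
    """Search one note against one condition's keyword and medication lists.

    Returns at most one hit per (term, note).  Empty note text yields no hits.
    """
    hits: list[AbstractionHit] = []
    text = note.text or ""
    if not text:
        return hits
    for term in rule.phenotype_keywords:
        if _phrase_pattern(term).search(text):
            hits.append(AbstractionHit(note.patient_id, "phenotype", rule.condition_id,
                                       term, note.event_date))
    for term in rule.medication_names:
        if _phrase_pattern(term).search(text):
            hits.append(AbstractionHit(note.patient_id, "medication", rule.condition_id,
                                       term, note.event_date))
    for term in therapy_keywords:
        if _phrase_pattern(term).search(text):
            hits.append(AbstractionHit(note.patient_id, "therapy", None,
                                       term, note.event_date))
    return hits


def scan_notes(notes: pd.DataFrame, config: PhenotypeConfig) -> pd.DataFrame:
    """Run the keyword search over a whole cohort's notes table.

    Returns the ``abstraction_hits`` table
    (``patient_id,event_date,hit_kind,condition_id,matched_term``).
    Therapy hits are deduplicated against the per-condition loop so each
    (note, term) pair appears once.
    """
    rows: list[tuple] = []
    texts = notes["text"].fillna("").tolist()
    pids = notes["patient_id"].tolist()
    dates = notes["event_date"].tolist()

    term_index: list[tuple[re.Pattern, str, str | None, str]] = []
    for cid in config.condition_ids:
        rule = config.rules[cid]
        for term in rule.phenotype_keywords:
            term_index.append((_phrase_pattern(term), "phenotype", cid, term))
        for term in rule.medication_names:
            term_index.append((_phrase_pattern(term), "medication", cid, term))
    for term in config.therapy_keywords:
        term_index.append((_phrase_pattern(term), "therapy", None, term))

    for pid, date, text in zip(pids, dates, texts):
        if not text:
            continue
        for pattern, kind, cid, term in term_index:
            if pattern.search(text):
                rows.append((pid, date, kind, cid, term))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def aggregate_hits(hits: pd.DataFrame, condition_ids: Iterable[str]) -> pd.DataFrame:
    """Per-patient, per-condition OR of hit kinds.

    Returns one row per (patient_id, condition_id) that had any hit, with
    boolean ``has_phenotype_hit``/``has_medication_hit`` columns and a
    per-patient ``has_therapy_hit`` (therapy hits are condition-independent
    and broadcast to every condition row of that patient).
    """
    condition_ids = list(condition_ids)
    if hits.empty:
        return pd.DataFrame(columns=["patient_id", "condition_id", "has_phenotype_hit",
                                     "has_medication_hit", "has_therapy_hit"])
    cond_hits = hits[hits["hit_kind"].isin(["phenotype", "medication"])]
    summary = (
        cond_hits.assign(
            has_phenotype_hit=cond_hits["hit_kind"] == "phenotype",
            has_medication_hit=cond_hits["hit_kind"] == "medication",
        )
        .groupby(["patient_id", "condition_id"], as_index=False)[
            ["has_phenotype_hit", "has_medication_hit"]
        ]
        .any()
    )
    therapy_patients = set(hits.loc[hits["hit_kind"] == "therapy", "patient_id"])
    all_patients = sorted(set(hits["patient_id"]))
    # patients with only therapy hits still need a row for each condition? no:
    # therapy is patient-level; carry it on a per-patient frame instead.
    therapy = pd.DataFrame({
        "patient_id": all_patients,
        "has_therapy_hit": [p in therapy_patients for p in all_patients],
    })
    out = summary.merge(therapy, on="patient_id", how="outer")
    for col in ("has_phenotype_hit", "has_medication_hit", "has_therapy_hit"):
        out[col] = out[col].notna() & out[col].astype("boolean").fillna(False)
    return out
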