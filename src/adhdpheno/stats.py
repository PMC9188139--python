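"""Cohort reporting: status bookkeeping, search-method ablation, and the
ADHD-by-comorbidity table.

Percentages are rounded half-up, matching the convention of printed clinical
tables; the comorbidity table is marginal (a patient appears in every row
they qualify for, and no row conditions on the others).
"""

from __future__ import annotations

import warnings
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional

import pandas as pd

from .config import PhenotypeConfig, COMORBID_CONDITIONS
from .model import Cohort
from .rule_engine import (
    CohortEvidence,
    EvidenceChannels,
    build_cohort_evidence,
    evaluate_cohort,
)

#: evidence-channel masks for the search-method comparison.
ABLATION_MODES: dict[str, EvidenceChannels] = {
    "icd_only": EvidenceChannels(diagnoses=True, medications=False,
                                 note_phenotype=False, note_medication=False),
    "icd_plus_keywords": EvidenceChannels(diagnoses=True, medications=False,
                                          note_phenotype=True, note_medication=False),
    "icd_plus_medications": EvidenceChannels(diagnoses=True, medications=True,
                                             note_phenotype=False, note_medication=False),
    "icd_plus_abstractions": EvidenceChannels(diagnoses=True, medications=False,
                                              note_phenotype=True, note_medication=True),
    "icd_plus_medications_plus_abstractions": EvidenceChannels(
        diagnoses=True, medications=True, note_phenotype=True, note_medication=True),
}


def percent(numerator: int, denominator: int, decimals: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals``."""
    if denominator == 0:
        raise ZeroDivisionError("percent denominator is zero")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


def status_counts(statuses: pd.DataFrame) -> pd.DataFrame:
    """Status bookkeeping (case / control / excluded / total)."""
    counts = statuses["status"].value_counts()
    rows = [
        ("total", len(statuses)),
        ("cases", int(counts.get("case", 0))),
        ("controls", int(counts.get("control", 0))),
        ("excluded", int(counts.get("excluded", 0))),
    ]
    return pd.DataFrame(rows, columns=["group", "n"])


def run_ablation(
    cohort: Cohort,
    config: PhenotypeConfig,
    modes: Optional[Iterable[str]] = None,
    evidence: Optional[CohortEvidence] = None,
) -> dict[str, int]:
    """ADHD case counts under each evidence-channel mask.

    Each mode re-runs the unchanged rule engine with channels masked; counts
    are ADHD cases after case exclusion, so they are directly comparable to
    the full pipeline's ADHD count.
    """
    if modes is None:
        modes = list(ABLATION_MODES)
    unknown = [m for m in modes if m not in ABLATION_MODES]
    if unknown:
        raise KeyError(f"unknown ablation mode(s): {unknown}")
    if evidence is None:
        evidence = build_cohort_evidence(cohort, config)
    out: dict[str, int] = {}
    for mode in modes:
        statuses, _ = evaluate_cohort(evidence, config, ABLATION_MODES[mode])
        out[mode] = int(statuses["adhd"].sum())
    return out


def comorbidity_table(statuses: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """ADHD-by-comorbidity table: one marginal row per condition plus an
    isolation row (ADHD cases with no comorbidity flag)."""
    adhd = statuses[statuses["adhd"] & (statuses["status"] == "case")]
    n_adhd = len(adhd)
    rows = [("ADHD_total", n_adhd, 100.0 if n_adhd else 0.0)]
    if n_adhd == 0:
        warnings.warn("no ADHD cases; comorbidity table is empty")
        return pd.DataFrame(rows, columns=["condition", "n", "percent_of_adhd"])
    present = [c for c in COMORBID_CONDITIONS if c in adhd.columns]
    isolation = int((~adhd[present].any(axis=1)).sum())
    rows.append(("ADHD_in_isolation", isolation, percent(isolation, n_adhd, decimals)))
    for cid in present:
        n = int(adhd[cid].sum())
        rows.append((cid, n, percent(n, n_adhd, decimals)))
    return pd.DataFrame(rows, columns=["condition", "n", "percent_of_adhd"])
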