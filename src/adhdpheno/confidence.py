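"""ADHD confidence scoring.

Each ADHD case receives a total score: the sum of (1) unique ADHD diagnosis
days, (2) unique ADHD medication days, (3) whether an ADHD phenotype was
found in the psych abstraction (0/1), (4) whether an ADHD medication was
found in the abstraction (0/1), and (5) whether psychotherapy or
neurocognitive therapy was noted (0/1).  The number of sources is the count
of the five components that are positive (1..5 for any case).

Class rules:

* high — total score >= 20; or total score > 9 with 4–5 sources; or more
  than 9 diagnosis days or more than 9 medication days with 2–3 sources;
* low — diagnosis days + medication days = 2 with total score < 3; or zero
  diagnosis days, total score < 10, more than 2 medication days, and no
  abstraction sources;
* moderate — everything else.

The high and low predicates are disjoint (verified exhaustively in the test
suite), so evaluation order is cosmetic.  The score reflects evidence
accumulation, not disease severity: a stable, long-followed mild case can
score high.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

LEVELS = ("high", "moderate", "low")


@dataclass(frozen=True)
class ConfidenceInputs:
    """The five scoring components for one ADHD case."""

    diag_days: int
    med_days: int
    abs_phenotype: int
    abs_medication: int
    therapy: int

    def __post_init__(self):
        if self.diag_days < 0 or self.med_days < 0:
            raise ValueError("day counts must be non-negative")
        for name in ("abs_phenotype", "abs_medication", "therapy"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")


@dataclass(frozen=True)
class ConfidenceResult:
    total_score: int
    n_sources: int
    level: str


def score(inputs: ConfidenceInputs, therapy_is_abstraction_source: bool = False) -> ConfidenceResult:
    """Score one ADHD case and classify it high/moderate/low.

    ``therapy_is_abstraction_source`` controls whether therapy participation
    counts as an "abstraction source" in the second low-confidence clause;
    by default only the two abstraction indicators do.
    """
    d, m = inputs.diag_days, inputs.med_days
    components = (d, m, inputs.abs_phenotype, inputs.abs_medication, inputs.therapy)
    total = sum(components)
    n_sources = sum(1 for c in components if c > 0)

    high = (
        total >= 20
        or (total > 9 and n_sources in (4, 5))
        or ((d > 9 or m > 9) and n_sources in (2, 3))
    )
    no_abstraction = inputs.abs_phenotype == 0 and inputs.abs_medication == 0
    if therapy_is_abstraction_source:
        no_abstraction = no_abstraction and inputs.therapy == 0
    low = (d + m == 2 and total < 3) or (
        d == 0 and total < 10 and m > 2 and no_abstraction
    )

    level = "high" if high else ("low" if low else "moderate")
    return ConfidenceResult(total_score=total, n_sources=n_sources, level=level)


CONFIDENCE_COLUMNS = [
    "patient_id", "diag_days", "med_days", "abs_phenotype", "abs_medication",
    "therapy", "total_score", "n_sources", "level",
]


def classify_cohort(
    inputs: Iterable[tuple[str, ConfidenceInputs]],
    therapy_is_abstraction_source: bool = False,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Score a list of ``(patient_id, ConfidenceInputs)`` ADHD cases.

    Returns the confidence table and the class distribution as fractions.
    An empty case list yields an empty table and an all-zero distribution.
    """
    rows = []
    for pid, inp in inputs:
        res = score(inp, therapy_is_abstraction_source)
        rows.append(
            (pid, inp.diag_days, inp.med_days, inp.abs_phenotype, inp.abs_medication,
             inp.therapy, res.total_score, res.n_sources, res.level)
        )
    table = pd.DataFrame(rows, columns=CONFIDENCE_COLUMNS)
    if table.empty:
        import warnings

        warnings.warn("no ADHD cases to score; distribution reported as zeros")
        return table, {lvl: 0.0 for lvl in LEVELS}
    counts = table["level"].value_counts()
    n = len(table)
    distribution = {lvl: float(counts.get(lvl, 0)) / n for lvl in LEVELS}
    return table, distribution
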