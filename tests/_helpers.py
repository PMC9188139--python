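"""Shared test fixtures: tiny in-memory cohorts built from literal tuples."""

from __future__ import annotations

import datetime as dt

import pandas as pd

from adhdpheno.codes import normalize_code
from adhdpheno.model import (
    Cohort,
    DIAGNOSIS_COLUMNS,
    MEDICATION_COLUMNS,
    NOTE_COLUMNS,
    PATIENT_COLUMNS,
)

EXTRACTION = dt.date(2016, 12, 31)


def d(iso: str) -> dt.date:
    return dt.date.fromisoformat(iso)


def make_cohort(patients, diagnoses=(), medications=(), notes=()) -> Cohort:
    """Build a cohort from literal tuples.

    patients: (pid, birth_iso[, sex[, extraction_iso]])
    diagnoses: (pid, date_iso, code_system, code)
    medications: (pid, date_iso, drug_name, drug_class)
    notes: (pid, date_iso, text)
    """
    prow = []
    for p in patients:
        pid, birth = p[0], d(p[1])
        sex = p[2] if len(p) > 2 else "female"
        ext = d(p[3]) if len(p) > 3 else EXTRACTION
        prow.append((pid, birth, sex, ext))
    dx = [(pid, d(day), sys, normalize_code(code)) for pid, day, sys, code in diagnoses]
    rx = [(pid, d(day), name.lower(), cls.lower()) for pid, day, name, cls in medications]
    nt = [(pid, d(day), text) for pid, day, text in notes]
    return Cohort(
        pd.DataFrame(prow, columns=PATIENT_COLUMNS),
        pd.DataFrame(dx, columns=DIAGNOSIS_COLUMNS),
        pd.DataFrame(rx, columns=MEDICATION_COLUMNS),
        pd.DataFrame(nt, columns=NOTE_COLUMNS),
    )


def record_of(cohort: Cohort, pid: str):
    return cohort.record(pid)


_DX_POOL = [
    ("ICD9", "314.01"), ("ICD10", "F90.0"), ("ICD9", "3140"),
    ("ICD9", "300.00"), ("ICD10", "F41.1"),
    ("ICD9", "296.20"), ("ICD10", "F32.9"),
    ("ICD9", "296.40"), ("ICD10", "F31.9"),
    ("ICD10", "F20.9"), ("ICD9", "313.81"), ("ICD10", "F91.1"),
    ("ICD9", "307.23"), ("ICD10", "F95.0"),
    ("ICD9", "317"), ("ICD9", "315.1"),
    ("ICD9", "191.9"), ("ICD10", "S06.9"),
    ("ICD9", "V20.2"),
]

_MED_POOL = [
    ("methylphenidate", "cns stimulants"),
    ("clonidine", "cardiovascular agents"),
    ("guanfacine", "adhd agents"),
    ("sertraline", "psychotherapeutic agents"),
    ("lorazepam", "benzodiazepines"),
    ("lithium", "mood stabilizers"),
    ("risperidone", "antipsychotics"),
    ("ibuprofen", "analgesics"),
]

_NOTE_POOL = [
    "assessment consistent with adhd",
    "patient does not have adhd",
    "continues methylphenidate daily",
    "well child visit, no concerns",
    "generalized anxiety noted at school",
    "participates in behavioral therapy weekly",
    "",
]


def random_micro_cohort(n: int, seed: int) -> Cohort:
    """n patients with at most 6 events each, drawn from small pools so that
    same-day collisions, age-boundary diagnoses, excluded drug classes and
    exclusionary codes all occur."""
    import numpy as np

    rng = np.random.default_rng(seed)
    patients, dx, rx, notes = [], [], [], []
    for i in range(n):
        pid = f"M{i:04d}"
        birth = EXTRACTION - dt.timedelta(days=int(rng.integers(700, 5500)))
        patients.append((pid, birth.isoformat(), "male" if rng.random() < 0.5 else "female"))
        for _ in range(int(rng.integers(0, 7))):
            day = (EXTRACTION - dt.timedelta(days=int(rng.integers(0, 400)))).isoformat()
            u = rng.random()
            if u < 0.55:
                sys_, code = _DX_POOL[int(rng.integers(0, len(_DX_POOL)))]
                dx.append((pid, day, sys_, code))
            elif u < 0.85:
                name, cls = _MED_POOL[int(rng.integers(0, len(_MED_POOL)))]
                rx.append((pid, day, name, cls))
            else:
                notes.append((pid, day, _NOTE_POOL[int(rng.integers(0, len(_NOTE_POOL)))]))
    return make_cohort(patients, dx, rx, notes)
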