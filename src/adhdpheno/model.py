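"""EHR domain types and delimited-text interchange I/O.

A cohort is four tables — patients, diagnoses, medications, notes — linked by
``patient_id``.  Dates are calendar dates (ISO-8601, no times): every temporal
rule in the pipeline is phrased in distinct calendar days.  The interchange
format is plain CSV, one file per table; an adapter layer over richer source
models (OMOP, FHIR) is out of scope.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .codes import normalize_code

PATIENT_COLUMNS = ["patient_id", "birth_date", "sex", "extraction_date"]
DIAGNOSIS_COLUMNS = ["patient_id", "event_date", "code_system", "code"]
MEDICATION_COLUMNS = ["patient_id", "event_date", "drug_name", "drug_class"]
NOTE_COLUMNS = ["patient_id", "event_date", "text"]

SEXES = ("male", "female", "other")
CODE_SYSTEMS = ("ICD9", "ICD10")


class SchemaError(ValueError):
    """A required column is missing or a row fails to parse."""


@dataclass(frozen=True)
class Patient:
    patient_id: str
    birth_date: dt.date
    sex: str
    extraction_date: dt.date

    def age_years(self, on: dt.date) -> int:
        """Age in whole completed years on a given date."""
        return on.year - self.birth_date.year - (
            (on.month, on.day) < (self.birth_date.month, self.birth_date.day)
        )


@dataclass(frozen=True)
class DiagnosisEvent:
    patient_id: str
    event_date: dt.date
    code_system: str
    code: str


@dataclass(frozen=True)
class MedicationEvent:
    patient_id: str
    event_date: dt.date
    drug_name: str
    drug_class: str


@dataclass(frozen=True)
class NoteAbstraction:
    patient_id: str
    event_date: dt.date
    text: str


@dataclass(frozen=True)
class PatientRecord:
    """One patient's demographics plus event streams, for per-patient rules."""

    patient: Patient
    diagnoses: tuple[DiagnosisEvent, ...] = ()
    medications: tuple[MedicationEvent, ...] = ()
    notes: tuple[NoteAbstraction, ...] = ()


@dataclass
class Cohort:
    """In-memory cohort: four pandas tables with normalized codes/names."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    medications: pd.DataFrame
    notes: pd.DataFrame
    _records: dict = field(default_factory=dict, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> list[str]:
        return self.patients["patient_id"].tolist()

    def record(self, patient_id: str) -> PatientRecord:
        """Materialize one patient's :class:`PatientRecord`."""
        row = self.patients.loc[self.patients["patient_id"] == patient_id]
        if row.empty:
            raise KeyError(patient_id)
        r = row.iloc[0]
        patient = Patient(r["patient_id"], r["birth_date"], r["sex"], r["extraction_date"])
        dx = tuple(
            DiagnosisEvent(t.patient_id, t.event_date, t.code_system, t.code)
            for t in self.diagnoses[self.diagnoses["patient_id"] == patient_id].itertuples()
        )
        rx = tuple(
            MedicationEvent(t.patient_id, t.event_date, t.drug_name, t.drug_class)
            for t in self.medications[self.medications["patient_id"] == patient_id].itertuples()
        )
        notes = tuple(
            NoteAbstraction(t.patient_id, t.event_date, t.text)
            for t in self.notes[self.notes["patient_id"] == patient_id].itertuples()
        )
        return PatientRecord(patient, dx, rx, notes)


def _parse_dates(df: pd.DataFrame, column: str, table: str) -> pd.Series:
    parsed = pd.to_datetime(df[column], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & df[column].notna()
    if bad.any():
        rownum = int(bad.idxmax()) + 2  # 1-based plus header line
        raise SchemaError(
            f"{table}: unparseable date {df.loc[bad.idxmax(), column]!r} "
            f"in column {column!r} at file row {rownum}"
        )
    if df[column].isna().any():
        rownum = int(df[column].isna().idxmax()) + 2
        raise SchemaError(f"{table}: missing date in column {column!r} at file row {rownum}")
    return parsed.dt.date


def _require_columns(df: pd.DataFrame, columns: list[str], table: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{table}: missing required column {col!r}")


def _read_table(path: Path, columns: list[str], date_columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    _require_columns(df, columns, path.name)
    for col in date_columns:
        df[col] = _parse_dates(df.replace({col: {"": None}}), col, path.name)
    return df[columns]


def read_cohort(data_dir) -> Cohort:
    """Read a cohort from ``patients/diagnoses/medications/notes`` CSV files.

    Codes are normalized to canonical dotted form, drug names and classes to
    lowercase.  Events referencing an unknown ``patient_id`` raise a
    referential-integrity error listing the orphan ids.
    """
    data_dir = Path(data_dir)
    patients = _read_table(data_dir / "patients.csv", PATIENT_COLUMNS,
                           ["birth_date", "extraction_date"])
    diagnoses = _read_table(data_dir / "diagnoses.csv", DIAGNOSIS_COLUMNS, ["event_date"])
    medications = _read_table(data_dir / "medications.csv", MEDICATION_COLUMNS, ["event_date"])
    notes = _read_table(data_dir / "notes.csv", NOTE_COLUMNS, ["event_date"])

    dup = patients["patient_id"].duplicated()
    if dup.any():
        raise SchemaError(
            "patients.csv: duplicate patient_id(s): "
            + ", ".join(sorted(patients.loc[dup, "patient_id"].unique()))
        )
    bad_order = patients["birth_date"] > patients["extraction_date"]
    if bad_order.any():
        raise SchemaError(
            "patients.csv: birth_date after extraction_date for "
            + ", ".join(patients.loc[bad_order, "patient_id"])
        )

    known = set(patients["patient_id"])
    for name, df in (("diagnoses", diagnoses), ("medications", medications), ("notes", notes)):
        orphans = sorted(set(df["patient_id"]) - known)
        if orphans:
            raise SchemaError(f"{name}.csv: unknown patient_id(s): {', '.join(orphans)}")

    if (diagnoses["code"].str.strip() == "").any():
        raise SchemaError("diagnoses.csv: empty diagnosis code")
    unknown_sys = ~diagnoses["code_system"].isin(CODE_SYSTEMS)
    if unknown_sys.any():
        raise SchemaError(
            "diagnoses.csv: unknown code_system "
            + ", ".join(sorted(diagnoses.loc[unknown_sys, "code_system"].unique()))
        )
    diagnoses = diagnoses.assign(code=diagnoses["code"].map(normalize_code))
    medications = medications.assign(
        drug_name=medications["drug_name"].str.strip().str.lower(),
        drug_class=medications["drug_class"].str.strip().str.lower(),
    )
    if (medications["drug_name"] == "").any():
        raise SchemaError("medications.csv: empty drug_name")
    return Cohort(patients, diagnoses, medications, notes)


def write_cohort(cohort: Cohort, data_dir) -> None:
    """Write the four cohort tables as CSV (dates in ISO-8601)."""
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    cohort.patients[PATIENT_COLUMNS].to_csv(data_dir / "patients.csv", index=False)
    cohort.diagnoses[DIAGNOSIS_COLUMNS].to_csv(data_dir / "diagnoses.csv", index=False)
    cohort.medications[MEDICATION_COLUMNS].to_csv(data_dir / "medications.csv", index=False)
    cohort.notes[NOTE_COLUMNS].to_csv(data_dir / "notes.csv", index=False)
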