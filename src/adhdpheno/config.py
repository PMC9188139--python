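"""Phenotype rule configuration.

One :class:`ConditionRule` per condition (ADHD plus eleven psychiatric or
related conditions), one :class:`ExclusionRule` for case exclusions and one
for control exclusions.  The shipped default lists are implementer-curated
stand-ins for institution-specific code/keyword tables: they carry the ICD-9
and ICD-10-CM families standardly used for each condition, but are not a
clinical reference.  Every list is overridable from YAML or JSON.
"""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .codes import normalize_prefix

#: Condition identifiers, ADHD first.  "Psychiatric conditions" in reports
#: means the first ten; learning disability and mild/moderate intellectual
#: disability are tracked as related conditions.
CONDITIONS: tuple[str, ...] = (
    "ADHD",
    "anxiety",
    "autism",
    "major_depression",
    "ODD",
    "conduct_disorder",
    "tic_disorder",
    "tourette",
    "schizophrenia",
    "bipolar",
    "intellectual_disability",
    "learning_disability",
)

COMORBID_CONDITIONS: tuple[str, ...] = CONDITIONS[1:]


class ConditionRule(BaseModel):
    """Inclusion criteria for one condition.

    ``min_distinct_days`` is the number of distinct calendar days on which a
    qualifying diagnosis code must appear; ``gap_window_days`` (used for
    major depression and bipolar disorder) additionally requires at least one
    pair of distinct diagnosis days separated by a gap inside the closed
    window.  ``medication_criterion_enabled`` turns on the prescription-based
    inclusion paths (anxiety, schizophrenia, bipolar, ADHD); drugs listed in
    ``excluded_medication_names`` (e.g. benzodiazepines for anxiety) never
    count as qualifying evidence.  ``min_age_years_at_event`` discards
    diagnosis events before that age in completed years (ADHD: 4).
    """

    condition_id: str
    icd9_prefixes: list[str] = Field(default_factory=list)
    icd10_prefixes: list[str] = Field(default_factory=list)
    medication_names: list[str] = Field(default_factory=list)
    excluded_medication_names: list[str] = Field(default_factory=list)
    phenotype_keywords: list[str] = Field(default_factory=list)
    min_distinct_days: int = 2
    medication_criterion_enabled: bool = False
    gap_window_days: Optional[tuple[int, int]] = None
    min_age_years_at_event: Optional[int] = None

    @field_validator("condition_id")
    @classmethod
    def _known_condition(cls, v: str) -> str:
        if v not in CONDITIONS:
            raise ValueError(f"unknown condition_id {v!r}")
        return v

    @field_validator("medication_names", "excluded_medication_names", "phenotype_keywords")
    @classmethod
    def _lowercase(cls, v: list[str]) -> list[str]:
        return [s.strip().lower() for s in v]

    @field_validator("icd9_prefixes", "icd10_prefixes")
    @classmethod
    def _normalize_prefixes(cls, v: list[str]) -> list[str]:
        return [normalize_prefix(p) for p in v]

    @field_validator("min_distinct_days")
    @classmethod
    def _min_days_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("min_distinct_days must be >= 1")
        return v

    @model_validator(mode="after")
    def _gap_window_consistent(self) -> "ConditionRule":
        if self.gap_window_days is not None:
            lo, hi = self.gap_window_days
            if not lo < hi:
                raise ValueError("gap_window_days requires min_gap < max_gap")
            if self.min_distinct_days < 2:
                raise ValueError("gap_window_days requires min_distinct_days >= 2")
        return self

    @property
    def all_prefixes(self) -> list[str]:
        return self.icd9_prefixes + self.icd10_prefixes


class ExclusionRule(BaseModel):
    """Diagnosis/medication/keyword patterns that disqualify a subject.

    For cases: diagnoses likely to be etiologically distinct from a primary
    psychiatric presentation (neuronal damage, CNS neoplasms and infections,
    severe/profound intellectual disability) plus EHR pharmacologic classes
    ("cardiovascular agents", "analgesics") whose orders never count as
    psychiatric-medication evidence.  For controls: any psychiatric code,
    medication or mention, plus chromosomal anomalies and genetic syndromes;
    learning disability and mild/moderate intellectual disability codes are
    deliberately absent from the control list.
    """

    excluded_icd9_prefixes: list[str] = Field(default_factory=list)
    excluded_icd10_prefixes: list[str] = Field(default_factory=list)
    excluded_drug_classes: list[str] = Field(default_factory=list)
    excluded_medication_names: list[str] = Field(default_factory=list)
    excluded_keywords: list[str] = Field(default_factory=list)
    min_age_years: Optional[int] = None

    @field_validator("excluded_drug_classes", "excluded_medication_names", "excluded_keywords")
    @classmethod
    def _lowercase(cls, v: list[str]) -> list[str]:
        return [s.strip().lower() for s in v]

    @field_validator("excluded_icd9_prefixes", "excluded_icd10_prefixes")
    @classmethod
    def _normalize_prefixes(cls, v: list[str]) -> list[str]:
        return [normalize_prefix(p) for p in v]

    @property
    def all_prefixes(self) -> list[str]:
        return self.excluded_icd9_prefixes + self.excluded_icd10_prefixes


class PhenotypeConfig(BaseModel):
    """Complete rule set for one pipeline run."""

    rules: dict[str, ConditionRule]
    case_exclusion: ExclusionRule
    control_exclusion: ExclusionRule
    therapy_keywords: list[str] = Field(default_factory=list)
    #: count Tourette-syndrome codes toward the tic-disorder flag as well
    #: (tic disorders "including Tourette syndrome"); off by default so the
    #: two conditions report separately.
    tourette_counts_as_tic: bool = False
    #: keyword hits found in free-text notes count as abstraction results
    #: for the abstraction-based inclusion paths.
    notes_count_as_abstraction: bool = True
    #: reserved: drop keyword hits inside negated phrases.  The shipped
    #: matcher deliberately performs no negation handling.
    negation_filter_enabled: bool = False
    #: treat therapy participation as an abstraction source in the
    #: low-confidence "no abstraction sources" clause.
    therapy_is_abstraction_source: bool = False

    @field_validator("therapy_keywords")
    @classmethod
    def _lowercase(cls, v: list[str]) -> list[str]:
        return [s.strip().lower() for s in v]

    @model_validator(mode="after")
    def _rules_cover_ids(self) -> "PhenotypeConfig":
        for cid, rule in self.rules.items():
            if rule.condition_id != cid:
                raise ValueError(f"rule key {cid!r} != condition_id {rule.condition_id!r}")
        if "ADHD" not in self.rules:
            raise ValueError("an ADHD rule is required")
        return self

    @property
    def condition_ids(self) -> list[str]:
        return [c for c in CONDITIONS if c in self.rules]


# --------------------------------------------------------------------------
# default rule set (curated stand-in lists)

_ADHD_MEDICATIONS = [
    "methylphenidate",
    "dexmethylphenidate",
    "amphetamine",
    "dextroamphetamine",
    "lisdexamfetamine",
    "atomoxetine",
    "guanfacine",
    "clonidine",
]

_BENZODIAZEPINES = ["lorazepam", "diazepam", "midazolam", "clonazepam", "alprazolam"]

_ANXIETY_MEDICATIONS = [
    "sertraline",
    "fluoxetine",
    "escitalopram",
    "citalopram",
    "duloxetine",
    "buspirone",
]

_ANTIPSYCHOTICS = [
    "risperidone",
    "aripiprazole",
    "olanzapine",
    "quetiapine",
    "haloperidol",
    "ziprasidone",
]

_MOOD_STABILIZERS = ["lithium", "valproate", "lamotrigine", "carbamazepine"]

_THERAPY_KEYWORDS = [
    "psychotherapy",
    "neurocognitive therapy",
    "behavioral therapy",
    "cognitive behavioral therapy",
]


def default_config() -> PhenotypeConfig:
    """Build the shipped default rule set.

    Code, medication and keyword lists are curated stand-ins for
    institutional supplementary tables; they are pairwise disjoint across
    conditions so that each condition's evidence is unambiguous.
    """
    rules = {
        "ADHD": ConditionRule(
            condition_id="ADHD",
            icd9_prefixes=["314."],
            icd10_prefixes=["F90."],
            medication_names=_ADHD_MEDICATIONS,
            phenotype_keywords=["adhd", "attention deficit", "hyperactivity disorder"],
            medication_criterion_enabled=True,
            min_age_years_at_event=4,
        ),
        "anxiety": ConditionRule(
            condition_id="anxiety",
            icd9_prefixes=["300.0", "300.2", "300.3", "309.21", "313.23"],
            icd10_prefixes=["F40.", "F41.", "F93.0"],
            medication_names=_ANXIETY_MEDICATIONS,
            excluded_medication_names=_BENZODIAZEPINES,
            phenotype_keywords=["anxiety disorder", "generalized anxiety", "separation anxiety"],
            medication_criterion_enabled=True,
        ),
        "autism": ConditionRule(
            condition_id="autism",
            icd9_prefixes=["299."],
            icd10_prefixes=["F84."],
            phenotype_keywords=["autism", "autistic", "asperger"],
        ),
        "major_depression": ConditionRule(
            condition_id="major_depression",
            icd9_prefixes=["296.2", "296.3", "311"],
            icd10_prefixes=["F32.", "F33."],
            phenotype_keywords=["major depression", "major depressive disorder"],
            gap_window_days=(30, 180),
        ),
        "ODD": ConditionRule(
            condition_id="ODD",
            icd9_prefixes=["313.81"],
            icd10_prefixes=["F91.3"],
            phenotype_keywords=["oppositional defiant"],
        ),
        "conduct_disorder": ConditionRule(
            condition_id="conduct_disorder",
            icd9_prefixes=["312.0", "312.1", "312.2", "312.8"],
            icd10_prefixes=["F91.0", "F91.1", "F91.2", "F91.8", "F91.9"],
            phenotype_keywords=["conduct disorder"],
        ),
        "tic_disorder": ConditionRule(
            condition_id="tic_disorder",
            icd9_prefixes=["307.20", "307.21", "307.22"],
            icd10_prefixes=["F95.0", "F95.1", "F95.9"],
            phenotype_keywords=["tic disorder", "motor tics", "vocal tics"],
        ),
        "tourette": ConditionRule(
            condition_id="tourette",
            icd9_prefixes=["307.23"],
            icd10_prefixes=["F95.2"],
            phenotype_keywords=["tourette"],
        ),
        "schizophrenia": ConditionRule(
            condition_id="schizophrenia",
            icd9_prefixes=["295.", "298.9"],
            icd10_prefixes=["F20.", "F29"],
            medication_names=_ANTIPSYCHOTICS,
            phenotype_keywords=["schizophrenia", "psychosis", "psychotic disorder"],
            medication_criterion_enabled=True,
        ),
        "bipolar": ConditionRule(
            condition_id="bipolar",
            icd9_prefixes=["296.0", "296.1", "296.4", "296.5", "296.6", "296.7", "296.8"],
            icd10_prefixes=["F31."],
            medication_names=_MOOD_STABILIZERS,
            phenotype_keywords=["bipolar"],
            medication_criterion_enabled=True,
            gap_window_days=(30, 180),
        ),
        "intellectual_disability": ConditionRule(
            condition_id="intellectual_disability",
            icd9_prefixes=["317", "318.0"],
            icd10_prefixes=["F70", "F71"],
            phenotype_keywords=["intellectual disability"],
        ),
        "learning_disability": ConditionRule(
            condition_id="learning_disability",
            icd9_prefixes=["315."],
            icd10_prefixes=["F81."],
            phenotype_keywords=["learning disability", "dyslexia"],
        ),
    }

    # Etiologically distinct presentations: CNS neoplasms, neuronal damage,
    # CNS infection, severe/profound intellectual disability, TBI.
    case_exclusion = ExclusionRule(
        excluded_icd9_prefixes=[
            "191.", "192.", "225.",      # CNS neoplasms
            "320.", "323.", "324.",      # CNS infection / encephalitis / abscess
            "348.1",                     # anoxic brain damage
            "854.",                      # intracranial injury
            "318.1", "318.2",            # severe / profound ID
        ],
        excluded_icd10_prefixes=[
            "C71.", "D33.",
            "G00.", "G04.", "G05.", "G06.",
            "G93.1",
            "S06.",
            "F72", "F73",
        ],
        excluded_drug_classes=["cardiovascular agents", "analgesics"],
    )

    # Controls: no psychiatric or neurological codes, medications, or
    # mentions; chromosomal anomalies / genetic syndromes also exclude.
    # LD (315./F81.) and mild/moderate ID (317/318.0, F70/F71) are allowed.
    psychiatric_prefixes_9: list[str] = []
    psychiatric_prefixes_10: list[str] = []
    med_union: list[str] = []
    keyword_union: list[str] = []
    for cid, rule in rules.items():
        if cid in ("learning_disability", "intellectual_disability"):
            continue
        psychiatric_prefixes_9 += rule.icd9_prefixes
        psychiatric_prefixes_10 += rule.icd10_prefixes
        med_union += rule.medication_names
        keyword_union += rule.phenotype_keywords
    control_exclusion = ExclusionRule(
        excluded_icd9_prefixes=psychiatric_prefixes_9
        + case_exclusion.excluded_icd9_prefixes
        + ["758.", "345.", "343."],          # chromosomal, epilepsy, cerebral palsy
        excluded_icd10_prefixes=psychiatric_prefixes_10
        + case_exclusion.excluded_icd10_prefixes
        + ["Q90.", "Q91.", "Q92.", "Q93.", "Q99.", "G40.", "G80."],
        excluded_medication_names=sorted(set(med_union) | set(_BENZODIAZEPINES)),
        excluded_keywords=sorted(set(keyword_union)),
        min_age_years=8,
    )

    return PhenotypeConfig(
        rules=rules,
        case_exclusion=case_exclusion,
        control_exclusion=control_exclusion,
        therapy_keywords=_THERAPY_KEYWORDS,
    )


def save_config(config: PhenotypeConfig, path) -> None:
    """Write a config to YAML (lists fully expanded, round-trippable)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


def load_config(path) -> PhenotypeConfig:
    """Load a YAML or JSON phenotype config."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PhenotypeConfig.model_validate(data)
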