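"""Generator determinism, planted prevalences, and config alignment."""

import filecmp

import numpy as np
import pytest
from scipy.stats import binom

import adhdpheno as ap
from adhdpheno.codes import code_matches_any
from adhdpheno.config import CONDITIONS, default_config
from adhdpheno.synthetic import (
    _DX_POOL,
    _MED_POOL,
    _NOTE_KEYWORD,
    SimulationConfig,
    preset_paper_like,
    simulate,
    simulate_to_dir,
)


def binom99(p, n):
    lo, hi = binom.ppf([0.005, 0.995], n, p) / n
    return lo, hi


def test_clean_mode_determinism_byte_identical(tmp_path):
    cfg = SimulationConfig(n_patients=200, seed=7, abstraction_fraction=0.5,
                           med_only_fraction=0.1)
    a = simulate_to_dir(cfg, tmp_path / "a")
    b = simulate_to_dir(cfg, tmp_path / "b")
    for name in ("patients.csv", "diagnoses.csv", "medications.csv",
                 "notes.csv", "gold_labels.csv"):
        assert filecmp.cmp(a / name, b / name, shallow=False), name


def test_planted_adhd_prevalence_within_binomial_interval():
    cfg = SimulationConfig(n_patients=2000, seed=3)
    assert cfg.prevalence["ADHD"] == 0.11
    _, gold = simulate(cfg)
    frac = gold["ADHD"].mean()
    lo, hi = binom99(0.11, 2000)
    assert lo <= frac <= hi


def test_med_only_fraction_within_binomial_interval():
    cfg = SimulationConfig(n_patients=4000, seed=5, med_only_fraction=0.12)
    _, gold = simulate(cfg)
    adhd = gold[gold["ADHD"]]
    frac = adhd["adhd_med_only"].mean()
    lo, hi = binom99(0.12, len(adhd))
    assert lo <= frac <= hi


def test_preset_validates_and_single_patient_ok():
    cfg = preset_paper_like(n_patients=1, seed=9)
    assert isinstance(cfg, SimulationConfig)
    cohort, gold = simulate(cfg)
    assert len(cohort) == 1 and len(gold) == 1


def test_preset_recovered_adhd_fraction_in_range():
    cohort, _ = simulate(preset_paper_like(n_patients=5000, seed=1))
    res = ap.run_pipeline(cohort)
    frac = res.n_adhd_cases / len(cohort)
    assert 0.08 <= frac <= 0.14


def test_pathological_prevalence_warns():
    with pytest.warns(UserWarning):
        SimulationConfig(n_patients=10, prevalence={c: 0.99 for c in CONDITIONS})


def test_generator_pools_align_with_default_rules():
    """Every planted code maps to exactly its own condition's rule; planted
    medications and note keywords are recognized by the matching rule."""
    cfg = default_config()
    for cid, pool in _DX_POOL.items():
        for _, code in pool:
            assert code_matches_any(code, cfg.rules[cid].all_prefixes), (cid, code)
            for other in cfg.condition_ids:
                if other != cid:
                    assert not code_matches_any(code, cfg.rules[other].all_prefixes), \
                        (cid, code, other)
    for cid, pool in _MED_POOL.items():
        rule = cfg.rules[cid]
        for name, _ in pool:
            assert name in rule.medication_names
            assert name not in rule.excluded_medication_names
        for other in cfg.condition_ids:
            if other != cid:
                assert not set(n for n, _ in pool) & set(cfg.rules[other].medication_names)
    for cid, kw in _NOTE_KEYWORD.items():
        assert any(kw == k for k in cfg.rules[cid].phenotype_keywords), (cid, kw)


def test_event_dates_respect_age_constraints():
    cfg = SimulationConfig(n_patients=600, seed=13, med_only_fraction=0.15)
    cohort, gold = simulate(cfg)
    merged = cohort.diagnoses.merge(cohort.patients[["patient_id", "birth_date"]],
                                    on="patient_id")
    adhd_dx = merged[merged["code"].str.startswith(("314.", "F90."))]
    age_days = (adhd_dx["event_date"] - adhd_dx["birth_date"]).map(lambda x: x.days)
    assert (np.asarray(age_days) >= 4 * 365).all()


def test_depression_plants_satisfy_gap_window():
    cfg = SimulationConfig(n_patients=1500, seed=17)
    cohort, gold = simulate(cfg)
    dep_ids = set(gold.loc[gold["major_depression"], "patient_id"])
    dep_dx = cohort.diagnoses[
        cohort.diagnoses["patient_id"].isin(dep_ids)
        & cohort.diagnoses["code"].str.startswith(("296.2", "296.3", "311", "F32", "F33"))
    ]
    assert len(dep_ids) > 5
    for pid, grp in dep_dx.groupby("patient_id"):
        days = sorted(set(grp["event_date"]))
        gaps = [(b - a).days for i, a in enumerate(days) for b in days[i + 1:]]
        assert any(30 <= g <= 180 for g in gaps), pid
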