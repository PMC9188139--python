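"""Reporting arithmetic: percentages, bookkeeping, ablation masking."""

import pandas as pd
import pytest

import adhdpheno as ap
from adhdpheno.config import CONDITIONS, default_config
from adhdpheno.stats import (
    ABLATION_MODES,
    comorbidity_table,
    percent,
    run_ablation,
    status_counts,
)
from adhdpheno.synthetic import SimulationConfig, simulate


@pytest.mark.parametrize(
    "num,den,dec,expected",
    [
        (881, 5840, 2, 15.09),
        (105, 5840, 2, 1.80),
        (1, 3, 2, 33.33),
        (219, 5840, 2, 3.75),   # exact .5 rounds up at the next digit? 3.75 exactly
        (1, 8, 2, 12.5),
        (1, 800, 2, 0.13),      # 0.125 -> half-up
        (0, 100, 2, 0.0),
    ],
)
def test_percent_half_up(num, den, dec, expected):
    assert percent(num, den, dec) == expected


def test_percent_zero_denominator():
    with pytest.raises(ZeroDivisionError):
        percent(1, 0)


def _statuses_frame(rows):
    cols = ["patient_id", "status", "adhd", "comorbid_adhd", *CONDITIONS,
            "exclusion_reasons"]
    out = []
    for pid, status, conds in rows:
        flags = {c: c in conds for c in CONDITIONS}
        adhd = flags["ADHD"]
        out.append({"patient_id": pid, "status": status, "adhd": adhd,
                    "comorbid_adhd": adhd and any(flags[c] for c in CONDITIONS[1:]),
                    **flags, "exclusion_reasons": ""})
    return pd.DataFrame(out, columns=cols)


def test_comorbidity_table_isolation_identity():
    rows = (
        [(f"A{i}", "case", ("ADHD",)) for i in range(5)]
        + [(f"B{i}", "case", ("ADHD", "anxiety")) for i in range(3)]
        + [("C0", "case", ("ADHD", "anxiety", "autism"))]
        + [("D0", "case", ("anxiety",))]
        + [(f"E{i}", "control", ()) for i in range(4)]
    )
    table = comorbidity_table(_statuses_frame(rows)).set_index("condition")
    assert table.loc["ADHD_total", "n"] == 9
    assert table.loc["ADHD_in_isolation", "n"] == 5
    assert table.loc["anxiety", "n"] == 4
    assert table.loc["autism", "n"] == 1
    # isolation + (>=1 comorbidity) = ADHD total
    n_comorbid = 9 - 5
    assert table.loc["ADHD_in_isolation", "n"] + n_comorbid == table.loc["ADHD_total", "n"]
    assert table.loc["ADHD_in_isolation", "percent_of_adhd"] == percent(5, 9, 2)


def test_comorbidity_table_zero_adhd_warns():
    rows = [("D0", "case", ("anxiety",))]
    with pytest.warns(UserWarning):
        table = comorbidity_table(_statuses_frame(rows))
    assert table.iloc[0]["n"] == 0


def test_status_counts_bookkeeping():
    rows = ([(f"A{i}", "case", ("ADHD",)) for i in range(2)]
            + [(f"E{i}", "control", ()) for i in range(3)]
            + [(f"X{i}", "excluded", ()) for i in range(4)])
    t = status_counts(_statuses_frame(rows)).set_index("group")["n"]
    assert t["total"] == t["cases"] + t["controls"] + t["excluded"] == 9


def test_ablation_monotone_and_modes():
    cfg = SimulationConfig(n_patients=800, seed=21, med_only_fraction=0.15,
                           single_dx_plus_med_fraction=0.1,
                           abstraction_only_fraction=0.02,
                           abstraction_fraction=0.7)
    cohort, _ = simulate(cfg)
    counts = run_ablation(cohort, default_config())
    assert set(counts) == set(ABLATION_MODES)
    assert counts["icd_only"] <= counts["icd_plus_keywords"]
    assert counts["icd_only"] <= counts["icd_plus_medications"]
    assert counts["icd_only"] <= counts["icd_plus_abstractions"]
    assert counts["icd_plus_medications"] <= counts["icd_plus_medications_plus_abstractions"]
    assert counts["icd_plus_abstractions"] <= counts["icd_plus_medications_plus_abstractions"]


def test_ablation_unknown_mode_raises():
    cohort, _ = simulate(SimulationConfig(n_patients=5, seed=1))
    with pytest.raises(KeyError):
        run_ablation(cohort, default_config(), modes=["icd_plus_tarot"])


def test_full_mode_equals_pipeline_adhd_count():
    cfg = SimulationConfig(n_patients=500, seed=23, med_only_fraction=0.1,
                           abstraction_fraction=0.5)
    cohort, _ = simulate(cfg)
    res = ap.run_pipeline(cohort)
    counts = run_ablation(cohort, default_config(), evidence=res.evidence)
    assert counts["icd_plus_medications_plus_abstractions"] == res.n_adhd_cases
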