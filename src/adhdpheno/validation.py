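"""Positive-predictive-value estimation against a gold standard.

The gold standard is a table, not a code path: in simulation it is the
generator's planted labels; in real use it is a chart-review adjudication
file with the same columns.  Intervals are exact (Clopper–Pearson): review
samples of ~15 per stratum are far too small for a normal approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import beta

from .config import COMORBID_CONDITIONS, CONDITIONS


@dataclass(frozen=True)
class PpvEstimate:
    stratum: str
    n_sampled: int
    n_true: int
    ppv: float
    ci_low: float
    ci_high: float


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval for a proportion."""
    if n == 0:
        return 0.0, 1.0
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def stratum_members(statuses: pd.DataFrame, stratum: str) -> list[str]:
    """Patient ids in a named stratum.

    Strata: ``controls``; a condition id (algorithm-positive for it); or
    ``ADHD+<condition>`` for a comorbidity combination.
    """
    if stratum == "controls":
        mask = statuses["status"] == "control"
    elif stratum.startswith("ADHD+"):
        other = stratum.split("+", 1)[1]
        if other not in statuses.columns:
            raise KeyError(f"unknown condition {other!r}")
        mask = statuses["adhd"] & statuses[other] & (statuses["status"] == "case")
    elif stratum in statuses.columns:
        mask = statuses[stratum] & (statuses["status"] == "case")
    else:
        raise KeyError(f"unknown stratum {stratum!r}")
    return statuses.loc[mask, "patient_id"].tolist()


def sample_for_review(
    statuses: pd.DataFrame, stratum: str, k: int, seed: int
) -> list[str]:
    """Draw ``min(k, |stratum|)`` patient ids without replacement."""
    members = stratum_members(statuses, stratum)
    if not members:
        warnings.warn(f"stratum {stratum!r} is empty; nothing to sample")
        return []
    rng = np.random.default_rng(seed)
    k = min(k, len(members))
    idx = rng.choice(len(members), size=k, replace=False)
    return [members[i] for i in sorted(idx)]


def _gold_truth(gold: pd.DataFrame, stratum: str) -> pd.Series:
    g = gold.set_index("patient_id")
    if stratum == "controls":
        return g["true_status"] == "control"
    if stratum.startswith("ADHD+"):
        other = stratum.split("+", 1)[1]
        return g["ADHD"].astype(bool) & g[other].astype(bool)
    return g[stratum].astype(bool)


def compute_ppv(
    sample: Iterable[str],
    gold: pd.DataFrame,
    stratum: str,
    alpha: float = 0.05,
) -> PpvEstimate:
    """PPV of a review sample: fraction adjudicated true, with an exact
    binomial interval.  For the control stratum the estimate is the fraction
    of sampled controls that are truly psychiatric-negative."""
    sample = list(sample)
    truth = _gold_truth(gold, stratum)
    missing = [pid for pid in sample if pid not in truth.index]
    if missing:
        raise KeyError(f"no gold adjudication for: {', '.join(missing)}")
    n = len(sample)
    k = int(truth.loc[sample].sum()) if n else 0
    lo, hi = clopper_pearson(k, n, alpha)
    return PpvEstimate(stratum=stratum, n_sampled=n, n_true=k,
                       ppv=(k / n if n else float("nan")), ci_low=lo, ci_high=hi)


def ppv_report(
    statuses: pd.DataFrame,
    gold: pd.DataFrame,
    strata: Iterable[str],
    k: int = 15,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample each stratum and estimate its PPV; one row per stratum.

    Each stratum gets a distinct sampling substream derived from ``seed``.
    """
    rows = []
    for i, stratum in enumerate(strata):
        sample = sample_for_review(statuses, stratum, k, seed=seed * 100003 + i)
        est = compute_ppv(sample, gold, stratum)
        rows.append(est.__dict__)
    return pd.DataFrame(rows, columns=["stratum", "n_sampled", "n_true", "ppv",
                                       "ci_low", "ci_high"])


def comorbidity_strata() -> list[str]:
    """The ADHD+comorbidity combination strata (one per non-ADHD condition)."""
    return [f"ADHD+{c}" for c in COMORBID_CONDITIONS]


def recovery_metrics(statuses: pd.DataFrame, gold: pd.DataFrame) -> pd.DataFrame:
    """Per-condition sensitivity, specificity and PPV of the pipeline's
    post-exclusion flags against gold labels, plus a status-agreement row.

    On a clean-mode synthetic cohort all three metrics are exactly 1 for
    every condition.
    """
    merged = statuses.merge(gold, on="patient_id", suffixes=("_pred", "_gold"))
    rows = []
    for cid in CONDITIONS:
        pred = merged[f"{cid}_pred"].astype(bool)
        true = merged[f"{cid}_gold"].astype(bool)
        tp = int((pred & true).sum())
        fp = int((pred & ~true).sum())
        fn = int((~pred & true).sum())
        tn = int((~pred & ~true).sum())
        rows.append({
            "condition": cid,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        })
    out = pd.DataFrame(rows)
    out.attrs["status_agreement"] = float(
        (merged["status"] == merged["true_status"]).mean()
    )
    return out
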