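"""Per-model performance measures: Harrell's C, calibration-in-the-large,
practical mean absolute prediction error and net benefit.

These four quantities summarise each replicate model fitted in the resampling
experiment and drive the performance-conditioned stability subsets.  All risk
quantities are on the percent scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .errors import (
    EmptyCohortError,
    InvalidThresholdError,
    SchemaError,
    UndefinedStatisticError,
)
from .survival_engine import kaplan_meier
from .synthetic_cohort import EVENT, PATIENT_ID, TIME

__all__ = [
    "ReplicatePerformance",
    "harrells_c",
    "calibration_in_the_large",
    "mape_practical",
    "net_benefit",
]


@dataclass(frozen=True)
class ReplicatePerformance:
    """Performance of one replicate model on the validation cohort."""

    replicate_id: int
    c_statistic: float
    citl: float
    mape_practical: float
    net_benefit: float


@njit(cache=True)
def _concordance_counts(time, event, risk):
    """Concordant weight and comparable-pair count under Harrell's rule.

    A pair is comparable iff the strictly earlier time is an event; the
    comparison is attributed to that earlier (event) member, so each pair is
    counted once.  Risk ties score 0.5.
    """
    n = time.shape[0]
    concordant = 0.0
    comparable = 0
    for i in range(n):
        if event[i] == 0:
            continue
        ti = time[i]
        ri = risk[i]
        for j in range(n):
            if time[j] > ti:
                comparable += 1
                if risk[j] < ri:
                    concordant += 1.0
                elif risk[j] == ri:
                    concordant += 0.5
    return concordant, comparable


def _aligned_risks(risks: pd.Series, cohort: pd.DataFrame) -> np.ndarray:
    aligned = risks.reindex(cohort[PATIENT_ID])
    if aligned.isna().any():
        raise SchemaError("risk vector does not cover every patient in the cohort")
    return aligned.to_numpy(dtype=float)


def harrells_c(risks: pd.Series, cohort: pd.DataFrame) -> float:
    """Harrell's concordance: concordant pairs / comparable pairs.

    Pair (i, j) is comparable iff the earlier observed time belongs to an
    event; the higher-risk member failing first is concordant; risk ties count
    half.  Raises if no pair is comparable.
    """
    risk = _aligned_risks(risks, cohort)
    concordant, comparable = _concordance_counts(
        cohort[TIME].to_numpy(dtype=np.float64),
        cohort[EVENT].to_numpy(dtype=np.int64),
        risk.astype(np.float64),
    )
    if comparable == 0:
        raise UndefinedStatisticError("no comparable pairs")
    return concordant / comparable


def calibration_in_the_large(
    risks: pd.Series, cohort: pd.DataFrame, horizon: float
) -> float:
    """Mean predicted risk minus Kaplan-Meier observed risk at the horizon,
    in percentage points (negative = under-prediction)."""
    if len(cohort) == 0:
        raise EmptyCohortError("cohort is empty")
    risk = _aligned_risks(risks, cohort)
    observed = 100.0 * kaplan_meier(cohort, horizon)
    return float(np.mean(risk) - observed)


def mape_practical(replicate_risks: pd.Series, population_risks: pd.Series) -> float:
    """Mean absolute difference between a replicate model's risks and the
    population-derived risks, in percentage points.

    A practical stand-in for mean absolute prediction error when the true risk
    is unobservable: the population-derived risk plays the role of the truth.
    """
    if set(replicate_risks.index) != set(population_risks.index):
        raise SchemaError("replicate and population risk vectors cover different patients")
    diff = replicate_risks - population_risks.reindex(replicate_risks.index)
    return float(diff.abs().mean())


def net_benefit(
    risks: pd.Series,
    cohort: pd.DataFrame,
    threshold: float = 0.10,
    horizon: float = 10.0,
) -> float:
    """Decision-curve net benefit of treating at ``threshold`` (probability
    scale), adapted to censored outcomes.

    With h patients classified high-risk (risk >= threshold) and q the
    Kaplan-Meier event risk at the horizon within that group,
    NB = (h*q - h*(1-q) * threshold/(1-threshold)) / n.
    """
    if not 0.0 <= threshold < 1.0:
        raise InvalidThresholdError("threshold must be in [0, 1)")
    if len(cohort) == 0:
        raise EmptyCohortError("cohort is empty")
    risk = _aligned_risks(risks, cohort)
    high = risk >= 100.0 * threshold
    h = int(high.sum())
    if h == 0:
        return 0.0
    q = kaplan_meier(cohort.loc[high], horizon)
    n = len(cohort)
    tp = h * q
    fp = h * (1.0 - q)
    return float((tp - fp * threshold / (1.0 - threshold)) / n)
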