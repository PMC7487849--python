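"""Stability analyses of a patients-by-replicates risk matrix.

The headline instability measure is the per-patient 5-95th percentile range of
predicted risks across replicate models, summarised within 1%-wide bins of the
population-derived risk.  Companion analyses condition on the best-performing
replicates (by C-statistic, calibration deviation or MAPE) and compute the
probability that a replicate model classifies a patient on the opposite side
of the treatment threshold from their population-derived risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .resampling_experiment import RiskMatrix

__all__ = [
    "ReplicateSubset",
    "percentile_range",
    "per_patient_ranges",
    "summarise_by_bin",
    "subset_replicates",
    "threshold_crossing_probability",
]

SUBSET_METRICS = ("c_statistic", "citl_deviation", "mape_practical")


@dataclass(frozen=True)
class ReplicateSubset:
    """A performance-conditioned subset of replicate models."""

    metric: str
    fraction: float
    replicate_ids: tuple


def percentile_range(values, lo: float = 5.0, hi: float = 95.0) -> float:
    """hi-th minus lo-th percentile of ``values``.

    Percentiles use linear interpolation between closest order statistics: the
    q-th percentile of sorted values x_(1) <= ... <= x_(n) sits at fractional
    position 1 + q*(n-1)/100.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InvalidArgumentError("need at least 2 values for a percentile range")
    if not 0.0 <= lo < hi <= 100.0:
        raise InvalidArgumentError("need 0 <= lo < hi <= 100")
    p_lo, p_hi = np.percentile(values, [lo, hi])
    return float(p_hi - p_lo)


def _select_columns(matrix: RiskMatrix, subset: ReplicateSubset | None) -> np.ndarray:
    if subset is None:
        return matrix.risks
    return matrix.risks[:, matrix.column_index(subset.replicate_ids)]


def per_patient_ranges(
    matrix: RiskMatrix,
    subset: ReplicateSubset | None = None,
    lo: float = 5.0,
    hi: float = 95.0,
) -> np.ndarray:
    """Per-patient percentile range of risks across (a subset of) replicates."""
    risks = _select_columns(matrix, subset)
    if risks.shape[1] < 2:
        raise InvalidArgumentError("need at least 2 replicates for percentile ranges")
    p = np.percentile(risks, [lo, hi], axis=1)
    return p[1] - p[0]


def _bin_lower_edges(population_risk: np.ndarray, bin_width: float) -> np.ndarray:
    return np.floor(population_risk / bin_width) * bin_width


def summarise_by_bin(
    matrix: RiskMatrix,
    bin_width: float = 1.0,
    subset: ReplicateSubset | None = None,
    lo: float = 5.0,
    hi: float = 95.0,
) -> pd.DataFrame:
    """Distribution of per-patient percentile ranges within population-risk bins.

    Patients are assigned to half-open bins [k, k+bin_width) of their
    population-derived risk; per-bin patient count, median and quartiles of
    the ranges are reported; empty bins are omitted.
    """
    if matrix.n_patients == 0:
        raise InvalidArgumentError("risk matrix has no patients")
    ranges = per_patient_ranges(matrix, subset, lo, hi)
    edges = _bin_lower_edges(matrix.population_risk, bin_width)
    df = pd.DataFrame({"bin_lo": edges, "range": ranges})
    grouped = df.groupby("bin_lo")["range"]
    out = pd.DataFrame(
        {
            "bin_lo": grouped.median().index,
            "bin_hi": grouped.median().index + bin_width,
            "n_patients": grouped.size().to_numpy(),
            "median_range": grouped.median().to_numpy(),
            "q25_range": grouped.quantile(0.25).to_numpy(),
            "q75_range": grouped.quantile(0.75).to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def subset_replicates(
    performance: list,
    population_citl: float,
    metric: str,
    fraction: float,
) -> ReplicateSubset:
    """Best-performing replicates by one metric.

    * ``c_statistic``: largest values kept.
    * ``citl_deviation``: smallest |CITL - population CITL| kept.
    * ``mape_practical``: smallest values kept.

    Subset size is floor(fraction * n_replicates) (all replicates when
    fraction == 1); ties are broken deterministically by replicate id.
    """
    if metric not in SUBSET_METRICS:
        raise InvalidArgumentError(f"unknown subset metric {metric!r}")
    if not 0.0 < fraction <= 1.0:
        raise InvalidArgumentError("fraction must be in (0, 1]")
    ids = np.array([p.replicate_id for p in performance])
    if metric == "c_statistic":
        key = -np.array([p.c_statistic for p in performance])
    elif metric == "citl_deviation":
        key = np.abs(np.array([p.citl for p in performance]) - population_citl)
    else:
        key = np.array([p.mape_practical for p in performance])
    order = np.lexsort((ids, key))
    k = len(ids) if fraction == 1.0 else math.floor(fraction * len(ids))
    if k < 1:
        raise InvalidArgumentError("fraction keeps no replicates")
    kept = np.sort(ids[order[:k]])
    return ReplicateSubset(metric=metric, fraction=fraction, replicate_ids=tuple(kept))


def threshold_crossing_probability(
    matrix: RiskMatrix,
    threshold: float = 10.0,
    bin_width: float = 1.0,
    subset: ReplicateSubset | None = None,
) -> pd.DataFrame:
    """Per-bin probability of being classified on the opposite side of the
    treatment threshold (percent scale) from the population-derived risk.

    A risk >= threshold counts as high-risk (the boundary is assigned to
    treatment).  Per patient, the proportion of replicate models on the
    opposite side of the threshold is computed, then averaged within each
    population-risk bin.
    """
    if not 0.0 < threshold < 100.0:
        raise InvalidArgumentError("threshold must be in (0, 100) percent")
    risks = _select_columns(matrix, subset)
    pop_high = matrix.population_risk >= threshold
    rep_high = risks >= threshold
    crossing = (rep_high != pop_high[:, None]).mean(axis=1)
    edges = _bin_lower_edges(matrix.population_risk, bin_width)
    df = pd.DataFrame({"bin_lo": edges, "crossing": crossing})
    grouped = df.groupby("bin_lo")["crossing"]
    return pd.DataFrame(
        {
            "bin_lo": grouped.mean().index,
            "bin_hi": grouped.mean().index + bin_width,
            "n_patients": grouped.size().to_numpy(),
            "crossing_probability": grouped.mean().to_numpy(),
        }
    ).reset_index(drop=True)
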