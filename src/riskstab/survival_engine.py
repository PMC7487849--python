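"""Proportional-hazards risk models and 10-year risk prediction.

A :class:`RiskModel` bundles Cox coefficients, the Breslow baseline cumulative
hazard and the design-encoding/centering conventions needed to turn a fitted
model into individual risks.  Risks are carried on the percent scale (0–100)
end-to-end, because every downstream stability quantity is an absolute
difference in risk, in percentage points.

Model fitting is delegated to scikit-survival (Newton optimisation of the Cox
partial likelihood with Breslow tie handling and the matching Breslow baseline
estimator); Kaplan–Meier estimation to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from sklearn.exceptions import ConvergenceWarning
from sksurv.linear_model import CoxPHSurvivalAnalysis
from sksurv.util import Surv

from .errors import (
    EmptyCohortError,
    FitFailureError,
    InvalidArgumentError,
    NoEventsError,
    SchemaError,
)
from .synthetic_cohort import EVENT, PATIENT_ID, TIME

__all__ = ["RiskModel", "fit_cox", "predict_risk", "kaplan_meier"]


@dataclass
class RiskModel:
    """A fitted proportional-hazards risk model.

    ``coefficients`` is indexed by design-column name; categorical covariates
    are dummy-coded against the reference level recorded in ``term_encoding``
    (reference = most prevalent level in the fitting cohort, alphabetical
    tie-break).  Design columns were centred at ``centering`` (fitting-sample
    means) before the baseline hazard was estimated, so predictions must use
    the same convention.
    """

    coefficients: pd.Series
    term_encoding: dict
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    centering: pd.Series
    horizon: float
    n_events: int
    max_observed_time: float

    def cumulative_baseline_hazard(self, t: float) -> float:
        """H0(t): step-function value at the largest event time <= t (0 before
        the first event; flat beyond the last observed event time)."""
        idx = np.searchsorted(self.baseline_times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.baseline_cumhaz[idx])

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        design = build_design(covariates, self.term_encoding)
        return (design - self.centering).to_numpy() @ self.coefficients.to_numpy()


def _infer_encoding(cohort: pd.DataFrame, terms: list[str]) -> dict:
    """Design encoding per covariate: numeric columns pass through; non-numeric
    columns are dummy-coded with the most prevalent level as reference."""
    encoding: dict = {}
    for term in terms:
        if term not in cohort.columns:
            raise SchemaError(f"covariate {term!r} not in cohort")
        col = cohort[term]
        if pd.api.types.is_numeric_dtype(col):
            encoding[term] = {"kind": "numeric"}
        else:
            counts = col.value_counts()
            top = counts.max()
            reference = sorted(counts[counts == top].index)[0]
            levels = [reference] + sorted(l for l in counts.index if l != reference)
            encoding[term] = {"kind": "categorical", "reference": reference, "levels": levels}
    return encoding


def build_design(covariates: pd.DataFrame, encoding: dict) -> pd.DataFrame:
    """Design matrix under a fixed encoding.  Raises SchemaError on missing
    terms or categorical levels unseen at fitting time."""
    cols = {}
    for term, enc in encoding.items():
        if term not in covariates.columns:
            raise SchemaError(f"covariate {term!r} missing from prediction data")
        col = covariates[term]
        if enc["kind"] == "numeric":
            cols[term] = col.astype(float).to_numpy()
        else:
            known = set(enc["levels"])
            seen = set(col.unique())
            if not seen <= known:
                raise SchemaError(
                    f"covariate {term!r} has unseen levels {sorted(seen - known)}"
                )
            arr = col.to_numpy()
            for level in enc["levels"][1:]:
                cols[f"{term}__{level}"] = (arr == level).astype(float)
    return pd.DataFrame(cols, index=covariates.index)


def fit_cox(cohort: pd.DataFrame, terms: list[str], *, horizon: float = 10.0) -> RiskModel:
    """Fit a Cox proportional-hazards model by partial likelihood (Breslow ties)
    and estimate the Breslow baseline cumulative hazard on centred covariates.

    Raises :class:`NoEventsError` if the cohort has no events and
    :class:`FitFailureError` (with diagnostics) on rank deficiency,
    non-convergence or numerically degenerate fits; the resampling layer
    decides what to do with failures.
    """
    if len(cohort) == 0:
        raise EmptyCohortError("cannot fit on an empty cohort")
    n_events = int(cohort[EVENT].sum())
    if n_events == 0:
        raise NoEventsError("cohort has no events")
    if n_events < 2:
        raise FitFailureError("fewer than 2 events", {"n_events": n_events})

    encoding = _infer_encoding(cohort, list(terms))
    design = build_design(cohort, encoding)
    centering = design.mean()
    centred = design - centering

    # rank check before handing to the optimiser
    if len(centred.columns) == 0:
        raise InvalidArgumentError("no design columns")
    rank = np.linalg.matrix_rank(centred.to_numpy())
    if rank < centred.shape[1]:
        raise FitFailureError(
            "design matrix is rank deficient",
            {"rank": int(rank), "n_columns": int(centred.shape[1])},
        )

    y = Surv.from_arrays(
        event=cohort[EVENT].to_numpy().astype(bool),
        time=cohort[TIME].to_numpy().astype(float),
    )
    est = CoxPHSurvivalAnalysis(alpha=0.0, ties="breslow", n_iter=200)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=ConvergenceWarning)
            # transient exp overflow inside Newton steps is harmless; final
            # coefficients are checked for finiteness below
            warnings.simplefilter("ignore", category=RuntimeWarning)
            est.fit(centred.to_numpy(), y)
    except Exception as exc:  # non-convergence, overflow, singular information
        raise FitFailureError(f"Cox fit failed: {exc}", {"n_events": n_events}) from exc
    coef = np.asarray(est.coef_, dtype=float)
    if not np.all(np.isfinite(coef)):
        raise FitFailureError("non-finite coefficients", {"n_events": n_events})

    step = est.cum_baseline_hazard_
    return RiskModel(
        coefficients=pd.Series(coef, index=centred.columns),
        term_encoding=encoding,
        baseline_times=np.asarray(step.x, dtype=float),
        baseline_cumhaz=np.asarray(step.y, dtype=float),
        centering=centering,
        horizon=horizon,
        n_events=n_events,
        max_observed_time=float(cohort[TIME].max()),
    )


def predict_risk(
    model: RiskModel, covariates: pd.DataFrame, horizon: float | None = None
) -> pd.Series:
    """Individual event risks by ``horizon`` years, percent scale.

    risk = 100 * (1 - exp(-H0(horizon) * exp(lp))) with the linear predictor
    computed under the model's centering convention.  Returns a Series indexed
    by patient id.
    """
    horizon = model.horizon if horizon is None else horizon
    if horizon > model.max_observed_time:
        warnings.warn(
            "prediction horizon exceeds the fitting cohort's follow-up; "
            "baseline hazard extrapolated flat",
            stacklevel=2,
        )
    h0 = model.cumulative_baseline_hazard(horizon)
    lp = model.linear_predictor(covariates)
    risk = 100.0 * (-np.expm1(-h0 * np.exp(lp)))
    index = (
        covariates[PATIENT_ID]
        if PATIENT_ID in covariates.columns
        else covariates.index
    )
    return pd.Series(risk, index=pd.Index(index, name=PATIENT_ID), name="risk")


def kaplan_meier(cohort: pd.DataFrame, t: float) -> float:
    """Kaplan–Meier estimate of the event risk by time ``t``: 1 - S_hat(t).

    Events at t are included (S_hat is right-continuous); censorings at t leave
    the risk set only after t.
    """
    if t < 0:
        raise InvalidArgumentError("t must be nonnegative")
    if len(cohort) == 0:
        raise EmptyCohortError("Kaplan-Meier undefined on an empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(cohort[TIME].to_numpy(), cohort[EVENT].to_numpy())
    return float(1.0 - kmf.predict(t))
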