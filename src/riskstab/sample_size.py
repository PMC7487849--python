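"""Sample-size calculators for risk prediction models.

Two families are provided: the traditional events-per-variable rule (EPV, with
EPV = 10 as the classic target), and the published minimum-sample-size
criteria for multivariable prediction models that bound (i) expected
shrinkage, (ii) absolute optimism in the Cox-Snell R-squared, and (iii) the
error in the estimated overall risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InfeasibleError, InvalidArgumentError

__all__ = [
    "SampleSizeInputs",
    "epv10_sample_size",
    "max_cox_snell_r2",
    "riley_minimum_sample_size",
]

_Z975 = 1.959963984540054  # standard-normal 97.5th percentile


@dataclass(frozen=True)
class SampleSizeInputs:
    """Inputs to the minimum-sample-size criteria.

    ``n_parameters`` is the number of candidate predictor parameters p (13 for
    the default 9-variable CVD model); ``event_proportion`` the anticipated
    outcome proportion phi; ``shrinkage_target`` the acceptable expected
    shrinkage S (0.9 = at most 10% expected overfitting);
    ``r2_cs_adj`` the anticipated adjusted Cox-Snell R-squared;
    ``optimism_delta`` the acceptable absolute optimism in R-squared;
    ``risk_margin`` the acceptable absolute error in the overall risk estimate.
    """

    n_parameters: int
    event_proportion: float
    shrinkage_target: float = 0.9
    r2_cs_adj: float = 0.05
    optimism_delta: float = 0.05
    risk_margin: float = 0.05
    epv_target: float = 10.0

    def __post_init__(self):
        if self.n_parameters < 1:
            raise InvalidArgumentError("n_parameters must be >= 1")
        if not 0.0 < self.event_proportion < 1.0:
            raise InvalidArgumentError("event_proportion must be in (0, 1)")
        if not 0.0 < self.shrinkage_target < 1.0:
            raise InvalidArgumentError("shrinkage_target must be in (0, 1)")
        if not self.r2_cs_adj > 0.0:
            raise InvalidArgumentError("r2_cs_adj must be positive")
        for name in ("optimism_delta", "risk_margin"):
            if not getattr(self, name) > 0.0:
                raise InvalidArgumentError(f"{name} must be positive")


def epv10_sample_size(
    n_parameters: int, event_proportion: float, epv_target: float = 10.0
) -> int:
    """Sample size meeting the events-per-variable rule.

    Required events = epv_target * n_parameters; the returned cohort size is
    required events / event proportion, rounded to the nearest integer.
    """
    if n_parameters < 1:
        raise InvalidArgumentError("n_parameters must be >= 1")
    if not 0.0 < event_proportion <= 1.0:
        raise InfeasibleError("event_proportion must be in (0, 1]")
    required_events = epv_target * n_parameters
    return int(math.floor(required_events / event_proportion + 0.5))


def max_cox_snell_r2(event_proportion: float) -> float:
    """Maximum attainable Cox-Snell R-squared for a binary outcome with the
    given event proportion: 1 - exp(2 * log-likelihood of the null model / n)."""
    phi = event_proportion
    if not 0.0 < phi < 1.0:
        raise InvalidArgumentError("event_proportion must be in (0, 1)")
    ll0 = phi * math.log(phi) + (1.0 - phi) * math.log(1.0 - phi)
    return 1.0 - math.exp(2.0 * ll0)


def _shrinkage_criterion_n(n_parameters: int, shrinkage: float, r2_cs_adj: float) -> float:
    return n_parameters / ((shrinkage - 1.0) * math.log(1.0 - r2_cs_adj / shrinkage))


def riley_minimum_sample_size(inputs: SampleSizeInputs, *, variant: str = "proportion") -> dict:
    """Minimum sample size from the three published criteria.

    (i)   expected shrinkage >= S:  n = p / ((S-1) * ln(1 - R2/S));
    (ii)  small optimism: S* = R2 / (R2 + delta * R2_max), then criterion (i)
          with max(S, S*);
    (iii) precise overall risk: n = (z_.975 / margin)^2 * phi * (1 - phi).

    ``variant="person_time"`` swaps criterion (iii) for a rate-based form that
    bounds the error of the cumulative incidence at the horizon estimated from
    an exponential event rate over the anticipated person-time (requires
    ``mean_followup`` and ``horizon`` via keyword use of the proportion form's
    inputs is then approximate); the proportion-based forms are the default.

    Returns the per-criterion sizes (rounded up) and their maximum ``n_min``.
    """
    r2_max = max_cox_snell_r2(inputs.event_proportion)
    if inputs.r2_cs_adj >= r2_max:
        raise InvalidArgumentError(
            f"r2_cs_adj={inputs.r2_cs_adj} must be below the attainable maximum {r2_max:.4f}"
        )
    n_i = _shrinkage_criterion_n(
        inputs.n_parameters, inputs.shrinkage_target, inputs.r2_cs_adj
    )
    s_star = inputs.r2_cs_adj / (inputs.r2_cs_adj + inputs.optimism_delta * r2_max)
    s_eff = max(inputs.shrinkage_target, s_star)
    n_ii = _shrinkage_criterion_n(inputs.n_parameters, s_eff, inputs.r2_cs_adj)
    phi = inputs.event_proportion
    if variant == "proportion":
        n_iii = (_Z975 / inputs.risk_margin) ** 2 * phi * (1.0 - phi)
    elif variant == "person_time":
        # exponential-rate form: risk at 10y from lambda-hat = events / person-time,
        # mean follow-up 7y assumed; delta-method bound on the incidence error
        horizon, mean_followup = 10.0, 7.0
        lam = -math.log(1.0 - phi) / mean_followup
        deriv = horizon * math.exp(-lam * horizon)
        n_iii = (_Z975 * deriv / inputs.risk_margin) ** 2 * lam / mean_followup
    else:
        raise InvalidArgumentError(f"unknown variant {variant!r}")
    per_criterion = {
        "shrinkage": math.ceil(n_i),
        "optimism": math.ceil(n_ii),
        "risk_precision": math.ceil(n_iii),
    }
    return {"n_min": max(per_criterion.values()), "criteria": per_criterion}
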