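"""The core resampling experiment.

A model developed on the whole development cohort (the "population") defines
population-derived risks.  For each sample size N, the experiment draws N
patients from the development cohort (without replacement, or bootstrap with
replacement), fits a Cox model on the draw, scores the contemporary cohort
(feeding the stability analyses) and the validation cohort (feeding the four
performance measures), and repeats.  The patients-by-replicates risk matrix is
the object every stability analysis consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EmptyCohortError,
    ExperimentFailureError,
    FitFailureError,
    InvalidArgumentError,
    NoEventsError,
    SchemaError,
)
from .performance_metrics import (
    ReplicatePerformance,
    calibration_in_the_large,
    harrells_c,
    mape_practical,
    net_benefit,
)
from .survival_engine import RiskModel, fit_cox, kaplan_meier, predict_risk
from .synthetic_cohort import EVENT, PATIENT_ID, TIME

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentDesign",
    "RiskMatrix",
    "PopulationReference",
    "derive_population_model",
    "run_replicates",
    "bootstrap_replicates",
]

WITHOUT_REPLACEMENT = "without_replacement"
BOOTSTRAP = "bootstrap"


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of the resampling experiment.

    ``sample_sizes`` lists the development-sample sizes N to evaluate;
    ``replicates`` models are fitted per N; ``threshold`` is the treatment
    threshold on the probability scale (0.10 = the 10% statin-eligibility
    threshold).
    """

    sample_sizes: tuple[int, ...] = (10_000, 50_000, 100_000)
    replicates: int = 1000
    sampling_mode: str = WITHOUT_REPLACEMENT
    master_seed: int = 0
    horizon: float = 10.0
    threshold: float = 0.10

    def __post_init__(self):
        if self.replicates < 1:
            raise InvalidArgumentError("replicates must be >= 1")
        if self.sampling_mode not in (WITHOUT_REPLACEMENT, BOOTSTRAP):
            raise InvalidArgumentError(f"unknown sampling mode {self.sampling_mode!r}")
        if not 0.0 <= self.threshold < 1.0:
            raise InvalidArgumentError("threshold must be in [0, 1)")


@dataclass
class RiskMatrix:
    """Patients-by-replicates matrix of predicted risks (percent scale) for the
    contemporary cohort, plus the population-derived risk of each patient.

    Columns correspond to the successful replicates listed in
    ``replicate_ids``; failed fits are recorded in ``failures`` and excluded
    (never silently retried, since retrying would bias the instability
    estimate)."""

    patient_ids: np.ndarray
    population_risk: np.ndarray
    risks: np.ndarray
    replicate_ids: np.ndarray
    replicate_seeds: list
    failures: list
    metadata: dict = field(default_factory=dict)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_replicates(self) -> int:
        return self.risks.shape[1]

    def column_index(self, replicate_ids) -> np.ndarray:
        """Column positions of the given replicate ids."""
        lookup = {rid: k for k, rid in enumerate(self.replicate_ids)}
        try:
            return np.array([lookup[rid] for rid in replicate_ids], dtype=int)
        except KeyError as exc:
            raise InvalidArgumentError(f"unknown replicate id {exc.args[0]}") from exc


@dataclass
class PopulationReference:
    """Population model plus the risks and performance derived from it."""

    model: RiskModel
    risks: dict  # cohort name -> pd.Series of percent risks
    performance: ReplicatePerformance  # on the validation cohort; mape = 0 by definition


def derive_population_model(
    development: pd.DataFrame,
    score_cohorts: dict,
    terms: list[str],
    *,
    horizon: float = 10.0,
    threshold: float = 0.10,
) -> PopulationReference:
    """Fit the population model on the entire development cohort and score
    every supplied cohort with it (the population-derived risks).

    ``score_cohorts`` maps cohort names to tables; performance is evaluated on
    the cohort named ``"validation"`` when present.
    """
    if len(development) == 0:
        raise EmptyCohortError("development cohort is empty")
    model = fit_cox(development, terms, horizon=horizon)
    risks = {name: predict_risk(model, cohort) for name, cohort in score_cohorts.items()}
    if "validation" in score_cohorts:
        validation = score_cohorts["validation"]
        vrisks = risks["validation"]
        perf = ReplicatePerformance(
            replicate_id=-1,
            c_statistic=harrells_c(vrisks, validation),
            citl=calibration_in_the_large(vrisks, validation, horizon),
            mape_practical=0.0,
            net_benefit=net_benefit(vrisks, validation, threshold, horizon),
        )
    else:
        perf = ReplicatePerformance(-1, np.nan, np.nan, 0.0, np.nan)
    return PopulationReference(model=model, risks=risks, performance=perf)


def _draw_indices(
    n_development: int, n_sample: int, mode: str, rng: np.random.Generator
) -> np.ndarray:
    """One replicate's patient draw, returned sorted so that the fitted model
    is invariant to the draw order (and a full-population draw without
    replacement is exactly the development cohort)."""
    replace = mode == BOOTSTRAP
    if not replace and n_sample > n_development:
        raise InvalidArgumentError(
            "sample size exceeds development cohort for without-replacement sampling"
        )
    return np.sort(rng.choice(n_development, size=n_sample, replace=replace))


def _replicate_seed(master_seed: int, mode: str, n_sample: int, replicate: int):
    mode_code = 0 if mode == WITHOUT_REPLACEMENT else 1
    return np.random.SeedSequence([master_seed, mode_code, n_sample, replicate])


def run_replicates(
    development: pd.DataFrame,
    contemporary: pd.DataFrame,
    validation: pd.DataFrame,
    design: ExperimentDesign,
    n_sample: int,
    *,
    terms: list[str] | None = None,
    population: PopulationReference | None = None,
    sampling_mode: str | None = None,
):
    """Run the resampling experiment at one sample size.

    Per replicate: draw ``n_sample`` patients from the development cohort
    (child seed derived deterministically from the master seed, the sample
    size and the replicate index), fit a Cox model, score the contemporary
    cohort into a risk-matrix column and the validation cohort into the four
    performance measures (MAPE against the validation population-derived
    risks).  Failed fits are logged and excluded.

    Returns ``(RiskMatrix, list[ReplicatePerformance])``.
    """
    mode = design.sampling_mode if sampling_mode is None else sampling_mode
    if terms is None:
        terms = [
            c for c in development.columns if c not in (PATIENT_ID, TIME, EVENT)
        ]
    if n_sample < len(terms) + 1:
        raise InvalidArgumentError("sample size too small for the model terms")
    if population is None:
        population = derive_population_model(
            development,
            {"contemporary": contemporary, "validation": validation},
            terms,
            horizon=design.horizon,
            threshold=design.threshold,
        )
    pop_contemporary = population.risks["contemporary"]
    pop_validation = population.risks["validation"]

    columns = []
    replicate_ids = []
    seeds = []
    failures = []
    performance = []
    for r in range(design.replicates):
        seed_seq = _replicate_seed(design.master_seed, mode, n_sample, r)
        rng = np.random.default_rng(seed_seq)
        idx = _draw_indices(len(development), n_sample, mode, rng)
        sample = development.iloc[idx].reset_index(drop=True)
        try:
            model = fit_cox(sample, terms, horizon=design.horizon)
            # a sample missing a categorical level yields a model that cannot
            # score the full cohorts; that is a failure of the replicate too
            contemporary_risks = predict_risk(model, contemporary).to_numpy()
            vrisks = predict_risk(model, validation)
        except (FitFailureError, NoEventsError, SchemaError) as exc:
            logger.info("replicate %d at N=%d failed: %s", r, n_sample, exc)
            failures.append({"replicate": r, "reason": str(exc)})
            continue
        columns.append(contemporary_risks)
        performance.append(
            ReplicatePerformance(
                replicate_id=r,
                c_statistic=harrells_c(vrisks, validation),
                citl=calibration_in_the_large(vrisks, validation, design.horizon),
                mape_practical=mape_practical(vrisks, pop_validation),
                net_benefit=net_benefit(vrisks, validation, design.threshold, design.horizon),
            )
        )
        replicate_ids.append(r)
        seeds.append(seed_seq.entropy)

    if not columns:
        raise ExperimentFailureError(f"all {design.replicates} replicates failed at N={n_sample}")

    matrix = RiskMatrix(
        patient_ids=contemporary[PATIENT_ID].to_numpy(),
        population_risk=pop_contemporary.to_numpy(),
        risks=np.column_stack(columns),
        replicate_ids=np.asarray(replicate_ids, dtype=int),
        replicate_seeds=seeds,
        failures=failures,
        metadata={
            "sampling_mode": mode,
            "n_sample": n_sample,
            "master_seed": design.master_seed,
            "horizon": design.horizon,
        },
    )
    return matrix, performance


def bootstrap_replicates(
    development: pd.DataFrame,
    contemporary: pd.DataFrame,
    validation: pd.DataFrame,
    design: ExperimentDesign,
    n_sample: int | None = None,
    *,
    terms: list[str] | None = None,
    population: PopulationReference | None = None,
):
    """Bootstrap variant: draw with replacement, N defaulting to the full
    development-cohort size.

    This is the procedure available in practice when the overarching
    population cannot be resampled: bootstrap risks are centred on the risks
    of the development sample rather than on the population-derived risks, but
    the level of variation is comparable, so stability can still be assessed.
    """
    if n_sample is None:
        n_sample = len(development)
    matrix, performance = run_replicates(
        development,
        contemporary,
        validation,
        design,
        n_sample,
        terms=terms,
        population=population,
        sampling_mode=BOOTSTRAP,
    )
    matrix.metadata["caveat"] = (
        "bootstrap risks are centred on the risk of the development sample, "
        "not the population-derived risk; only the spread is comparable"
    )
    return matrix, performance
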