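import numpy as np
import pandas as pd
import pytest

from riskstab.synthetic_cohort import (
    CovariateSpec,
    GeneratorTruth,
    calibrate_baseline,
    default_female_spec,
    generate_cohort,
)


def make_cohort(times, events, **covariates) -> pd.DataFrame:
    """Hand-build a small cohort table."""
    n = len(times)
    data = {"patient_id": np.arange(n), "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=int)}
    data.update({k: np.asarray(v) for k, v in covariates.items()})
    return pd.DataFrame(data)


@pytest.fixture(scope="session")
def female_truth():
    return default_female_spec()


@pytest.fixture(scope="session")
def female_cohort_100k(female_truth):
    """One large cohort from the default truth, shared across recovery tests."""
    return generate_cohort(female_truth, 100_000, seed=0)


def _tiny_covariates():
    return (
        CovariateSpec("biomarker", "continuous", mean=0.0, sd=1.0, log_hazard_ratio=0.8),
        CovariateSpec("exposed", "binary", prevalence=0.3, log_hazard_ratio=0.5),
        CovariateSpec(
            "grp", "categorical",
            category_labels=("a", "b", "c"),
            category_probs=(0.5, 0.3, 0.2),
            level_log_hazard_ratios={"b": 0.4, "c": 0.7},
        ),
    )


@pytest.fixture(scope="session")
def tiny_truth():
    """A cheap 3-covariate truth with a 25% event proportion, for unit tests
    that need plentiful events at small n."""
    shell = GeneratorTruth(
        covariates=_tiny_covariates(),
        baseline_rate=0.0,
        target_event_proportion=0.25,
        target_mean_followup=7.0,
    )
    rate = calibrate_baseline(shell, 0.25, n_lp_samples=100_000)
    return GeneratorTruth(
        covariates=_tiny_covariates(),
        baseline_rate=rate,
        target_event_proportion=0.25,
        target_mean_followup=7.0,
    )


@pytest.fixture(scope="session")
def tiny_cohorts(tiny_truth):
    """(development, contemporary, validation) trio from the tiny truth."""
    development = generate_cohort(tiny_truth, 4000, seed=101)
    contemporary = generate_cohort(tiny_truth, 600, seed=102)
    validation = generate_cohort(tiny_truth, 600, seed=103)
    return development, contemporary, validation
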