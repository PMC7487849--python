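import numpy as np
import pandas as pd
import pytest

from riskstab.errors import InvalidArgumentError
from riskstab.resampling_experiment import (
    BOOTSTRAP,
    WITHOUT_REPLACEMENT,
    ExperimentDesign,
    _draw_indices,
    bootstrap_replicates,
    derive_population_model,
    run_replicates,
)
from riskstab.stability_analysis import per_patient_ranges, threshold_crossing_probability
from riskstab.synthetic_cohort import generate_cohort


@pytest.fixture(scope="module")
def tiny_design():
    return ExperimentDesign(sample_sizes=(), replicates=25, master_seed=5, horizon=10.0)


@pytest.fixture(scope="module")
def tiny_population(tiny_truth, tiny_cohorts):
    development, contemporary, validation = tiny_cohorts
    return derive_population_model(
        development,
        {"contemporary": contemporary, "validation": validation},
        tiny_truth.covariate_names,
    )


class TestDesign:
    def test_invalid_mode_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ExperimentDesign(sampling_mode="jackknife")

    def test_replicates_must_be_positive(self):
        with pytest.raises(InvalidArgumentError):
            ExperimentDesign(replicates=0)


class TestDrawIndices:
    def test_without_replacement_has_no_duplicates(self):
        rng = np.random.default_rng(0)
        idx = _draw_indices(1000, 400, WITHOUT_REPLACEMENT, rng)
        assert len(np.unique(idx)) == 400

    def test_bootstrap_can_duplicate(self):
        rng = np.random.default_rng(0)
        idx = _draw_indices(50, 50, BOOTSTRAP, rng)
        assert len(np.unique(idx)) < 50  # overwhelmingly likely; seed fixed

    def test_oversized_without_replacement_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(InvalidArgumentError):
            _draw_indices(10, 11, WITHOUT_REPLACEMENT, rng)


class TestPopulationModel:
    def test_scoring_duplicate_cohort_gives_identical_risks(self, tiny_truth, tiny_cohorts):
        development, contemporary, _ = tiny_cohorts
        ref = derive_population_model(
            development,
            {"a": contemporary, "b": contemporary.copy()},
            tiny_truth.covariate_names,
        )
        pd.testing.assert_series_equal(ref.risks["a"], ref.risks["b"])

    def test_population_mape_against_itself_is_zero(self, tiny_population):
        from riskstab.performance_metrics import mape_practical

        v = tiny_population.risks["validation"]
        assert mape_practical(v, v.copy()) == 0.0
        assert tiny_population.performance.mape_practical == 0.0

    def test_population_performance_recorded(self, tiny_population):
        assert 0.5 < tiny_population.performance.c_statistic <= 1.0
        assert np.isfinite(tiny_population.performance.citl)
        assert np.isfinite(tiny_population.performance.net_benefit)


class TestRunReplicates:
    def test_sample_size_below_terms_rejected(self, tiny_truth, tiny_cohorts, tiny_design):
        development, contemporary, validation = tiny_cohorts
        with pytest.raises(InvalidArgumentError):
            run_replicates(development, contemporary, validation, tiny_design, 3,
                           terms=tiny_truth.covariate_names)

    def test_same_master_seed_identical_matrices(self, tiny_truth, tiny_cohorts,
                                                 tiny_population):
        development, contemporary, validation = tiny_cohorts
        design = ExperimentDesign(sample_sizes=(), replicates=8, master_seed=9)
        out = [
            run_replicates(development, contemporary, validation, design, 400,
                           terms=tiny_truth.covariate_names, population=tiny_population)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(out[0][0].risks, out[1][0].risks)
        assert [p.c_statistic for p in out[0][1]] == [p.c_statistic for p in out[1][1]]

    def test_full_population_draw_reproduces_population_risks(
        self, tiny_truth, tiny_cohorts, tiny_population, tiny_design
    ):
        development, contemporary, validation = tiny_cohorts
        design = ExperimentDesign(sample_sizes=(), replicates=4, master_seed=3)
        matrix, _ = run_replicates(
            development, contemporary, validation, design, len(development),
            terms=tiny_truth.covariate_names, population=tiny_population,
        )
        pop = matrix.population_risk
        for col in range(matrix.n_replicates):
            np.testing.assert_array_equal(matrix.risks[:, col], pop)
        assert (per_patient_ranges(matrix) == 0.0).all()
        crossing = threshold_crossing_probability(matrix, threshold=10.0)
        assert (crossing["crossing_probability"] == 0.0).all()

    def test_jensen_bound_mape_at_least_mean_signed_difference(
        self, tiny_truth, tiny_cohorts, tiny_population, tiny_design
    ):
        # per replicate, mean |risk - population risk| >= |mean signed difference|
        development, contemporary, validation = tiny_cohorts
        matrix, _ = run_replicates(
            development, contemporary, validation, tiny_design, 300,
            terms=tiny_truth.covariate_names, population=tiny_population,
        )
        deviations = matrix.risks - matrix.population_risk[:, None]
        signed = deviations.mean(axis=0)
        mape_contemporary = np.abs(deviations).mean(axis=0)
        assert (mape_contemporary >= np.abs(signed) - 1e-12).all()

    def test_monotone_stability_in_sample_size(self, tiny_truth, tiny_cohorts,
                                               tiny_population):
        development, contemporary, validation = tiny_cohorts
        design = ExperimentDesign(sample_sizes=(), replicates=30, master_seed=17)
        medians = []
        for n_sample in (100, 400, 1600):
            matrix, _ = run_replicates(
                development, contemporary, validation, design, n_sample,
                terms=tiny_truth.covariate_names, population=tiny_population,
            )
            medians.append(np.median(per_patient_ranges(matrix)))
        assert medians[0] > medians[1] > medians[2]

    def test_failures_are_logged_not_retried(self, tiny_truth, tiny_cohorts,
                                             tiny_population):
        development, contemporary, validation = tiny_cohorts
        # N barely above the parameter count: some replicates fail to fit
        design = ExperimentDesign(sample_sizes=(), replicates=40, master_seed=23)
        matrix, performance = run_replicates(
            development, contemporary, validation, design, 8,
            terms=tiny_truth.covariate_names, population=tiny_population,
        )
        assert matrix.n_replicates + len(matrix.failures) == design.replicates
        assert len(performance) == matrix.n_replicates


class TestBootstrap:
    def test_degenerate_single_pattern_cohort_cannot_vary(self):
        # a cohort that is one patient row duplicated has a constant design
        # column, so no Cox model exists for it: the population fit itself is
        # rank deficient rather than the replicates exhibiting variability
        from riskstab.errors import FitFailureError
        from conftest import make_cohort

        base = make_cohort(times=[2.0] * 20, events=[1] * 20, x=[1.0] * 20)
        design = ExperimentDesign(sample_sizes=(), replicates=4, master_seed=2)
        with pytest.raises(FitFailureError):
            bootstrap_replicates(base, base, base, design, terms=["x"])

    def test_bootstrap_same_seed_identical(self, tiny_truth, tiny_cohorts, tiny_population):
        development, contemporary, validation = tiny_cohorts
        design = ExperimentDesign(sample_sizes=(), replicates=6, master_seed=31)
        a, _ = bootstrap_replicates(development, contemporary, validation, design, 500,
                                    terms=tiny_truth.covariate_names,
                                    population=tiny_population)
        b, _ = bootstrap_replicates(development, contemporary, validation, design, 500,
                                    terms=tiny_truth.covariate_names,
                                    population=tiny_population)
        np.testing.assert_array_equal(a.risks, b.risks)

    def test_bootstrap_caveat_recorded(self, tiny_truth, tiny_cohorts, tiny_population):
        development, contemporary, validation = tiny_cohorts
        design = ExperimentDesign(sample_sizes=(), replicates=4, master_seed=8)
        matrix, _ = bootstrap_replicates(development, contemporary, validation, design,
                                         400, terms=tiny_truth.covariate_names,
                                         population=tiny_population)
        assert "centred on the risk" in matrix.metadata["caveat"]
        assert matrix.metadata["n_sample"] == 400
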