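"""End-to-end pipeline: configuration, cohort assembly, experiment execution
and machine-readable result tables.

``run_pipeline`` materialises the whole experiment for every configured sample
size and writes four artifacts to the output directory:

* ``performance_quantiles.csv`` — 2.5/25/50/75/97.5th percentiles of the
  C-statistic, calibration-in-the-large, MAPE and net benefit per sample size;
* ``stability_by_bin.csv`` — per-bin percentile-range summaries for all
  replicates and for every performance-conditioned subset;
* ``crossing_by_bin.csv`` — per-bin threshold-crossing probabilities;
* ``run_manifest.json`` — seeds, versions, fit-failure counts, population
  performance.

Everything is deterministic given the master seed.
"""

from __future__ import annotations

import json
import math
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InvalidArgumentError, PipelineError
from .performance_metrics import ReplicatePerformance
from .resampling_experiment import (
    ExperimentDesign,
    derive_population_model,
    run_replicates,
)
from .sample_size import SampleSizeInputs, epv10_sample_size, riley_minimum_sample_size
from .stability_analysis import (
    SUBSET_METRICS,
    subset_replicates,
    summarise_by_bin,
    threshold_crossing_probability,
)
from .synthetic_cohort import (
    EVENT,
    PATIENT_ID,
    TIME,
    GeneratorTruth,
    default_female_contemporary_spec,
    default_female_spec,
    generate_cohort,
    read_cohort_csv,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_SUBSET_FRACTIONS = (2.0 / 3.0, 1.0 / 3.0)

_TRUTH_PRESETS = {
    "default_female": default_female_spec,
    "default_female_contemporary": default_female_contemporary_spec,
}


def _resolve_truth(value) -> GeneratorTruth:
    if isinstance(value, str):
        try:
            return _TRUTH_PRESETS[value]()
        except KeyError:
            raise InvalidArgumentError(f"unknown truth preset {value!r}") from None
    return GeneratorTruth.from_dict(value)


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    Cohorts come either from the synthetic generator (``generator`` mapping
    with ``population_n``, ``validation_n``, ``contemporary_n`` and truth
    presets/specs) or from user CSV paths (``paths`` mapping with
    ``development``, ``validation``, ``contemporary``); exactly one of the two
    must be supplied.  ``sample_sizes`` entries are integers or the symbolic
    names ``"epv10"`` / ``"riley_min"`` resolved from the development cohort's
    event proportion.
    """

    generator: dict | None = None
    paths: dict | None = None
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    sample_sizes: tuple = (10_000, 50_000, 100_000, "epv10", "riley_min")
    riley: dict = field(default_factory=dict)
    output_dir: str = "riskstab_out"
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.generator is None) == (self.paths is None):
            raise InvalidArgumentError(
                "exactly one of generator settings or cohort paths must be supplied"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        design_kwargs = dict(d.pop("design", {}))
        sample_sizes = tuple(design_kwargs.pop("sample_sizes", cls.sample_sizes))
        design = ExperimentDesign(sample_sizes=(), **design_kwargs)
        return cls(
            generator=d.get("generator"),
            paths=d.get("paths"),
            design=design,
            sample_sizes=sample_sizes,
            riley=d.get("riley", {}),
            output_dir=d.get("output_dir", "riskstab_out"),
            log_level=d.get("log_level", "INFO"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _assemble_cohorts(config: RunConfig):
    """Build (development, validation, contemporary) per the configuration.

    With the generator, the validation cohort is carved at random from the
    synthetic population before the development cohort is formed, mirroring a
    split-sample internal validation; the contemporary cohort is generated
    from its own (default: shifted) marginals under the same truth.
    """
    if config.paths is not None:
        return (
            read_cohort_csv(config.paths["development"]),
            read_cohort_csv(config.paths["validation"]),
            read_cohort_csv(config.paths["contemporary"]),
        )
    g = dict(config.generator)
    truth = _resolve_truth(g.get("truth", "default_female"))
    contemporary_truth = _resolve_truth(
        g.get("contemporary_truth", "default_female_contemporary")
    )
    population_n = int(g["population_n"])
    validation_n = int(g.get("validation_n", 0))
    contemporary_n = int(g["contemporary_n"])
    if validation_n >= population_n:
        raise InvalidArgumentError("validation_n must be below population_n")
    seed = config.design.master_seed
    population = generate_cohort(truth, population_n, seed=seed * 3 + 1)
    carve_rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    val_idx = np.sort(carve_rng.choice(population_n, size=validation_n, replace=False))
    mask = np.zeros(population_n, dtype=bool)
    mask[val_idx] = True
    validation = population[mask].reset_index(drop=True)
    development = population[~mask].reset_index(drop=True)
    contemporary = generate_cohort(contemporary_truth, contemporary_n, seed=seed * 3 + 2)
    return development, validation, contemporary


def _resolve_sample_sizes(sample_sizes, development, riley_settings) -> list[int]:
    event_proportion = float(development[EVENT].mean())
    resolved = []
    for entry in sample_sizes:
        if entry == "epv10":
            resolved.append(epv10_sample_size(13, event_proportion))
        elif entry == "riley_min":
            inputs = SampleSizeInputs(
                n_parameters=int(riley_settings.get("n_parameters", 13)),
                event_proportion=event_proportion,
                shrinkage_target=float(riley_settings.get("shrinkage_target", 0.9)),
                r2_cs_adj=float(riley_settings.get("r2_cs_adj", 0.05)),
                optimism_delta=float(riley_settings.get("optimism_delta", 0.05)),
                risk_margin=float(riley_settings.get("risk_margin", 0.05)),
            )
            resolved.append(riley_minimum_sample_size(inputs)["n_min"])
        else:
            resolved.append(int(entry))
    return resolved


def _performance_quantiles(performance: list, n_sample: int) -> pd.DataFrame:
    qs = (2.5, 25.0, 50.0, 75.0, 97.5)
    rows = []
    for metric in ("c_statistic", "citl", "mape_practical", "net_benefit"):
        values = np.array([getattr(p, metric) for p in performance])
        row = {"sample_size": n_sample, "metric": metric}
        row.update({f"q{q:g}": np.percentile(values, q) for q in qs})
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full experiment and write the output bundle.

    Returns a summary dict with the output paths and per-sample-size failure
    counts.  Raises :class:`PipelineError` after writing a failure manifest if
    any sample size could not be completed.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    development, validation, contemporary = _assemble_cohorts(config)
    terms = [c for c in development.columns if c not in (PATIENT_ID, TIME, EVENT)]
    sample_sizes = _resolve_sample_sizes(config.sample_sizes, development, config.riley)
    design = config.design

    logger.info("deriving population model on %d patients", len(development))
    population = derive_population_model(
        development,
        {"contemporary": contemporary, "validation": validation},
        terms,
        horizon=design.horizon,
        threshold=design.threshold,
    )

    perf_tables, stability_tables, crossing_tables = [], [], []
    errors = {}
    failure_counts = {}
    for n_sample in sample_sizes:
        logger.info("running %d replicates at N=%d", design.replicates, n_sample)
        try:
            matrix, performance = run_replicates(
                development, contemporary, validation, design, n_sample,
                terms=terms, population=population,
            )
        except Exception as exc:
            logger.error("sample size %d failed: %s", n_sample, exc)
            errors[n_sample] = str(exc)
            continue
        failure_counts[n_sample] = len(matrix.failures)
        perf_tables.append(_performance_quantiles(performance, n_sample))

        all_bins = summarise_by_bin(matrix)
        all_bins.insert(0, "sample_size", n_sample)
        all_bins.insert(1, "subset_metric", "all")
        all_bins.insert(2, "fraction", 1.0)
        stability_tables.append(all_bins)
        for metric in SUBSET_METRICS:
            for fraction in _SUBSET_FRACTIONS:
                if math.floor(fraction * len(performance)) < 2:
                    logger.warning(
                        "skipping %s subset at N=%d: fewer than 2 replicates",
                        metric, n_sample,
                    )
                    continue
                subset = subset_replicates(
                    performance, population.performance.citl, metric, fraction
                )
                tab = summarise_by_bin(matrix, subset=subset)
                tab.insert(0, "sample_size", n_sample)
                tab.insert(1, "subset_metric", metric)
                tab.insert(2, "fraction", fraction)
                stability_tables.append(tab)

        crossing = threshold_crossing_probability(
            matrix, threshold=100.0 * design.threshold
        )
        crossing.insert(0, "sample_size", n_sample)
        crossing_tables.append(crossing)

    paths = {
        "performance_quantiles": outdir / "performance_quantiles.csv",
        "stability_by_bin": outdir / "stability_by_bin.csv",
        "crossing_by_bin": outdir / "crossing_by_bin.csv",
        "run_manifest": outdir / "run_manifest.json",
    }
    if perf_tables:
        pd.concat(perf_tables, ignore_index=True).to_csv(
            paths["performance_quantiles"], index=False
        )
        pd.concat(stability_tables, ignore_index=True).to_csv(
            paths["stability_by_bin"], index=False
        )
        pd.concat(crossing_tables, ignore_index=True).to_csv(
            paths["crossing_by_bin"], index=False
        )

    manifest = {
        "riskstab_version": __version__,
        "master_seed": design.master_seed,
        "replicates": design.replicates,
        "sampling_mode": design.sampling_mode,
        "horizon": design.horizon,
        "threshold": design.threshold,
        "sample_sizes": sample_sizes,
        "cohort_sizes": {
            "development": len(development),
            "validation": len(validation),
            "contemporary": len(contemporary),
        },
        "development_event_proportion": float(development[EVENT].mean()),
        "population_performance": {
            "c_statistic": population.performance.c_statistic,
            "citl": population.performance.citl,
            "net_benefit": population.performance.net_benefit,
        },
        "fit_failures": {str(k): v for k, v in failure_counts.items()},
        "errors": {str(k): v for k, v in errors.items()},
    }
    with open(paths["run_manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    if errors:
        raise PipelineError(
            f"{len(errors)} sample size(s) failed; see {paths['run_manifest']}"
        )
    return {"paths": {k: str(v) for k, v in paths.items()}, "manifest": manifest}
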