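"""Replicated ISVS experiments, parameter sweeps and population mixtures.

Each replicate draws its own allele-frequency spectrum, cohort and ISVS
run from an independent child random stream spawned deterministically
from the master seed, so results do not depend on execution order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .classify import (
    CellTable,
    FEATURE_COLUMNS,
    PathogenicityModel,
    build_cell_table,
    evaluate_classifiers,
    feature_rows,
    summarize_accuracy,
    train_model,
)
from .cohort import build_cohort, sample_spectra
from .engine import evaluate_run, run_isvs
from .params import ParameterError, SimParams

RUN_COLUMNS = [
    "sim_id",
    "success",
    "pat_fraction_detected",
    "mut_fraction_detected",
    "steps",
    "sequenced_sample_nr",
    "screened_vars_nr",
    "degenerate",
]

METRIC_NAMES = [
    "success_rate",
    "pat_fract_detected",
    "mut_fract_detected",
    "avg_steps",
    "sequenced_sample_nr",
    "screened_vars_nr",
]


@dataclass
class ExperimentSummary:
    """Means (with standard errors) of the six ISVS performance metrics.

    Degenerate replicates (cohorts without a bi-allelic proband) are
    vacuously successful and contribute neither to the detected-fraction
    averages nor to step/sample counts.
    """

    success_rate: float
    pat_fract_detected: float
    mut_fract_detected: float
    avg_steps: float
    sequenced_sample_nr: float
    screened_vars_nr: float
    success_rate_se: float
    pat_fract_detected_se: float
    mut_fract_detected_se: float
    avg_steps_se: float
    sequenced_sample_nr_se: float
    screened_vars_nr_se: float
    n_sims: int
    n_degenerate: int
    accuracy: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            f.name: getattr(self, f.name)
            for f in dc_fields(self)
            if f.name != "accuracy"
        }
        return out


@dataclass
class ExperimentResult:
    """Everything one replicated experiment produced."""

    params: SimParams
    summary: ExperimentSummary
    runs: pd.DataFrame
    features: pd.DataFrame
    cell_table: CellTable | None = None
    model: PathogenicityModel | None = None
    classification: pd.DataFrame | None = None


def _nan_mean_se(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return float("nan"), float("nan")
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else float("nan")
    return mean, se


def summarize_runs(runs: pd.DataFrame, accuracy: pd.DataFrame | None = None) -> ExperimentSummary:
    """Aggregate per-run metrics into an experiment summary."""
    nondeg = runs[~runs["degenerate"]]
    succ = nondeg["success"].to_numpy(dtype=float)
    stats = {}
    for name, col in [
        ("success_rate", succ),
        ("pat_fract_detected", nondeg["pat_fraction_detected"].to_numpy()),
        ("mut_fract_detected", nondeg["mut_fraction_detected"].to_numpy()),
        ("avg_steps", nondeg["steps"].to_numpy(dtype=float)),
        ("sequenced_sample_nr", nondeg["sequenced_sample_nr"].to_numpy(dtype=float)),
        ("screened_vars_nr", nondeg["screened_vars_nr"].to_numpy(dtype=float)),
    ]:
        mean, se = _nan_mean_se(col)
        stats[name] = mean
        stats[name + "_se"] = se
    return ExperimentSummary(
        n_sims=len(runs),
        n_degenerate=int(runs["degenerate"].sum()),
        accuracy=accuracy,
        **stats,
    )


def run_experiment(
    params: SimParams,
    *,
    classify: bool = True,
    confidences: tuple[float, ...] = (0.5, 0.95),
    folds: int = 5,
) -> ExperimentResult:
    """Run ``params.n_sims`` independent ISVS replicates and aggregate.

    When ``classify`` is set (and at least ``folds`` replicates exist),
    the cross-validated accuracy report is attached to the summary and a
    calibration cell table plus SVM are fitted on all replicates for
    later assessment of observed variants.
    """
    children = np.random.SeedSequence(params.master_seed).spawn(params.n_sims)
    run_rows = []
    feat_rows: list[tuple] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        spectrum = sample_spectra(params, rng)
        cohort = build_cohort(params, spectrum, rng)
        result = run_isvs(cohort, rng)
        metrics = evaluate_run(cohort, result)
        run_rows.append(
            (
                i,
                metrics.success,
                metrics.pat_fraction_detected,
                metrics.mut_fraction_detected,
                metrics.steps,
                metrics.sequenced_sample_nr,
                metrics.screened_vars_nr,
                metrics.degenerate,
            )
        )
        feat_rows.extend(feature_rows(cohort, result, sim_id=i))

    runs = pd.DataFrame(run_rows, columns=RUN_COLUMNS)
    features = pd.DataFrame(feat_rows, columns=FEATURE_COLUMNS)

    classification = None
    cell_table = None
    model = None
    if classify and params.n_sims >= folds and not features.empty:
        classification = evaluate_classifiers(
            features, confidences=confidences, folds=folds, seed=params.master_seed
        )
        cell_table = build_cell_table(features)
        if features["true_class"].nunique() > 1:
            model = train_model(features, seed=params.master_seed)

    accuracy = summarize_accuracy(classification) if classification is not None else None
    summary = summarize_runs(runs, accuracy=accuracy)
    return ExperimentResult(
        params=params,
        summary=summary,
        runs=runs,
        features=features,
        cell_table=cell_table,
        model=model,
        classification=classification,
    )


def parameter_sweep(
    base: SimParams,
    grid: dict[str, list],
    *,
    n_sims: int | None = 1000,
    classify: bool = False,
) -> pd.DataFrame:
    """Run one experiment per point of the cartesian parameter grid.

    Every grid point reuses the base master seed, so a sweep over a
    single point reproduces ``run_experiment`` on that point exactly.
    ``n_sims`` (default 1000) overrides the base replicate count to keep
    grids desk-scale; pass ``None`` to keep the base value.
    """
    from .params import FIELD_NAMES

    unknown = set(grid) - set(FIELD_NAMES)
    if unknown:
        raise ParameterError(f"unknown sweep parameter(s): {sorted(unknown)}")
    names = list(grid)
    rows = []
    for values in itertools.product(*(grid[n] for n in names)):
        point = dict(zip(names, values))
        if n_sims is not None:
            point.setdefault("n_sims", n_sims)
        params = base.with_(**point)
        result = run_experiment(params, classify=classify)
        row = {n: v for n, v in zip(names, values)}
        row.update(result.summary.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def mixed_population_experiment(
    params: SimParams,
    proportions: list[tuple[float, float]],
    *,
    classify: bool = False,
) -> pd.DataFrame:
    """Run experiments on two-population mixture cohorts.

    Each entry of ``proportions`` is a (p, 1-p) pair; both populations
    share the variant identities but receive independently sampled
    allele-frequency spectra scaled to the same cumulative targets.
    """
    rows = []
    for pair in proportions:
        if len(pair) != 2:
            raise ParameterError("each mixture entry must be a pair of proportions")
        mix = params.with_(population_proportions=tuple(float(p) for p in pair))
        result = run_experiment(mix, classify=classify)
        row = {"prop_pop1": pair[0], "prop_pop2": pair[1]}
        row.update(result.summary.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
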