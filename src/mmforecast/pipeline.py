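"""Cross-validated training and evaluation of the progression metamodel.

Orchestrates the full study design: patient-level k-fold splits, fold-wise
preprocessing (exclusion, LOCF imputation, train-only power transforms),
independent training of the forecaster and the annotator on each training
split, F-beta threshold calibration on training data, evaluation on the held
out fold, aggregation into fold-mean +/- sd report tables, and external
validation in which every fold's frozen artifacts are applied to one full
external cohort without refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .annotator import (
    AnnotatorConfig,
    AnnotatorHyper,
    AnnotatorParams,
    ThresholdCalibration,
    annotate,
    annotation_inputs,
    calibrate_threshold,
    fit_annotation_transform,
    train_annotator,
)
from .checkpoint import load_checkpoint, save_checkpoint
from .cohort import FEATURE_NAMES, LABEL_UNKNOWN, CohortDataset
from .evaluate import (
    DEFAULT_HORIZONS,
    classification_metrics,
    collect_forecasts,
    correlation_fidelity,
    horizon_grid,
    mann_whitney_one_sided,
    mse_report,
    significance_tier,
)
from .forecaster import ForecasterConfig, ForecasterHyper, ForecasterParams, train_forecaster
from .preprocess import (
    PowerTransformParams,
    apply_power_transform,
    exclude_unmeasured,
    fit_power_transform,
    impute_cohort,
    make_folds,
    stack_observed,
)


@dataclass
class PipelineConfig:
    """Resolved configuration of one cross-validation run."""

    k: int = 5
    beta: float = 5.0
    horizons: tuple = DEFAULT_HORIZONS
    prior_lengths: tuple = (2, 4, 6, 8, 10, 12)
    #: Monte-Carlo ensemble size used during evaluation sweeps (the
    #: 1000-trajectory default remains in ForecasterConfig for single-patient
    #: forecasts; evaluation sweeps use a smaller ensemble since the point
    #: forecast's Monte-Carlo error shrinks as 1/sqrt(n)).
    eval_trajectories: int = 200
    seed: int = 0
    forecaster: ForecasterConfig = field(default_factory=ForecasterConfig)
    forecaster_hyper: ForecasterHyper = field(default_factory=ForecasterHyper)
    annotator: AnnotatorConfig = field(default_factory=AnnotatorConfig)
    annotator_hyper: AnnotatorHyper = field(default_factory=AnnotatorHyper)


@dataclass
class FoldArtifacts:
    """Everything fitted on one training fold; frozen thereafter."""

    fold: int
    seed: int
    panel_transform: PowerTransformParams
    annotation_transform: PowerTransformParams
    forecaster: ForecasterParams
    annotator: AnnotatorParams
    calibration: ThresholdCalibration
    forecaster_loss: list = field(default_factory=list)
    annotator_loss: list = field(default_factory=list)


def fold_seed(base_seed: int, fold: int) -> int:
    """Per-fold integer seed derived from the run seed (stays below 2^31)."""
    return (int(base_seed) * 31 + fold) % (2**31 - 1)


def _annotation_data(cohort: CohortDataset, transform: PowerTransformParams):
    sequences = [annotation_inputs(t, transform) for t in cohort]
    labels = [t.pd_labels for t in cohort]
    return sequences, labels


def train_fold(
    train_cohort: CohortDataset, fold: int, config: PipelineConfig
) -> FoldArtifacts:
    """Fit transforms and both models on one training split only."""
    seed = fold_seed(config.seed, fold)
    name = f"fold-{fold}"
    panel_transform = fit_power_transform(
        stack_observed(train_cohort), fitted_on=name, column_names=FEATURE_NAMES
    )
    matrices = [apply_power_transform(panel_transform, t.values) for t in train_cohort]
    forecaster, f_loss = train_forecaster(
        matrices, config.forecaster, config.forecaster_hyper, seed=seed
    )
    annotation_transform = fit_annotation_transform(train_cohort, fitted_on=name)
    sequences, labels = _annotation_data(train_cohort, annotation_transform)
    annotator, a_loss = train_annotator(
        sequences, labels, config.annotator, config.annotator_hyper, seed=seed
    )
    # calibrate on the natural (unbalanced) training data
    scores, labs = _annotation_scores(train_cohort, annotator, annotation_transform)
    calibration = calibrate_threshold(scores, labs, beta=config.beta)
    return FoldArtifacts(
        fold=fold,
        seed=seed,
        panel_transform=panel_transform,
        annotation_transform=annotation_transform,
        forecaster=forecaster,
        annotator=annotator,
        calibration=calibration,
        forecaster_loss=f_loss,
        annotator_loss=a_loss,
    )


def _annotation_scores(cohort, annotator, transform):
    scores, labels = [], []
    for traj in cohort:
        p = annotate(annotator, annotation_inputs(traj, transform))
        known = traj.pd_labels != LABEL_UNKNOWN
        scores.extend(p[known])
        labels.extend(traj.pd_labels[known])
    return np.asarray(scores), np.asarray(labels, dtype=int)


def evaluate_fold(
    test_cohort: CohortDataset,
    train_cohort: CohortDataset,
    artifacts: FoldArtifacts,
    config: PipelineConfig,
) -> dict:
    """All per-fold evaluation products on held-out (or external) patients."""
    test_matrices = [
        apply_power_transform(artifacts.panel_transform, t.values) for t in test_cohort
    ]
    train_matrices = [
        apply_power_transform(artifacts.panel_transform, t.values) for t in train_cohort
    ]
    collection = collect_forecasts(
        test_matrices,
        artifacts.forecaster,
        horizons=config.horizons,
        config=config.forecaster,
        seed=artifacts.seed,
        n_trajectories=config.eval_trajectories,
    )
    mse = mse_report(collection, train_matrices)
    corr = correlation_fidelity(collection, test_matrices)
    scores, labels = _annotation_scores(
        test_cohort, artifacts.annotator, artifacts.annotation_transform
    )
    annotation = classification_metrics(
        scores, labels, threshold=artifacts.calibration.threshold
    )
    grid = horizon_grid(
        list(test_cohort),
        artifacts.forecaster,
        artifacts.annotator,
        artifacts.panel_transform,
        artifacts.annotation_transform,
        artifacts.calibration,
        prior_lengths=config.prior_lengths,
        horizons=config.horizons,
        config=config.forecaster,
        seed=artifacts.seed,
        n_trajectories=config.eval_trajectories,
    )
    return {"mse": mse, "correlation": corr, "annotation": annotation, "grid": grid}


def preprocess_cohort(cohort: CohortDataset) -> tuple[CohortDataset, list[str]]:
    """Exclusion then imputation; never produces non-finite values."""
    kept, removed = exclude_unmeasured(cohort)
    return impute_cohort(kept), removed


def run_cross_validation(
    cohort: CohortDataset, config: PipelineConfig
) -> tuple[dict, list[FoldArtifacts]]:
    """Full k-fold study on a labeled cohort (raw scale, pre-imputation)."""
    prepared, removed = preprocess_cohort(cohort)
    split = make_folds(prepared, k=config.k, seed=config.seed)
    prepared.fold_assignment.update(split.assignment())
    fold_reports, artifacts_list = [], []
    for fold in range(1, config.k + 1):
        train_cohort = prepared.subset(split.train_ids(fold))
        test_cohort = prepared.subset(split.fold_test_ids(fold))
        artifacts = train_fold(train_cohort, fold, config)
        fold_reports.append(evaluate_fold(test_cohort, train_cohort, artifacts, config))
        artifacts_list.append(artifacts)
    report = aggregate_fold_reports(fold_reports, config)
    report["excluded_patients"] = removed
    return report, artifacts_list


def external_validate(
    external_cohort: CohortDataset,
    artifacts_list: list[FoldArtifacts],
    config: PipelineConfig,
    reference_train: CohortDataset,
) -> dict:
    """Apply every fold's frozen artifacts to one full external cohort.

    ``reference_train`` supplies the training-split change SDs for the
    extreme-change analysis; nothing is refitted.
    """
    prepared, removed = preprocess_cohort(external_cohort)
    fold_reports = [
        evaluate_fold(prepared, reference_train, artifacts, config)
        for artifacts in artifacts_list
    ]
    report = aggregate_fold_reports(fold_reports, config)
    report["excluded_patients"] = removed
    return report


# ---------------------------------------------------------------------------
# aggregation


def _mean_sd(values) -> dict:
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    if arr.size == 0:
        return {"mean": None, "sd": None, "n_folds": 0}
    return {"mean": float(arr.mean()), "sd": float(arr.std(ddof=0)), "n_folds": int(arr.size)}


def aggregate_fold_reports(fold_reports: list[dict], config: PipelineConfig) -> dict:
    """Fold-mean +/- sd tables with Mann-Whitney significance marks."""
    horizons = tuple(config.horizons)
    methods = ("model", "LOCF", "MA")
    baselines = ("LOCF", "MA")

    mse_table: dict = {}
    significance: dict = {}
    for j, feat in enumerate(FEATURE_NAMES):
        mse_table[feat] = {}
        significance[feat] = {}
        for h in horizons:
            per_fold = {
                m: [fr["mse"]["per_feature"][h][m][j] for fr in fold_reports
                    if h in fr["mse"]["per_feature"]]
                for m in methods
            }
            mse_table[feat][h] = {m: _mean_sd(per_fold[m]) for m in methods}
            significance[feat][h] = {}
            for base in baselines:
                if len(per_fold["model"]) >= 2:
                    p = mann_whitney_one_sided(per_fold["model"], per_fold[base])
                    significance[feat][h][base] = {"p": p, "tier": significance_tier(p)}

    pooled: dict = {}
    pooled_significance: dict = {}
    for h in horizons:
        per_fold = {
            m: [fr["mse"]["pooled"][h][m] for fr in fold_reports if h in fr["mse"]["pooled"]]
            for m in methods
        }
        pooled[h] = {m: {"folds": list(map(float, per_fold[m])), **_mean_sd(per_fold[m])}
                     for m in methods}
        pooled_significance[h] = {}
        for base in baselines:
            if len(per_fold["model"]) >= 2:
                p = mann_whitney_one_sided(per_fold["model"], per_fold[base])
                pooled_significance[h][base] = {"p": p, "tier": significance_tier(p)}

    annotation = {
        key: _mean_sd([fr["annotation"].get(key) for fr in fold_reports])
        for key in ("auroc", "auprc", "sensitivity", "specificity", "prevalence")
    }
    annotation["folds"] = [
        {k: fr["annotation"].get(k) for k in ("auroc", "auprc", "sensitivity", "specificity")}
        for fr in fold_reports
    ]

    metamodel: dict = {}
    for h in horizons:
        per_h = [fr["grid"]["per_horizon"].get(h) for fr in fold_reports]
        metamodel[h] = {
            key: _mean_sd([m[key] if m else None for m in per_h])
            for key in ("auroc", "auprc", "sensitivity", "specificity")
        }

    grid_names = ("auroc", "auprc", "sensitivity", "specificity")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN grid cells
        grid_stack = {
            k: np.nanmean(np.stack([fr["grid"]["grids"][k] for fr in fold_reports]), axis=0)
            for k in grid_names
        }

    corr_summary: dict = {}
    for h in horizons:
        corr_summary[h] = {"per_feature": {}, "cross_correlation": {}, "lag_correlation": {}}
        for feat in FEATURE_NAMES:
            corr_summary[h]["per_feature"][feat] = {
                key: _mean_sd(
                    [fr["correlation"]["per_feature"].get(h, {}).get(feat, {}).get(key)
                     for fr in fold_reports]
                )
                for key in ("r", "r_delta")
            }
        for key in ("slope", "intercept", "r2"):
            corr_summary[h]["cross_correlation"][key] = _mean_sd(
                [fr["correlation"]["cross_correlation"].get(h, {}).get(key)
                 for fr in fold_reports]
            )
    lag_summary = {}
    all_lags = sorted(
        {lag for fr in fold_reports for lag in fr["correlation"]["lag_correlation"]}
    )
    for lag in all_lags:
        lag_summary[lag] = {
            key: _mean_sd(
                [fr["correlation"]["lag_correlation"].get(lag, {}).get(key)
                 for fr in fold_reports]
            )
            for key in ("slope", "intercept", "r2")
        }

    extreme_fraction = _mean_sd(
        [fr["mse"].get("extreme_fraction", {}).get(1) for fr in fold_reports]
    )

    return {
        "horizons": list(horizons),
        "prior_lengths": list(config.prior_lengths),
        "mse_table": mse_table,
        "significance_marks": significance,
        "pooled_mse": pooled,
        "pooled_significance": pooled_significance,
        "annotation": annotation,
        "metamodel": metamodel,
        "grids": {k: v.tolist() for k, v in grid_stack.items()},
        "correlation_summary": corr_summary,
        "lag_correlation_summary": lag_summary,
        "extreme_change_fraction": extreme_fraction,
        "n_folds": len(fold_reports),
    }


# ---------------------------------------------------------------------------
# artifact checkpointing


def save_fold_artifacts(artifacts: FoldArtifacts, path) -> None:
    manifest = {
        "kind": "mmforecast-fold-artifacts",
        "fold": artifacts.fold,
        "seed": artifacts.seed,
        "panel_transform": artifacts.panel_transform.to_dict(),
        "annotation_transform": artifacts.annotation_transform.to_dict(),
        "calibration": artifacts.calibration.to_dict(),
        "forecaster_config": vars(artifacts.forecaster.config).copy(),
        "annotator_config": vars(artifacts.annotator.config).copy(),
        "forecaster_loss": [float(x) for x in artifacts.forecaster_loss],
        "annotator_loss": [float(x) for x in artifacts.annotator_loss],
    }
    tensors = {
        **{f"forecaster.{k}": v for k, v in artifacts.forecaster.parameters().items()},
        **{f"annotator.{k}": v for k, v in artifacts.annotator.parameters().items()},
    }
    save_checkpoint(path, manifest, tensors)


def load_fold_artifacts(path) -> FoldArtifacts:
    manifest, tensors = load_checkpoint(path)
    fconfig = ForecasterConfig(**manifest["forecaster_config"])
    aconfig = AnnotatorConfig(**manifest["annotator_config"])
    forecaster = ForecasterParams(fconfig)
    forecaster.load(
        {k[len("forecaster."):]: v for k, v in tensors.items() if k.startswith("forecaster.")}
    )
    annotator = AnnotatorParams(aconfig)
    annotator.load(
        {k[len("annotator."):]: v for k, v in tensors.items() if k.startswith("annotator.")}
    )
    return FoldArtifacts(
        fold=manifest["fold"],
        seed=manifest["seed"],
        panel_transform=PowerTransformParams.from_dict(manifest["panel_transform"]),
        annotation_transform=PowerTransformParams.from_dict(manifest["annotation_transform"]),
        forecaster=forecaster,
        annotator=annotator,
        calibration=ThresholdCalibration.from_dict(manifest["calibration"]),
        forecaster_loss=manifest.get("forecaster_loss", []),
        annotator_loss=manifest.get("annotator_loss", []),
    )
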