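"""End-to-end experiment orchestration.

synthesize -> standardize -> extract -> balance -> select -> train ->
evaluate -> compare, for any subset of the nine model configurations, with
all randomness flowing from the seeds recorded in the provenance block.

Leakage policy (asserted, not just documented): standardization scales,
imputation medians, SMOTE and Boruta see the training cohort only; the
validation cohort is touched exactly once, at evaluation time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boruta import BorutaConfig, BorutaSelector
from .catalog import CLINICAL_COLUMNS, build_catalog
from .extraction import extract_cohort, learn_cohort_scales
from .modeling import (
    MODEL_CONFIGS,
    EvaluationReport,
    delong_compare,
    evaluate,
    train_model,
)
from .phantom import PhantomSpec, generate_cohort
from .regions import REGION_NAMES
from .smote import BalancingConfig, smote_oversample

#: Features kept when a model's all-relevant selection comes back empty.
_FALLBACK_K = 5

#: Region subsets backing each radiomics model configuration.
CONFIG_REGIONS = {
    "enhance": ("enhancement",),
    "non_enhance": ("non_enhancement",),
    "necrosis": ("necrosis",),
    "edema": ("edema",),
    "tumor_core": ("tumor_core",),
    "whole_tumor": ("whole_tumor",),
    "all_region": REGION_NAMES,
    "combined": REGION_NAMES,
}


@dataclass
class ExperimentConfig:
    spec: PhantomSpec = field(default_factory=PhantomSpec)
    n_train: int = 120
    n_validation: int = 100
    train_seed: int = 11
    validation_seed: int = 22
    balancing: BalancingConfig = field(default_factory=BalancingConfig)
    boruta: BorutaConfig = field(default_factory=BorutaConfig)
    model_seed: int = 33
    models: tuple = MODEL_CONFIGS
    reoptimize_threshold: bool = False
    output_dir: str | None = None

    def validate(self) -> None:
        unknown = set(self.models) - set(MODEL_CONFIGS)
        if unknown:
            raise ValueError(f"unknown model configs: {sorted(unknown)}")
        if self.train_seed == self.validation_seed:
            raise ValueError("train and validation cohorts must use distinct seeds")


@dataclass
class ExperimentResult:
    reports: dict  # model name -> EvaluationReport (validation)
    train_reports: dict  # model name -> EvaluationReport (training)
    delong: dict  # other model name -> DeLongResult vs all_region
    selections: dict  # model name -> selected feature list
    provenance: dict


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def _config_hash(config: ExperimentConfig) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def candidate_columns(table: pd.DataFrame, model: str) -> list:
    """Candidate feature columns of one model configuration."""
    if model == "clinical":
        return list(CLINICAL_COLUMNS)
    regions = CONFIG_REGIONS[model]
    catalog = build_catalog(region_subset=regions)
    cols = [n for n in catalog.names if n in table.columns]
    if model == "combined":
        cols += list(CLINICAL_COLUMNS)
    return cols


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full experiment and return per-model reports + provenance."""
    config.validate()
    spec = config.spec

    train_cases, train_manifest = generate_cohort(
        spec, config.n_train, config.train_seed, cohort_name="train"
    )
    val_cases, val_manifest = generate_cohort(
        spec, config.n_validation, config.validation_seed, cohort_name="val"
    )
    train_ids = set(train_manifest["case_id"])
    val_ids = set(val_manifest["case_id"])
    assert not (train_ids & val_ids), "train/validation case sets must be disjoint"

    # standardization scales learned on the training cohort only
    scales = learn_cohort_scales(train_cases)
    catalog = build_catalog(include_clinical=True)
    train_table = extract_cohort(train_cases, scales, catalog)
    val_table = extract_cohort(val_cases, scales, catalog)

    if train_table["idh1"].nunique() < 2:
        raise RuntimeError("training cohort drew a single class; change the seed or n_train")

    # training-only median imputation, then SMOTE once on the full table
    feature_cols = [c for c in train_table.columns if c != "idh1"]
    medians = train_table[feature_cols].median()
    train_filled = train_table.copy()
    train_filled[feature_cols] = train_filled[feature_cols].fillna(medians)
    val_filled = val_table.copy()
    val_filled[feature_cols] = val_filled[feature_cols].fillna(medians)

    balanced = smote_oversample(train_filled, config.balancing)

    reports: dict = {}
    train_reports: dict = {}
    selections: dict = {}
    scores_val: dict = {}
    for model in config.models:
        cols = candidate_columns(train_table, model)
        if model == "clinical":
            selected = cols
        else:
            selector = BorutaSelector(
                max_iterations=config.boruta.max_iterations,
                alpha=config.boruta.alpha,
                rf_trees_per_iter=config.boruta.rf_trees_per_iter,
                random_state=config.boruta.seed,
            )
            selector.fit(balanced[cols], balanced["idh1"])
            selected = selector.selected_features_
            if not selected:
                # all-relevant selection can legitimately come back empty on
                # weak or tiny cohorts; fall back to the features with the
                # highest median importance so every configuration still
                # yields a fitted, evaluable model
                med = selector.importance_history_.median(axis=0, skipna=True)
                selected = list(med.sort_values(ascending=False).index[:_FALLBACK_K])
        selections[model] = list(selected)
        bundle = train_model(balanced, selected, model, seed=config.model_seed)
        train_reports[model] = evaluate(bundle, train_filled)
        reports[model] = evaluate(
            bundle, val_filled, reoptimize_threshold=config.reoptimize_threshold
        )
        scores_val[model] = bundle.scores(val_filled)

    delong = {}
    if "all_region" in scores_val:
        labels = val_filled["idh1"].to_numpy().astype(int)
        for model, scores in scores_val.items():
            if model == "all_region":
                continue
            delong[model] = delong_compare(scores_val["all_region"], scores, labels)

    provenance = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seeds": {
            "train": config.train_seed,
            "validation": config.validation_seed,
            "balancing": config.balancing.seed,
            "boruta": config.boruta.seed,
            "model": config.model_seed,
        },
        "n_train": config.n_train,
        "n_validation": config.n_validation,
        "n_train_mutated": int(train_table["idh1"].sum()),
        "n_validation_mutated": int(val_table["idh1"].sum()),
        "models": list(config.models),
    }

    result = ExperimentResult(
        reports=reports,
        train_reports=train_reports,
        delong=delong,
        selections=selections,
        provenance=provenance,
    )
    if config.output_dir:
        _write_outputs(result, train_table, val_table, Path(config.output_dir))
    return result


def _report_to_dict(report: EvaluationReport) -> dict:
    return {
        "model": report.model,
        "threshold": report.threshold,
        "metrics": {k: (None if isinstance(v, float) and np.isnan(v) else v)
                    for k, v in report.metrics.items()},
        "auc": report.auc,
        "roc_points": report.roc_points,
        "prc_points": report.prc_points,
    }


def _write_outputs(result: ExperimentResult, train_table, val_table, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    train_table.to_csv(out / "train_features.csv")
    val_table.to_csv(out / "validation_features.csv")
    pd.DataFrame(
        [r.rounded() for r in result.reports.values()]
    ).to_csv(out / "validation_metrics.csv", index=False)
    for model, report in result.reports.items():
        if report.roc_points:
            pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(
                out / f"roc_{model}.tsv", sep="\t", index=False
            )
            pd.DataFrame(report.prc_points, columns=["recall", "precision"]).to_csv(
                out / f"prc_{model}.tsv", sep="\t", index=False
            )
    payload = {
        "provenance": result.provenance,
        "selections": result.selections,
        "validation_reports": {m: _report_to_dict(r) for m, r in result.reports.items()},
        "train_reports": {m: _report_to_dict(r) for m, r in result.train_reports.items()},
        "delong_vs_all_region": {
            m: dataclasses.asdict(d) for m, d in result.delong.items()
        },
    }
    (out / "reports.json").write_text(json.dumps(payload, indent=2))
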