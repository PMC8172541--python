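"""End-to-end pipeline: simulate -> features -> label -> classify -> predict -> importance.

Each stage writes plain-text artifacts into a run directory; a manifest
records the configuration hash, package versions and per-stage row
counts so two runs with the same config and seed are byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import persglu
from persglu.classification import ClassifierConfig, balance_classes, classifier_config_from_dict, run_cv, run_holdout
from persglu.features import FEATURE_NAMES, FeaturesConfig, assemble_features, features_config_from_dict
from persglu.importance import importance_report, load_taxonomy
from persglu.io_formats import GlucoseSeries, read_cohort_dir, write_feature_table, write_participant
from persglu.labeling import class_summary, label_glucose
from persglu.regression import (
    RegressorConfig,
    fit_predict_lopocv,
    fit_predict_personalized,
    naive_lopocv,
    regressor_config_from_dict,
)
from persglu.synthetic import CohortConfig, config_from_dict, generate_participant, planted_truth

log = logging.getLogger("persglu")


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    regressor: RegressorConfig = field(default_factory=RegressorConfig)
    min_history_points: int = 144
    importance_rf_trees: int = 1000
    seed: int = 0

    def apply_seed(self) -> None:
        """Propagate the global seed into every stage config."""
        self.cohort.seed = self.seed
        self.classifier.seed = self.seed
        self.regressor.seed = self.seed


_SECTIONS = {
    "cohort": config_from_dict,
    "features": features_config_from_dict,
    "classifier": classifier_config_from_dict,
    "regressor": regressor_config_from_dict,
}


def pipeline_config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d or {})
    kwargs = {}
    for key, builder in _SECTIONS.items():
        if key in d:
            kwargs[key] = builder(d.pop(key) or {})
    for key in ("min_history_points", "importance_rf_trees", "seed"):
        if key in d:
            kwargs[key] = d.pop(key)
    if d:
        raise ValueError(f"unknown pipeline config key(s): {sorted(d)}")
    cfg = PipelineConfig(**kwargs)
    if "seed" in kwargs:
        cfg.apply_seed()
    return cfg


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        return pipeline_config_from_dict(yaml.safe_load(fh) or {})


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, out_dir: Path) -> None:
    """Write the synthetic cohort as participant directories plus truth tables."""
    out_dir.mkdir(parents=True, exist_ok=True)
    for pid in range(1, config.cohort.n_participants + 1):
        rec = generate_participant(config.cohort, pid)
        write_participant(rec, out_dir / f"participant_{pid:03d}")
        log.info("simulate: wrote participant %d (%d glucose points)", pid, len(rec.glucose))
    truth = planted_truth(config.cohort)
    for name, df in truth.items():
        df.to_csv(out_dir / f"truth_{name}.csv", index=False)


def _labeled_features(record, config: PipelineConfig) -> pd.DataFrame:
    table = assemble_features(record, config.features)
    labels = label_glucose(record.glucose, config.min_history_points)
    lab = labels.reindex(table["epoch_start"].to_numpy())
    table = table.copy()
    table["excursion_label"] = lab.to_numpy()
    return table


def build_feature_table(config: PipelineConfig, cohort_dir: Path | None = None) -> pd.DataFrame:
    """Assemble the labeled feature table for the whole cohort.

    Reads a cohort directory if given, otherwise regenerates the
    synthetic cohort participant by participant (raw streams are
    discarded as soon as a participant's rows are assembled).
    """
    tables = []
    if cohort_dir is not None:
        for rec in read_cohort_dir(cohort_dir):
            tables.append(_labeled_features(rec, config))
    else:
        for pid in range(1, config.cohort.n_participants + 1):
            rec = generate_participant(config.cohort, pid)
            tables.append(_labeled_features(rec, config))
            log.info("features: participant %d -> %d rows", pid, len(tables[-1]))
    return pd.concat(tables, ignore_index=True)


def stage_classify(table: pd.DataFrame, config: PipelineConfig, out_dir: Path) -> dict:
    labeled = table[table["excursion_label"].notna()]
    X = labeled[FEATURE_NAMES]
    y = labeled["excursion_label"]
    Xb, yb = balance_classes(X, y, seed=config.seed)
    cv_report = run_cv(Xb, yb, config.classifier)
    holdout = run_holdout(Xb, yb, config.classifier)
    logistic_cfg = dataclasses.replace(config.classifier, final_model="logistic",
                                       rfe_estimator="logistic")
    logistic = run_holdout(Xb, yb, logistic_cfg)
    report = {
        "balanced_n": int(len(yb)),
        "cv": cv_report.summary(),
        "holdout_decision_tree": holdout.summary(),
        "holdout_logistic": logistic.summary(),
    }
    _dump_json(report, out_dir / "classification_report.json")
    return report


def stage_predict(table: pd.DataFrame, config: PipelineConfig, out_dir: Path) -> dict:
    pop = fit_predict_lopocv(table, config.regressor)
    pers_rows = []
    for pid in sorted(table["participant_id"].unique()):
        sub = table[table["participant_id"] == pid]
        pers_rows.append(fit_predict_personalized(sub, config.regressor).per_fold)
    pers = pd.concat(pers_rows, ignore_index=True)
    naive = naive_lopocv(table)

    def _summ(df: pd.DataFrame) -> dict:
        out = {}
        for col in ("rmse", "mape", "accuracy"):
            out[col] = float(df[col].mean())
            out[f"{col}_sd"] = float(df[col].std(ddof=1)) if len(df) > 1 else 0.0
        out["n_folds"] = int(len(df))
        return out

    report = {
        "population_lopocv": pop.summary(),
        "personalized": _summ(pers),
        "naive_mean": _summ(naive["mean"]),
        "naive_median": _summ(naive["median"]),
    }
    _dump_json(report, out_dir / "regression_report.json")
    pop.predictions.to_csv(out_dir / "predictions_lopocv.csv", index=False)
    return report


def stage_importance(table: pd.DataFrame, config: PipelineConfig, out_dir: Path) -> dict:
    rep = importance_report(table, load_taxonomy(), rf_trees=config.importance_rf_trees,
                            seed=config.seed)
    report = {
        "per_feature_mean": {k: float(v) for k, v in rep.per_feature["mean"].items()},
        "aggregates": {axis: {k: float(v) for k, v in s.items()}
                       for axis, s in rep.aggregates.items()},
    }
    _dump_json(report, out_dir / "importance_report.json")
    return report


def run_pipeline(config: PipelineConfig, out_dir, write_cohort: bool = False) -> dict:
    """Run every stage; returns the manifest and leaves artifacts in ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": _config_hash(config), "persglu_version": persglu.__version__,
                "stages": {}}
    try:
        if write_cohort:
            stage_simulate(config, out_dir / "cohort")
        table = build_feature_table(config,
                                    out_dir / "cohort" if write_cohort else None)
        write_feature_table(table, out_dir / "features.csv")
        manifest["stages"]["features"] = {"rows": int(len(table)),
                                          "participants": int(table["participant_id"].nunique())}
        labeled = table[table["excursion_label"].notna()]
        counts = labeled["excursion_label"].value_counts().to_dict()
        manifest["stages"]["labeling"] = {"labeled_rows": int(len(labeled)),
                                          "class_counts": {k: int(v) for k, v in counts.items()}}
        # per-cohort class distribution summary over labeled readings
        summaries = []
        for pid in sorted(table["participant_id"].unique()):
            sub = labeled[labeled["participant_id"] == pid]
            series = GlucoseSeries(sub["epoch_start"].to_numpy(), sub["glucose_target"].to_numpy())
            lab = pd.Series(sub["excursion_label"].to_numpy(), index=series.timestamps)
            summaries.append(class_summary(series, lab).assign(participant_id=pid))
        pd.concat(summaries).to_csv(out_dir / "class_summary.csv")

        manifest["stages"]["classification"] = {
            "balanced_n": stage_classify(table, config, out_dir)["balanced_n"]}
        manifest["stages"]["regression"] = {
            "folds": stage_predict(table, config, out_dir)["population_lopocv"]["n_folds"]}
        stage_importance(table, config, out_dir)
        manifest["stages"]["importance"] = {"features": len(FEATURE_NAMES)}
    except Exception as exc:  # pragma: no cover - error path
        manifest["error"] = str(exc)
        _dump_json(manifest, out_dir / "manifest.json")
        raise
    _dump_json(manifest, out_dir / "manifest.json")
    return manifest
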