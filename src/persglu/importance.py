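"""Feature-importance analysis of the glucose regressors.

Impurity-based importances from a random-forest regression fit on each
leave-one-person-out training set, averaged across folds, then
aggregated along three taxonomy axes (physiological category, data
source, engineering method) as percent of total importance.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestRegressor

from persglu.features import FEATURE_NAMES

AXES = ("category", "source", "engineering")


class TaxonomyError(ValueError):
    pass


def load_taxonomy(path=None) -> pd.DataFrame:
    """Load the feature taxonomy (index = feature, columns = the 3 axes)."""
    if path is None:
        ref = importlib.resources.files("persglu").joinpath("data/feature_taxonomy.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    df = pd.DataFrame.from_dict(raw["features"], orient="index")
    df.index.name = "feature"
    return df[list(AXES)]


def validate_taxonomy(taxonomy: pd.DataFrame, feature_names=None) -> None:
    feature_names = list(FEATURE_NAMES if feature_names is None else feature_names)
    missing = [f for f in feature_names if f not in taxonomy.index]
    if missing:
        raise TaxonomyError(f"feature(s) not in taxonomy: {missing}")


@dataclass
class ImportanceReport:
    per_feature: pd.DataFrame   # index feature; columns mean, sd
    per_fold: pd.DataFrame      # one row per fold, one column per feature
    aggregates: dict            # axis -> Series of percentages summing to 100


def lopocv_importances(table: pd.DataFrame, rf_trees: int = 1000, seed: int = 0,
                       feature_names=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalized impurity importances per LOPOCV fold.

    Fits a random-forest regressor on each fold's training rows (all
    participants but one) and records its impurity-based importances,
    which the library normalizes to sum to 1. Returns (per-feature
    mean/sd across folds, per-fold matrix).
    """
    feature_names = list(feature_names or FEATURE_NAMES)
    pids = sorted(table["participant_id"].unique())
    if len(pids) < 2:
        raise ValueError("LOPOCV importances require at least 2 participants")
    rows = []
    for f_idx, pid in enumerate(pids):
        train = table[table["participant_id"] != pid]
        if len(train) == 0 or train["glucose_target"].nunique() < 2:
            warnings.warn(f"fold {pid}: degenerate training set, skipped")
            continue
        rf = RandomForestRegressor(n_estimators=rf_trees, random_state=seed + f_idx, n_jobs=1)
        rf.fit(train[feature_names].to_numpy(float), train["glucose_target"].to_numpy(float))
        rows.append(pd.Series(rf.feature_importances_, index=feature_names, name=pid))
    per_fold = pd.DataFrame(rows)
    per_feature = pd.DataFrame({
        "mean": per_fold.mean(axis=0),
        "sd": per_fold.std(axis=0, ddof=1) if len(per_fold) > 1 else 0.0,
    })
    return per_feature, per_fold


def aggregate_importance(per_feature: pd.DataFrame, taxonomy: pd.DataFrame) -> dict:
    """Percent of total importance per group, for each taxonomy axis.

    Each axis's percentages sum to 100 (importances are renormalized by
    their total before aggregation, so the result is exact even if the
    means do not sum exactly to 1).
    """
    validate_taxonomy(taxonomy, per_feature.index)
    mean_imp = per_feature["mean"]
    total = mean_imp.sum()
    if total <= 0:
        raise ValueError("total importance must be positive")
    out = {}
    for axis in AXES:
        groups = taxonomy.loc[mean_imp.index, axis]
        pct = mean_imp.groupby(groups).sum() / total * 100.0
        out[axis] = pct.sort_values(ascending=False)
    return out


def top_features(per_feature: pd.DataFrame, threshold: float = 0.02) -> pd.DataFrame:
    """Features with mean importance above the threshold, ranked.

    Sorted by descending mean importance with ties broken by feature
    name so the ranking is deterministic.
    """
    sel = per_feature[per_feature["mean"] > threshold].copy()
    sel = sel.sort_index().sort_values("mean", ascending=False, kind="stable")
    return sel


def importance_report(table: pd.DataFrame, taxonomy: pd.DataFrame | None = None,
                      rf_trees: int = 1000, seed: int = 0) -> ImportanceReport:
    taxonomy = taxonomy if taxonomy is not None else load_taxonomy()
    per_feature, per_fold = lopocv_importances(table, rf_trees=rf_trees, seed=seed)
    aggregates = aggregate_importance(per_feature, taxonomy)
    return ImportanceReport(per_feature=per_feature, per_fold=per_fold, aggregates=aggregates)
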