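"""Multiclass classification of personalized glucose excursions.

The modeling protocol: random undersampling to a class-balanced set,
repeated stratified k-fold cross-validation (10 splits x 3 repeats), a
per-fold recursive feature elimination down to the 20 most important
features (decision-tree estimator by default), and a decision-tree final
classifier, reported with balanced accuracy, weighted precision/recall/
F1, a confusion matrix, and an R^2 on integer-coded labels floored at
zero. A single stratified 70/30 holdout variant and a logistic-regression
baseline mirror the secondary analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression, Perceptron
from sklearn.metrics import (
    balanced_accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    r2_score,
    recall_score,
)
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

from persglu.labeling import CLASS_CODES, CLASSES


@dataclass
class ClassifierConfig:
    n_splits: int = 10
    n_repeats: int = 3
    seed: int = 0
    rfe_k: int = 20
    rfe_estimator: str = "decision_tree"
    final_model: str = "decision_tree"
    max_depth: int | None = None  # decision-tree depth; library default

    def validate(self, n_features: int | None = None) -> None:
        if self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")
        if n_features is not None and self.rfe_k > n_features:
            raise ValueError(f"rfe_k={self.rfe_k} exceeds {n_features} features")
        if self.rfe_estimator not in _ESTIMATORS:
            raise ValueError(f"unknown rfe_estimator {self.rfe_estimator!r}")
        if self.final_model not in ("decision_tree", "logistic"):
            raise ValueError(f"unknown final_model {self.final_model!r}")


def classifier_config_from_dict(d: dict) -> ClassifierConfig:
    valid = {f.name for f in dataclasses.fields(ClassifierConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown classifier config key(s): {sorted(unknown)}")
    cfg = ClassifierConfig(**d)
    cfg.validate()
    return cfg


_ESTIMATORS = {
    "logistic": lambda seed: LogisticRegression(random_state=seed),
    "perceptron": lambda seed: Perceptron(random_state=seed),
    "decision_tree": lambda seed: DecisionTreeClassifier(random_state=seed),
    "random_forest": lambda seed: RandomForestClassifier(n_estimators=100, random_state=seed),
    "gradient_boosting": lambda seed: GradientBoostingClassifier(random_state=seed),
}


@dataclass
class ClassifEvalReport:
    """Per-fold metrics with mean/sd summaries and a pooled confusion matrix."""

    fold_metrics: pd.DataFrame                      # one row per fold
    confusion: np.ndarray                            # 3x3, rows = true class
    classes: list = field(default_factory=lambda: list(CLASSES))

    def summary(self) -> dict:
        out = {}
        for col in self.fold_metrics.columns:
            out[col] = float(self.fold_metrics[col].mean())
            out[f"{col}_sd"] = float(self.fold_metrics[col].std(ddof=1)) \
                if len(self.fold_metrics) > 1 else 0.0
        out["per_class_accuracy"] = {
            c: float(v) for c, v in zip(self.classes, per_class_accuracy(self.confusion))
        }
        out["confusion_matrix"] = self.confusion.tolist()
        return out


def per_class_accuracy(confusion: np.ndarray) -> np.ndarray:
    """Diagonal over row sums: recall of each true class."""
    confusion = np.asarray(confusion, dtype=float)
    rows = confusion.sum(axis=1)
    return np.divide(np.diag(confusion), rows, out=np.full(len(rows), np.nan), where=rows > 0)


def balance_classes(X: pd.DataFrame, y: pd.Series, seed: int = 0):
    """Random undersampling of every class to the minority-class count."""
    y = pd.Series(np.asarray(y, dtype=object), index=X.index)
    counts = y.value_counts()
    for cls in CLASSES:
        if cls not in counts.index or counts[cls] == 0:
            raise ValueError(f"class {cls!r} is absent; cannot balance")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep = []
    for cls in CLASSES:
        idx = np.flatnonzero((y == cls).to_numpy())
        keep.append(rng.choice(idx, size=n_min, replace=False))
    keep = np.sort(np.concatenate(keep))
    return X.iloc[keep].reset_index(drop=True), y.iloc[keep].reset_index(drop=True)


def rfe_select(X: np.ndarray, y: np.ndarray, k: int,
               estimator: str = "decision_tree", seed: int = 0,
               feature_names=None) -> np.ndarray:
    """Recursive feature elimination down to ``k`` features.

    Repeatedly fits the estimator and drops the least important feature
    (tree impurity importance or absolute coefficient) until ``k``
    remain. Returns the boolean support mask (or selected names when
    ``feature_names`` is given).
    """
    n_features = X.shape[1]
    if k > n_features:
        raise ValueError(f"k={k} exceeds {n_features} available features")
    rfe = RFE(_ESTIMATORS[estimator](seed), n_features_to_select=k, step=1)
    rfe.fit(X, y)
    if feature_names is not None:
        return np.asarray(feature_names)[rfe.support_]
    return rfe.support_


def _final_model(config: ClassifierConfig, seed: int):
    if config.final_model == "logistic":
        return LogisticRegression(random_state=seed)
    return DecisionTreeClassifier(max_depth=config.max_depth, random_state=seed)


def _encode(y) -> np.ndarray:
    return np.asarray([CLASS_CODES[v] for v in y])


def _fold_metrics(y_true, y_pred) -> dict:
    return {
        "balanced_accuracy": balanced_accuracy_score(y_true, y_pred),
        "weighted_precision": precision_score(y_true, y_pred, average="weighted", zero_division=0),
        "weighted_recall": recall_score(y_true, y_pred, average="weighted", zero_division=0),
        "weighted_f1": f1_score(y_true, y_pred, average="weighted", zero_division=0),
        # R^2 on integer-coded labels, floored at zero
        "r2": max(0.0, r2_score(_encode(y_true), _encode(y_pred))),
    }


def _fit_eval_fold(X_tr, y_tr, X_te, y_te, config: ClassifierConfig, seed: int):
    import warnings as _w

    from sklearn.exceptions import ConvergenceWarning

    with _w.catch_warnings():
        # unscaled features routinely stop lbfgs at the iteration cap;
        # the resulting baseline is used as-is
        _w.simplefilter("ignore", ConvergenceWarning)
        support = rfe_select(X_tr, y_tr, config.rfe_k, config.rfe_estimator, seed)
        model = _final_model(config, seed).fit(X_tr[:, support], y_tr)
    y_pred = model.predict(X_te[:, support])
    cm = confusion_matrix(y_te, y_pred, labels=CLASSES)
    return _fold_metrics(y_te, y_pred), cm


def run_cv(X: pd.DataFrame, y: pd.Series, config: ClassifierConfig | None = None) -> ClassifEvalReport:
    """Repeated stratified k-fold evaluation with per-fold feature selection.

    Feature selection and model fitting see only the training rows of
    each fold; the report aggregates metrics over the
    ``n_splits * n_repeats`` folds and pools the test confusion matrices.
    """
    config = config or ClassifierConfig()
    config.validate(X.shape[1])
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=object)
    cv = RepeatedStratifiedKFold(n_splits=config.n_splits, n_repeats=config.n_repeats,
                                 random_state=config.seed)
    fold_rows = []
    cm_total = np.zeros((3, 3), dtype=int)
    for f_idx, (tr, te) in enumerate(cv.split(Xa, ya)):
        metrics, cm = _fit_eval_fold(Xa[tr], ya[tr], Xa[te], ya[te], config,
                                     config.seed + f_idx)
        fold_rows.append(metrics)
        cm_total += cm
    return ClassifEvalReport(fold_metrics=pd.DataFrame(fold_rows), confusion=cm_total)


def run_holdout(X: pd.DataFrame, y: pd.Series,
                config: ClassifierConfig | None = None) -> ClassifEvalReport:
    """Single stratified 70/30 train/test split evaluation."""
    config = config or ClassifierConfig()
    config.validate(X.shape[1])
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=object)
    X_tr, X_te, y_tr, y_te = train_test_split(
        Xa, ya, test_size=0.3, random_state=config.seed, stratify=ya
    )
    metrics, cm = _fit_eval_fold(X_tr, y_tr, X_te, y_te, config, config.seed)
    return ClassifEvalReport(fold_metrics=pd.DataFrame([metrics]), confusion=cm)
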