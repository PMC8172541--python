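"""Interstitial glucose regression at 5-minute resolution.

Two protocols share one modeling recipe — random-forest feature selection
(1000 trees, keep features whose normalized impurity importance reaches
the 0.005 cutoff) followed by a gradient-boosted tree regressor
(max depth 6, 100 estimators, learning rate 0.1):

* a population model evaluated with leave-one-person-out cross-validation
  (LOPOCV), and
* a personalized model trained on the first contiguous half of each
  participant's rows and tested on the remaining half.

Both are compared against naive mean/median predictors. Metrics: RMSE in
mg/dL, MAPE in percent, and accuracy = 100 - MAPE.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from xgboost import XGBRegressor

from persglu.features import FEATURE_NAMES


@dataclass
class RegressorConfig:
    gbt_max_depth: int = 6
    gbt_n_estimators: int = 100
    gbt_learning_rate: float = 0.1
    rf_trees: int = 1000
    importance_cutoff: float = 0.005
    seed: int = 0
    clip_range: tuple | None = None  # e.g. (40, 400); off by default

    def validate(self) -> None:
        if not 0.0 <= self.importance_cutoff <= 1.0:
            raise ValueError("importance_cutoff must be in [0, 1]")
        if self.rf_trees < 1:
            raise ValueError("rf_trees must be >= 1")


def regressor_config_from_dict(d: dict) -> RegressorConfig:
    valid = {f.name for f in dataclasses.fields(RegressorConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown regressor config key(s): {sorted(unknown)}")
    if "clip_range" in d and d["clip_range"] is not None:
        d = {**d, "clip_range": tuple(d["clip_range"])}
    cfg = RegressorConfig(**d)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# metrics


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or len(y) == 0:
        raise ValueError("y and y_hat must be non-empty and equal length")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def mape(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean absolute percent error, in percent."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or len(y) == 0:
        raise ValueError("y and y_hat must be non-empty and equal length")
    if np.any(y == 0):
        raise ValueError("MAPE undefined when a true value is 0")
    return float(100.0 * np.mean(np.abs(y - y_hat) / np.abs(y)))


def accuracy_from_mape(mape_pct: float) -> float:
    return 100.0 - mape_pct


def _metric_row(y, y_hat) -> dict:
    m = mape(y, y_hat)
    return {"rmse": rmse(y, y_hat), "mape": m, "accuracy": accuracy_from_mape(m)}


@dataclass
class RegressionEvalReport:
    per_fold: pd.DataFrame          # one row per fold/participant
    predictions: pd.DataFrame       # participant, epoch_start, y, y_hat
    selected_features: dict         # fold id -> list of kept feature names

    def summary(self) -> dict:
        out = {}
        for col in ("rmse", "mape", "accuracy"):
            out[col] = float(self.per_fold[col].mean())
            out[f"{col}_sd"] = float(self.per_fold[col].std(ddof=1)) \
                if len(self.per_fold) > 1 else 0.0
        out["n_folds"] = int(len(self.per_fold))
        return out


# ---------------------------------------------------------------------------
# model recipe


def select_features_rf(X: np.ndarray, y: np.ndarray, config: RegressorConfig,
                       seed: int, feature_names) -> list[str]:
    """Impurity-importance feature selection with a random forest.

    Importances are normalized to sum to 1 (the library already does
    this); features at or above the cutoff are kept. If nothing clears
    the cutoff the single most important feature is kept so the
    downstream model is fittable.
    """
    rf = RandomForestRegressor(n_estimators=config.rf_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    imp = rf.feature_importances_
    keep = imp >= config.importance_cutoff
    if not keep.any():
        keep[np.argmax(imp)] = True
    return [feature_names[i] for i in np.flatnonzero(keep)]


def _fit_gbt(X: np.ndarray, y: np.ndarray, config: RegressorConfig, seed: int) -> XGBRegressor:
    model = XGBRegressor(
        max_depth=config.gbt_max_depth,
        n_estimators=config.gbt_n_estimators,
        learning_rate=config.gbt_learning_rate,
        random_state=seed,
        n_jobs=1,
        verbosity=0,
    )
    model.fit(X, y)
    return model


def _predict(model, X, config: RegressorConfig) -> np.ndarray:
    y_hat = np.asarray(model.predict(X), dtype=float)
    if config.clip_range is not None:
        y_hat = np.clip(y_hat, *config.clip_range)
    return y_hat


def _feature_matrix(table: pd.DataFrame, names) -> np.ndarray:
    return table[list(names)].to_numpy(dtype=float)


def fit_predict_lopocv(table: pd.DataFrame, config: RegressorConfig | None = None,
                       feature_names=None) -> RegressionEvalReport:
    """Leave-one-person-out population model.

    Every participant serves once as the full test set; feature selection
    and fitting use only the remaining participants' rows.
    """
    config = config or RegressorConfig()
    config.validate()
    feature_names = list(feature_names or FEATURE_NAMES)
    pids = sorted(table["participant_id"].unique())
    if len(pids) < 2:
        raise ValueError("LOPOCV requires at least 2 participants")
    fold_rows, preds, selected = [], [], {}
    for f_idx, pid in enumerate(pids):
        test = table[table["participant_id"] == pid]
        train = table[table["participant_id"] != pid]
        if len(test) == 0:
            warnings.warn(f"participant {pid}: empty feature table, fold skipped")
            continue
        seed = config.seed + f_idx
        X_tr = _feature_matrix(train, feature_names)
        y_tr = train["glucose_target"].to_numpy(float)
        kept = select_features_rf(X_tr, y_tr, config, seed, feature_names)
        model = _fit_gbt(_feature_matrix(train, kept), y_tr, config, seed)
        y_te = test["glucose_target"].to_numpy(float)
        y_hat = _predict(model, _feature_matrix(test, kept), config)
        fold_rows.append({"participant_id": pid, **_metric_row(y_te, y_hat)})
        preds.append(pd.DataFrame({
            "participant_id": pid, "epoch_start": test["epoch_start"].to_numpy(),
            "y": y_te, "y_hat": y_hat,
        }))
        selected[pid] = kept
    return RegressionEvalReport(
        per_fold=pd.DataFrame(fold_rows),
        predictions=pd.concat(preds, ignore_index=True),
        selected_features=selected,
    )


def personalized_split(n_rows: int) -> int:
    """Index of the first test row of the chronological half-split."""
    return int(np.ceil(n_rows / 2))


def fit_predict_personalized(table: pd.DataFrame, config: RegressorConfig | None = None,
                             feature_names=None) -> RegressionEvalReport:
    """Personalized model for one participant: train on the first
    contiguous half of the rows (chronological), test on the rest."""
    config = config or RegressorConfig()
    config.validate()
    feature_names = list(feature_names or FEATURE_NAMES)
    table = table.sort_values("epoch_start").reset_index(drop=True)
    n = len(table)
    if n < 4:
        raise ValueError("too few rows for a personalized half-split")
    split = personalized_split(n)
    train, test = table.iloc[:split], table.iloc[split:]
    pid = int(table["participant_id"].iloc[0])
    X_tr = _feature_matrix(train, feature_names)
    y_tr = train["glucose_target"].to_numpy(float)
    kept = select_features_rf(X_tr, y_tr, config, config.seed, feature_names)
    model = _fit_gbt(_feature_matrix(train, kept), y_tr, config, config.seed)
    y_te = test["glucose_target"].to_numpy(float)
    y_hat = _predict(model, _feature_matrix(test, kept), config)
    return RegressionEvalReport(
        per_fold=pd.DataFrame([{"participant_id": pid, **_metric_row(y_te, y_hat)}]),
        predictions=pd.DataFrame({
            "participant_id": pid, "epoch_start": test["epoch_start"].to_numpy(),
            "y": y_te, "y_hat": y_hat,
        }),
        selected_features={pid: kept},
    )


def naive_baselines(y_train: np.ndarray, y_test: np.ndarray) -> dict:
    """Metrics for constant mean- and median-of-train predictors."""
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    if len(y_train) == 0:
        raise ValueError("naive baselines need a non-empty training set")
    out = {}
    for name, const in (("mean", float(np.mean(y_train))),
                        ("median", float(np.median(y_train)))):
        out[name] = _metric_row(y_test, np.full(len(y_test), const))
    return out


def naive_lopocv(table: pd.DataFrame) -> dict:
    """Naive mean/median baselines under the same LOPOCV folds."""
    pids = sorted(table["participant_id"].unique())
    rows = {"mean": [], "median": []}
    for pid in pids:
        y_te = table.loc[table["participant_id"] == pid, "glucose_target"].to_numpy(float)
        y_tr = table.loc[table["participant_id"] != pid, "glucose_target"].to_numpy(float)
        res = naive_baselines(y_tr, y_te)
        for k in rows:
            rows[k].append({"participant_id": pid, **res[k]})
    return {k: pd.DataFrame(v) for k, v in rows.items()}
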