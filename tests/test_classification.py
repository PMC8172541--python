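"""Excursion classification: balancing, RFE, CV calibration, metric identities."""

import numpy as np
import pandas as pd
import pytest

from persglu.classification import (
    ClassifEvalReport,
    ClassifierConfig,
    balance_classes,
    per_class_accuracy,
    rfe_select,
    run_cv,
    run_holdout,
)
from persglu.labeling import CLASSES, PERS_HIGH, PERS_LOW, PERS_NORM


def _labeled_frame(rng, counts):
    rows = []
    for cls, n in zip(CLASSES, counts):
        rows += [cls] * n
    y = pd.Series(rows, dtype=object)
    X = pd.DataFrame(rng.normal(size=(len(y), 5)), columns=[f"f{i}" for i in range(5)])
    return X, y


def test_balance_undersamples_to_minority():
    rng = np.random.default_rng(0)
    X, y = _labeled_frame(rng, (100, 50, 75))
    Xb, yb = balance_classes(X, y, seed=1)
    assert yb.value_counts().to_dict() == {c: 50 for c in CLASSES}
    # already balanced -> sizes unchanged
    X2, y2 = _labeled_frame(rng, (40, 40, 40))
    Xb2, yb2 = balance_classes(X2, y2, seed=1)
    assert len(yb2) == 120
    # two seeds: same sizes, generally different membership
    Xa, ya = balance_classes(X, y, seed=1)
    Xc, yc = balance_classes(X, y, seed=2)
    assert len(Xa) == len(Xc)
    assert not Xa.equals(Xc)
    with pytest.raises(ValueError, match="PersLow"):
        balance_classes(X.iloc[:150], pd.Series([PERS_NORM] * 75 + [PERS_HIGH] * 75))


def test_rfe_identity_and_planted_signal():
    rng = np.random.default_rng(1)
    n = 300
    X = rng.normal(size=(n, 10))
    y = np.where(X[:, 0] > 0, PERS_HIGH, PERS_LOW)
    names = [f"f{i}" for i in range(10)]
    assert list(rfe_select(X, y, 10, feature_names=names)) == names
    kept = rfe_select(X, y, 5, feature_names=names)
    assert "f0" in kept
    with pytest.raises(ValueError):
        rfe_select(X, y, 11)


def test_rfe_keeps_separating_feature_at_k1():
    rng = np.random.default_rng(2)
    n = 200
    X = rng.normal(size=(n, 3))
    y = np.where(X[:, 2] > 0.0, PERS_HIGH, PERS_NORM)
    kept = rfe_select(X, y, 1, feature_names=["a", "b", "sep"])
    assert list(kept) == ["sep"]


def test_cv_chance_level_on_label_independent_noise():
    """Balanced noise: balanced accuracy sits at 1/3 over the 10x3 CV."""
    rng = np.random.default_rng(3)
    X, y = _labeled_frame(rng, (110, 110, 110))
    X = pd.DataFrame(rng.normal(size=(330, 12)), columns=[f"f{i}" for i in range(12)])
    cfg = ClassifierConfig(rfe_k=5, seed=0)
    report = run_cv(X, y, cfg)
    assert report.summary()["balanced_accuracy"] == pytest.approx(1 / 3, abs=0.05)
    assert len(report.fold_metrics) == 30


def test_cv_perfect_on_separable_data():
    rng = np.random.default_rng(4)
    n = 120
    y = pd.Series(([PERS_LOW] * n + [PERS_NORM] * n + [PERS_HIGH] * n), dtype=object)
    sig = np.repeat([0.0, 10.0, 20.0], n)
    X = pd.DataFrame({"sig": sig + rng.normal(0, 0.1, 3 * n),
                      "noise": rng.normal(size=3 * n)})
    report = run_cv(X, y, ClassifierConfig(rfe_k=1, seed=0))
    assert report.summary()["balanced_accuracy"] >= 0.99


def test_holdout_deterministic_and_chance_f1():
    rng = np.random.default_rng(5)
    X, y = _labeled_frame(rng, (120, 120, 120))
    cfg = ClassifierConfig(rfe_k=3, seed=7)
    a = run_holdout(X, y, cfg)
    b = run_holdout(X, y, cfg)
    pd.testing.assert_frame_equal(a.fold_metrics, b.fold_metrics)
    np.testing.assert_array_equal(a.confusion, b.confusion)
    assert a.summary()["weighted_f1"] == pytest.approx(1 / 3, abs=0.12)


def test_no_leakage_from_test_fold():
    """The selector and model fitted on the training rows are invariant
    to arbitrary poisoning of the test rows."""
    rng = np.random.default_rng(6)
    n = 240
    X = rng.normal(size=(n, 8))
    y = np.where(X[:, 1] + 0.5 * rng.normal(size=n) > 0, PERS_HIGH, PERS_LOW)
    tr, te = np.arange(0, 180), np.arange(180, n)
    support = rfe_select(X[tr], y[tr], 3, seed=0)
    X_poison = X.copy()
    X_poison[te] = 1e6
    support2 = rfe_select(X_poison[tr], y[tr], 3, seed=0)
    np.testing.assert_array_equal(support, support2)
    from sklearn.tree import DecisionTreeClassifier

    m1 = DecisionTreeClassifier(random_state=0).fit(X[tr][:, support], y[tr])
    m2 = DecisionTreeClassifier(random_state=0).fit(X_poison[tr][:, support2], y[tr])
    probe = rng.normal(size=(50, int(support.sum())))
    np.testing.assert_array_equal(m1.predict(probe), m2.predict(probe))


def test_metric_identities_on_hand_built_confusion():
    cm = np.array([[8, 1, 1], [2, 6, 2], [0, 3, 7]])
    pca = per_class_accuracy(cm)
    np.testing.assert_allclose(pca, [0.8, 0.6, 0.7])
    # balanced accuracy = unweighted mean of per-class recalls
    y_true = sum(([c] * 10 for c in CLASSES), [])
    y_pred = []
    for i, row in enumerate(cm):
        for j, k in enumerate(row):
            y_pred += [CLASSES[j]] * k
    from sklearn.metrics import balanced_accuracy_score

    assert balanced_accuracy_score(y_true, y_pred) == pytest.approx(pca.mean())


def test_report_metrics_consistent_with_stored_confusion():
    rng = np.random.default_rng(7)
    X, y = _labeled_frame(rng, (60, 60, 60))
    report = run_holdout(X, y, ClassifierConfig(rfe_k=2, seed=1))
    cm = report.confusion
    assert cm.sum() == 54  # 30% of 180
    # recomputed balanced accuracy from the stored confusion equals the scalar
    assert np.nanmean(per_class_accuracy(cm)) == pytest.approx(
        report.fold_metrics["balanced_accuracy"].iloc[0])
    # confusion rows sum to per-class test support (stratified: 18 each)
    np.testing.assert_array_equal(cm.sum(axis=1), [18, 18, 18])


def test_r2_floor_at_zero():
    rng = np.random.default_rng(8)
    X, y = _labeled_frame(rng, (80, 80, 80))
    report = run_cv(X, y, ClassifierConfig(rfe_k=2, n_splits=4, n_repeats=1, seed=0))
    assert (report.fold_metrics["r2"] >= 0).all()
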