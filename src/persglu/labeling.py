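"""Personalized glucose excursion labels.

Each interstitial glucose reading is compared with the participant's own
rolling previous-24-hour window (excluding the reading itself): values
more than one standard deviation above the window mean are PersHigh,
more than one below are PersLow, and everything within one standard
deviation (boundaries inclusive) is PersNorm. Readings with fewer than
``min_history_points`` prior readings in the window are left unlabeled
and excluded downstream.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from persglu.io_formats import GlucoseSeries

PERS_HIGH = "PersHigh"
PERS_LOW = "PersLow"
PERS_NORM = "PersNorm"
CLASSES = [PERS_LOW, PERS_NORM, PERS_HIGH]

#: integer coding used wherever the classes are treated numerically
CLASS_CODES = {PERS_LOW: 0, PERS_NORM: 1, PERS_HIGH: 2}

WINDOW_S = 86400.0


def rolling_baseline(series: GlucoseSeries, window_s: float = WINDOW_S):
    """Rolling mean and sample sd of the readings in ``[t - 24 h, t)`` for each t."""
    t = series.timestamps
    g = series.glucose_mg_dl
    n = len(t)
    lo = np.searchsorted(t, t - window_s, side="left")
    # prefix sums for O(n) windowed moments
    c1 = np.concatenate([[0.0], np.cumsum(g)])
    c2 = np.concatenate([[0.0], np.cumsum(g**2)])
    idx = np.arange(n)
    cnt = idx - lo  # window excludes the current point
    mu = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    ok = cnt >= 1
    s1 = c1[idx] - c1[lo]
    s2 = c2[idx] - c2[lo]
    mu[ok] = s1[ok] / cnt[ok]
    ok2 = cnt >= 2
    var = np.full(n, np.nan)
    var[ok2] = (s2[ok2] - cnt[ok2] * mu[ok2] ** 2) / (cnt[ok2] - 1)
    sd[ok2] = np.sqrt(np.maximum(var[ok2], 0.0))
    return mu, sd, cnt


def label_glucose(series: GlucoseSeries, min_history_points: int = 144) -> pd.Series:
    """Assign PersHigh / PersLow / PersNorm per reading; NaN where history is short.

    ``min_history_points`` (default 144 readings = 12 h of a complete
    5-min grid) controls how much of the wear start is left unlabeled.
    """
    mu, sd, cnt = rolling_baseline(series)
    g = series.glucose_mg_dl
    labels = np.full(len(g), None, dtype=object)
    ok = (cnt >= max(min_history_points, 2)) & np.isfinite(sd)
    hi = ok & (g > mu + sd)
    lo = ok & (g < mu - sd)
    labels[ok] = PERS_NORM
    labels[hi] = PERS_HIGH
    labels[lo] = PERS_LOW
    if not ok.any():
        warnings.warn("series shorter than the minimum history: no labels assigned")
    return pd.Series(labels, index=series.timestamps, dtype=object)


def class_summary(series: GlucoseSeries, labels: pd.Series) -> pd.DataFrame:
    """Per-class distribution summary.

    For each class: mean, sample sd, min, max, adjusted Fisher-Pearson
    skewness, excess kurtosis, and the Kolmogorov-Smirnov statistic of
    the class sample against a normal distribution with the class's own
    fitted mean and sd. Classes with fewer than 2 points are all-NaN.
    """
    rows = []
    vals = pd.Series(series.glucose_mg_dl, index=series.timestamps)
    for cls in CLASSES:
        x = vals[labels == cls].to_numpy(float)
        if len(x) < 2:
            rows.append({"class": cls, "n": len(x), "mean": np.nan, "sd": np.nan,
                         "min": np.nan, "max": np.nan, "skewness": np.nan,
                         "kurtosis": np.nan, "ks_stat": np.nan})
            continue
        mu = x.mean()
        sd = x.std(ddof=1)
        skew = stats.skew(x, bias=False) if sd > 0 else 0.0
        kurt = stats.kurtosis(x, fisher=True, bias=False) if sd > 0 else 0.0
        ks = stats.kstest(x, "norm", args=(mu, sd)).statistic if sd > 0 else np.nan
        rows.append({"class": cls, "n": len(x), "mean": mu, "sd": sd,
                     "min": x.min(), "max": x.max(), "skewness": float(skew),
                     "kurtosis": float(kurt), "ks_stat": float(ks)})
    return pd.DataFrame(rows).set_index("class")
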