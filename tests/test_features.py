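"""Feature engineering: closed-form examples, brute-force oracles, anti-leakage.

The oracles below recompute every windowed quantity from first
principles (python loops over raw samples/events) and stay independent
of the production implementation.
"""

import numpy as np
import pandas as pd
import pytest

from persglu.features import (
    EPOCH_SECONDS,
    FEATURE_NAMES,
    Epoch,
    FeaturesConfig,
    activity_bout,
    activity_rollups,
    assemble_features,
    circadian_features,
    detect_eda_peaks,
    eda_peak_rollups,
    food_features,
    hrv_metrics,
    summary_stats,
    vector_magnitude,
    wake_times_by_day,
)
from persglu.io_formats import FoodLog, GlucoseSeries, IBISequence, ParticipantRecord, SensorKind, SensorStream
from persglu.synthetic import planted_truth


# ---------------------------------------------------------------------------
# independent oracles


def oracle_stats(x):
    """7 summary statistics from first principles."""
    x = sorted(float(v) for v in x)
    n = len(x)
    mean = sum(x) / n
    sd = (sum((v - mean) ** 2 for v in x) / (n - 1)) ** 0.5

    def quant(q):  # linear interpolation of order statistics
        pos = q * (n - 1)
        lo = int(pos)
        hi = min(lo + 1, n - 1)
        return x[lo] + (pos - lo) * (x[hi] - x[lo])

    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    if m2 == 0:
        skew = 0.0
    else:
        skew = (m3 / m2**1.5) * (n * (n - 1)) ** 0.5 / (n - 2)
    return [mean, sd, x[0], x[-1], quant(0.25), quant(0.75), skew]


def oracle_peaks(x, prominence=0.3, distance=4):
    """From-scratch unique-peak count: strict local maxima, highest-first
    minimum-distance pruning, then topographic prominence thresholding."""
    x = list(map(float, x))
    n = len(x)
    maxima = [i for i in range(1, n - 1) if x[i - 1] < x[i] > x[i + 1]]
    keep = set(maxima)
    for i in sorted(maxima, key=lambda i: -x[i]):
        if i not in keep:
            continue
        for j in list(keep):
            if j != i and abs(j - i) < distance and x[j] <= x[i]:
                keep.discard(j)
    count = 0
    for i in sorted(keep):
        left_min = x[i]
        j = i - 1
        while j >= 0 and x[j] <= x[i]:
            left_min = min(left_min, x[j])
            j -= 1
        right_min = x[i]
        j = i + 1
        while j < n and x[j] <= x[i]:
            right_min = min(right_min, x[j])
            j += 1
        prom = x[i] - max(left_min, right_min)
        if prom >= prominence:
            count += 1
    return count


def oracle_hrv(iv_ms):
    iv = list(map(float, iv_ms))
    n = len(iv)
    if n == 0:
        return [np.nan] * 8
    mean = sum(iv) / n
    med = sorted(iv)[n // 2] if n % 2 else sum(sorted(iv)[n // 2 - 1: n // 2 + 1]) / 2
    out = [mean, med, max(iv), min(iv)] + [np.nan] * 4
    if n >= 2:
        out[4] = (sum((v - mean) ** 2 for v in iv) / (n - 1)) ** 0.5
        diffs = [iv[i + 1] - iv[i] for i in range(n - 1)]
        out[5] = (sum(d**2 for d in diffs) / len(diffs)) ** 0.5
        out[6] = sum(1 for d in diffs if abs(d) > 50)
        out[7] = out[6] / n
    return out


def _stream(kind, values, rate, start=0.0):
    return SensorStream(kind, start, rate, np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# elementary features


def test_vector_magnitude_conventions():
    np.testing.assert_allclose(vector_magnitude([0, 0, 0]), 0)
    np.testing.assert_allclose(vector_magnitude([3, 4, 0]), 5)
    np.testing.assert_allclose(vector_magnitude([64, 0, 0]), 64)  # 1 g


def test_summary_stats_examples():
    s = _stream(SensorKind.EDA, [5.0] * 20, 4.0)
    got = summary_stats(s, Epoch(0.0))
    np.testing.assert_allclose(got, [5, 0, 5, 5, 5, 5, 0])
    s = _stream(SensorKind.HR, [1, 2, 3, 4], 1.0)
    got = summary_stats(s, Epoch(0.0))
    assert got[0] == 2.5 and got[2] == 1 and got[3] == 4
    # under 2 samples -> all missing
    s = _stream(SensorKind.HR, [7.0], 1.0)
    assert np.isnan(summary_stats(s, Epoch(0.0))).all()


def test_summary_stats_against_oracle():
    rng = np.random.default_rng(1)
    for _ in range(30):
        vals = rng.normal(size=300)
        s = _stream(SensorKind.EDA, vals, 1.0)
        got = summary_stats(s, Epoch(0.0))
        np.testing.assert_allclose(got, oracle_stats(vals), rtol=1e-10, atol=1e-12)


def test_acc_summary_uses_vector_magnitude():
    rng = np.random.default_rng(2)
    vals = rng.normal(size=(300, 3))
    s = _stream(SensorKind.ACC, vals, 1.0)
    got = summary_stats(s, Epoch(0.0))
    np.testing.assert_allclose(got, oracle_stats(np.linalg.norm(vals, axis=1)),
                               rtol=1e-10, atol=1e-12)


def _bumps(centers, heights, n=1200, rate=4.0, width=2.0, base=1.0):
    t = np.arange(n) / rate
    x = np.full(n, base)
    for c, h in zip(centers, heights):
        x = x + h * np.exp(-((t - c) ** 2) / (2 * width**2))
    return x


def test_eda_peaks_prominence_threshold():
    flat = _stream(SensorKind.EDA, np.ones(1200), 4.0)
    assert detect_eda_peaks(flat, Epoch(0.0)) == 0
    three = _stream(SensorKind.EDA, _bumps([100, 110, 120], [0.5, 0.5, 0.5]), 4.0)
    assert detect_eda_peaks(three, Epoch(0.0)) == 3
    small = _stream(SensorKind.EDA, _bumps([150], [0.2]), 4.0)
    assert detect_eda_peaks(small, Epoch(0.0)) == 0  # below 0.3 uS prominence


def test_eda_peaks_match_oracle_on_random_signals():
    rng = np.random.default_rng(3)
    for _ in range(100):
        # piecewise-smooth: random bumps on a slow baseline + mild noise
        k = int(rng.integers(0, 8))
        x = _bumps(rng.uniform(5, 295, size=k), rng.uniform(0.1, 1.0, size=k))
        x = x + 0.3 * np.sin(np.arange(1200) / 200.0) + rng.normal(0, 0.02, 1200)
        s = _stream(SensorKind.EDA, x, 4.0)
        assert detect_eda_peaks(s, Epoch(0.0)) == oracle_peaks(x)


def test_eda_rollups_examples_and_oracle():
    total, mean = eda_peak_rollups(np.zeros(30))
    assert total[-1] == 0 and mean[-1] == 0
    total, mean = eda_peak_rollups(np.full(24, 2.0))
    assert total[-1] == 48 and mean[-1] == 2
    rng = np.random.default_rng(4)
    counts = rng.integers(0, 6, size=200).astype(float)
    total, mean = eda_peak_rollups(counts)
    for k in range(len(counts)):
        window = counts[max(0, k - 23): k + 1]
        assert total[k] == window.sum()
        assert mean[k] == pytest.approx(window.mean())


def test_hrv_closed_forms():
    ibi = IBISequence(0.0, [1.0, 1.8, 2.6], [0.8, 0.8, 0.8])
    got = hrv_metrics(ibi, Epoch(0.0))
    np.testing.assert_allclose(got, [800, 800, 800, 800, 0, 0, 0, 0])
    ibi = IBISequence(0.0, [1.0, 1.76], [0.7, 0.76])
    got = hrv_metrics(ibi, Epoch(0.0))
    assert got[5] == pytest.approx(60.0)   # RMSSD
    assert got[6] == 1                      # NN50
    assert got[7] == pytest.approx(0.5)     # pNN50, denominator = 2 intervals


def test_hrv_against_oracle_and_degenerate_windows():
    rng = np.random.default_rng(5)
    for _ in range(50):
        n = int(rng.integers(0, 40))
        iv = rng.uniform(0.4, 1.4, size=n)
        offsets = np.cumsum(iv)
        ibi = IBISequence(0.0, offsets, iv) if n else IBISequence(0.0, [], [])
        got = hrv_metrics(ibi, Epoch(0.0, ))
        np.testing.assert_allclose(got, oracle_hrv(iv * 1000), rtol=1e-10, atol=1e-12,
                                   equal_nan=True)
    one = IBISequence(0.0, [1.0], [0.8])
    got = hrv_metrics(one, Epoch(0.0))
    assert np.isnan(got[4:]).all() and got[0] == 800


def test_activity_bout_definition():
    # epoch means both strictly above the expanding prior average -> 1
    acc = [10, 10, 20]
    hr = [60, 60, 80]
    assert list(activity_bout(acc, hr)) == [0, 0, 1]
    # HR above but ACC below -> 0
    assert list(activity_bout([10, 10, 5], hr)) == [0, 0, 0]


def test_activity_rollups_against_oracle():
    rng = np.random.default_rng(6)
    bouts = (rng.random(400) < 0.2).astype(float)
    am = rng.uniform(60, 80, 400)
    ax = rng.uniform(80, 120, 400)
    tot1h, mean24h, m2h, x2h = activity_rollups(bouts, am, ax)
    for k in range(400):
        assert tot1h[k] == bouts[max(0, k - 11): k + 1].sum()
        assert mean24h[k] == pytest.approx(bouts[max(0, k - 287): k + 1].mean())
        assert m2h[k] == pytest.approx(am[max(0, k - 23): k + 1].mean())
        assert x2h[k] == ax[max(0, k - 23): k + 1].max()
    # 12 consecutive bout epochs ending at t -> total prev 1 h = 12
    tot1h, *_ = activity_rollups(np.ones(12), np.ones(12), np.ones(12))
    assert tot1h[-1] == 12


def test_circadian_features_clock_arithmetic():
    day0 = 1_600_041_600.0  # a UTC midnight
    m, h = circadian_features([day0, day0 + 5400, day0 + 86100])
    np.testing.assert_allclose(m, [0, 90, 1435])
    np.testing.assert_allclose(h, [0, 1.5, 1435 / 60])


def test_wake_time_square_wave_and_degenerate_day():
    """A day that is flat-low for 8 h then flat-high pins the wake time to
    the step; an all-constant day yields no wake."""
    n = 288
    starts = 86400.0 + EPOCH_SECONDS * np.arange(n)
    step = 96  # 08:00
    lowhigh = np.where(np.arange(n) >= step, 10.0, 1.0)
    wake = wake_times_by_day(starts, lowhigh, lowhigh, lowhigh, lowhigh)
    assert abs(wake.iloc[0] - step * 5) <= 15
    flat = np.ones(n)
    wake = wake_times_by_day(starts, flat, flat, flat, flat)
    assert np.isnan(wake.iloc[0])


def test_wake_time_recovers_planted_schedule(tiny_record):
    rec, cfg = tiny_record
    table = assemble_features(rec)
    # wake feature is the previous day's estimate; planted wake ~07:00
    wakes = table["wake_time"].dropna().unique()
    assert len(wakes) > 0
    med = np.median(table["wake_time"].dropna())
    assert abs(med - 7 * 60) <= 30


def test_food_features_window_membership():
    t = 1_000_000.0
    food = FoodLog(entries=pd.DataFrame({
        "timestamp": [t - 36000, t - 3600],
        "calories_kcal": [100.0, 200.0], "protein_g": [10.0, 20.0],
        "carbs_g": [40.0, 50.0], "sugar_g": [20.0, 30.0],
        "label": ["early", "late"],
    }))
    row = food_features(food, t).iloc[0]
    assert (row["sugar_2h"], row["sugar_8h"], row["sugar_24h"]) == (30, 30, 50)
    assert row["eating_count_24h"] == 2
    assert row["eating_mean_24h"] == pytest.approx(2 / 288)
    assert row["eating_event"] == 0
    empty = food_features(FoodLog(), t).iloc[0]
    assert (empty == 0).all()


def test_food_features_against_oracle():
    rng = np.random.default_rng(7)
    for _ in range(100):
        n = int(rng.integers(0, 20))
        ts = np.sort(rng.uniform(0, 2 * 86400, size=n))
        g = rng.integers(0, 100, size=(n, 4)).astype(float)  # integer grams: exact sums
        food = FoodLog(entries=pd.DataFrame({
            "timestamp": ts, "calories_kcal": g[:, 0], "protein_g": g[:, 1],
            "carbs_g": g[:, 2], "sugar_g": g[:, 3], "label": [""] * n,
        }))
        t = float(rng.uniform(86400, 2.5 * 86400))
        row = food_features(food, t).iloc[0]
        for w_name, w in (("2h", 7200), ("8h", 28800), ("24h", 86400)):
            sel = (ts > t - w) & (ts <= t - 300)
            assert row[f"sugar_{w_name}"] == g[sel, 3].sum()
            assert row[f"calories_{w_name}"] == g[sel, 0].sum()
            assert row[f"eating_count_{w_name}"] == sel.sum()
        sel_e = (ts > t - 600) & (ts <= t - 300)
        assert row["eating_event"] == float(sel_e.any())


# ---------------------------------------------------------------------------
# assembly


def _cheap_record(days=10, pid=1, seed=0, rate=1.0):
    """A record with 1-Hz stand-in streams, gap-free CGM, for schema tests."""
    rng = np.random.default_rng(seed)
    n = int(days * 86400 * rate)
    t0 = 0.0
    streams = {
        SensorKind.HR: SensorStream(SensorKind.HR, t0, rate, rng.uniform(55, 90, n)),
        SensorKind.EDA: SensorStream(SensorKind.EDA, t0, rate, rng.uniform(0.5, 2, n)),
        SensorKind.TEMP: SensorStream(SensorKind.TEMP, t0, rate, rng.uniform(32, 34, n)),
        SensorKind.ACC: SensorStream(SensorKind.ACC, t0, rate, rng.uniform(-5, 70, (n, 3))),
    }
    iv = rng.uniform(0.6, 1.1, int(days * 86400 / 0.8))
    offsets = np.cumsum(iv)
    keep = offsets < days * 86400
    ibi = IBISequence(t0, offsets[keep], iv[keep])
    n_ep = int(days * 288)
    glucose = GlucoseSeries(t0 + EPOCH_SECONDS * np.arange(n_ep),
                            rng.uniform(80, 160, n_ep))
    food = FoodLog(entries=pd.DataFrame({
        "timestamp": np.sort(rng.uniform(0, days * 86400, days * 3)),
        "calories_kcal": rng.integers(100, 800, days * 3).astype(float),
        "protein_g": rng.integers(0, 40, days * 3).astype(float),
        "carbs_g": rng.integers(0, 90, days * 3).astype(float),
        "sugar_g": rng.integers(0, 50, days * 3).astype(float),
        "label": ["m"] * (days * 3),
    }))
    return ParticipantRecord(pid, 0, 5.6, streams, ibi, glucose, food)


def test_assembled_table_shape_and_history_rule():
    rec = _cheap_record(days=10)
    table = assemble_features(rec)
    assert len(table) == 9 * 288  # first 24 h dropped
    assert list(table.columns) == ["participant_id", "epoch_start", *FEATURE_NAMES,
                                   "glucose_target", "excursion_label"]
    assert len(FEATURE_NAMES) == 69
    feats = table[FEATURE_NAMES]
    assert not feats.isna().any().any()


def test_assembly_deterministic_under_stream_order():
    rec = _cheap_record(days=2)
    reordered = ParticipantRecord(
        rec.participant_id, rec.sex, rec.hba1c,
        dict(reversed(list(rec.streams.items()))),
        rec.ibi, rec.glucose, rec.food,
    )
    pd.testing.assert_frame_equal(assemble_features(rec), assemble_features(reordered))


def test_no_lookahead_leakage():
    """Perturbing any sensor, food or glucose data at times >= t leaves
    the feature row for target t unchanged."""
    rec = _cheap_record(days=3, seed=3)
    base = assemble_features(rec)
    t_cut = float(base["epoch_start"].iloc[len(base) // 2])

    poisoned_streams = {}
    for kind, s in rec.streams.items():
        vals = s.values.copy()
        idx = s.timestamps() >= t_cut
        vals[idx] = vals[idx] * 7.7 + 100.0
        poisoned_streams[kind] = SensorStream(kind, s.start_time, s.rate_hz, vals)
    f = rec.food.entries.copy()
    late = f["timestamp"] >= t_cut
    f.loc[late, ["calories_kcal", "protein_g", "carbs_g", "sugar_g"]] *= 3
    times = rec.ibi.start_time + rec.ibi.offsets
    keep = times < t_cut
    ibi = IBISequence(rec.ibi.start_time, rec.ibi.offsets[keep], rec.ibi.intervals[keep])
    g = rec.glucose.glucose_mg_dl.copy()
    g[rec.glucose.timestamps > t_cut] += 50.0
    poisoned = ParticipantRecord(rec.participant_id, rec.sex, rec.hba1c,
                                 poisoned_streams, ibi,
                                 GlucoseSeries(rec.glucose.timestamps, g),
                                 FoodLog(entries=f))
    other = assemble_features(poisoned)
    sel = base["epoch_start"] <= t_cut
    pd.testing.assert_frame_equal(base[sel].drop(columns="glucose_target"),
                                  other[sel].drop(columns="glucose_target"))


def test_bout_detection_recovers_planted_bouts(tiny_record):
    rec, cfg = tiny_record
    table = assemble_features(rec)
    truth = planted_truth(cfg)
    bouts = truth["bouts"]
    bouts = bouts[bouts["participant_id"] == rec.participant_id]
    # epochs fully inside a planted bout should be flagged
    flagged = []
    for s, e in bouts[["start", "end"]].itertuples(index=False):
        # the feature row at target t describes the epoch [t-600, t-300)
        sel = (table["epoch_start"] - 600 >= s) & (table["epoch_start"] - 300 <= e)
        if sel.any():
            flagged.extend(table.loc[sel, "activity_bout"].tolist())
    assert len(flagged) > 0
    assert np.mean(flagged) >= 0.7
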