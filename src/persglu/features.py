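"""The 69 historical features computed per 5-minute epoch.

Feature groups
--------------
* 28 data-driven: {mean, sd, min, max, q1, q3, skew} for heart rate,
  accelerometry vector magnitude, electrodermal activity, skin temperature
* 8 HRV: mean/median/max/min inter-beat interval, SDNN, RMSSD, NN50, pNN50
* 3 EDA peaks: unique peaks in the epoch (prominence >= 0.3 uS, minimum
  separation 4 samples), rolling 2-h total, rolling 2-h mean per epoch
* 5 activity: bout indicator, total bouts last 1 h, mean bouts last 24 h,
  ACC vector-magnitude mean and max over the last 2 h
* 3 circadian: minutes from midnight, hours from midnight, wake time
* 19 food: {calories, protein, carbs, sugar} x {2 h, 8 h, 24 h} sums,
  eating-event binary, event counts and event means over 2/8/24 h
* 2 demographics: biological sex, HbA1c
* 1 personalization: participant id

Historical rule
---------------
Every feature for the glucose target at time ``t`` uses only data from 5
minutes to 24 hours before ``t``. Writing ``c = t - 300 s`` for the
cutoff: per-epoch sensor features describe the last fully historical
epoch ``[c - 300, c)``; rolling windows on the epoch grid cover the
epochs ending at or before ``c``; food windows are ``(t - w, c]``.
Wake time is the most recent *completed* day's estimate, so no same-day
lookahead enters the row.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from persglu.io_formats import (
    EPOCH_SECONDS,
    FoodLog,
    IBISequence,
    ParticipantRecord,
    SensorKind,
    SensorStream,
)

DAY_S = 86400.0
EPOCHS_2H = 24
EPOCHS_8H = 96
EPOCHS_24H = 288

STAT_NAMES = ["mean", "sd", "min", "max", "q1", "q3", "skew"]
_SENSOR_PREFIX = {SensorKind.HR: "hr", SensorKind.ACC: "acc",
                  SensorKind.EDA: "eda", SensorKind.TEMP: "temp"}

FEATURE_NAMES: list[str] = (
    [f"{p}_{s}" for p in ("hr", "acc", "eda", "temp") for s in STAT_NAMES]
    + ["ibi_mean", "ibi_median", "ibi_max", "ibi_min", "sdnn", "rmssd", "nn50", "pnn50"]
    + ["eda_peaks", "eda_peaks_total_2h", "eda_peaks_mean_2h"]
    + ["activity_bout", "bouts_total_1h", "bouts_mean_24h", "acc_mean_2h", "acc_max_2h"]
    + ["minutes_from_midnight", "hours_from_midnight", "wake_time"]
    + [f"{n}_{w}" for n in ("calories", "protein", "carbs", "sugar") for w in ("2h", "8h", "24h")]
    + ["eating_event", "eating_count_2h", "eating_count_8h", "eating_count_24h",
       "eating_mean_2h", "eating_mean_8h", "eating_mean_24h"]
    + ["sex", "hba1c", "personalization"]
)
assert len(FEATURE_NAMES) == 69


@dataclass(frozen=True)
class Epoch:
    """A half-open 5-minute interval [start, start + 300 s)."""

    start: float

    @property
    def end(self) -> float:
        return self.start + EPOCH_SECONDS


@dataclass
class FeaturesConfig:
    tz_offset_hours: float = 0.0
    wake_slope_threshold: float = 0.02  # per-epoch first difference of the smoothed series
    imputation: str = "ffill_median"    # or "none"

    def validate(self) -> None:
        if self.imputation not in ("ffill_median", "none"):
            raise ValueError(f"unknown imputation strategy {self.imputation!r}")


def features_config_from_dict(d: dict) -> FeaturesConfig:
    valid = {f.name for f in dataclasses.fields(FeaturesConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown features config key(s): {sorted(unknown)}")
    cfg = FeaturesConfig(**d)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# elementary operations


def vector_magnitude(acc: np.ndarray) -> np.ndarray:
    """Euclidean norm across the 3 accelerometer axes (units of 1/64 g)."""
    acc = np.asarray(acc, dtype=float)
    return np.sqrt(np.sum(acc**2, axis=-1))


def _stats_1d(x: np.ndarray) -> np.ndarray:
    """mean, sample sd, min, max, q1, q3, adjusted Fisher-Pearson skew."""
    n = len(x)
    if n < 2:
        return np.full(7, np.nan)
    mu = x.mean()
    sd = x.std(ddof=1)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    m2 = ((x - mu) ** 2).mean()
    if m2 == 0.0 or n < 3:
        skew = 0.0
    else:
        g1 = ((x - mu) ** 3).mean() / m2**1.5
        skew = g1 * np.sqrt(n * (n - 1)) / (n - 2)
    return np.array([mu, sd, x.min(), x.max(), q1, q3, skew])


def _window_indices(stream: SensorStream, start: float, end: float) -> tuple[int, int]:
    r = stream.rate_hz
    i0 = int(np.ceil((start - stream.start_time) * r - 1e-9))
    i1 = int(np.ceil((end - stream.start_time) * r - 1e-9))
    return max(i0, 0), min(max(i1, 0), len(stream))


def summary_stats(stream: SensorStream, epoch: Epoch) -> np.ndarray:
    """7 summary statistics of the samples falling in the epoch.

    ACC streams are reduced to the per-sample vector magnitude first.
    Fewer than 2 samples yields all-missing. Skew of a constant window is
    defined as 0.
    """
    i0, i1 = _window_indices(stream, epoch.start, epoch.end)
    vals = stream.values[i0:i1]
    if stream.kind is SensorKind.ACC and vals.ndim == 2:
        vals = vector_magnitude(vals)
    return _stats_1d(np.asarray(vals, dtype=float))


def detect_eda_peaks(eda: SensorStream, epoch: Epoch,
                     prominence_us: float = 0.3, min_distance: int = 4) -> int:
    """Count unique EDA peaks in the epoch.

    A unique peak is a local maximum with topographic prominence of at
    least ``prominence_us`` micro-siemens after enforcing a minimum
    separation of ``min_distance`` samples (1 s at 4 Hz); of two closer
    candidates the higher survives.
    """
    i0, i1 = _window_indices(eda, epoch.start, epoch.end)
    window = np.asarray(eda.values[i0:i1], dtype=float)
    if len(window) < 3:
        return 0
    peaks, _ = find_peaks(window, distance=min_distance, prominence=prominence_us)
    return int(len(peaks))


def eda_peak_rollups(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-h total and per-epoch mean of the peak counts.

    Trailing windows of up to 24 epochs ending at (and including) each
    grid position; shorter head windows use the epochs that exist.
    """
    s = pd.Series(np.asarray(counts, dtype=float))
    total = s.rolling(EPOCHS_2H, min_periods=1).sum().to_numpy()
    mean = s.rolling(EPOCHS_2H, min_periods=1).mean().to_numpy()
    return total, mean


def hrv_metrics(ibi: IBISequence, epoch: Epoch) -> np.ndarray:
    """8 HRV metrics from the inter-beat intervals whose events fall in the epoch.

    Intervals are taken in milliseconds: mean, median, max, min, SDNN
    (sample sd), RMSSD (root mean square of successive differences),
    NN50 (count of successive differences > 50 ms), and pNN50 = NN50
    divided by the number of intervals.
    """
    times = ibi.start_time + ibi.offsets
    sel = (times >= epoch.start) & (times < epoch.end)
    return _hrv_from_intervals(ibi.intervals[sel] * 1000.0)


def _hrv_from_intervals(iv_ms: np.ndarray) -> np.ndarray:
    n = len(iv_ms)
    if n == 0:
        return np.full(8, np.nan)
    out = np.full(8, np.nan)
    out[0] = iv_ms.mean()
    out[1] = np.median(iv_ms)
    out[2] = iv_ms.max()
    out[3] = iv_ms.min()
    if n >= 2:
        out[4] = iv_ms.std(ddof=1)
        d = np.diff(iv_ms)
        out[5] = np.sqrt(np.mean(d**2))
        nn50 = int(np.sum(np.abs(d) > 50.0))
        out[6] = nn50
        out[7] = nn50 / n
    return out


def activity_bout(acc_mean: np.ndarray, hr_mean: np.ndarray) -> np.ndarray:
    """Per-epoch activity-bout indicator.

    An epoch is a bout when both its mean accelerometry vector magnitude
    and its mean heart rate exceed the participant's expanding average
    over all prior epochs. The first epoch (no history) is 0; epochs with
    missing means are 0.
    """
    acc = pd.Series(np.asarray(acc_mean, dtype=float))
    hr = pd.Series(np.asarray(hr_mean, dtype=float))
    prior_acc = acc.expanding().mean().shift(1)
    prior_hr = hr.expanding().mean().shift(1)
    bout = (acc > prior_acc) & (hr > prior_hr)
    return bout.to_numpy(dtype=float)


def activity_rollups(bouts: np.ndarray, acc_mean: np.ndarray, acc_max: np.ndarray):
    """(total bouts prev 1 h, mean bouts prev 24 h, ACC-VM mean prev 2 h, ACC-VM max prev 2 h)."""
    b = pd.Series(np.asarray(bouts, dtype=float))
    am = pd.Series(np.asarray(acc_mean, dtype=float))
    ax = pd.Series(np.asarray(acc_max, dtype=float))
    return (
        b.rolling(12, min_periods=1).sum().to_numpy(),
        b.rolling(EPOCHS_24H, min_periods=1).mean().to_numpy(),
        am.rolling(EPOCHS_2H, min_periods=1).mean().to_numpy(),
        ax.rolling(EPOCHS_2H, min_periods=1).max().to_numpy(),
    )


def circadian_features(t, tz_offset_hours: float = 0.0):
    """(minutes from local midnight in [0, 1440), hours = minutes / 60)."""
    local = np.asarray(t, dtype=float) + tz_offset_hours * 3600.0
    minutes = np.mod(local, DAY_S) / 60.0
    return minutes, minutes / 60.0


def wake_times_by_day(
    epoch_starts: np.ndarray,
    acc_mean: np.ndarray,
    acc_sd: np.ndarray,
    hr_mean: np.ndarray,
    hr_sd: np.ndarray,
    tz_offset_hours: float = 0.0,
    slope_threshold: float = 0.02,
) -> pd.Series:
    """Estimate one wake time (minutes from local midnight) per calendar day.

    Per epoch, an awake indicator is 1 unless at least two of the four
    measures (ACC mean/sd, HR mean/sd) are below their average for that
    day. The indicator is smoothed with a trailing 3-h rolling mean; the
    wake time is the earliest epoch of the day whose smoothed first
    difference exceeds ``slope_threshold`` while the smoothed value 25
    and 75 minutes later both exceed the value at the candidate. Days
    with no qualifying epoch get NaN (callers fall back to the previous
    day).
    """
    t_local = np.asarray(epoch_starts, dtype=float) + tz_offset_hours * 3600.0
    day = np.floor(t_local / DAY_S).astype(int)
    measures = np.column_stack([acc_mean, acc_sd, hr_mean, hr_sd]).astype(float)

    below = np.zeros(measures.shape, dtype=bool)
    for d in np.unique(day):
        rows = day == d
        avg = np.nanmean(measures[rows], axis=0)
        below[rows] = measures[rows] < avg
    indicator = (below.sum(axis=1) < 2).astype(float)

    smooth = pd.Series(indicator).rolling(36, min_periods=1).mean().to_numpy()
    slope = np.diff(smooth, prepend=smooth[0])

    out = {}
    n = len(smooth)
    for d in np.unique(day):
        idx = np.flatnonzero(day == d)
        wake = np.nan
        for k in idx:
            if slope[k] <= slope_threshold:
                continue
            k25, k75 = k + 5, k + 15
            # the confirmation window must stay inside the day being scored
            if k75 >= n or day[k75] != d:
                continue
            if smooth[k25] > smooth[k] and smooth[k75] > smooth[k]:
                wake = np.mod(t_local[k], DAY_S) / 60.0
                break
        out[d] = wake
    return pd.Series(out)


def food_features(food: FoodLog, t) -> pd.DataFrame:
    """The 19 diet features for target time(s) ``t``.

    Nutrient sums and eating-event counts are over the historical windows
    ``(t - w, t - 300]`` for w in {2 h, 8 h, 24 h}; the eating-event
    binary marks a consumption in the latest historical epoch
    ``(t - 600, t - 300]``; event means divide the count by the number of
    epochs in the window (24, 96, 288).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    ts = food.entries["timestamp"].to_numpy(float)
    nutrients = food.entries[["calories_kcal", "protein_g", "carbs_g", "sugar_g"]].to_numpy(float)
    prefix = np.vstack([np.zeros(4), np.cumsum(nutrients, axis=0)]) if len(ts) else np.zeros((1, 4))

    cutoff = t - EPOCH_SECONDS
    hi = np.searchsorted(ts, cutoff, side="right")
    cols = {}
    names = ["calories", "protein", "carbs", "sugar"]
    for w_name, w_s, n_ep in (("2h", 7200.0, EPOCHS_2H), ("8h", 28800.0, EPOCHS_8H),
                              ("24h", 86400.0, EPOCHS_24H)):
        lo = np.searchsorted(ts, t - w_s, side="right")
        for j, nm in enumerate(names):
            cols[f"{nm}_{w_name}"] = prefix[hi, j] - prefix[lo, j]
        count = (hi - lo).astype(float)
        cols[f"eating_count_{w_name}"] = count
        cols[f"eating_mean_{w_name}"] = count / n_ep
    lo_epoch = np.searchsorted(ts, t - 2 * EPOCH_SECONDS, side="right")
    cols["eating_event"] = (hi - lo_epoch > 0).astype(float)

    order = ([f"{n}_{w}" for n in names for w in ("2h", "8h", "24h")]
             + ["eating_event", "eating_count_2h", "eating_count_8h", "eating_count_24h",
                "eating_mean_2h", "eating_mean_8h", "eating_mean_24h"])
    return pd.DataFrame({k: cols[k] for k in order})


# ---------------------------------------------------------------------------
# per-epoch grids


def _epoch_grid(record: ParticipantRecord) -> np.ndarray:
    """5-min epoch starts covering the sensor span, phase-aligned to the CGM grid."""
    if len(record.glucose) == 0:
        raise ValueError("participant has no glucose data")
    phase = record.glucose.timestamps[0] % EPOCH_SECONDS
    starts = [s.start_time for s in record.streams.values()]
    ends = [s.end_time for s in record.streams.values()]
    t_lo = max(min(starts), -np.inf)
    first = np.ceil((t_lo - phase) / EPOCH_SECONDS) * EPOCH_SECONDS + phase
    last = max(ends)
    n = int(np.floor((last - first) / EPOCH_SECONDS))
    return first + EPOCH_SECONDS * np.arange(n)


def _epoch_summaries(stream: SensorStream, grid: np.ndarray) -> np.ndarray:
    """(n_epochs, 7) summary statistics, vectorized when the stream is grid-aligned."""
    n_ep = len(grid)
    out = np.full((n_ep, 7), np.nan)
    per_epoch = stream.rate_hz * EPOCH_SECONDS
    i0 = np.ceil((grid - stream.start_time) * stream.rate_hz - 1e-9).astype(np.int64)
    aligned = (
        per_epoch == int(per_epoch)
        and n_ep > 0
        and i0[0] >= 0
        and i0[0] + int(per_epoch) * n_ep <= len(stream)
        and np.all(np.diff(i0) == int(per_epoch))
    )
    vals = stream.values
    if stream.kind is SensorKind.ACC and vals.ndim == 2:
        vals = vector_magnitude(vals)
    if aligned:
        m = int(per_epoch)
        block = vals[i0[0]: i0[0] + m * n_ep].reshape(n_ep, m)
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        q1 = np.quantile(block, 0.25, axis=1)
        q3 = np.quantile(block, 0.75, axis=1)
        centered = block - mu[:, None]
        m2 = np.mean(centered**2, axis=1)
        m3 = np.mean(centered**3, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            g1 = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, 0.0)
        skew = g1 * np.sqrt(m * (m - 1)) / (m - 2)
        out[:, 0] = mu
        out[:, 1] = sd
        out[:, 2] = block.min(axis=1)
        out[:, 3] = block.max(axis=1)
        out[:, 4] = q1
        out[:, 5] = q3
        out[:, 6] = skew
    else:
        for k, a in enumerate(grid):
            lo, hi = _window_indices(stream, a, a + EPOCH_SECONDS)
            out[k] = _stats_1d(np.asarray(vals[lo:hi], dtype=float))
    return out


def _epoch_peak_counts(eda: SensorStream, grid: np.ndarray,
                       prominence_us: float = 0.3, min_distance: int = 4) -> np.ndarray:
    counts = np.zeros(len(grid))
    for k, a in enumerate(grid):
        counts[k] = detect_eda_peaks(eda, Epoch(a), prominence_us, min_distance)
    return counts


def _epoch_hrv(ibi: IBISequence, grid: np.ndarray) -> np.ndarray:
    out = np.full((len(grid), 8), np.nan)
    times = ibi.start_time + ibi.offsets
    iv_ms = ibi.intervals * 1000.0
    lo = np.searchsorted(times, grid, side="left")
    hi = np.searchsorted(times, grid + EPOCH_SECONDS, side="left")
    for k in range(len(grid)):
        out[k] = _hrv_from_intervals(iv_ms[lo[k]:hi[k]])
    return out


# ---------------------------------------------------------------------------
# full assembly


def assemble_features(record: ParticipantRecord,
                      config: FeaturesConfig | None = None) -> pd.DataFrame:
    """One feature row per glucose timestamp with >= 24 h of prior data.

    Returns a table with columns ``participant_id``, ``epoch_start`` (the
    target's own timestamp), the 69 features, ``glucose_target`` and an
    (empty) ``excursion_label`` column filled by the labeling stage.
    """
    config = config or FeaturesConfig()
    config.validate()
    grid = _epoch_grid(record)
    if len(grid) < EPOCHS_24H + 2:
        import warnings

        warnings.warn(f"participant {record.participant_id}: under 24 h of data, empty table")
        return pd.DataFrame(columns=["participant_id", "epoch_start", *FEATURE_NAMES,
                                     "glucose_target", "excursion_label"])

    hr_stats = _epoch_summaries(record.streams[SensorKind.HR], grid)
    acc_stats = _epoch_summaries(record.streams[SensorKind.ACC], grid)
    eda_stats = _epoch_summaries(record.streams[SensorKind.EDA], grid)
    temp_stats = _epoch_summaries(record.streams[SensorKind.TEMP], grid)
    hrv = _epoch_hrv(record.ibi, grid)
    peaks = _epoch_peak_counts(record.streams[SensorKind.EDA], grid)
    peaks_tot, peaks_mean = eda_peak_rollups(peaks)
    bouts = activity_bout(acc_stats[:, 0], hr_stats[:, 0])
    bouts_1h, bouts_24h, acc_2h_mean, acc_2h_max = activity_rollups(
        bouts, acc_stats[:, 0], acc_stats[:, 3]
    )
    wake_by_day = wake_times_by_day(
        grid, acc_stats[:, 0], acc_stats[:, 1], hr_stats[:, 0], hr_stats[:, 1],
        config.tz_offset_hours, config.wake_slope_threshold,
    )
    # previous completed day's wake, carried forward over undetectable days
    wake_filled = wake_by_day.sort_index().ffill()

    # targets: glucose timestamps with >= 24 h of sensor history whose
    # historical epoch [t-600, t-300) lies on the grid
    g_t = record.glucose.timestamps
    g_v = record.glucose.glucose_mg_dl
    j = np.round((g_t - 2 * EPOCH_SECONDS - grid[0]) / EPOCH_SECONDS).astype(int)
    ok = (g_t - grid[0] >= DAY_S) & (j >= 0) & (j < len(grid))
    g_t, g_v, j = g_t[ok], g_v[ok], j[ok]

    rows = pd.DataFrame(index=np.arange(len(g_t)))
    rows["participant_id"] = record.participant_id
    rows["epoch_start"] = g_t
    for stats, prefix in ((hr_stats, "hr"), (acc_stats, "acc"),
                          (eda_stats, "eda"), (temp_stats, "temp")):
        for s_i, s_name in enumerate(STAT_NAMES):
            rows[f"{prefix}_{s_name}"] = stats[j, s_i]
    for h_i, h_name in enumerate(["ibi_mean", "ibi_median", "ibi_max", "ibi_min",
                                  "sdnn", "rmssd", "nn50", "pnn50"]):
        rows[h_name] = hrv[j, h_i]
    rows["eda_peaks"] = peaks[j]
    rows["eda_peaks_total_2h"] = peaks_tot[j]
    rows["eda_peaks_mean_2h"] = peaks_mean[j]
    rows["activity_bout"] = bouts[j]
    rows["bouts_total_1h"] = bouts_1h[j]
    rows["bouts_mean_24h"] = bouts_24h[j]
    rows["acc_mean_2h"] = acc_2h_mean[j]
    rows["acc_max_2h"] = acc_2h_max[j]

    minutes, hours = circadian_features(g_t, config.tz_offset_hours)
    rows["minutes_from_midnight"] = minutes
    rows["hours_from_midnight"] = hours
    target_day = np.floor((g_t + config.tz_offset_hours * 3600.0) / DAY_S).astype(int)
    rows["wake_time"] = wake_filled.reindex(target_day - 1).to_numpy()

    food = food_features(record.food, g_t)
    for c in food.columns:
        rows[c] = food[c].to_numpy()

    rows["sex"] = float(record.sex)
    rows["hba1c"] = float(record.hba1c)
    rows["personalization"] = float(record.participant_id)
    rows["glucose_target"] = g_v
    rows["excursion_label"] = np.nan

    if config.imputation == "ffill_median":
        feats = rows[FEATURE_NAMES]
        feats = feats.ffill()
        feats = feats.fillna(feats.median(numeric_only=True)).fillna(0.0)
        rows[FEATURE_NAMES] = feats
    return rows[["participant_id", "epoch_start", *FEATURE_NAMES,
                 "glucose_target", "excursion_label"]]
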