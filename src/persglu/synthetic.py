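"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
16-person cohort wearing a wrist device (heart rate 1 Hz, electrodermal
activity and skin temperature 4 Hz, accelerometry 32 Hz, inter-beat
intervals) and a 5-minute CGM for 8-10 days, with

* a per-participant glucose baseline (~N(110, 8) mg/dL) plus a 24-h
  circadian sinusoid,
* meal-driven glucose rises: a log-normal-shaped impulse per logged meal,
  peak amplitude linear in grams of sugar and carbohydrate,
* activity-driven dips: a rectangular drop during each planted activity
  bout with exponential recovery, accompanied by elevated heart rate and
  accelerometry,
* AR(1) measurement noise, clipping to [40, 300] mg/dL,
* stochastic electrodermal "stress burst" peaks (~0.5 uS prominence)
  during waking hours, and
* a sleep/wake schedule that quiets heart rate and accelerometry at night
  so wake-time detection is exercised.

All randomness flows from one seed; per-participant substreams are keyed
by (seed, participant id) so a participant's data does not change when
the cohort size does. ``planted_truth`` reconstructs the planted meal,
bout, and burst windows from the same substreams for validation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from persglu.io_formats import (
    EPOCH_SECONDS,
    FoodLog,
    GlucoseSeries,
    IBISequence,
    ParticipantRecord,
    SensorKind,
    SensorStream,
)

DAY_S = 86400.0


class ConfigError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Parameters of the simulated study.

    Magnitudes are stand-ins chosen for qualitative realism (the source
    study reports no distributional parameters of its raw streams); the
    cohort size, wear duration, sampling rates and CGM missingness match
    the study design (16 participants, 8-10 days, ~60% of the complete
    5-min grid observed, i.e. ~1500 glucose points per participant).
    """

    n_participants: int = 16
    days_min: int = 8
    days_max: int = 10
    seed: int = 0
    start_time: float = 1_600_041_600.0  # a UTC midnight

    glucose_baseline_mean: float = 110.0
    glucose_baseline_sd: float = 8.0
    circadian_amp_mg_dl: float = 8.0
    circadian_phase_hour: float = 16.0

    # meal response: log-normal impulse peaking `meal_lag_min` after the
    # meal, half-amplitude `meal_decay_min` later; peak rise linear in
    # sugar and carbohydrate grams
    meal_rise_per_g_sugar: float = 0.8
    meal_rise_per_g_carb: float = 0.3
    meal_lag_min: float = 30.0
    meal_decay_min: float = 90.0
    meals_per_day: float = 4.0

    # activity: planted bouts with HR/ACC elevation and a glucose dip
    activity_bouts_per_day: float = 2.0
    bout_duration_min: float = 30.0
    activity_dip_mg_dl: float = 15.0
    activity_dip_lag_min: float = 10.0
    activity_recovery_min: float = 45.0

    noise_ar1: float = 0.8
    noise_sd: float = 3.0
    wear_gap_fraction: float = 0.42

    eda_bursts_per_day: float = 8.0
    eda_burst_prominence_us: float = 0.5
    eda_burst_prominence_sd: float = 0.1

    wake_hour: float = 7.0
    sleep_hour: float = 23.0
    hba1c_range: tuple = (5.2, 6.4)
    ibi_jitter_s: float = 0.025

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("n_participants must be >= 2")
        if self.days_min < 2:
            raise ConfigError("days must be >= 2 (the 24-h rolling window needs history)")
        if self.days_max < self.days_min:
            raise ConfigError("days_max must be >= days_min")
        for name in (
            "circadian_amp_mg_dl", "meal_rise_per_g_sugar", "meal_rise_per_g_carb",
            "meals_per_day", "activity_bouts_per_day", "activity_dip_mg_dl",
            "noise_sd", "eda_bursts_per_day", "glucose_baseline_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0.0 <= self.wear_gap_fraction < 1.0:
            raise ConfigError("wear_gap_fraction must be in [0, 1)")


def _rng_for(config: CohortConfig, pid: int, stage: str) -> np.random.Generator:
    # fixed per-(participant, stage) substream: reproducible under cohort
    # size changes and independent of generation order
    tag = sum(ord(c) for c in stage)
    return np.random.default_rng([config.seed % (2**31), pid, tag])


@dataclass
class _Plan:
    """Planted ground truth for one participant."""

    pid: int
    days: int
    sex: int
    hba1c: float
    baseline: float
    meals: pd.DataFrame      # timestamp, calories_kcal, protein_g, carbs_g, sugar_g
    bouts: pd.DataFrame      # start, end
    bursts: pd.DataFrame     # time, prominence_us
    wake_minutes: np.ndarray  # per day, minutes from midnight


def _plan_participant(config: CohortConfig, pid: int) -> _Plan:
    rng = _rng_for(config, pid, "plan")
    days = int(rng.integers(config.days_min, config.days_max + 1))
    sex = int(rng.integers(0, 2))
    hba1c = float(rng.uniform(*config.hba1c_range))
    baseline = float(config.glucose_baseline_mean + config.glucose_baseline_sd * rng.standard_normal())

    t0 = config.start_time
    wake_minutes = config.wake_hour * 60.0 + rng.normal(0.0, 15.0, size=days)

    meal_rows = []
    bout_rows = []
    burst_rows = []
    for d in range(days):
        day_start = t0 + d * DAY_S
        wake = day_start + wake_minutes[d] * 60.0
        sleep = day_start + config.sleep_hour * 3600.0
        n_meals = int(rng.poisson(config.meals_per_day))
        meal_times = np.sort(rng.uniform(wake + 900.0, sleep - 3600.0, size=n_meals))
        for mt in meal_times:
            carbs = float(rng.uniform(20.0, 90.0))
            sugar = float(rng.uniform(5.0, 45.0))
            protein = float(rng.uniform(5.0, 40.0))
            kcal = 4.0 * (carbs + protein) + float(rng.uniform(50.0, 250.0))
            meal_rows.append((float(mt), kcal, protein, carbs, sugar))
        n_bouts = int(rng.poisson(config.activity_bouts_per_day))
        bout_starts = np.sort(rng.uniform(wake + 1800.0, sleep - 5400.0, size=n_bouts))
        for bs in bout_starts:
            bout_rows.append((float(bs), float(bs + config.bout_duration_min * 60.0)))
        n_bursts = int(rng.poisson(config.eda_bursts_per_day))
        for bt in np.sort(rng.uniform(wake, sleep, size=n_bursts)):
            prom = max(0.05, float(rng.normal(config.eda_burst_prominence_us,
                                              config.eda_burst_prominence_sd)))
            burst_rows.append((float(bt), prom))

    meals = pd.DataFrame(meal_rows, columns=["timestamp", "calories_kcal", "protein_g", "carbs_g", "sugar_g"])
    bouts = pd.DataFrame(bout_rows, columns=["start", "end"])
    bursts = pd.DataFrame(burst_rows, columns=["time", "prominence_us"])
    return _Plan(pid=pid, days=days, sex=sex, hba1c=hba1c, baseline=baseline,
                 meals=meals, bouts=bouts, bursts=bursts, wake_minutes=wake_minutes)


def _lognormal_kernel(tau_s: np.ndarray, lag_min: float, decay_min: float) -> np.ndarray:
    """Unit-peak log-normal impulse: peak at `lag_min`, half-amplitude `decay_min` later."""
    t_peak = lag_min * 60.0
    s = np.log((lag_min + decay_min) / lag_min) / np.sqrt(2.0 * np.log(2.0))
    out = np.zeros_like(tau_s, dtype=float)
    pos = tau_s > 0
    out[pos] = np.exp(-(np.log(tau_s[pos] / t_peak)) ** 2 / (2.0 * s**2))
    return out


def _circadian(t: np.ndarray, config: CohortConfig) -> np.ndarray:
    tod = np.mod(t, DAY_S)
    return config.circadian_amp_mg_dl * np.sin(
        2.0 * np.pi * (tod - config.circadian_phase_hour * 3600.0) / DAY_S
    )


def _awake_mask(t: np.ndarray, plan: _Plan, config: CohortConfig) -> np.ndarray:
    day = np.floor((t - config.start_time) / DAY_S).astype(int)
    day = np.clip(day, 0, plan.days - 1)
    tod_min = np.mod(t - config.start_time, DAY_S) / 60.0
    return (tod_min >= plan.wake_minutes[day]) & (tod_min < config.sleep_hour * 60.0)


def _bout_mask(t: np.ndarray, plan: _Plan) -> np.ndarray:
    mask = np.zeros(len(t), dtype=bool)
    for start, end in plan.bouts.itertuples(index=False):
        mask |= (t >= start) & (t < end)
    return mask


def _glucose_trace(plan: _Plan, config: CohortConfig, rng: np.random.Generator) -> GlucoseSeries:
    n_epochs = int(plan.days * DAY_S / EPOCH_SECONDS)
    t = config.start_time + EPOCH_SECONDS * np.arange(n_epochs)
    g = plan.baseline + _circadian(t, config)

    for row in plan.meals.itertuples(index=False):
        amp = (config.meal_rise_per_g_sugar * row.sugar_g
               + config.meal_rise_per_g_carb * row.carbs_g)
        if amp > 0:
            g = g + amp * _lognormal_kernel(t - row.timestamp, config.meal_lag_min,
                                            config.meal_decay_min)
    if config.activity_dip_mg_dl > 0:
        lag = config.activity_dip_lag_min * 60.0
        rec = config.activity_recovery_min * 60.0
        for start, end in plan.bouts.itertuples(index=False):
            tau = t - (start + lag)
            dip = np.zeros(n_epochs)
            during = (tau >= 0) & (t < end + lag)
            dip[during] = 1.0
            after = t >= end + lag
            dip[after] = np.exp(-(t[after] - (end + lag)) / rec)
            g = g - config.activity_dip_mg_dl * dip

    if config.noise_sd > 0:
        eps = rng.normal(0.0, config.noise_sd, size=n_epochs)
        noise = np.empty(n_epochs)
        phi = config.noise_ar1
        noise[0] = eps[0] / np.sqrt(max(1.0 - phi**2, 1e-12)) if abs(phi) < 1 else eps[0]
        for i in range(1, n_epochs):
            noise[i] = phi * noise[i - 1] + eps[i]
        g = g + noise

    g = np.clip(g, 40.0, 300.0)
    keep = np.ones(n_epochs, dtype=bool)
    if config.wear_gap_fraction > 0:
        keep = rng.random(n_epochs) >= config.wear_gap_fraction
    return GlucoseSeries(timestamps=t[keep], glucose_mg_dl=g[keep])


def _hr_per_second(plan: _Plan, config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    n = int(plan.days * DAY_S)
    t = config.start_time + np.arange(n, dtype=float)
    awake = _awake_mask(t, plan, config)
    hr = np.where(awake, 70.0, 55.0) + 3.0 * np.sin(2.0 * np.pi * np.mod(t, DAY_S) / DAY_S)
    hr = hr + 30.0 * _bout_mask(t, plan)
    # beat-to-beat variability is larger awake than asleep
    hr = hr + rng.normal(0.0, 1.0, size=n) * np.where(awake, 3.0, 1.0)
    return np.clip(hr, 35.0, 190.0)


def _generate_streams(plan: _Plan, config: CohortConfig) -> tuple[dict, IBISequence]:
    t0 = config.start_time
    n_sec = int(plan.days * DAY_S)

    hr_vals = _hr_per_second(plan, config, _rng_for(config, plan.pid, "hr"))
    # device exports are quantized: HR to 0.01 bpm
    hr = SensorStream(SensorKind.HR, t0, 1.0, np.round(hr_vals, 2))

    # EDA: slow drift + planted bursts (Gaussian bumps, ~1.5 s sd) + small noise
    rng_eda = _rng_for(config, plan.pid, "eda")
    n4 = n_sec * 4
    t4 = t0 + np.arange(n4) / 4.0
    eda = 1.0 + 0.2 * np.sin(2.0 * np.pi * np.mod(t4, DAY_S) / DAY_S)
    for bt, prom in plan.bursts.itertuples(index=False):
        lo = int(max(0, (bt - 8.0 - t0) * 4))
        hi = int(min(n4, (bt + 8.0 - t0) * 4))
        if hi > lo:
            eda[lo:hi] += prom * np.exp(-((t4[lo:hi] - bt) ** 2) / (2.0 * 1.5**2))
    eda = eda + rng_eda.normal(0.0, 0.01, size=n4)
    eda_stream = SensorStream(SensorKind.EDA, t0, 4.0,
                              np.round(np.maximum(eda, 0.01), 3))

    rng_temp = _rng_for(config, plan.pid, "temp")
    temp = (33.0 + 0.5 * np.sin(2.0 * np.pi * np.mod(t4, DAY_S) / DAY_S)
            + rng_temp.normal(0.0, 0.05, size=n4))
    temp_stream = SensorStream(SensorKind.TEMP, t0, 4.0, np.round(temp, 2))

    # ACC: gravity on z (~64 counts = 1 g) plus state-dependent motion noise
    rng_acc = _rng_for(config, plan.pid, "acc")
    t1 = t0 + np.arange(n_sec, dtype=float)
    awake = _awake_mask(t1, plan, config)
    bout = _bout_mask(t1, plan)
    # ordinary waking movement is far noisier than sleep; bouts noisier still
    sd_per_sec = np.where(bout, 12.0, np.where(awake, 8.0, 0.3))
    sd32 = np.repeat(sd_per_sec, 32).astype(np.float64)
    n32 = n_sec * 32
    acc = np.empty((n32, 3))
    acc[:, 0] = rng_acc.normal(0.0, 1.0, size=n32) * sd32
    acc[:, 1] = rng_acc.normal(0.0, 1.0, size=n32) * sd32
    acc[:, 2] = 64.0 + rng_acc.normal(0.0, 1.0, size=n32) * sd32
    # rhythmic arm swing during bouts raises the vector-magnitude mean
    bout32 = np.repeat(bout, 32)
    t32 = t0 + np.arange(n32) / 32.0
    acc[bout32, 0] += 20.0 * np.sin(2.0 * np.pi * 2.0 * t32[bout32])
    # accelerometer counts are integers (1/64 g per count)
    acc_stream = SensorStream(SensorKind.ACC, t0, 32.0, np.round(acc))

    # IBI from integrated heart rate phase, with timing jitter
    rng_ibi = _rng_for(config, plan.pid, "ibi")
    phase = np.concatenate([[0.0], np.cumsum(hr_vals / 60.0)])
    n_beats = int(np.floor(phase[-1]))
    beat_times = np.interp(np.arange(1, n_beats + 1, dtype=float),
                           phase, np.arange(n_sec + 1, dtype=float))
    intervals = np.diff(beat_times)
    if config.ibi_jitter_s > 0:
        intervals = intervals + rng_ibi.normal(0.0, config.ibi_jitter_s, size=len(intervals))
    intervals = np.clip(intervals, 0.25, 2.5)
    offsets = beat_times[0] + np.concatenate([[0.0], np.cumsum(intervals)])[:-1] + intervals
    ibi = IBISequence(start_time=t0, offsets=offsets, intervals=intervals)

    streams = {SensorKind.HR: hr, SensorKind.EDA: eda_stream,
               SensorKind.TEMP: temp_stream, SensorKind.ACC: acc_stream}
    return streams, ibi


def generate_participant(config: CohortConfig, pid: int) -> ParticipantRecord:
    """Generate one participant's full record (streams, IBI, CGM, food, demographics)."""
    config.validate()
    plan = _plan_participant(config, pid)
    streams, ibi = _generate_streams(plan, config)
    glucose = _glucose_trace(plan, config, _rng_for(config, plan.pid, "glucose"))
    food_df = plan.meals.copy()
    food_df["label"] = [f"meal_{i}" for i in range(len(food_df))]
    food = FoodLog(entries=food_df)
    return ParticipantRecord(
        participant_id=pid, sex=plan.sex, hba1c=plan.hba1c,
        streams=streams, ibi=ibi, glucose=glucose, food=food,
    )


def generate_cohort(config: CohortConfig) -> list[ParticipantRecord]:
    """Generate all participants; deterministic given ``config.seed``.

    Holds every raw stream in memory at once — for large cohorts prefer
    :func:`generate_participant` in a loop and process incrementally.
    """
    config.validate()
    return [generate_participant(config, pid) for pid in range(1, config.n_participants + 1)]


def planted_truth(config: CohortConfig) -> dict:
    """Reconstruct the planted ground truth of a cohort.

    Returns dataframes keyed ``meals`` (timestamp + nutrients), ``bouts``
    (start/end), and ``bursts`` (time + prominence), each carrying a
    ``participant_id`` column; windows enable downstream validation of
    detected activity bouts, EDA peaks, and meal effects.
    """
    config.validate()
    meals, bouts, bursts = [], [], []
    for pid in range(1, config.n_participants + 1):
        plan = _plan_participant(config, pid)
        for df, acc in ((plan.meals, meals), (plan.bouts, bouts), (plan.bursts, bursts)):
            d = df.copy()
            d.insert(0, "participant_id", pid)
            acc.append(d)
    return {
        "meals": pd.concat(meals, ignore_index=True),
        "bouts": pd.concat(bouts, ignore_index=True),
        "bursts": pd.concat(bursts, ignore_index=True),
    }


def config_from_dict(d: dict) -> CohortConfig:
    """Build a :class:`CohortConfig` from a mapping, rejecting unknown keys."""
    valid = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ConfigError(f"unknown cohort config key(s): {sorted(unknown)}")
    if "hba1c_range" in d:
        d = {**d, "hba1c_range": tuple(d["hba1c_range"])}
    cfg = CohortConfig(**d)
    cfg.validate()
    return cfg
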