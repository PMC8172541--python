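"""On-disk formats and in-memory containers for cohort data.

Wearable channels use the wrist-device export dialect: a plain CSV whose
first line is the UNIX start time of the recording, second line the
sampling rate in Hz, followed by one sample per line (three comma-separated
columns for the accelerometer). The inter-beat-interval file is an event
list rather than a uniform stream: a start-time header line followed by
``offset_seconds,interval_seconds`` rows.

CGM traces, food logs, demographics and feature tables are ordinary
headered CSVs; every reader round-trips losslessly with the matching
writer.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when a file does not parse as its documented dialect."""


class SchemaError(ValueError):
    """Raised when a CSV is missing or carrying unexpected columns."""


class SensorKind(str, enum.Enum):
    HR = "HR"
    EDA = "EDA"
    TEMP = "TEMP"
    ACC = "ACC"


#: nominal sampling rate of each channel, in Hz
NOMINAL_RATE_HZ = {
    SensorKind.HR: 1.0,
    SensorKind.EDA: 4.0,
    SensorKind.TEMP: 4.0,
    SensorKind.ACC: 32.0,
}

#: CGM epoch length in seconds
EPOCH_SECONDS = 300.0


@dataclass
class SensorStream:
    """A uniformly sampled wearable channel.

    ``values`` has shape (n,) for single-channel kinds and (n, 3) for the
    accelerometer (units of 1/64 g per axis). Sample i is at
    ``start_time + i / rate_hz`` (UTC epoch seconds).
    """

    kind: SensorKind
    start_time: float
    rate_hz: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.kind = SensorKind(self.kind)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.kind is SensorKind.ACC:
            if self.values.ndim != 2 or self.values.shape[1] != 3:
                raise ValueError("ACC stream requires exactly 3 channels")
        else:
            if self.values.ndim != 1:
                raise ValueError(f"{self.kind.value} stream must be single-channel")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def end_time(self) -> float:
        return self.start_time + len(self) / self.rate_hz

    def timestamps(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) / self.rate_hz


@dataclass
class IBISequence:
    """Inter-beat-interval events: (offset from start in s, interval in s)."""

    start_time: float
    offsets: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=np.float64)
        self.intervals = np.asarray(self.intervals, dtype=np.float64)
        if self.offsets.shape != self.intervals.shape or self.offsets.ndim != 1:
            raise ValueError("offsets and intervals must be 1-D and equal length")
        if len(self.offsets) and np.any(np.diff(self.offsets) <= 0):
            raise ValueError("IBI offsets must be strictly increasing")
        if np.any(self.intervals <= 0):
            raise ValueError("IBI intervals must be positive")

    def __len__(self) -> int:
        return len(self.offsets)


@dataclass
class GlucoseSeries:
    """5-minute interstitial glucose trace (mg/dL); gaps permitted."""

    timestamps: np.ndarray
    glucose_mg_dl: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.glucose_mg_dl = np.asarray(self.glucose_mg_dl, dtype=np.float64)
        if self.timestamps.shape != self.glucose_mg_dl.shape or self.timestamps.ndim != 1:
            raise ValueError("timestamps and glucose must be 1-D and equal length")
        if len(self.timestamps) and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("glucose timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.glucose_mg_dl)):
            raise ValueError("glucose values must be finite")
        if np.any(self.glucose_mg_dl < 0):
            raise ValueError("glucose values must be non-negative")

    def __len__(self) -> int:
        return len(self.timestamps)


FOOD_COLUMNS = ["timestamp", "calories_kcal", "protein_g", "carbs_g", "sugar_g", "label"]
NUTRIENT_COLUMNS = ["calories_kcal", "protein_g", "carbs_g", "sugar_g"]


@dataclass
class FoodLog:
    """Timestamped consumption events with nutrient payloads."""

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=FOOD_COLUMNS)
    )

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.entries)
        missing = [c for c in FOOD_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"food log missing columns: {missing}")
        df = df[FOOD_COLUMNS].reset_index(drop=True)
        for col in ["timestamp"] + NUTRIENT_COLUMNS:
            df[col] = pd.to_numeric(df[col]).astype(float)
        if (df[NUTRIENT_COLUMNS] < 0).any().any():
            raise ValueError("nutrient fields must be non-negative")
        if not df["timestamp"].is_monotonic_increasing:
            raise ValueError("food log timestamps must be sorted")
        self.entries = df

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ParticipantRecord:
    """All data collected for one participant."""

    participant_id: int
    sex: int  # 0 = female, 1 = male
    hba1c: float
    streams: dict
    ibi: IBISequence
    glucose: GlucoseSeries
    food: FoodLog

    def __post_init__(self) -> None:
        self.streams = {SensorKind(k): v for k, v in self.streams.items()}


# ---------------------------------------------------------------------------
# wearable stream files


def read_e4_stream(path, kind) -> SensorStream:
    """Read a wearable channel from the device-export CSV dialect."""
    kind = SensorKind(kind)
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise FormatError(f"{path}: expected start-time and rate header lines")
    try:
        start_time = float(lines[0].split(",")[0])
    except ValueError as exc:
        raise FormatError(f"{path}: line 1 is not a numeric start time") from exc
    try:
        rate_hz = float(lines[1].split(",")[0])
    except ValueError as exc:
        raise FormatError(f"{path}: line 2 is not a numeric sample rate") from exc
    n_channels = 3 if kind is SensorKind.ACC else 1
    try:
        # fast path: homogeneous numeric rows via the C csv engine
        df = pd.read_csv(path, skiprows=2, header=None, dtype=np.float64,
                         skip_blank_lines=True, float_precision="round_trip")
        values = df.to_numpy()
        if values.size and (values.shape[1] != n_channels or np.isnan(values).any()):
            raise ValueError
        if values.size == 0:
            values = np.empty((0, n_channels))
    except pd.errors.EmptyDataError:
        values = np.empty((0, n_channels))
    except (ValueError, pd.errors.ParserError):
        # slow path only to locate and report the offending row
        for i, line in enumerate(lines[2:], start=3):
            if not line.strip():
                continue
            parts = line.split(",")
            if len(parts) != n_channels:
                raise FormatError(
                    f"{path}: row {i} has {len(parts)} columns, expected {n_channels}"
                )
            try:
                [float(p) for p in parts]
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric sample at row {i}") from exc
        raise FormatError(f"{path}: could not parse data section")  # pragma: no cover
    if values.size == 0:
        values = np.empty((0, 3) if kind is SensorKind.ACC else (0,))
    elif kind is not SensorKind.ACC:
        values = values[:, 0]
    return SensorStream(kind=kind, start_time=start_time, rate_hz=rate_hz, values=values)


def _fmt(v) -> str:
    return format(float(v), ".17g")


def write_e4_stream(stream: SensorStream, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{_fmt(stream.start_time)}\n{_fmt(stream.rate_hz)}\n")
        vals = stream.values
        if vals.size:
            pd.DataFrame(vals).to_csv(fh, header=False, index=False,
                                      float_format="%.17g", lineterminator="\n")


def read_ibi(path) -> IBISequence:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: expected a start-time header line")
    try:
        start_time = float(lines[0].split(",")[0])
    except ValueError as exc:
        raise FormatError(f"{path}: line 1 is not a numeric start time") from exc
    offsets, intervals = [], []
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != 2:
            raise FormatError(f"{path}: row {i} must be offset,interval")
        try:
            offsets.append(float(parts[0]))
            intervals.append(float(parts[1]))
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric value at row {i}") from exc
    return IBISequence(start_time=start_time, offsets=np.array(offsets), intervals=np.array(intervals))


def write_ibi(ibi: IBISequence, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_fmt(ibi.start_time) + "\n")
        for off, iv in zip(ibi.offsets, ibi.intervals):
            fh.write(f"{_fmt(off)},{_fmt(iv)}\n")


# ---------------------------------------------------------------------------
# CGM / food / demographics


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def read_cgm(path) -> GlucoseSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["timestamp", "glucose_mg_dl"], path)
    return GlucoseSeries(
        timestamps=df["timestamp"].to_numpy(float),
        glucose_mg_dl=df["glucose_mg_dl"].to_numpy(float),
    )


def write_cgm(series: GlucoseSeries, path) -> None:
    pd.DataFrame(
        {"timestamp": series.timestamps, "glucose_mg_dl": series.glucose_mg_dl}
    ).to_csv(path, index=False, float_format="%.17g")


def read_food_log(path) -> FoodLog:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, FOOD_COLUMNS, path)
    if df["label"].isna().all():
        df["label"] = df["label"].astype(object).fillna("")
    return FoodLog(entries=df)


def write_food_log(food: FoodLog, path) -> None:
    food.entries.to_csv(path, index=False, float_format="%.17g")


def read_demographics(path) -> tuple[int, int, float]:
    """Return (participant_id, sex, hba1c) from a one-row demographics CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["participant_id", "sex", "hba1c"], path)
    row = df.iloc[0]
    return int(row["participant_id"]), int(row["sex"]), float(row["hba1c"])


def write_demographics(participant_id: int, sex: int, hba1c: float, path) -> None:
    pd.DataFrame(
        {"participant_id": [participant_id], "sex": [sex], "hba1c": [hba1c]}
    ).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# participant directories

_STREAM_FILES = {
    SensorKind.HR: "HR.csv",
    SensorKind.EDA: "EDA.csv",
    SensorKind.TEMP: "TEMP.csv",
    SensorKind.ACC: "ACC.csv",
}


def write_participant(record: ParticipantRecord, directory) -> None:
    """Write one participant's data as a directory of CSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kind, fname in _STREAM_FILES.items():
        write_e4_stream(record.streams[kind], directory / fname)
    write_ibi(record.ibi, directory / "IBI.csv")
    write_cgm(record.glucose, directory / "cgm.csv")
    write_food_log(record.food, directory / "food.csv")
    write_demographics(record.participant_id, record.sex, record.hba1c, directory / "demographics.csv")


def read_participant(directory) -> ParticipantRecord:
    directory = Path(directory)
    streams = {
        kind: read_e4_stream(directory / fname, kind)
        for kind, fname in _STREAM_FILES.items()
    }
    pid, sex, hba1c = read_demographics(directory / "demographics.csv")
    return ParticipantRecord(
        participant_id=pid,
        sex=sex,
        hba1c=hba1c,
        streams=streams,
        ibi=read_ibi(directory / "IBI.csv"),
        glucose=read_cgm(directory / "cgm.csv"),
        food=read_food_log(directory / "food.csv"),
    )


def read_cohort_dir(directory) -> list[ParticipantRecord]:
    """Read every ``participant_*`` subdirectory of a cohort directory."""
    directory = Path(directory)
    subdirs = sorted(directory.glob("participant_*"))
    if not subdirs:
        raise FormatError(f"{directory}: no participant_* subdirectories found")
    return [read_participant(d) for d in subdirs]


# ---------------------------------------------------------------------------
# feature tables


def feature_table_columns(feature_names: Sequence[str]) -> list[str]:
    return ["participant_id", "epoch_start", *feature_names, "glucose_target", "excursion_label"]


def write_feature_table(table: pd.DataFrame, path, feature_names: Sequence[str] | None = None) -> None:
    from persglu.features import FEATURE_NAMES

    cols = feature_table_columns(feature_names or FEATURE_NAMES)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing column(s) {missing}")
    extra = [c for c in table.columns if c not in cols]
    if extra:
        raise SchemaError(f"feature table has unknown column(s) {extra}")
    table[cols].to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path, feature_names: Sequence[str] | None = None) -> pd.DataFrame:
    from persglu.features import FEATURE_NAMES

    cols = feature_table_columns(feature_names or FEATURE_NAMES)
    df = pd.read_csv(path, float_precision="round_trip")
    unknown = [c for c in df.columns if c not in cols]
    if unknown:
        raise SchemaError(f"{path}: unknown column(s) {unknown}")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    df = df[cols]
    numeric = ["epoch_start", *(feature_names or FEATURE_NAMES), "glucose_target"]
    df = df.astype({"participant_id": int, **{c: float for c in numeric}})
    if "excursion_label" in df.columns and len(df):
        df["excursion_label"] = df["excursion_label"].astype(object).where(df["excursion_label"].notna(), np.nan)
    return df
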