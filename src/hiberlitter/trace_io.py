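"""Readers, writers and validated record types for the pipeline's tabular inputs.

Four CSV streams feed the analysis:

* ``traces.csv`` — ``animal_id,timestamp,temp_c``: intraperitoneal logger
  readings on a nominally uniform grid (one sample every 135 min by default).
* ``captures.csv`` — ``animal_id,date,mass_g,sex,mother_id,group``:
  capture–recapture records from trapping sessions.
* ``feeding.csv`` — ``animal_id,interval_start,interval_end,crop,consumed_g``:
  net mass of each crop consumed per weighing interval.
* ``crops.csv`` — ``crop,protein_frac,lipid_frac,carb_frac,energy_kj_per_g``:
  dry-mass nutritional composition of each crop.

Traces are stored internally as ``(start_time, sampling_period, values)``;
missing readings on the implied grid are kept as NaN samples so that
downstream bout detection can treat logger gaps explicitly.  Validation is
total: malformed rows raise a typed error naming the offending rows, never a
silent drop.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraceIOError",
    "SchemaError",
    "ValidationError",
    "TemperatureTrace",
    "CaptureEvent",
    "FeedingRecord",
    "CropComposition",
    "Period",
    "read_traces",
    "read_captures",
    "read_feeding",
    "read_crops",
    "read_periods",
    "write_table",
    "records_to_frame",
]

TEMP_MIN_C = -10.0
TEMP_MAX_C = 45.0
SEXES = ("female", "male")
DIET_GROUPS = ("W", "WS", "RF", "ML")


class TraceIOError(ValueError):
    """Base class for input-validation failures."""


class SchemaError(TraceIOError):
    """A required column is missing or a file cannot be parsed at all."""


class ValidationError(TraceIOError):
    """Row-level invariant violation; carries the offending row numbers."""

    def __init__(self, message: str, rows: Sequence[int] = ()):  # rows are 1-based data rows
        super().__init__(message)
        self.rows = tuple(rows)


@dataclass
class TemperatureTrace:
    """One animal's uniformly sampled body-temperature series.

    ``temperatures`` lies on the implied grid
    ``start_time + i * sampling_period``; missing readings are NaN.
    """

    animal_id: str
    start_time: pd.Timestamp
    temperatures: np.ndarray
    sampling_period: float = 135.0  # minutes
    resolution: float = 0.06  # °C quantum of the logger

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.temperatures.ndim != 1 or self.temperatures.size == 0:
            raise ValidationError(f"trace {self.animal_id!r}: empty temperature sequence")
        if self.sampling_period <= 0:
            raise ValidationError(f"trace {self.animal_id!r}: non-positive sampling period")
        finite = self.temperatures[np.isfinite(self.temperatures)]
        bad = (finite < TEMP_MIN_C) | (finite > TEMP_MAX_C)
        if bad.any():
            raise ValidationError(
                f"trace {self.animal_id!r}: {int(bad.sum())} temperature(s) outside "
                f"[{TEMP_MIN_C}, {TEMP_MAX_C}] °C"
            )
        self.start_time = pd.Timestamp(self.start_time)

    def __len__(self) -> int:
        return self.temperatures.size

    @property
    def period(self) -> pd.Timedelta:
        return pd.Timedelta(minutes=self.sampling_period)

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(
            self.start_time + pd.to_timedelta(np.arange(len(self)) * self.sampling_period, unit="m")
        )

    def time_at(self, index: int) -> pd.Timestamp:
        return self.start_time + self.period * int(index)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.temperatures).sum())


@dataclass(frozen=True)
class CaptureEvent:
    animal_id: str
    date: date
    body_mass: float  # g
    sex: str
    mother_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.body_mass <= 700):
            raise ValidationError(
                f"capture of {self.animal_id!r}: body mass {self.body_mass} g outside (0, 700]"
            )
        if self.sex not in SEXES:
            raise ValidationError(
                f"capture of {self.animal_id!r}: sex {self.sex!r} not one of {SEXES}"
            )
        if self.group is not None and self.group not in DIET_GROUPS:
            raise ValidationError(
                f"capture of {self.animal_id!r}: group {self.group!r} not one of {DIET_GROUPS}"
            )


@dataclass(frozen=True)
class FeedingRecord:
    animal_id: str
    interval_start: date
    interval_end: date
    crop: str
    consumed_mass: float  # g, net consumed over the interval

    def __post_init__(self) -> None:
        if self.interval_end <= self.interval_start:
            raise ValidationError(
                f"feeding record for {self.animal_id!r}: interval_end "
                f"{self.interval_end} not after interval_start {self.interval_start}"
            )
        if self.consumed_mass < 0:
            raise ValidationError(
                f"feeding record for {self.animal_id!r}: negative consumed mass "
                f"{self.consumed_mass} g"
            )


@dataclass(frozen=True)
class CropComposition:
    crop: str
    protein_frac: float
    lipid_frac: float
    carbohydrate_frac: float
    energy_density: float  # kJ per g dry mass

    def __post_init__(self) -> None:
        fracs = (self.protein_frac, self.lipid_frac, self.carbohydrate_frac)
        if any(not (0 <= f <= 1) for f in fracs):
            raise ValidationError(f"crop {self.crop!r}: macronutrient fraction outside [0, 1]")
        if sum(fracs) > 1 + 1e-9:
            raise ValidationError(
                f"crop {self.crop!r}: macronutrient fractions sum to {sum(fracs):.3f} > 1"
            )
        if self.energy_density <= 0:
            raise ValidationError(f"crop {self.crop!r}: non-positive energy density")


@dataclass(frozen=True)
class Period:
    """A named per-animal date interval, e.g. hibernation vs post-hibernation."""

    animal_id: str
    name: str
    start: date
    end: date

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"period {self.name!r} of {self.animal_id!r}: end {self.end} not after "
                f"start {self.start}"
            )

    @property
    def days(self) -> int:
        return (self.end - self.start).days


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    try:
        return pd.read_csv(path, dtype={"animal_id": str, "mother_id": str})
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc


def read_traces(
    path,
    sampling_period: float | None = None,
    resolution: float = 0.06,
) -> list[TemperatureTrace]:
    """Read ``traces.csv`` and return one :class:`TemperatureTrace` per animal.

    Timestamps must be strictly increasing within an animal.  The sampling
    period is inferred per animal as the smallest positive spacing unless
    given explicitly; readings missing from the implied grid become NaN
    samples, so gaps are preserved rather than silently compacted.
    """
    df = _read_csv(path)
    _require_columns(df, ["animal_id", "timestamp", "temp_c"], path)
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    except Exception as exc:
        raise ValidationError(f"{path}: unparseable timestamp ({exc})") from exc
    df["_row"] = np.arange(1, len(df) + 1)

    traces: list[TemperatureTrace] = []
    for animal_id, sub in df.groupby("animal_id", sort=True):
        ts = sub["timestamp"].to_numpy()
        rows = sub["_row"].to_numpy()
        diffs = np.diff(ts).astype("timedelta64[s]").astype(float)
        dup = np.nonzero(diffs == 0)[0]
        if dup.size:
            raise ValidationError(
                f"{path}: duplicated timestamp for animal {animal_id!r} at row(s) "
                f"{[int(rows[i + 1]) for i in dup]}",
                rows=[int(rows[i + 1]) for i in dup],
            )
        neg = np.nonzero(diffs < 0)[0]
        if neg.size:
            raise ValidationError(
                f"{path}: non-monotone timestamps for animal {animal_id!r} at row(s) "
                f"{[int(rows[i + 1]) for i in neg]}",
                rows=[int(rows[i + 1]) for i in neg],
            )
        if sampling_period is None:
            period_min = float(diffs.min() / 60.0) if diffs.size else 135.0
        else:
            period_min = float(sampling_period)
        period_s = period_min * 60.0
        offsets = (ts - ts[0]).astype("timedelta64[s]").astype(float)
        slots = offsets / period_s
        slot_idx = np.rint(slots).astype(int)
        off_grid = np.nonzero(np.abs(slots - slot_idx) > 1e-3)[0]
        if off_grid.size:
            raise ValidationError(
                f"{path}: animal {animal_id!r} has readings off the {period_min:g}-min grid "
                f"at row(s) {[int(rows[i]) for i in off_grid[:5]]}",
                rows=[int(rows[i]) for i in off_grid],
            )
        values = np.full(slot_idx[-1] + 1, np.nan)
        temps = sub["temp_c"].to_numpy(dtype=float)
        finite = temps[np.isfinite(temps)]
        bad = np.nonzero((temps < TEMP_MIN_C) | (temps > TEMP_MAX_C))[0]
        if bad.size or finite.size < temps.size:
            bad_rows = [int(rows[i]) for i in bad]
            raise ValidationError(
                f"{path}: animal {animal_id!r} has {max(bad.size, temps.size - finite.size)} "
                f"temperature(s) outside [{TEMP_MIN_C}, {TEMP_MAX_C}] °C or non-numeric "
                f"at row(s) {bad_rows[:5]}",
                rows=bad_rows,
            )
        values[slot_idx] = temps
        traces.append(
            TemperatureTrace(
                animal_id=str(animal_id),
                start_time=pd.Timestamp(ts[0]),
                temperatures=values,
                sampling_period=period_min,
                resolution=resolution,
            )
        )
    return traces


def _parse_date(value, path, row) -> date:
    try:
        return pd.Timestamp(value).date()
    except Exception as exc:
        raise ValidationError(f"{path}: unparseable date {value!r} at row {row}", rows=[row]) from exc


def read_captures(path) -> list[CaptureEvent]:
    df = _read_csv(path)
    _require_columns(df, ["animal_id", "date", "mass_g", "sex", "mother_id", "group"], path)
    events = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        mother = None if pd.isna(rec.mother_id) or rec.mother_id in ("", "unknown") else str(rec.mother_id)
        group = None if pd.isna(rec.group) else str(rec.group)
        try:
            events.append(
                CaptureEvent(
                    animal_id=str(rec.animal_id),
                    date=_parse_date(rec.date, path, i),
                    body_mass=float(rec.mass_g),
                    sex=str(rec.sex),
                    mother_id=mother,
                    group=group,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}", rows=[i]) from exc
    return events


def read_feeding(path) -> list[FeedingRecord]:
    df = _read_csv(path)
    _require_columns(df, ["animal_id", "interval_start", "interval_end", "crop", "consumed_g"], path)
    records = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                FeedingRecord(
                    animal_id=str(rec.animal_id),
                    interval_start=_parse_date(rec.interval_start, path, i),
                    interval_end=_parse_date(rec.interval_end, path, i),
                    crop=str(rec.crop),
                    consumed_mass=float(rec.consumed_g),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}", rows=[i]) from exc
    return records


def read_crops(path) -> dict[str, CropComposition]:
    df = _read_csv(path)
    _require_columns(df, ["crop", "protein_frac", "lipid_frac", "carb_frac", "energy_kj_per_g"], path)
    comps: dict[str, CropComposition] = {}
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            comp = CropComposition(
                crop=str(rec.crop),
                protein_frac=float(rec.protein_frac),
                lipid_frac=float(rec.lipid_frac),
                carbohydrate_frac=float(rec.carb_frac),
                energy_density=float(rec.energy_kj_per_g),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}", rows=[i]) from exc
        if comp.crop in comps:
            raise ValidationError(f"{path}: row {i}: duplicate crop {comp.crop!r}", rows=[i])
        comps[comp.crop] = comp
    return comps


def read_periods(path) -> list[Period]:
    df = _read_csv(path)
    _require_columns(df, ["animal_id", "period", "start", "end"], path)
    periods = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            periods.append(
                Period(
                    animal_id=str(rec.animal_id),
                    name=str(rec.period),
                    start=_parse_date(rec.start, path, i),
                    end=_parse_date(rec.end, path, i),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}", rows=[i]) from exc
    return periods


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Convert a sequence of dataclass records to a DataFrame (empty-safe)."""
    records = list(records)
    if not records:
        return pd.DataFrame()
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def write_table(rows, path, columns: Sequence[str] | None = None) -> None:
    """Write a result table (DataFrame or dataclass sequence) to CSV.

    Values round-trip exactly: floats are serialized with full repr precision
    and an empty table yields a header-only file (pass ``columns`` to name the
    header when an empty dataclass sequence carries no schema of its own).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = rows if isinstance(rows, pd.DataFrame) else records_to_frame(rows)
    if df.empty and df.columns.empty and columns is not None:
        df = pd.DataFrame(columns=list(columns))
    df.to_csv(path, index=False)
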