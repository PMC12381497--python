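"""Torpor-bout detection and hibernation phenology.

A torpor bout is a maximal run of consecutive samples with body temperature
strictly below a threshold (30 °C by default) whose span is at least a
minimum duration (24 h by default).  Each sample represents the interval it
opens, so a run of k samples at 135-min sampling spans k x 135 minutes; at
the defaults a bout therefore requires >= 11 consecutive sub-threshold
samples (11 x 135 = 1485 min >= 1440).  A single sample at or above the
threshold terminates a run, as does a logger gap (NaN sample) — missing data
never fabricates torpor.

Isolated bouts occurring long after the main hibernation period are excluded
by a greedy chain rule: starting from the first bout, the next bout is
retained while the gap to the end of the last retained bout stays within a
maximum (15 days by default); once the chain breaks, all later bouts are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .trace_io import TemperatureTrace, ValidationError

__all__ = [
    "TorporBout",
    "HibernationSummary",
    "detect_torpor_bouts",
    "exclude_isolated_bouts",
    "summarize_hibernation",
    "phenology_table",
    "sem",
]


@dataclass(frozen=True)
class TorporBout:
    """One detected torpor bout (sample indices inclusive)."""

    start_index: int
    end_index: int
    start_time: pd.Timestamp
    end_time: pd.Timestamp  # end of the interval opened by the last in-bout sample
    duration: float  # hours
    min_temperature: float  # °C

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass
class HibernationSummary:
    animal_id: str
    n_bouts: int
    total_torpor: float  # hours
    hibernation_start: pd.Timestamp | None
    hibernation_end: pd.Timestamp | None
    hibernation_duration: float  # days; 0 when the animal never hibernated
    excluded_bouts: int
    did_hibernate: bool


def sem(values) -> float:
    """Standard error of the mean (ddof=1); NaN for fewer than two values."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


def detect_torpor_bouts(
    trace: TemperatureTrace,
    threshold: float = 30.0,
    min_duration: float = 24.0,
) -> list[TorporBout]:
    """Find maximal sub-threshold runs spanning at least ``min_duration`` hours.

    Parameters
    ----------
    trace:
        Validated temperature trace; NaN samples (logger gaps) break runs.
    threshold:
        Torpor cutoff in °C; a sample exactly at the threshold is euthermic
        (strict ``<``).
    min_duration:
        Minimum bout span in hours; a run of k samples spans
        ``k * sampling_period``.
    """
    if len(trace) == 0:
        raise ValidationError(f"trace {trace.animal_id!r}: empty trace")
    if not (0 < threshold < 45):
        raise ValueError(f"threshold {threshold} outside (0, 45) °C")
    if min_duration <= 0:
        raise ValueError("min_duration must be positive")

    temps = trace.temperatures
    below = np.zeros(len(temps), dtype=bool)
    finite = np.isfinite(temps)
    below[finite] = temps[finite] < threshold

    # Maximal runs of True via edge detection.
    padded = np.concatenate(([False], below, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0] - 1  # inclusive

    period_h = trace.sampling_period / 60.0
    bouts: list[TorporBout] = []
    for s, e in zip(starts, ends):
        n = e - s + 1
        span_h = n * period_h
        if span_h < min_duration:
            continue
        bouts.append(
            TorporBout(
                start_index=int(s),
                end_index=int(e),
                start_time=trace.time_at(s),
                end_time=trace.time_at(e) + trace.period,
                duration=float(span_h),
                min_temperature=float(np.min(temps[s : e + 1])),
            )
        )
    return bouts


def exclude_isolated_bouts(
    bouts: Sequence[TorporBout], max_gap: float = 15.0
) -> tuple[list[TorporBout], list[TorporBout]]:
    """Split bouts into (retained, excluded) by the greedy main-period chain.

    The main hibernation period grows forward from the first bout; bout i+1
    is retained iff its start follows the end of the last retained bout by at
    most ``max_gap`` days.  Once the chain breaks, every later bout is
    excluded.  Idempotent: re-applying to the retained set changes nothing.
    """
    bouts = list(bouts)
    for a, b in zip(bouts, bouts[1:]):
        if b.start_time < a.end_time:
            raise ValidationError("bouts are not time-ordered/disjoint")
    if not bouts:
        return [], []
    retained = [bouts[0]]
    excluded: list[TorporBout] = []
    for bout in bouts[1:]:
        gap_days = (bout.start_time - retained[-1].end_time) / pd.Timedelta(days=1)
        if gap_days <= max_gap and not excluded:
            retained.append(bout)
        else:
            excluded.append(bout)
    return retained, excluded


def summarize_hibernation(
    animal_id: str,
    retained: Sequence[TorporBout],
    excluded_count: int = 0,
) -> HibernationSummary:
    """Per-animal winter phenology from the retained bouts.

    Hibernation duration is the span from the start of the first bout to the
    end of the last retained bout, in days.  An animal with no bouts did not
    hibernate and gets zero totals and missing start/end dates.
    """
    retained = list(retained)
    if not retained:
        return HibernationSummary(
            animal_id=animal_id,
            n_bouts=0,
            total_torpor=0.0,
            hibernation_start=None,
            hibernation_end=None,
            hibernation_duration=0.0,
            excluded_bouts=excluded_count,
            did_hibernate=False,
        )
    start = retained[0].start_time
    end = retained[-1].end_time
    return HibernationSummary(
        animal_id=animal_id,
        n_bouts=len(retained),
        total_torpor=float(sum(b.duration for b in retained)),
        hibernation_start=start,
        hibernation_end=end,
        hibernation_duration=float((end - start) / pd.Timedelta(days=1)),
        excluded_bouts=excluded_count,
        did_hibernate=True,
    )


def phenology_table(
    summaries: Iterable[HibernationSummary],
    group_of: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate phenology per animal and per diet group (mean ± s.e.m.).

    Returns ``(animals, groups)``.  Start/end dates are averaged on the
    day-number scale and reported back as timestamps; animals that never
    hibernated contribute to counts but not to date or duration means.
    """
    rows = []
    for s in summaries:
        rows.append(
            {
                "animal_id": s.animal_id,
                "group": (group_of or {}).get(s.animal_id),
                "n_bouts": s.n_bouts,
                "total_torpor_h": s.total_torpor,
                "hibernation_start": s.hibernation_start,
                "hibernation_end": s.hibernation_end,
                "hibernation_duration_d": s.hibernation_duration if s.did_hibernate else np.nan,
                "excluded_bouts": s.excluded_bouts,
                "did_hibernate": s.did_hibernate,
            }
        )
    animals = pd.DataFrame(rows)
    if animals.empty:
        return animals, pd.DataFrame()

    epoch = pd.Timestamp("2000-01-01")

    def _date_num(col):
        return (pd.to_datetime(animals[col]) - epoch) / pd.Timedelta(days=1)

    animals["_start_num"] = _date_num("hibernation_start")
    animals["_end_num"] = _date_num("hibernation_end")

    group_rows = []
    for group, sub in animals.groupby("group", dropna=False):
        rec = {"group": group, "n_animals": len(sub), "n_hibernated": int(sub["did_hibernate"].sum())}
        for col, label in [
            ("total_torpor_h", "total_torpor_h"),
            ("n_bouts", "n_bouts"),
            ("hibernation_duration_d", "hibernation_duration_d"),
        ]:
            rec[f"{label}_mean"] = float(np.nanmean(sub[col])) if len(sub) else np.nan
            rec[f"{label}_sem"] = sem(sub[col])
        for col, label in [("_start_num", "start"), ("_end_num", "end")]:
            vals = sub[col].dropna()
            rec[f"{label}_mean"] = (
                epoch + pd.Timedelta(days=float(vals.mean())) if len(vals) else pd.NaT
            )
            rec[f"{label}_sem_d"] = sem(vals)
        group_rows.append(rec)
    animals = animals.drop(columns=["_start_num", "_end_num"])
    return animals, pd.DataFrame(group_rows)
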