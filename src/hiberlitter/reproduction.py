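"""Parturition detection, pup growth models and litter assignment.

Parturition in the common hamster shows up as an abrupt rise (~1 °C) in mean
daily body temperature at the end of gestation.  The detector works on daily
means: a candidate day d is scored by the contrast between the mean of a
post window starting at d and the mean of a pre (baseline) window ending at
d−1; a contrast of at least the jump threshold flags a parturition.  With
pre/post windows of 1 day this reduces to plain previous-day differencing;
the defaults (12 before, 4 after) average out day-level noise so that a 1 °C
step is detected reliably at realistic daily-mean noise; the baseline window
always fits inside the preceding gestation (18 days), so lengthening it
costs nothing in specificity.  Candidates are accepted in decreasing order
of noise-normalized contrast, suppressing any candidate within a refractory
period (18 days, the minimal gestation) of an accepted event, and the
accepted events are numbered sequentially by date (litter 1, 2, ...).

Pups are tied to parturitions through growth: pups captured too early to
belong to any second litter have a known birth date and anchor per
(diet-group, sex) linear mass-vs-age models; the models back-project every
pup's first capture to an inferred birth date, and each pup is assigned to
its mother's nearest parturition date (ties toward the earlier litter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hibernation import sem
from .trace_io import CaptureEvent, TemperatureTrace, ValidationError

__all__ = [
    "DailyMeanSeries",
    "ParturitionEvent",
    "GrowthModel",
    "LitterRecord",
    "PupAssignment",
    "daily_means",
    "detect_parturitions",
    "flag_certain_first_litter",
    "growth_points",
    "fit_growth_models",
    "infer_birth_date",
    "assign_pups",
    "litter_table",
    "season_mass",
    "apply_removal_rule",
]


@dataclass
class DailyMeanSeries:
    """Mean body temperature per calendar date (under-sampled days omitted)."""

    animal_id: str
    dates: list[date]
    mean_temps: np.ndarray

    def __post_init__(self) -> None:
        self.mean_temps = np.asarray(self.mean_temps, dtype=float)
        if len(self.dates) != self.mean_temps.size:
            raise ValidationError("dates and mean_temps length mismatch")


@dataclass(frozen=True)
class ParturitionEvent:
    mother_id: str
    date: date
    litter_number: int
    jump_magnitude: float  # °C


@dataclass(frozen=True)
class GrowthModel:
    """Linear emergence-phase mass-vs-age model for one (diet group, sex) stratum.

    The intercept is the free OLS parameter — mass at age 0 of the linear
    model, a surrogate for emergence mass, not true neonatal mass.
    """

    group: str
    sex: str
    slope: float  # g/day
    intercept: float  # g at age 0
    n_pups: int
    n_points: int
    r_squared: float


@dataclass(frozen=True)
class LitterRecord:
    mother_id: str
    litter_number: int
    parturition_date: date
    n_pups_assigned: int
    successful: bool  # at least one attributed pup


@dataclass(frozen=True)
class PupAssignment:
    pup_id: str
    mother_id: str
    inferred_birth_date: date
    assigned_parturition_date: date
    assigned_litter_number: int
    discrepancy: float  # |inferred − assigned| in days
    certain_first_litter: bool


def daily_means(trace: TemperatureTrace, min_coverage: float = 0.5) -> DailyMeanSeries:
    """Arithmetic mean temperature per calendar date.

    A date is kept only if at least ``min_coverage`` of its scheduled samples
    were actually recorded (non-missing), so sparse logger days cannot fake a
    jump.
    """
    ts = trace.timestamps()
    dates = ts.normalize()
    df = pd.DataFrame({"date": dates, "temp": trace.temperatures})
    grouped = df.groupby("date")["temp"]
    scheduled = grouped.size()
    observed = grouped.count()
    means = grouped.mean()
    keep = observed >= min_coverage * scheduled
    kept = means[keep]
    return DailyMeanSeries(
        animal_id=trace.animal_id,
        dates=[d.date() for d in kept.index],
        mean_temps=kept.to_numpy(),
    )


def detect_parturitions(
    series: DailyMeanSeries,
    jump: float = 1.0,
    refractory: int = 18,
    window: tuple[date, date] | None = None,
    pre_window: int = 12,
    post_window: int = 4,
) -> list[ParturitionEvent]:
    """Detect parturition days from a daily-mean temperature series.

    A day d is a candidate when
    ``mean(temps[d .. d+post_window-1]) − mean(temps[d-pre_window .. d-1]) >= jump``
    with both windows fully covered by recorded days; post windows from 2 to
    ``post_window`` days are all scored.  Candidates are accepted in
    decreasing order of noise-normalized contrast; a candidate within
    ``refractory`` days of an already accepted event is suppressed (two
    births cannot be closer than one gestation).  ``pre_window=post_window=1``
    recovers plain previous-day differencing.  Accepted events are numbered
    by date from 1.
    """
    if len(series.dates) < 2:
        raise ValidationError(
            f"series for {series.animal_id!r} has fewer than 2 days; cannot difference"
        )
    # Re-index onto the full calendar range so missing days break windows.
    full = pd.date_range(series.dates[0], series.dates[-1], freq="D")
    temp = pd.Series(np.nan, index=full)
    temp.loc[pd.DatetimeIndex(series.dates)] = series.mean_temps
    vals = temp.to_numpy()
    n = len(vals)

    # Post windows shorter than post_window are also scored (down to 2 days)
    # so that a birth followed by a short inter-litter gap — where the next
    # gestation begins within days — is not masked by its own successor.
    # Competing windows are ranked by their noise-normalized contrast
    # (contrast / sqrt(1/pre + 1/post)), so a long window's precise estimate
    # outranks a short window's noisier one unless only the short window sees
    # the step; ranking raw contrasts would let 2-day noise bumps mislocalize
    # events by a couple of days.
    post_lengths = list(range(min(2, post_window), post_window + 1))
    candidates: list[tuple[float, float, int]] = []  # (score, contrast, day)
    for i in range(pre_window, n - min(post_lengths) + 1):
        pre = vals[i - pre_window : i]
        if np.isnan(pre).any():
            continue
        best_score, best_contrast = -np.inf, -np.inf
        for length in post_lengths:
            post = vals[i : i + length]
            if post.size < length or np.isnan(post).any():
                continue
            contrast = float(post.mean() - pre.mean())
            if contrast < jump:
                continue
            score = contrast / np.sqrt(1.0 / pre_window + 1.0 / length)
            if score > best_score:
                best_score, best_contrast = score, contrast
        if best_score > -np.inf:
            candidates.append((best_score, best_contrast, i))

    day0 = full[0].date()
    if window is not None:
        lo, hi = window
        candidates = [
            (s, c, i) for s, c, i in candidates if lo <= day0 + timedelta(days=i) <= hi
        ]

    accepted: list[tuple[int, float]] = []
    for _score, contrast, i in sorted(candidates, key=lambda t: (-t[0], t[2])):
        if all(abs(i - j) >= refractory for j, _ in accepted):
            accepted.append((i, contrast))

    accepted.sort()
    return [
        ParturitionEvent(
            mother_id=series.animal_id,
            date=day0 + timedelta(days=i),
            litter_number=k + 1,
            jump_magnitude=contrast,
        )
        for k, (i, contrast) in enumerate(accepted)
    ]


def _first_captures(pups: Sequence[CaptureEvent]) -> dict[str, CaptureEvent]:
    firsts: dict[str, CaptureEvent] = {}
    for ev in sorted(pups, key=lambda e: e.date):
        firsts.setdefault(ev.animal_id, ev)
    return firsts


def flag_certain_first_litter(
    pups: Sequence[CaptureEvent],
    parturitions: Mapping[str, Sequence[ParturitionEvent]],
    emergence_age_min: int = 18,
) -> dict[str, bool]:
    """Flag pups whose first capture is too early for any later litter.

    A pup is certainly from its mother's first litter when the mother has
    only one detected parturition, or when the pup's first capture precedes
    ``second parturition + emergence_age_min`` — a second-litter pup cannot
    have emerged from the burrow before that date.
    """
    flags: dict[str, bool] = {}
    for pup_id, first in _first_captures(pups).items():
        mother = first.mother_id
        if mother is None or mother not in parturitions or not parturitions[mother]:
            raise ValidationError(f"pup {pup_id!r}: mother has no detected parturition")
        events = sorted(parturitions[mother], key=lambda e: e.date)
        if len(events) == 1:
            flags[pup_id] = True
        else:
            flags[pup_id] = first.date < events[1].date + timedelta(days=emergence_age_min)
    return flags


def growth_points(
    captures: Sequence[CaptureEvent],
    birth_dates: Mapping[str, date],
) -> pd.DataFrame:
    """Pooled (age, mass) capture points for pups with known birth dates."""
    rows = []
    for ev in captures:
        if ev.animal_id not in birth_dates:
            continue
        rows.append(
            {
                "pup_id": ev.animal_id,
                "group": ev.group,
                "sex": ev.sex,
                "age_d": (ev.date - birth_dates[ev.animal_id]).days,
                "mass_g": ev.body_mass,
            }
        )
    return pd.DataFrame(rows, columns=["pup_id", "group", "sex", "age_d", "mass_g"])


def _ols_line(age: np.ndarray, mass: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(age, mass, 1)
    pred = intercept + slope * age
    ss_res = float(np.sum((mass - pred) ** 2))
    ss_tot = float(np.sum((mass - mass.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def fit_growth_models(
    points: pd.DataFrame, min_pups: int = 2, trim_sd: float | None = 3.0
) -> dict[tuple[str, str], GrowthModel]:
    """Fit one OLS mass-on-age line per (group, sex), pooling capture points.

    A stratum with fewer than ``min_pups`` pups (or fewer than 2 distinct
    capture points) falls back to the group-level model with sexes pooled; a
    warning is emitted so the fallback is visible.

    When ``trim_sd`` is set (default 3), points whose residual exceeds
    ``trim_sd`` robust standard deviations (1.4826 x MAD) are dropped once
    and the line refit.  This guards the anchor fit against pups whose
    assumed first-litter birth date is wrong (e.g. the mother's true first
    parturition was missed), which shows up as gross mass-vs-age outliers.
    """
    if points.empty:
        raise ValidationError("no growth points supplied")
    models: dict[tuple[str, str], GrowthModel] = {}
    for (group, sex), sub in points.groupby(["group", "sex"]):
        pooled = False
        data = sub
        if sub["pup_id"].nunique() < min_pups or len(sub) < 2:
            data = points[points["group"] == group]
            pooled = True
            warnings.warn(
                f"growth stratum ({group}, {sex}) under-populated "
                f"({sub['pup_id'].nunique()} pup(s)); falling back to group-level model",
                stacklevel=2,
            )
            if data["pup_id"].nunique() < min_pups or len(data) < 2:
                raise ValidationError(f"group {group!r} has too few pups to fit a growth model")
        age = data["age_d"].to_numpy(float)
        mass = data["mass_g"].to_numpy(float)
        if trim_sd is not None and len(data) > 4 and np.ptp(age) > 0:
            # Theil–Sen reference line: robust to the clustered outliers a
            # misdated litter produces, unlike an OLS-initialized trim.
            ts_slope, ts_intercept, *_ = stats.theilslopes(mass, age)
            resid = mass - (ts_intercept + ts_slope * age)
            sd_robust = 1.4826 * np.median(np.abs(resid - np.median(resid)))
            if sd_robust > 0:
                keep = np.abs(resid - np.median(resid)) <= trim_sd * sd_robust
                if keep.sum() >= 3 and not keep.all():
                    data = data[keep]
                    age, mass = age[keep], mass[keep]
        slope, intercept, r2 = _ols_line(age, mass)
        models[(group, sex)] = GrowthModel(
            group=group,
            sex=sex if not pooled else sex,
            slope=slope,
            intercept=intercept,
            n_pups=int(data["pup_id"].nunique()),
            n_points=len(data),
            r_squared=r2,
        )
    return models


def infer_birth_date(capture: CaptureEvent, model: GrowthModel) -> date:
    """Back-project a first capture to a birth date via the growth model.

    ``age = (mass − intercept) / slope`` rounded to the nearest whole day;
    masses below the model intercept clamp to age 0 with a warning.
    """
    if model.slope <= 0:
        raise ValidationError(f"growth model ({model.group}, {model.sex}) has non-positive slope")
    age = (capture.body_mass - model.intercept) / model.slope
    if -1e-9 <= age < 0:
        age = 0.0
    if age < 0:
        warnings.warn(
            f"pup {capture.animal_id!r}: mass {capture.body_mass} g below model intercept "
            f"{model.intercept:.1f} g; clamping age to 0",
            stacklevel=2,
        )
        age = 0.0
    age_days = int(np.floor(age + 0.5))
    return capture.date - timedelta(days=age_days)


def assign_pups(
    inferred: Mapping[str, tuple[str, date]],
    parturitions: Mapping[str, Sequence[ParturitionEvent]],
    certain_flags: Mapping[str, bool] | None = None,
) -> list[PupAssignment]:
    """Assign each pup to its mother's most likely parturition.

    ``inferred`` maps pup_id -> (mother_id, inferred_birth_date).  The most
    likely parturition is the one minimizing |inferred − parturition date|,
    with ties broken toward the earlier litter.  Pups flagged as certain
    first-litter go to litter 1 regardless of back-projection.
    """
    assignments: list[PupAssignment] = []
    for pup_id, (mother, birth) in sorted(inferred.items()):
        events = sorted(parturitions.get(mother, []), key=lambda e: e.date)
        if not events:
            raise ValidationError(f"pup {pup_id!r}: mother {mother!r} has no parturition")
        certain = bool(certain_flags.get(pup_id, False)) if certain_flags else False
        if certain:
            best = events[0]
        else:
            best = min(events, key=lambda e: (abs((birth - e.date).days), e.date))
        assignments.append(
            PupAssignment(
                pup_id=pup_id,
                mother_id=mother,
                inferred_birth_date=birth,
                assigned_parturition_date=best.date,
                assigned_litter_number=best.litter_number,
                discrepancy=float(abs((birth - best.date).days)),
                certain_first_litter=certain,
            )
        )
    return assignments


def litter_table(
    assignments: Sequence[PupAssignment],
    parturitions: Mapping[str, Sequence[ParturitionEvent]],
    pup_sexes: Mapping[str, str] | None = None,
) -> tuple[list[LitterRecord], dict]:
    """Litter records plus derived reproductive metrics.

    Every detected parturition yields a record; parturitions with no
    attributed pup are counted as zero-pup (failed) litters.  Metrics:
    pups per female, successful-litter counts per female, litter sizes by
    litter number, inter-litter intervals, first-parturition dates, and the
    pup sex ratio when sexes are supplied.
    """
    counts: dict[tuple[str, int], int] = {}
    for a in assignments:
        counts[(a.mother_id, a.assigned_litter_number)] = (
            counts.get((a.mother_id, a.assigned_litter_number), 0) + 1
        )

    records: list[LitterRecord] = []
    intervals: list[int] = []
    first_dates: dict[str, date] = {}
    for mother, events in sorted(parturitions.items()):
        events = sorted(events, key=lambda e: e.date)
        if events:
            first_dates[mother] = events[0].date
        for prev, nxt in zip(events, events[1:]):
            intervals.append((nxt.date - prev.date).days)
        for ev in events:
            n = counts.get((mother, ev.litter_number), 0)
            records.append(
                LitterRecord(
                    mother_id=mother,
                    litter_number=ev.litter_number,
                    parturition_date=ev.date,
                    n_pups_assigned=n,
                    successful=n >= 1,
                )
            )

    pups_per_female = {
        mother: sum(r.n_pups_assigned for r in records if r.mother_id == mother)
        for mother in parturitions
    }
    successful_per_female = {
        mother: sum(1 for r in records if r.mother_id == mother and r.successful)
        for mother in parturitions
    }
    size_by_litter_number: dict[int, list[int]] = {}
    for r in records:
        size_by_litter_number.setdefault(r.litter_number, []).append(r.n_pups_assigned)

    metrics = {
        "pups_per_female": pups_per_female,
        "successful_litters_per_female": successful_per_female,
        "litter_sizes_by_number": size_by_litter_number,
        "interlitter_intervals_d": intervals,
        "interlitter_interval_mean_d": float(np.mean(intervals)) if intervals else float("nan"),
        "interlitter_interval_sem_d": sem(intervals),
        "first_parturition_dates": first_dates,
    }
    if pup_sexes is not None:
        assigned_ids = [a.pup_id for a in assignments]
        males = sum(1 for p in assigned_ids if pup_sexes.get(p) == "male")
        females = sum(1 for p in assigned_ids if pup_sexes.get(p) == "female")
        total = males + females
        metrics["sex_ratio_male_pct"] = 100.0 * males / total if total else float("nan")
    return records, metrics


def season_mass(
    captures: Sequence[CaptureEvent],
    window: tuple[date, date],
    group_of: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean adult body mass over a season, per animal then per group ± s.e.m."""
    lo, hi = window
    rows: dict[str, list[float]] = {}
    groups: dict[str, str] = {}
    for ev in captures:
        if lo <= ev.date <= hi:
            rows.setdefault(ev.animal_id, []).append(ev.body_mass)
            if ev.group is not None:
                groups[ev.animal_id] = ev.group
    animals = pd.DataFrame(
        [
            {
                "animal_id": a,
                "group": (group_of or groups).get(a),
                "mean_mass_g": float(np.mean(m)),
                "n_captures": len(m),
            }
            for a, m in sorted(rows.items())
        ]
    )
    if animals.empty:
        return animals, pd.DataFrame()
    group_rows = [
        {
            "group": g,
            "n_animals": len(sub),
            "mass_mean_g": float(sub["mean_mass_g"].mean()),
            "mass_sem_g": sem(sub["mean_mass_g"]),
            "points_per_animal_mean": float(sub["n_captures"].mean()),
        }
        for g, sub in animals.groupby("group", dropna=False)
    ]
    return animals, pd.DataFrame(group_rows)


def apply_removal_rule(
    captures: Sequence[CaptureEvent], cutoff: float = 140.0
) -> tuple[dict[str, date], list[CaptureEvent]]:
    """Censor pups at their first capture strictly heavier than ``cutoff`` g.

    Returns the per-pup censoring date (the removal capture itself is kept)
    and the capture list with post-removal records suppressed.  A capture at
    exactly the cutoff does not trigger removal ("more than" is strict).
    """
    censor: dict[str, date] = {}
    kept: list[CaptureEvent] = []
    by_animal: dict[str, list[CaptureEvent]] = {}
    for ev in sorted(captures, key=lambda e: (e.animal_id, e.date)):
        by_animal.setdefault(ev.animal_id, []).append(ev)
    for animal, events in by_animal.items():
        removed = False
        for ev in events:
            if removed:
                continue
            kept.append(ev)
            if ev.body_mass > cutoff:
                censor[animal] = ev.date
                removed = True
    return censor, kept
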