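"""Synthetic study cohorts with known ground truth.

Emulates the three observable input streams of a mesocosm diet experiment on
a food-storing hibernator — winter body-temperature traces, reproduction
traces, capture–recapture records and feeding logs — under a configurable
ground truth (bout schedules, parturition dates, growth slopes, crop
preference fractions), so that every pipeline stage can be tested for
parameter recovery without any external download.

Phenomenology, not mechanism: euthermic samples are Gaussian around 37 °C,
torpor samples relax to ambient (10 °C) with 1-sample entry/exit ramps;
gestation depresses the daily mean by the parturition jump, producing the
step the detector looks for; pup mass grows linearly with age plus noise.
All temperatures are quantized to the 0.06 °C logger resolution after noise,
so detector tests face realistic discretization.  Identical config + seed
give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hibernation import detect_torpor_bouts
from .trace_io import (
    CaptureEvent,
    CropComposition,
    FeedingRecord,
    Period,
    TemperatureTrace,
)

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "default_crop_table",
    "simulate_winter_trace",
    "simulate_reproduction_trace",
    "simulate_pups",
    "simulate_feeding",
    "simulate_sessions",
    "emit_cohort",
    "config_to_yaml",
    "config_from_yaml",
]

DIET_CROPS: dict[str, tuple[str, ...]] = {
    "W": ("wheat",),
    "WS": ("wheat", "soybean"),
    "RF": ("rapeseed", "fava_bean"),
    "ML": ("maize", "lablab_bean"),
}
FOCAL_CROP: dict[str, str] = {"WS": "soybean", "RF": "rapeseed", "ML": "maize"}


@dataclass
class CohortConfig:
    """Generator configuration; every field is part of the ground truth.

    Defaults mirror the study conditions: 4 diet groups x 8 females, winter
    19 Oct–19 Apr at 10 °C ambient, 135-min logger sampling at 0.06 °C
    resolution, parturition jump 1.2 °C over daily-mean noise sd 0.2 °C,
    inter-litter intervals 30 ± 5 days with an 18-day gestation, and
    hibernation/post-hibernation intakes of 3.45 / 7.60 g/day.
    """

    seed: int = 0
    n_females_per_group: int = 8
    groups: tuple[str, ...] = ("W", "WS", "RF", "ML")
    # calendar
    winter_start: date = date(2021, 10, 19)
    winter_end: date = date(2022, 4, 19)
    active_start: date = date(2022, 4, 19)
    active_end: date = date(2022, 10, 19)
    # logger
    sampling_period_min: float = 135.0
    resolution_c: float = 0.06
    # winter thermal phenomenology
    euthermic_temp_c: float = 37.0
    euthermic_noise_sd_c: float = 0.3
    torpor_temp_c: float = 10.0  # ambient cage temperature
    torpor_noise_sd_c: float = 0.3
    hibernation_onset_mean_d: float = 4.0  # days after winter start
    hibernation_onset_sd_d: float = 1.7
    n_bouts_mean: float = 16.0  # Poisson
    bout_duration_median_d: float = 3.5  # lognormal median
    bout_duration_sigma: float = 0.45
    arousal_duration_mean_h: float = 12.0
    arousal_duration_sd_h: float = 3.0
    # reproduction thermal phenomenology
    repro_baseline_c: float = 36.5
    parturition_jump_c: float = 1.2
    daily_mean_noise_sd_c: float = 0.2
    within_day_noise_sd_c: float = 0.1
    gestation_d: int = 18
    first_parturition_mean: date = date(2022, 5, 24)
    first_parturition_sd_d: float = 4.0
    group_first_delay_d: dict = field(default_factory=lambda: {"ML": 16.0})
    interlitter_mean_d: float = 30.0
    interlitter_sd_d: float = 5.0
    interlitter_min_d: int = 19
    litters_min: int = 1
    litters_max: int = 4
    # litters and pups
    litter_size_first_mean: float = 6.6
    litter_size_later_mean: float = 2.6
    group_size_factor: dict = field(
        default_factory=lambda: {"W": 0.8, "ML": 0.8, "WS": 1.1, "RF": 1.2}
    )
    sex_ratio_male: float = 0.633
    growth_slope_g_d: dict = field(
        default_factory=lambda: {"W": 2.0, "ML": 2.0, "WS": 2.5, "RF": 3.0}
    )
    male_growth_bonus_g_d: float = 0.35
    birth_model_mass_g: float = 10.0  # linear-model mass at age 0
    growth_noise_sd_g: float = 5.0
    emergence_age_d: int = 18
    pup_dispersal_rate: float = 0.1
    # trapping
    capture_prob: float = 0.8
    adult_capture_prob: float = 0.35
    adult_mass_g: dict = field(
        default_factory=lambda: {"W": 263.0, "WS": 297.5, "RF": 297.5, "ML": 297.5}
    )
    adult_mass_sd_g: float = 12.0
    removal_cutoff_g: float = 140.0
    # feeding
    intake_hibernation_g_d: float = 3.45
    intake_posthibernation_g_d: float = 7.60
    intake_animal_sd_g_d: float = 0.6
    intake_interval_sd_g_d: float = 0.6
    preference_mean: dict = field(
        default_factory=lambda: {"WS": 0.65, "ML": 0.65, "RF": 0.5}
    )
    preference_animal_sd: float = 0.02
    preference_interval_sd: float = 0.10

    def validate(self) -> None:
        if self.n_females_per_group < 1:
            raise ValueError("n_females_per_group must be >= 1")
        for name in (
            "hibernation_onset_sd_d", "bout_duration_sigma", "arousal_duration_sd_h",
            "daily_mean_noise_sd_c", "within_day_noise_sd_c", "interlitter_sd_d",
            "growth_noise_sd_g", "euthermic_noise_sd_c", "torpor_noise_sd_c",
            "first_parturition_sd_d", "intake_animal_sd_g_d", "intake_interval_sd_g_d",
            "preference_animal_sd", "preference_interval_sd", "adult_mass_sd_g",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.winter_start < self.winter_end <= self.active_start < self.active_end:
            raise ValueError("study windows must be ordered and non-overlapping")
        if not (0 <= self.litters_min <= self.litters_max):
            raise ValueError("litter count bounds inconsistent")
        unknown = set(self.groups) - set(DIET_CROPS)
        if unknown:
            raise ValueError(f"unknown diet group(s) {sorted(unknown)}")

    def females(self) -> list[tuple[str, str]]:
        """Stable (animal_id, group) roster."""
        return [
            (f"{group}{i + 1:02d}", group)
            for group in self.groups
            for i in range(self.n_females_per_group)
        ]


@dataclass
class GroundTruth:
    """Generating parameters keyed to the emitted observables."""

    bouts: pd.DataFrame  # animal_id, start_time, end_time, duration_h
    hibernation_end: dict[str, date]
    parturitions: pd.DataFrame  # mother_id, date, litter_number
    pups: pd.DataFrame  # pup_id, mother_id, group, sex, birth_date, slope_g_d, dispersed
    growth_slopes: dict[tuple[str, str], float]
    preference: dict[str, float]


def default_crop_table() -> dict[str, CropComposition]:
    """Dry-mass macronutrient fractions and energy densities of the six crops.

    Representative seed compositions (protein, lipid, carbohydrate fractions
    of dry mass; gross energy kJ/g dry mass): oleaginous seeds (soybean,
    rapeseed) are lipid-rich and energy-dense, cereals carbohydrate-rich,
    legume beans protein-intermediate.
    """
    rows = [
        ("wheat", 0.13, 0.02, 0.76, 17.0),
        ("soybean", 0.38, 0.20, 0.29, 20.5),
        ("rapeseed", 0.21, 0.45, 0.22, 26.0),
        ("fava_bean", 0.28, 0.02, 0.60, 16.5),
        ("maize", 0.09, 0.04, 0.78, 16.8),
        ("lablab_bean", 0.24, 0.02, 0.64, 16.3),
    ]
    return {
        name: CropComposition(name, p, l, c, e) for name, p, l, c, e in rows
    }


def _rng(config: CohortConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, *stream]))


def _quantize(temps: np.ndarray, resolution: float) -> np.ndarray:
    return np.round(temps / resolution) * resolution


def _n_samples(start: date, end: date, period_min: float) -> int:
    return int((end - start).days * 1440.0 / period_min)


def simulate_winter_trace(
    config: CohortConfig, animal_index: int
) -> tuple[TemperatureTrace, list]:
    """One female's winter trace plus her true torpor bouts.

    Bout schedule: onset a few days into winter, then alternating lognormal
    torpor bouts and Gaussian arousals until the drawn bout count or the end
    of the window.  Entry/exit transitions each span one sample.  The true
    bouts are computed by scanning the noiseless temperature profile with the
    same maximal-run convention the detector uses, so truth and detection
    share one duration convention.
    """
    animal_id, _ = config.females()[animal_index]
    rng = _rng(config, 1, animal_index)
    period = config.sampling_period_min
    n = _n_samples(config.winter_start, config.winter_end, period)
    level = np.full(n, config.euthermic_temp_c)

    n_bouts = rng.poisson(config.n_bouts_mean)
    t_days = max(0.5, rng.normal(config.hibernation_onset_mean_d, config.hibernation_onset_sd_d))
    mid = 0.5 * (config.euthermic_temp_c + config.torpor_temp_c)
    exit_ramp = 33.0  # supra-threshold recovery sample
    samples_per_day = 1440.0 / period
    for _ in range(n_bouts):
        dur_d = float(
            np.exp(rng.normal(np.log(config.bout_duration_median_d), config.bout_duration_sigma))
        )
        s = int(round(t_days * samples_per_day))
        e = s + max(1, int(round(dur_d * samples_per_day))) - 1
        if e + 2 >= n:
            break
        level[s] = mid
        level[s + 1 : e + 1] = config.torpor_temp_c
        level[e + 1] = exit_ramp
        arousal_h = max(3.0, rng.normal(config.arousal_duration_mean_h, config.arousal_duration_sd_h))
        t_days = (e + 1) / samples_per_day + arousal_h / 24.0

    sd = np.where(level > 30.0, config.euthermic_noise_sd_c, config.torpor_noise_sd_c)
    temps = _quantize(level + rng.normal(0.0, 1.0, n) * sd, config.resolution_c)
    start_time = pd.Timestamp(config.winter_start)
    trace = TemperatureTrace(
        animal_id=animal_id,
        start_time=start_time,
        temperatures=temps,
        sampling_period=period,
        resolution=config.resolution_c,
    )
    truth_trace = TemperatureTrace(
        animal_id=animal_id,
        start_time=start_time,
        temperatures=level,
        sampling_period=period,
        resolution=config.resolution_c,
    )
    true_bouts = detect_torpor_bouts(truth_trace, threshold=30.0, min_duration=24.0)
    return trace, true_bouts


def simulate_reproduction_trace(
    config: CohortConfig, animal_index: int
) -> tuple[TemperatureTrace, list[date]]:
    """One female's reproduction-season trace plus her true parturition dates.

    Gestation segments (``gestation_d`` days before each birth) sit
    ``parturition_jump_c`` below the euthermic baseline; the return to
    baseline on the parturition day is the detectable step.  Day-level noise
    (sd ``daily_mean_noise_sd_c``) is shared by all samples of a day, with
    additional small within-day sample noise.
    """
    animal_id, group = config.females()[animal_index]
    rng = _rng(config, 2, animal_index)
    n_litters = int(rng.integers(config.litters_min, config.litters_max + 1))

    delay = float(config.group_first_delay_d.get(group, 0.0))
    births: list[date] = []
    earliest = config.active_start + timedelta(days=config.gestation_d + 1)
    latest = config.active_end - timedelta(days=10)
    if n_litters >= 1:
        offset = rng.normal(delay, config.first_parturition_sd_d)
        first = config.first_parturition_mean + timedelta(days=int(round(offset)))
        first = min(max(first, earliest), latest)
        births.append(first)
        for _ in range(n_litters - 1):
            gap = max(
                config.interlitter_min_d,
                int(round(rng.normal(config.interlitter_mean_d, config.interlitter_sd_d))),
            )
            nxt = births[-1] + timedelta(days=gap)
            if nxt > latest:
                break
            births.append(nxt)

    period = config.sampling_period_min
    n = _n_samples(config.active_start, config.active_end, period)
    n_days = (config.active_end - config.active_start).days
    day_level = np.full(n_days, config.repro_baseline_c)
    for b in births:
        g0 = (b - config.active_start).days - config.gestation_d
        g1 = (b - config.active_start).days  # exclusive: birth day back at baseline
        day_level[max(0, g0) : max(0, g1)] = config.repro_baseline_c - config.parturition_jump_c
    day_offsets = rng.normal(0.0, config.daily_mean_noise_sd_c, n_days)

    idx = np.arange(n)
    day_of_sample = np.minimum((idx * period / 1440.0).astype(int), n_days - 1)
    temps = (
        day_level[day_of_sample]
        + day_offsets[day_of_sample]
        + rng.normal(0.0, config.within_day_noise_sd_c, n)
    )
    trace = TemperatureTrace(
        animal_id=animal_id,
        start_time=pd.Timestamp(config.active_start),
        temperatures=_quantize(temps, config.resolution_c),
        sampling_period=period,
        resolution=config.resolution_c,
    )
    return trace, births


def simulate_sessions(config: CohortConfig) -> list[date]:
    """Trapping session dates: one or two per week, shared by all enclosures."""
    rng = _rng(config, 3)
    sessions: list[date] = []
    week_start = config.active_start + timedelta(days=14)  # traps open after release settles
    while week_start < config.active_end - timedelta(days=7):
        n_sessions = 2 if rng.random() < 0.5 else 1
        days = sorted(rng.choice(7, size=n_sessions, replace=False).tolist())
        for d in days:
            sessions.append(week_start + timedelta(days=int(d)))
        week_start += timedelta(days=7)
    return sessions


def simulate_pups(
    config: CohortConfig,
    parturitions: dict[str, tuple[str, list[date]]],
    sessions: list[date],
) -> tuple[list[CaptureEvent], pd.DataFrame]:
    """Pup roster and capture records from the true parturitions.

    ``parturitions`` maps mother_id -> (group, birth dates).  Litter sizes
    are Poisson (first litters larger, scaled per diet group, zero-pup
    litters possible).  Pups become trappable at the emergence age, are
    captured with fixed per-session probability, gain mass linearly with
    Gaussian noise, and are removed after their first capture above the
    removal cutoff.  Dispersing pups stop being available two weeks after
    emergence and carry a ``dispersed`` flag in the truth table.
    """
    rng = _rng(config, 4)
    captures: list[CaptureEvent] = []
    truth_rows = []
    for mother_id in sorted(parturitions):
        group, births = parturitions[mother_id]
        for litter_no, birth in enumerate(births, start=1):
            base = (
                config.litter_size_first_mean
                if litter_no == 1
                else config.litter_size_later_mean
            )
            size = int(rng.poisson(base * config.group_size_factor.get(group, 1.0)))
            for k in range(size):
                pup_id = f"{mother_id}-L{litter_no}P{k + 1}"
                male = bool(rng.random() < config.sex_ratio_male)
                sex = "male" if male else "female"
                slope = config.growth_slope_g_d[group] + (
                    config.male_growth_bonus_g_d if male else 0.0
                )
                dispersed = bool(rng.random() < config.pup_dispersal_rate)
                emergence = birth + timedelta(days=config.emergence_age_d)
                last_available = (
                    emergence + timedelta(days=14) if dispersed else config.active_end
                )
                n_caps = 0
                removed = False
                for s in sessions:
                    if s < emergence or s > last_available or removed:
                        continue
                    if rng.random() >= config.capture_prob:
                        continue
                    age = (s - birth).days
                    mass = max(
                        2.0,
                        config.birth_model_mass_g
                        + slope * age
                        + rng.normal(0.0, config.growth_noise_sd_g),
                    )
                    captures.append(
                        CaptureEvent(
                            animal_id=pup_id,
                            date=s,
                            body_mass=round(mass, 1),
                            sex=sex,
                            mother_id=mother_id,
                            group=group,
                        )
                    )
                    n_caps += 1
                    if mass > config.removal_cutoff_g:
                        removed = True
                truth_rows.append(
                    {
                        "pup_id": pup_id,
                        "mother_id": mother_id,
                        "group": group,
                        "sex": sex,
                        "birth_date": birth,
                        "litter_number": litter_no,
                        "slope_g_d": slope,
                        "dispersed": dispersed,
                        "n_captures": n_caps,
                    }
                )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "pup_id", "mother_id", "group", "sex", "birth_date",
            "litter_number", "slope_g_d", "dispersed", "n_captures",
        ],
    )
    return captures, truth


def simulate_adult_captures(
    config: CohortConfig, sessions: list[date]
) -> list[CaptureEvent]:
    """Season capture-and-weigh records for the adult females."""
    rng = _rng(config, 5)
    captures = []
    for idx, (animal_id, group) in enumerate(config.females()):
        for s in sessions:
            if rng.random() < config.adult_capture_prob:
                mass = rng.normal(config.adult_mass_g[group], config.adult_mass_sd_g)
                captures.append(
                    CaptureEvent(
                        animal_id=animal_id,
                        date=s,
                        body_mass=round(float(np.clip(mass, 120.0, 650.0)), 1),
                        sex="female",
                        mother_id=None,
                        group=group,
                    )
                )
    return captures


def simulate_feeding(
    config: CohortConfig,
    animal_index: int,
    hibernation_end: date,
) -> tuple[list[FeedingRecord], float | None]:
    """Weekly feeding records for one female; returns her true mean preference.

    Per-interval daily intake is the period mean (hibernation vs
    post-hibernation, split at the animal's own hibernation end) plus an
    animal-level and an interval-level Gaussian perturbation, truncated at
    zero.  Two-crop diets split each interval's mass by a noisy preference
    fraction around the group's configured mean.
    """
    animal_id, group = config.females()[animal_index]
    rng = _rng(config, 6, animal_index)
    crops = DIET_CROPS[group]
    pref_mean = config.preference_mean.get(group)
    animal_intake_shift = rng.normal(0.0, config.intake_animal_sd_g_d)
    animal_pref = (
        None
        if pref_mean is None or len(crops) == 1
        else float(np.clip(rng.normal(pref_mean, config.preference_animal_sd), 0.05, 0.95))
    )

    records: list[FeedingRecord] = []
    start = config.winter_start
    fracs = []
    while start < config.winter_end:
        end = min(start + timedelta(days=7), config.winter_end)
        midpoint = start + (end - start) / 2
        in_hib = midpoint < hibernation_end
        base = (
            config.intake_hibernation_g_d if in_hib else config.intake_posthibernation_g_d
        )
        daily = max(
            0.0, base + animal_intake_shift + rng.normal(0.0, config.intake_interval_sd_g_d)
        )
        total = daily * (end - start).days
        if animal_pref is None:
            split = {crops[0]: total}
        else:
            frac = float(np.clip(rng.normal(animal_pref, config.preference_interval_sd), 0.0, 1.0))
            fracs.append(frac)
            focal = FOCAL_CROP[group]
            other = next(c for c in crops if c != focal)
            split = {focal: total * frac, other: total * (1.0 - frac)}
        for crop, mass in split.items():
            records.append(
                FeedingRecord(
                    animal_id=animal_id,
                    interval_start=start,
                    interval_end=end,
                    crop=crop,
                    consumed_mass=round(mass, 3),
                )
            )
        start = end
    return records, (float(np.mean(fracs)) if fracs else None)


def _trace_rows(trace: TemperatureTrace) -> pd.DataFrame:
    ts = trace.timestamps()
    mask = np.isfinite(trace.temperatures)
    return pd.DataFrame(
        {
            "animal_id": trace.animal_id,
            "timestamp": ts[mask].strftime("%Y-%m-%dT%H:%M:%S"),
            "temp_c": np.round(trace.temperatures[mask], 4),
        }
    )


def emit_cohort(config: CohortConfig, out_dir) -> tuple[dict[str, Path], GroundTruth]:
    """Generate the full cohort and write every observable stream to CSV.

    Emits ``traces_winter.csv``, ``traces_reproduction.csv``,
    ``captures.csv`` (adults and pups), ``feeding.csv``, ``crops.csv``,
    ``periods.csv`` and keyed truth tables (``truth_*.csv``).  All files pass
    trace_io validation; identical config + seed reproduce the files
    byte-for-byte.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    females = config.females()

    winter_frames, bout_rows, hib_end = [], [], {}
    for idx, (animal_id, _group) in enumerate(females):
        trace, true_bouts = simulate_winter_trace(config, idx)
        winter_frames.append(_trace_rows(trace))
        for b in true_bouts:
            bout_rows.append(
                {
                    "animal_id": animal_id,
                    "start_time": b.start_time,
                    "end_time": b.end_time,
                    "duration_h": b.duration,
                }
            )
        if true_bouts:
            hib_end[animal_id] = true_bouts[-1].end_time.date()
        else:
            hib_end[animal_id] = config.winter_start + timedelta(
                days=int(0.8 * (config.winter_end - config.winter_start).days)
            )

    repro_frames, part_rows = [], []
    parturitions: dict[str, tuple[str, list[date]]] = {}
    for idx, (animal_id, group) in enumerate(females):
        trace, births = simulate_reproduction_trace(config, idx)
        repro_frames.append(_trace_rows(trace))
        parturitions[animal_id] = (group, births)
        for j, b in enumerate(births, start=1):
            part_rows.append({"mother_id": animal_id, "date": b, "litter_number": j})

    sessions = simulate_sessions(config)
    pup_captures, pup_truth = simulate_pups(config, parturitions, sessions)
    adult_captures = simulate_adult_captures(config, sessions)

    feeding_records, pref_rows = [], []
    for idx, (animal_id, group) in enumerate(females):
        recs, pref = simulate_feeding(config, idx, hib_end[animal_id])
        feeding_records.extend(recs)
        if pref is not None:
            pref_rows.append({"animal_id": animal_id, "group": group, "preference": pref})

    crops = default_crop_table()
    periods = []
    for animal_id, _group in females:
        periods.append(Period(animal_id, "hibernation", config.winter_start, hib_end[animal_id]))
        periods.append(Period(animal_id, "post_hibernation", hib_end[animal_id], config.winter_end))

    paths = {
        "traces_winter": out_dir / "traces_winter.csv",
        "traces_reproduction": out_dir / "traces_reproduction.csv",
        "captures": out_dir / "captures.csv",
        "feeding": out_dir / "feeding.csv",
        "crops": out_dir / "crops.csv",
        "periods": out_dir / "periods.csv",
        "truth_bouts": out_dir / "truth_bouts.csv",
        "truth_parturitions": out_dir / "truth_parturitions.csv",
        "truth_pups": out_dir / "truth_pups.csv",
        "truth_preference": out_dir / "truth_preference.csv",
    }
    pd.concat(winter_frames, ignore_index=True).to_csv(paths["traces_winter"], index=False)
    pd.concat(repro_frames, ignore_index=True).to_csv(paths["traces_reproduction"], index=False)

    cap_rows = pd.DataFrame(
        [
            {
                "animal_id": c.animal_id,
                "date": c.date.isoformat(),
                "mass_g": c.body_mass,
                "sex": c.sex,
                "mother_id": c.mother_id if c.mother_id is not None else "unknown",
                "group": c.group,
            }
            for c in adult_captures + pup_captures
        ],
        columns=["animal_id", "date", "mass_g", "sex", "mother_id", "group"],
    )
    cap_rows.to_csv(paths["captures"], index=False)

    pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "interval_start": r.interval_start.isoformat(),
                "interval_end": r.interval_end.isoformat(),
                "crop": r.crop,
                "consumed_g": r.consumed_mass,
            }
            for r in feeding_records
        ]
    ).to_csv(paths["feeding"], index=False)

    pd.DataFrame(
        [
            {
                "crop": c.crop,
                "protein_frac": c.protein_frac,
                "lipid_frac": c.lipid_frac,
                "carb_frac": c.carbohydrate_frac,
                "energy_kj_per_g": c.energy_density,
            }
            for c in crops.values()
        ]
    ).to_csv(paths["crops"], index=False)

    pd.DataFrame(
        [
            {
                "animal_id": p.animal_id,
                "period": p.name,
                "start": p.start.isoformat(),
                "end": p.end.isoformat(),
            }
            for p in periods
        ]
    ).to_csv(paths["periods"], index=False)

    bouts_df = pd.DataFrame(
        bout_rows, columns=["animal_id", "start_time", "end_time", "duration_h"]
    )
    bouts_df.to_csv(paths["truth_bouts"], index=False)
    part_df = pd.DataFrame(part_rows, columns=["mother_id", "date", "litter_number"])
    part_df.to_csv(paths["truth_parturitions"], index=False)
    pup_truth.to_csv(paths["truth_pups"], index=False)
    pref_df = pd.DataFrame(pref_rows, columns=["animal_id", "group", "preference"])
    pref_df.to_csv(paths["truth_preference"], index=False)

    slopes = {
        (group, sex): config.growth_slope_g_d[group]
        + (config.male_growth_bonus_g_d if sex == "male" else 0.0)
        for group in config.groups
        for sex in ("female", "male")
    }
    truth = GroundTruth(
        bouts=bouts_df,
        hibernation_end=hib_end,
        parturitions=part_df,
        pups=pup_truth,
        growth_slopes=slopes,
        preference={g: m for g, m in config.preference_mean.items()},
    )
    return paths, truth


def config_to_yaml(config: CohortConfig, path) -> None:
    d = dataclasses.asdict(config)
    for key, val in d.items():
        if isinstance(val, date):
            d[key] = val.isoformat()
        elif isinstance(val, tuple):
            d[key] = list(val)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def config_from_yaml(path) -> CohortConfig:
    d = yaml.safe_load(Path(path).read_text())
    fields = {f.name: f for f in dataclasses.fields(CohortConfig)}
    kwargs = {}
    for key, val in d.items():
        if key not in fields:
            raise ValueError(f"unknown config key {key!r}")
        if fields[key].type == "date" or key in (
            "winter_start", "winter_end", "active_start", "active_end", "first_parturition_mean",
        ):
            val = date.fromisoformat(val)
        elif key == "groups":
            val = tuple(val)
        kwargs[key] = val
    config = CohortConfig(**kwargs)
    config.validate()
    return config
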