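"""Daily food, energy and macronutrient intake accounting.

Feeding logs record the net mass of each crop consumed per weighing interval
(the upstream offered − refused − hoard-change correction is the caller's
responsibility).  Intakes are expressed per calendar day within named
per-animal periods (hibernation vs post-hibernation); intervals straddling a
period boundary are apportioned pro-rata by days.  All quantities are on a
dry-mass basis — moisture corrections belong in the crop composition table.

For two-crop diets the preference fraction is the focal crop's share of
total intake; a one-sample Wilcoxon signed-rank test against 0.5 asks
whether animals prefer one crop over the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .trace_io import CropComposition, FeedingRecord, Period, ValidationError

__all__ = [
    "IntakeSummary",
    "PreferenceTestResult",
    "compute_intake",
    "preference_fraction",
    "preference_test",
]


@dataclass
class IntakeSummary:
    """Per-animal, per-period daily intake (g/day, kJ/day)."""

    animal_id: str
    period: str
    food_intake: float  # g/day, total dry mass
    energy_intake: float  # kJ/day
    protein_intake: float  # g/day
    lipid_intake: float  # g/day
    carbohydrate_intake: float  # g/day
    per_crop: dict[str, float] = field(default_factory=dict)  # g/day by crop


class PreferenceTestResult(NamedTuple):
    statistic: float
    p_value: float
    direction: str  # "above", "below" or "none"
    n: int


def compute_intake(
    records: Sequence[FeedingRecord],
    comps: Mapping[str, CropComposition],
    periods: Sequence[Period],
) -> list[IntakeSummary]:
    """Fold feeding intervals into per-animal, per-period daily intakes.

    Each interval contributes ``consumed_mass * overlap_days / interval_days``
    to every period it overlaps.  Energy and macronutrients are linear images
    of the per-crop intakes through the composition table.

    Raises
    ------
    ValidationError
        If a crop lacks a composition or a period spans zero days.
    """
    missing = sorted({r.crop for r in records} - set(comps))
    if missing:
        raise ValidationError(f"crop(s) without composition: {missing}")

    by_animal: dict[str, list[FeedingRecord]] = {}
    for rec in records:
        by_animal.setdefault(rec.animal_id, []).append(rec)

    summaries: list[IntakeSummary] = []
    for period in periods:
        if period.days <= 0:  # Period.__post_init__ already forbids this; belt and braces
            raise ValidationError(
                f"period {period.name!r} of {period.animal_id!r} spans zero days"
            )
        per_crop_mass: dict[str, float] = {}
        for rec in by_animal.get(period.animal_id, []):
            overlap = (
                min(rec.interval_end, period.end) - max(rec.interval_start, period.start)
            ).days
            if overlap <= 0:
                continue
            interval_days = (rec.interval_end - rec.interval_start).days
            share = rec.consumed_mass * overlap / interval_days
            per_crop_mass[rec.crop] = per_crop_mass.get(rec.crop, 0.0) + share

        per_crop = {crop: mass / period.days for crop, mass in per_crop_mass.items()}
        food = sum(per_crop.values())
        energy = sum(g * comps[c].energy_density for c, g in per_crop.items())
        protein = sum(g * comps[c].protein_frac for c, g in per_crop.items())
        lipid = sum(g * comps[c].lipid_frac for c, g in per_crop.items())
        carb = sum(g * comps[c].carbohydrate_frac for c, g in per_crop.items())
        summaries.append(
            IntakeSummary(
                animal_id=period.animal_id,
                period=period.name,
                food_intake=food,
                energy_intake=energy,
                protein_intake=protein,
                lipid_intake=lipid,
                carbohydrate_intake=carb,
                per_crop=per_crop,
            )
        )
    return summaries


def preference_fraction(summary: IntakeSummary, focal_crop: str) -> float:
    """Share of the focal crop in a two-crop diet's total intake.

    Raises
    ------
    ValidationError
        For non-two-crop diets (e.g. the wheat monoculture) or zero total
        intake, where the fraction is undefined.
    """
    crops = sorted(summary.per_crop)
    if len(crops) != 2:
        raise ValidationError(
            f"preference undefined for {summary.animal_id!r} ({summary.period}): "
            f"diet has {len(crops)} crop(s) {crops}, need exactly 2"
        )
    if focal_crop not in summary.per_crop:
        raise ValidationError(
            f"focal crop {focal_crop!r} not in diet {crops} of {summary.animal_id!r}"
        )
    total = sum(summary.per_crop.values())
    if total <= 0:
        raise ValidationError(
            f"preference undefined for {summary.animal_id!r} ({summary.period}): zero total intake"
        )
    return summary.per_crop[focal_crop] / total


def preference_test(fractions: Sequence[float], null: float = 0.5) -> PreferenceTestResult:
    """Two-sided one-sample signed-rank test of preference fractions vs ``null``.

    Exact null distribution is used where scipy supports it (no ties in
    |differences|, small n).  Fractions exactly at the null carry no
    information; if every animal sits at the null the test degenerates to
    p = 1 (no rejection possible).
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size < 2:
        raise ValidationError("preference_test requires at least 2 animals")
    diffs = fractions - null
    if np.all(diffs == 0):
        return PreferenceTestResult(statistic=0.0, p_value=1.0, direction="none", n=0)
    res = stats.wilcoxon(diffs, alternative="two-sided")
    mean_frac = float(fractions.mean())
    direction = "above" if mean_frac > null else ("below" if mean_frac < null else "none")
    return PreferenceTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction=direction,
        n=int(np.count_nonzero(diffs)),
    )
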