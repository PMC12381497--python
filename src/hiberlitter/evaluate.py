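"""Recovery metrics: compare pipeline output against synthetic ground truth."""

from __future__ import annotations

from datetime import date
from typing import Mapping, Sequence

__all__ = [
    "match_events",
    "recall_precision",
    "assignment_accuracy",
    "slope_errors",
]


def match_events(
    true_dates: Sequence[date],
    detected_dates: Sequence[date],
    tolerance_days: int = 2,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to true event dates.

    Pairs are matched closest-first within ``tolerance_days``.  Returns
    (true positives, false positives, false negatives); a second detection
    of an already-matched truth counts as a false positive.
    """
    pairs = sorted(
        (abs((d - t).days), i, j)
        for i, t in enumerate(true_dates)
        for j, d in enumerate(detected_dates)
        if abs((d - t).days) <= tolerance_days
    )
    used_t: set[int] = set()
    used_d: set[int] = set()
    tp = 0
    for _dist, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        tp += 1
    return tp, len(detected_dates) - tp, len(true_dates) - tp


def recall_precision(tp: int, fp: int, fn: int) -> tuple[float, float]:
    recall = tp / (tp + fn) if tp + fn else float("nan")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    return recall, precision


def assignment_accuracy(
    assigned_dates: Mapping[str, date],
    true_dates: Mapping[str, date],
    tolerance_days: int = 2,
) -> float:
    """Fraction of pups whose assigned parturition matches their true birth.

    An assignment is correct when the assigned parturition date falls within
    ``tolerance_days`` of the pup's true birth date (the detected parturition
    may itself sit a day or two off the true date).
    """
    common = set(assigned_dates) & set(true_dates)
    if not common:
        return float("nan")
    hits = sum(
        1 for p in common if abs((assigned_dates[p] - true_dates[p]).days) <= tolerance_days
    )
    return hits / len(common)


def slope_errors(
    fitted: Mapping[tuple[str, str], float],
    truth: Mapping[tuple[str, str], float],
) -> dict[tuple[str, str], float]:
    """Relative slope error per stratum: (fitted − true) / true."""
    return {
        key: (fitted[key] - truth[key]) / truth[key]
        for key in fitted
        if key in truth and truth[key] != 0
    }
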