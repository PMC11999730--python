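"""Adherence percentage scoring and barrier-resolution scoring.

The primary adherence measure is the percentage of waking hours that
compression stockings are worn, computed from self-reported wear times:

    pct = (hours worn / hours awake) x (days per week / 7) x 100

calculated per leg and averaged when both legs are reported, clamped to
[0, 100].  Self-reports sometimes arrive as ranges; scalar resolution is
deliberately conservative by default (worn hours -> lower bound, awake
hours -> upper bound, days -> lower bound), and the full [min%, max%]
interval is available for sensitivity auditing.  A midpoint mode is
provided as the alternative resolution.

The percentage maps onto a four-level scale mirroring the VCSS compression
item (modified Q10): <=10% -> 0, 11-50% -> 1, 51-90% -> 2, >=91% -> 3 after
rounding half-up to a whole percent.  The clinician-assigned unmodified Q10
(0 None, 1 Intermittent, 2 Most Days, 3 Fully Comply) is an input carried
through, never derived.

Barrier resolution: each identified barrier earns 1-4 points from its
addressed/resolved flags; a participant's Mean Barrier Resolution Score is
the arithmetic mean over their barriers (adjusting for participants with
fewer than three barriers).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

from .types import BarrierOutcome, Interval, WearTimeReport

__all__ = [
    "AdherenceScore",
    "ResolutionSummary",
    "RESOLUTION_CATEGORIES",
    "adherence_percentage",
    "adherence_percentage_interval",
    "modified_q10",
    "resolution_points",
    "mean_barrier_resolution",
    "summarize_resolution",
]

Mode = Literal["conservative", "midpoint"]

#: Category order used throughout summaries (matches the 4..1 point order
#: reversed: index by (addressed, resolved)).
RESOLUTION_CATEGORIES = (
    "addressed_resolved",
    "addressed_unresolved",
    "unaddressed_unresolved",
    "unaddressed_resolved",
)


@dataclass(frozen=True)
class AdherenceScore:
    """Adherence at one timepoint: the percentage, its banded category, and
    the clinician-assigned unmodified category carried alongside."""

    percentage: float
    modified_q10: int
    unmodified_q10: Optional[int] = None

    def __post_init__(self):
        if not 0 <= self.percentage <= 100:
            raise ValueError(f"percentage {self.percentage} outside [0, 100]")
        if self.modified_q10 not in (0, 1, 2, 3):
            raise ValueError(f"modified_q10 {self.modified_q10} outside 0-3")
        if self.unmodified_q10 is not None and self.unmodified_q10 not in (0, 1, 2, 3):
            raise ValueError(f"unmodified_q10 {self.unmodified_q10} outside 0-3")


class UndefinedRatioError(ZeroDivisionError):
    """Awake hours resolved to zero while worn hours are positive."""


def _resolve(worn: Interval, awake: Interval, days: Interval, mode: Mode) -> tuple[float, float, float]:
    if mode == "conservative":
        # worn -> lower bound, awake -> upper bound, days -> lower bound:
        # consistent bias direction (never overstates adherence)
        return worn.lo, awake.hi, days.lo
    if mode == "midpoint":
        return worn.midpoint, awake.midpoint, days.lo
    raise ValueError(f"unknown interval-resolution mode {mode!r}")


def _leg_pct(worn_h: float, awake_h: float, days: float) -> float:
    if awake_h == 0:
        if worn_h == 0:
            return 0.0
        raise UndefinedRatioError(
            f"awake hours resolved to 0 with worn hours {worn_h} > 0"
        )
    if worn_h > awake_h:
        warnings.warn(
            f"worn hours {worn_h} exceed awake hours {awake_h}; clamping to awake hours",
            stacklevel=3,
        )
        worn_h = awake_h
    pct = (worn_h / awake_h) * (days / 7.0) * 100.0
    return min(max(pct, 0.0), 100.0)


def adherence_percentage(report: WearTimeReport, mode: Mode = "conservative") -> float:
    """Percentage of waking hours stockings were worn, in [0, 100].

    Per-leg percentages are averaged when both legs are reported. Ranges
    resolve per ``mode``; days always resolve to the lowest reported value.
    """
    worn_legs = [iv for iv in (report.hours_worn_left, report.hours_worn_right) if iv is not None]
    pcts = []
    for worn in worn_legs:
        w, a, d = _resolve(worn, report.hours_awake, report.days_per_week, mode)
        pcts.append(_leg_pct(w, a, d))
    return sum(pcts) / len(pcts)


def adherence_percentage_interval(report: WearTimeReport) -> tuple[float, float]:
    """[min%, max%] over all admissible scalar resolutions of the reported
    ranges — the audit interval for rule-orientation sensitivity."""
    worn_legs = [iv for iv in (report.hours_worn_left, report.hours_worn_right) if iv is not None]
    awake, days = report.hours_awake, report.days_per_week

    def bound(worn_h: float, awake_h: float, d: float) -> float:
        if awake_h == 0:
            return 100.0 if worn_h > 0 else 0.0
        worn_h = min(worn_h, awake_h)
        return min(max((worn_h / awake_h) * (d / 7.0) * 100.0, 0.0), 100.0)

    lo = sum(bound(w.lo, awake.hi, days.lo) for w in worn_legs) / len(worn_legs)
    hi = sum(bound(w.hi, awake.lo, days.hi) for w in worn_legs) / len(worn_legs)
    return lo, hi


def modified_q10(percentage: float) -> int:
    """Band an adherence percentage onto the modified 4-level scale.

    Rounds half-up to a whole percent first; 0% falls in category 0
    (the printed band starts at 1%, but the function is total on [0, 100]).
    """
    if not 0 <= percentage <= 100:
        raise ValueError(f"percentage {percentage} outside [0, 100]")
    pct = math.floor(percentage + 0.5)
    if pct <= 10:
        return 0
    if pct <= 50:
        return 1
    if pct <= 90:
        return 2
    return 3


def resolution_points(outcome: BarrierOutcome) -> int:
    """1 not addressed/not resolved, 2 not addressed/resolved,
    3 addressed/not resolved (an attempt was made), 4 addressed/resolved."""
    return {
        (False, False): 1,
        (False, True): 2,
        (True, False): 3,
        (True, True): 4,
    }[(outcome.addressed, outcome.resolved)]


def mean_barrier_resolution(outcomes: Iterable[BarrierOutcome]) -> float:
    """Mean Barrier Resolution Score: arithmetic mean of per-barrier points,
    reported to 2 decimals."""
    points = [resolution_points(o) for o in outcomes]
    if not points:
        raise ValueError("cannot score a participant with no barrier outcomes")
    return round(sum(points) / len(points), 2)


@dataclass(frozen=True)
class ResolutionSummary:
    """Pooled addressed/resolved category counts for a group of participants."""

    counts: dict[str, int]
    percentages: dict[str, float]
    total_barriers: int
    percentages_defined: bool = True

    def points_total(self) -> int:
        """Pooled resolution points implied by the category counts."""
        weights = {
            "addressed_resolved": 4,
            "addressed_unresolved": 3,
            "unaddressed_resolved": 2,
            "unaddressed_unresolved": 1,
        }
        return sum(weights[c] * n for c, n in self.counts.items())


def summarize_resolution(group: Iterable[Iterable[BarrierOutcome]]) -> ResolutionSummary:
    """Pool barrier outcomes across a group of participants.

    Percentages are 100 x count / total to 2 decimals; a zero-barrier group
    gets zero counts with ``percentages_defined=False``.
    """
    counts = {c: 0 for c in RESOLUTION_CATEGORIES}
    for participant_outcomes in group:
        for o in participant_outcomes:
            key = (
                "addressed_" if o.addressed else "unaddressed_"
            ) + ("resolved" if o.resolved else "unresolved")
            counts[key] += 1
    total = sum(counts.values())
    if total == 0:
        return ResolutionSummary(
            counts=counts,
            percentages={c: float("nan") for c in RESOLUTION_CATEGORIES},
            total_barriers=0,
            percentages_defined=False,
        )
    percentages = {c: round(100.0 * n / total, 2) for c, n in counts.items()}
    return ResolutionSummary(counts=counts, percentages=percentages, total_barriers=total)
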