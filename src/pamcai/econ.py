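"""Within-trial cost-utility analysis from the health-service perspective.

Per-participant costs are assembled from appointment counts at fixed unit
prices plus materials (stockings, applicators, postage). QALYs come from
the EQ-5D-5L utility trajectory over a 1-year horizon: linear (trapezoid)
interpolation from baseline to the 6-month measurement, then the 6-month
value extrapolated to 12 months — by default carried forward flat
(``locf``); a linear-trend continuation is available as an option.

The incremental QALY is baseline-adjusted: the arm coefficient of an OLS
fit of participant QALY on arm + baseline utility, since the arms were
imbalanced in baseline utility. ICER = delta cost / adjusted delta QALY,
classified into the cost-effectiveness plane quadrants and compared with a
willingness-to-pay threshold (default AUD 28,033 per QALY).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np

from .stats import adjusted_group_effect
from .types import (
    UTILITY_CEILING,
    UTILITY_FLOOR,
    Arm,
    ParticipantRecord,
    PriceTable,
    ResourceUse,
)

__all__ = [
    "CostBreakdown",
    "CUAResult",
    "Dominance",
    "DEFAULT_WTP",
    "cost_participant",
    "qaly_auc",
    "compute_icer",
    "cost_utility_analysis",
]

#: Reference Australian willingness-to-pay threshold, AUD per QALY.
DEFAULT_WTP = 28033.0

Extrapolation = Literal["locf", "linear"]


class MaterialPriceError(KeyError):
    """A material has no unit cost and no catalogue entry."""


class Dominance(str, enum.Enum):
    dominant = "dominant"  # cheaper and more effective
    dominated = "dominated"  # dearer and less effective
    tradeoff_ne = "tradeoff_ne"  # dearer and more effective: ICER vs WTP decides
    tradeoff_sw = "tradeoff_sw"  # cheaper and less effective


@dataclass(frozen=True)
class CostBreakdown:
    appointment_cost: float
    materials_cost: float
    specialist_cost: float
    admission_cost: float

    @property
    def total(self) -> float:
        return self.appointment_cost + self.materials_cost + self.specialist_cost + self.admission_cost


@dataclass(frozen=True)
class CUAResult:
    mean_cost_per_arm: dict[str, float]
    delta_cost: float  # intervention minus usual care
    qaly_per_arm: dict[str, float]
    delta_qaly_unadjusted: float
    delta_qaly_adjusted: float
    icer: Optional[float]
    dominance: Dominance
    wtp_threshold: float
    cost_effective: bool
    n_per_arm: dict[str, int] = field(default_factory=dict)
    notes: tuple[str, ...] = ()


def cost_participant(use: ResourceUse, prices: PriceTable) -> CostBreakdown:
    """Cost one participant's resource use at the given unit prices.

    Materials with an explicit unit cost use it; bare labels are priced
    from the catalogue (a missing entry is a configuration error).
    """
    appointment = use.n_f2f_appointments * prices.f2f_cost + use.n_phone_appointments * prices.phone_cost
    materials = 0.0
    for label, unit_cost in use.materials:
        if unit_cost is not None:
            materials += unit_cost
        elif label in prices.material_catalogue:
            materials += prices.material_catalogue[label]
        else:
            raise MaterialPriceError(
                f"material {label!r} has no unit cost and is absent from the catalogue"
            )
    return CostBreakdown(
        appointment_cost=appointment,
        materials_cost=materials,
        specialist_cost=use.n_specialist_vlu_appointments * prices.specialist_cost,
        admission_cost=use.n_vlu_admissions * prices.admission_cost,
    )


def qaly_auc(
    u_baseline: float,
    u_6mo: Optional[float],
    horizon_years: float = 1.0,
    extrapolation: Extrapolation = "locf",
) -> float:
    """Area under the utility-time curve over the horizon (years).

    Trapezoid from baseline to 6 months, then extrapolation of the 6-month
    value over the remaining horizon: ``locf`` holds it flat; ``linear``
    continues the baseline->6-month trend (clamped to the utility bounds).
    A missing 6-month utility carries the baseline forward (flagged by the
    caller).
    """
    if u_baseline is None:
        raise ValueError("baseline utility is required")
    for name, u in (("baseline", u_baseline), ("6-month", u_6mo)):
        if u is not None and not UTILITY_FLOOR <= u <= UTILITY_CEILING:
            raise ValueError(f"{name} utility {u} outside [{UTILITY_FLOOR}, {UTILITY_CEILING}]")
    if u_6mo is None:
        return u_baseline * horizon_years
    first = 0.5 * (u_baseline + u_6mo) / 2.0
    tail_years = horizon_years - 0.5
    if extrapolation == "locf":
        tail = u_6mo * tail_years
    elif extrapolation == "linear":
        # continue the 6-month slope over the tail, clamped to valid utilities
        u_end = u_6mo + (u_6mo - u_baseline) * (tail_years / 0.5)
        u_end = min(max(u_end, UTILITY_FLOOR), UTILITY_CEILING)
        tail = (u_6mo + u_end) / 2.0 * tail_years
    else:
        raise ValueError(f"unknown extrapolation {extrapolation!r}")
    return first + tail


def compute_icer(delta_cost: float, delta_qaly: float) -> float:
    """Incremental cost-effectiveness ratio, AUD per QALY gained."""
    if delta_qaly == 0:
        raise ZeroDivisionError("ICER undefined: incremental QALY is zero")
    return delta_cost / delta_qaly


def _classify(delta_cost: float, delta_qaly: float) -> Dominance:
    if delta_cost <= 0 and delta_qaly >= 0:
        return Dominance.dominant
    if delta_cost > 0 and delta_qaly < 0:
        return Dominance.dominated
    if delta_cost > 0:
        return Dominance.tradeoff_ne
    return Dominance.tradeoff_sw


def cost_utility_analysis(
    cohort: Iterable[ParticipantRecord],
    prices: Optional[PriceTable] = None,
    wtp: float = DEFAULT_WTP,
    extrapolation: Extrapolation = "locf",
) -> CUAResult:
    """Run the within-trial CUA on a cohort.

    Participants without a baseline utility are excluded (flagged in
    ``notes``); a missing follow-up utility carries baseline forward.
    Currency figures are reported to 2 decimals; internal arithmetic keeps
    full precision.
    """
    prices = prices or PriceTable()
    cohort = list(cohort)
    notes: list[str] = []

    costs: dict[Arm, list[float]] = {a: [] for a in Arm}
    qalys: dict[Arm, list[float]] = {a: [] for a in Arm}
    qaly_rows: list[tuple[float, int, float]] = []  # (qaly, arm indicator, baseline utility)

    for rec in cohort:
        costs[rec.arm].append(cost_participant(rec.resource_use, prices).total)
        u0 = rec.baseline.eq5d_utility
        if u0 is None:
            notes.append(f"{rec.participant_id}: no baseline utility; excluded from QALY analysis")
            continue
        u6 = rec.followup.eq5d_utility if rec.followup is not None else None
        if u6 is None:
            notes.append(f"{rec.participant_id}: missing 6-month utility; baseline carried forward")
        q = qaly_auc(u0, u6, extrapolation=extrapolation)
        qalys[rec.arm].append(q)
        qaly_rows.append((q, 1 if rec.arm is Arm.intervention else 0, u0))

    for arm in Arm:
        if not costs[arm]:
            raise ValueError(f"no participants in arm {arm.value}")
        if len(qalys[arm]) < 2:
            raise ValueError(f"need >= 2 participants with baseline utility in arm {arm.value}")

    mean_cost = {a.value: float(np.mean(costs[a])) for a in Arm}
    mean_qaly = {a.value: float(np.mean(qalys[a])) for a in Arm}
    delta_cost = mean_cost[Arm.intervention.value] - mean_cost[Arm.usual_care.value]
    delta_q_raw = mean_qaly[Arm.intervention.value] - mean_qaly[Arm.usual_care.value]

    q, g, b = zip(*qaly_rows)
    adj = adjusted_group_effect(q, g, b)
    delta_q_adj = adj.group_effect

    dominance = _classify(delta_cost, delta_q_adj)
    icer = None if delta_q_adj == 0 else compute_icer(delta_cost, delta_q_adj)
    if delta_q_adj == 0:
        notes.append("adjusted incremental QALY is zero: ICER undefined, cost-only comparison")
    cost_effective = dominance is Dominance.dominant or (
        dominance is Dominance.tradeoff_ne and icer is not None and icer <= wtp
    )

    return CUAResult(
        mean_cost_per_arm={k: round(v, 2) for k, v in mean_cost.items()},
        delta_cost=round(delta_cost, 2),
        qaly_per_arm={k: round(v, 4) for k, v in mean_qaly.items()},
        delta_qaly_unadjusted=round(delta_q_raw, 4),
        delta_qaly_adjusted=round(delta_q_adj, 4),
        icer=None if icer is None else round(icer, 2),
        dominance=dominance,
        wtp_threshold=wtp,
        cost_effective=cost_effective,
        n_per_arm={a.value: len(qalys[a]) for a in Arm},
        notes=tuple(notes),
    )
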