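"""Synthetic cohorts with the statistical structure of the pilot trial.

Every downstream stage (scoring, trial statistics, cost-utility analysis)
is exercised on cohorts from this generator, whose defaults are the
pilot's printed per-arm summaries: baseline adherence means/SDs and
change-score means/SDs, barrier counts and per-arm addressed/resolved
rates, EQ-5D-5L utility levels and changes, appointment rates and
materials costs.

Bounded outcomes and moment matching
------------------------------------
Adherence percentages live in [0, 100] and utilities in [-0.6, 1.0], and
the configured means/SDs are themselves moments of bounded pilot data. A
naive "sample normal, then clamp" generator would therefore produce
realized means biased away from the configured values (at the pilot's
usual-care parameters roughly a quarter of naive follow-up percentage
draws fall below zero). This generator instead treats the configured
means as *realized* moments: baseline values are drawn from a truncated
normal whose location is solved so the truncated mean equals the
configured mean, and follow-up values are baseline + change with the
change's latent location solved so that the censored (clamped) follow-up
reproduces the configured change mean exactly. Realized SDs are slightly
smaller than the configured (latent) scales — the cost of respecting the
bounds.

Wear-time reports are back-solved from the target percentage by fixing
hours awake = 16 h/day and wear on 7 days/week with equal wear on both
legs, which makes the generator exactly invertible through the adherence
formula. Change scores are drawn independently of baseline (the pilot's
within-person correlation is unreported) and barrier outcomes are drawn
independently of adherence.
"""

from __future__ import annotations

import functools
import math
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, stats as sps

from . import pilot_reference as pilot
from .types import (
    N_BARRIER_ITEMS,
    UTILITY_CEILING,
    UTILITY_FLOOR,
    Arm,
    BarrierAssessment,
    BarrierOutcome,
    Education,
    Gender,
    Interval,
    Marital,
    ParticipantRecord,
    ResourceUse,
    Smoker,
    TimepointData,
    WearTimeReport,
)

__all__ = [
    "NormalParams",
    "GeneratorConfig",
    "default_pilot_config",
    "generate_cohort",
    "load_generator_config",
    "dump_generator_config",
]

#: fixed scaffold for back-solving wear reports from a target percentage
HOURS_AWAKE = 16.0
DAYS_PER_WEEK = 7.0


class NormalParams(BaseModel):
    model_config = ConfigDict(frozen=True)
    mean: float
    sd: float = Field(ge=0)


def _probs_valid(d: dict, what: str) -> None:
    total = sum(d.values())
    if any(p < 0 for p in d.values()) or not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"{what}: probabilities must be >= 0 and sum to 1 (got {total})")


class GeneratorConfig(BaseModel):
    """All knobs of the synthetic cohort, keyed per arm where the pilot
    reports per-arm values. Defaults via :func:`default_pilot_config`."""

    model_config = ConfigDict(frozen=True)

    n_per_arm: int = Field(ge=1)
    seed: int

    baseline_pct: dict[Arm, NormalParams]
    change_pct: dict[Arm, NormalParams]

    barriers_per_participant: dict[int, float]  # distribution over {1, 2, 3}
    barrier_severity: dict[int, float]  # distribution over 1..5

    p_addressed: dict[Arm, float]
    p_resolved_given_addressed: dict[Arm, float]
    p_resolved_given_not_addressed: dict[Arm, float]

    utility_baseline: dict[Arm, NormalParams]
    utility_change: dict[Arm, NormalParams]

    appointment_rate_f2f: dict[Arm, float]
    appointment_rate_phone: dict[Arm, float]
    materials_cost_range: dict[Arm, tuple[float, float]]

    p_missing_followup: dict[Arm, float] = Field(
        default_factory=lambda: {Arm.usual_care: 0.0, Arm.intervention: 0.0}
    )

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        _probs_valid(self.barriers_per_participant, "barriers_per_participant")
        _probs_valid(self.barrier_severity, "barrier_severity")
        if set(self.barriers_per_participant) - {1, 2, 3}:
            raise ValueError("barriers_per_participant supports counts 1-3")
        if set(self.barrier_severity) - {1, 2, 3, 4, 5}:
            raise ValueError("barrier_severity supports severities 1-5")
        for name in ("p_addressed", "p_resolved_given_addressed", "p_resolved_given_not_addressed", "p_missing_followup"):
            for arm, p in getattr(self, name).items():
                if not 0 <= p <= 1:
                    raise ValueError(f"{name}[{arm.value}] = {p} outside [0, 1]")
        for arm, rate in list(self.appointment_rate_f2f.items()) + list(self.appointment_rate_phone.items()):
            if rate < 0:
                raise ValueError("appointment rates must be >= 0")
        for arm, (lo, hi) in self.materials_cost_range.items():
            if not 0 <= lo <= hi:
                raise ValueError(f"materials_cost_range[{arm.value}] must satisfy 0 <= lo <= hi")
        return self


def default_pilot_config(seed: int, n_per_arm: int = pilot.N_RANDOMISED_PER_ARM) -> GeneratorConfig:
    """A configuration whose parameters are the pilot's printed per-arm
    means/SDs, barrier-outcome proportions and appointment rates."""

    def np_(table):
        return {Arm(a): NormalParams(mean=m, sd=s) for a, (m, s) in table.items()}

    # uniform materials cost with the arm's printed mean: U(0, 2 * mean)
    materials = {
        Arm(a): (0.0, round(2 * m, 2)) for a, m in pilot.MATERIALS_COST_MEAN.items()
    }
    return GeneratorConfig(
        n_per_arm=n_per_arm,
        seed=seed,
        baseline_pct=np_(pilot.ADHERENCE_PCT_BASELINE),
        change_pct=np_(pilot.ADHERENCE_PCT_CHANGE),
        barriers_per_participant={1: 0.1, 2: 0.0, 3: 0.9},  # pilot: 1 of 10 UC participants had a single barrier
        barrier_severity={s: 0.2 for s in range(1, 6)},
        p_addressed={Arm(a): p for a, p in pilot.P_ADDRESSED.items()},
        p_resolved_given_addressed={Arm(a): p for a, p in pilot.P_RESOLVED_GIVEN_ADDRESSED.items()},
        p_resolved_given_not_addressed={Arm(a): p for a, p in pilot.P_RESOLVED_GIVEN_NOT_ADDRESSED.items()},
        utility_baseline=np_(pilot.EQ5D_UTILITY_BASELINE),
        utility_change=np_(pilot.EQ5D_UTILITY_CHANGE),
        appointment_rate_f2f={Arm(a): r for a, r in pilot.APPOINTMENT_RATE_F2F.items()},
        appointment_rate_phone={Arm(a): r for a, r in pilot.APPOINTMENT_RATE_PHONE.items()},
        materials_cost_range=materials,
    )


# ---------------------------------------------------------------------------
# moment-matching calibration

def _censored_normal_mean(m: float, sd: float, lo: float, hi: float) -> float:
    """E[clip(X, lo, hi)] for X ~ N(m, sd)."""
    if sd == 0:
        return min(max(m, lo), hi)
    a = (lo - m) / sd
    b = (hi - m) / sd
    Phi_a, Phi_b = sps.norm.cdf(a), sps.norm.cdf(b)
    phi_a, phi_b = sps.norm.pdf(a), sps.norm.pdf(b)
    return lo * Phi_a + hi * (1 - Phi_b) + m * (Phi_b - Phi_a) - sd * (phi_b - phi_a)


@functools.lru_cache(maxsize=None)
def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location of a truncated normal on [lo, hi] with the given latent scale
    whose truncated mean equals ``target_mean``."""
    if sd == 0:
        return target_mean
    if not lo < target_mean < hi:
        raise ValueError(f"target mean {target_mean} outside the open interval ({lo}, {hi})")

    def f(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return sps.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    span = (hi - lo) + 10 * sd
    return float(optimize.brentq(f, target_mean - span, target_mean + span, xtol=1e-10))


@functools.lru_cache(maxsize=None)
def _change_loc(
    baseline_mean: float,
    baseline_sd: float,
    change_mean: float,
    change_sd: float,
    lo: float,
    hi: float,
) -> float:
    """Latent location of the change draw so that the clamped follow-up
    baseline + change reproduces the configured change mean in expectation.

    Baseline ~ calibrated TruncNorm; follow-up = clip(baseline + change).
    Solves E[clip(B + C)] - E[B] = change_mean over the change location,
    integrating over the baseline density by Gauss-Legendre quadrature.
    """
    if baseline_sd == 0:
        nodes = np.array([baseline_mean])
        weights = np.array([1.0])
    else:
        b_loc = _truncnorm_loc(baseline_mean, baseline_sd, lo, hi)
        a, b = (lo - b_loc) / baseline_sd, (hi - b_loc) / baseline_sd
        xs, ws = np.polynomial.legendre.leggauss(200)
        nodes = 0.5 * (hi - lo) * xs + 0.5 * (hi + lo)
        weights = ws * 0.5 * (hi - lo) * sps.truncnorm.pdf(nodes, a, b, loc=b_loc, scale=baseline_sd)

    target_followup = baseline_mean + change_mean
    if not lo < target_followup < hi:
        raise ValueError(
            f"baseline mean + change mean = {target_followup} outside the open interval ({lo}, {hi})"
        )

    def f(c_loc: float) -> float:
        means = np.array([_censored_normal_mean(bv + c_loc, change_sd, lo, hi) for bv in nodes])
        return float(np.sum(weights * means)) - target_followup

    span = (hi - lo) + 10 * (change_sd + baseline_sd + 1.0)
    return float(optimize.brentq(f, change_mean - span, change_mean + span, xtol=1e-10))


def _sample_truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    """Rejection sampling from the calibrated truncated normal."""
    if sd == 0:
        return min(max(mean, lo), hi)
    loc = _truncnorm_loc(mean, sd, lo, hi)
    while True:
        x = rng.normal(loc, sd)
        if lo <= x <= hi:
            return float(x)


def _sample_followup(
    rng: np.random.Generator,
    baseline_value: float,
    baseline_params: NormalParams,
    change_params: NormalParams,
    lo: float,
    hi: float,
) -> float:
    c_loc = _change_loc(
        baseline_params.mean, baseline_params.sd, change_params.mean, change_params.sd, lo, hi
    )
    change = rng.normal(c_loc, change_params.sd) if change_params.sd > 0 else c_loc
    return float(min(max(baseline_value + change, lo), hi))


# ---------------------------------------------------------------------------
# participant assembly

_VCSS_ITEM_PROBS = (0.55, 0.31, 0.12, 0.02)  # items 1-9; mean ~0.61 as in the pilot totals


def _wear_report(pct: float) -> WearTimeReport:
    worn = round(pct / 100.0 * HOURS_AWAKE, 3)
    return WearTimeReport(
        hours_awake=Interval.point(HOURS_AWAKE),
        hours_worn_left=Interval.point(worn),
        hours_worn_right=Interval.point(worn),
        days_per_week=Interval.point(DAYS_PER_WEEK),
    )


def _categorical(rng: np.random.Generator, probs: dict) -> object:
    keys = list(probs)
    return keys[rng.choice(len(keys), p=np.array([probs[k] for k in keys], dtype=float))]


def _vcss_items(rng: np.random.Generator, q10: int) -> tuple[int, ...]:
    items = tuple(int(v) for v in rng.choice(4, size=9, p=_VCSS_ITEM_PROBS))
    return items + (q10,)


def _q10(rng: np.random.Generator, mean: float, sd: float) -> int:
    return int(min(max(round(rng.normal(mean, sd)), 0), 3))


def _generate_participant(
    rng: np.random.Generator, config: GeneratorConfig, arm: Arm, participant_id: str
) -> ParticipantRecord:
    arm_key = arm.value
    age = round(float(np.clip(rng.normal(*pilot.AGE[arm_key]), 18, 100)), 1)
    gender = Gender.female if rng.uniform() < pilot.P_FEMALE[arm_key] else Gender.male
    bmi = round(float(np.clip(rng.normal(*pilot.BMI[arm_key]), 13, 70)), 1)
    education = Education(_categorical(rng, pilot.EDUCATION_PROBS[arm_key]))
    marital = Marital(_categorical(rng, pilot.MARITAL_PROBS[arm_key]))
    smoker = Smoker(_categorical(rng, pilot.SMOKER_PROBS[arm_key]))

    # adherence percentage: calibrated truncated baseline, censored change
    b_pct = _sample_truncnorm(rng, config.baseline_pct[arm].mean, config.baseline_pct[arm].sd, 0.0, 100.0)
    f_pct = _sample_followup(rng, b_pct, config.baseline_pct[arm], config.change_pct[arm], 0.0, 100.0)

    # clinician-assigned Q10 and the other VCSS items
    q10_b = _q10(rng, *pilot.VCSS_Q10_BASELINE[arm_key])
    q10_f = int(min(max(q10_b + round(rng.normal(*pilot.VCSS_Q10_CHANGE[arm_key])), 0), 3))

    civiq_b = round(float(np.clip(rng.normal(*pilot.CIVIQ_BASELINE[arm_key]), 0, 100)), 1)
    civiq_f = round(float(np.clip(civiq_b + rng.normal(*pilot.CIVIQ_CHANGE[arm_key]), 0, 100)), 1)
    vas_b = round(float(np.clip(rng.normal(*pilot.EQ5D_VAS_BASELINE[arm_key]), 0, 100)), 1)
    vas_f = round(float(np.clip(vas_b + rng.normal(*pilot.EQ5D_VAS_CHANGE[arm_key]), 0, 100)), 1)

    u_b = round(
        _sample_truncnorm(
            rng, config.utility_baseline[arm].mean, config.utility_baseline[arm].sd, UTILITY_FLOOR, UTILITY_CEILING
        ),
        3,
    )
    u_f = round(
        _sample_followup(
            rng, u_b, config.utility_baseline[arm], config.utility_change[arm], UTILITY_FLOOR, UTILITY_CEILING
        ),
        3,
    )

    baseline = TimepointData(
        wear_report=_wear_report(b_pct),
        vcss_items=_vcss_items(rng, q10_b),
        civiq14_gis=civiq_b,
        eq5d_utility=u_b,
        eq5d_vas=vas_b,
    )
    followup = TimepointData(
        wear_report=_wear_report(f_pct),
        vcss_items=_vcss_items(rng, q10_f),
        civiq14_gis=civiq_f,
        eq5d_utility=u_f,
        eq5d_vas=vas_f,
    )

    # barriers and their six-month outcomes
    n_barriers = int(_categorical(rng, config.barriers_per_participant))
    barrier_ids = sorted(int(b) + 1 for b in rng.choice(N_BARRIER_ITEMS, size=n_barriers, replace=False))
    severities = {
        bid: int(_categorical(rng, config.barrier_severity)) for bid in barrier_ids
    }
    assessment = BarrierAssessment(responses=severities)
    outcomes = []
    for bid in barrier_ids:
        addressed = bool(rng.uniform() < config.p_addressed[arm])
        p_res = (
            config.p_resolved_given_addressed[arm]
            if addressed
            else config.p_resolved_given_not_addressed[arm]
        )
        resolved = bool(rng.uniform() < p_res)
        outcomes.append(BarrierOutcome(barrier_id=bid, addressed=addressed, resolved=resolved))

    # resource use and costs
    n_f2f = int(rng.poisson(config.appointment_rate_f2f[arm]))
    n_phone = int(rng.poisson(config.appointment_rate_phone[arm]))
    lo, hi = config.materials_cost_range[arm]
    materials = ()
    if hi > 0:
        materials = (("stockings_applicators_postage", round(float(rng.uniform(lo, hi)), 2)),)
    resource_use = ResourceUse(
        n_f2f_appointments=n_f2f,
        n_phone_appointments=n_phone,
        materials=materials,
    )

    missing = rng.uniform() < config.p_missing_followup.get(arm, 0.0)
    return ParticipantRecord(
        participant_id=participant_id,
        arm=arm,
        age=age,
        gender=gender,
        bmi=bmi,
        education=education,
        marital=marital,
        smoker=smoker,
        baseline=baseline,
        followup=None if missing else followup,
        barrier_assessment=assessment,
        barrier_outcomes=() if missing else tuple(outcomes),
        resource_use=resource_use,
    )


def generate_cohort(config: GeneratorConfig) -> list[ParticipantRecord]:
    """Generate a two-arm cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    records = []
    pid = 0
    for arm in (Arm.usual_care, Arm.intervention):
        for _ in range(config.n_per_arm):
            pid += 1
            records.append(_generate_participant(rng, config, arm, f"P{pid:02d}"))
    return records


# ---------------------------------------------------------------------------
# YAML round-trip for the CLI

def load_generator_config(path, seed: Optional[int] = None) -> GeneratorConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if seed is not None:
        data["seed"] = seed
    return GeneratorConfig(**data)


def dump_generator_config(config: GeneratorConfig, path) -> None:
    data = config.model_dump(mode="json")
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
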