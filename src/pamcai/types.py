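"""Domain types for the compression-stocking adherence trial pipeline.

The trial compares a multidimensional adherence decision aid (PAMCAI)
against usual care in people at risk of venous leg ulcer recurrence.
One record per participant holds the arm assignment, demographics, a
baseline and a follow-up measurement block (wear-time report, VCSS items,
CIVIQ-14, EQ-5D-5L utility and VAS), the 24-item barrier assessment, the
addressed/resolved outcome flags for each barrier, and resource use for
the costing.

All models validate on construction (pydantic); readers surface the
offending row/column rather than silently coercing.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "Arm",
    "Gender",
    "Education",
    "Marital",
    "Smoker",
    "Interval",
    "WearTimeReport",
    "BarrierAssessment",
    "BarrierOutcome",
    "ResourceUse",
    "TimepointData",
    "ParticipantRecord",
    "PriceTable",
    "BARRIER_CATALOGUE",
    "N_BARRIER_ITEMS",
    "UTILITY_FLOOR",
    "UTILITY_CEILING",
]

#: EQ-5D-5L utility bounds used throughout (worst states value below death).
UTILITY_FLOOR = -0.6
UTILITY_CEILING = 1.0

N_BARRIER_ITEMS = 24

#: The 24-item barrier catalogue. Twelve items carry the labels observed in
#: the pilot; the remainder of the instrument is represented by placeholder
#: labels (the full item text is not part of this package's scope).
BARRIER_CATALOGUE: dict[int, str] = {
    1: "too_hot",
    2: "cant_don",
    3: "cant_doff",
    4: "too_tight",
    5: "too_tight_over_toes",
    6: "skin_irritation",
    7: "slides_up_foot",
    8: "slides_down",
    9: "digs_in_at_ankle",
    10: "digs_in_at_top",
    11: "perception_of_looking_old",
    12: "low_mood",
    **{i: f"barrier_{i:02d}" for i in range(13, 25)},
}


class Arm(str, enum.Enum):
    usual_care = "usual_care"
    intervention = "intervention"


class Gender(str, enum.Enum):
    female = "female"
    male = "male"
    other = "other"


class Education(str, enum.Enum):
    less_than_grade10 = "less_than_grade10"
    grade10_to_12 = "grade10_to_12"
    trade_cert_diploma = "trade_cert_diploma"
    degree = "degree"


class Marital(str, enum.Enum):
    single = "single"  # single, divorced, separated, widowed
    partnered = "partnered"  # married, de facto


class Smoker(str, enum.Enum):
    never = "never"
    previous = "previous"
    current = "current"


class Interval(BaseModel):
    """A possibly-degenerate closed interval [lo, hi].

    Self-reported wear times are sometimes given as ranges ("12-14 hours");
    a single reported value is the degenerate interval lo == hi.
    """

    model_config = ConfigDict(frozen=True)

    lo: float = Field(ge=0)
    hi: float = Field(ge=0)

    @model_validator(mode="after")
    def _ordered(self) -> "Interval":
        if self.lo > self.hi:
            raise ValueError(f"interval lower bound {self.lo} exceeds upper bound {self.hi}")
        return self

    @classmethod
    def point(cls, value: float) -> "Interval":
        return cls(lo=value, hi=value)

    @property
    def is_point(self) -> bool:
        return self.lo == self.hi

    @property
    def midpoint(self) -> float:
        return (self.lo + self.hi) / 2.0


class WearTimeReport(BaseModel):
    """Self-reported wear times for one timepoint.

    ``hours_worn_left``/``hours_worn_right`` are per-leg daily wear; at least
    one leg must be reported.  Worn hours exceeding awake hours are *not*
    rejected here — the scoring layer clamps them (self-report noise).
    """

    model_config = ConfigDict(frozen=True)

    hours_awake: Interval
    hours_worn_left: Optional[Interval] = None
    hours_worn_right: Optional[Interval] = None
    days_per_week: Interval

    @model_validator(mode="after")
    def _bounds(self) -> "WearTimeReport":
        for name in ("hours_awake", "hours_worn_left", "hours_worn_right"):
            iv = getattr(self, name)
            if iv is not None and iv.hi > 24:
                raise ValueError(f"{name} upper bound {iv.hi} exceeds 24 h/day")
        if self.days_per_week.hi > 7:
            raise ValueError(f"days_per_week upper bound {self.days_per_week.hi} exceeds 7")
        if self.hours_worn_left is None and self.hours_worn_right is None:
            raise ValueError("at least one leg's worn hours must be reported")
        return self


class BarrierAssessment(BaseModel):
    """Responses to the 24-item barriers-to-compression questionnaire.

    Each applicable barrier is rated on a Likert severity from 1 (mild) to
    5 (severe); barriers that do not apply are simply absent from the map.
    """

    model_config = ConfigDict(frozen=True)

    responses: dict[int, int] = Field(default_factory=dict)

    @field_validator("responses")
    @classmethod
    def _check(cls, v: dict[int, int]) -> dict[int, int]:
        for barrier_id, severity in v.items():
            if barrier_id not in BARRIER_CATALOGUE:
                raise ValueError(f"unknown barrier id {barrier_id} (catalogue has 1-{N_BARRIER_ITEMS})")
            if severity not in (1, 2, 3, 4, 5):
                raise ValueError(f"barrier {barrier_id}: severity {severity} outside 1-5")
        return dict(sorted(v.items()))


class BarrierOutcome(BaseModel):
    """Six-month fate of one identified barrier.

    ``resolved`` means the barrier did not reappear at the 6-month review;
    ``addressed`` means the clinician acted on it.  All four combinations
    are meaningful (a barrier can resolve without being addressed).
    """

    model_config = ConfigDict(frozen=True)

    barrier_id: int = Field(ge=1, le=N_BARRIER_ITEMS)
    addressed: bool
    resolved: bool


class ResourceUse(BaseModel):
    """Per-participant resource consumption over the trial period."""

    model_config = ConfigDict(frozen=True)

    n_f2f_appointments: int = Field(default=0, ge=0)
    n_phone_appointments: int = Field(default=0, ge=0)
    n_specialist_vlu_appointments: int = Field(default=0, ge=0)
    n_vlu_admissions: int = Field(default=0, ge=0)
    #: (item label, unit cost in AUD); unit cost None means "price from catalogue".
    materials: tuple[tuple[str, Optional[float]], ...] = ()

    @field_validator("materials")
    @classmethod
    def _costs(cls, v):
        for label, cost in v:
            if cost is not None and cost < 0:
                raise ValueError(f"material {label!r}: unit cost {cost} < 0")
        return v


class TimepointData(BaseModel):
    """Measurements at one timepoint (baseline or 6-month follow-up).

    Individual fields may be None when a measure could not be collected
    (e.g. a follow-up converted to a phone consultation, preventing the
    clinician-scored VCSS).
    """

    model_config = ConfigDict(frozen=True)

    wear_report: Optional[WearTimeReport] = None
    vcss_items: Optional[tuple[int, ...]] = None
    civiq14_gis: Optional[float] = Field(default=None, ge=0, le=100)
    eq5d_utility: Optional[float] = Field(default=None, ge=UTILITY_FLOOR, le=UTILITY_CEILING)
    eq5d_vas: Optional[float] = Field(default=None, ge=0, le=100)

    @field_validator("vcss_items")
    @classmethod
    def _vcss(cls, v):
        if v is None:
            return v
        if len(v) != 10:
            raise ValueError(f"vcss_items must have 10 items, got {len(v)}")
        for i, item in enumerate(v, start=1):
            if item not in (0, 1, 2, 3):
                raise ValueError(f"VCSS item {i}: score {item} outside 0-3")
        return v

    @property
    def vcss_total(self) -> Optional[int]:
        return None if self.vcss_items is None else sum(self.vcss_items)

    @property
    def vcss_q10(self) -> Optional[int]:
        """Clinician-assigned (unmodified) compression-compliance item."""
        return None if self.vcss_items is None else self.vcss_items[9]


class ParticipantRecord(BaseModel):
    """One randomised participant: demographics, two timepoints, barriers, costs.

    ``followup`` is None for participants withdrawn or unreachable at the
    6-month review; intention-to-treat analyses use their available baseline
    data only.
    """

    model_config = ConfigDict(frozen=True)

    participant_id: str
    arm: Arm
    age: float = Field(ge=18, le=120)
    gender: Gender
    bmi: float = Field(gt=0)
    education: Education
    marital: Marital
    smoker: Smoker
    baseline: TimepointData
    followup: Optional[TimepointData] = None
    barrier_assessment: BarrierAssessment = Field(default_factory=BarrierAssessment)
    barrier_outcomes: tuple[BarrierOutcome, ...] = ()
    resource_use: ResourceUse = Field(default_factory=ResourceUse)

    @property
    def has_followup(self) -> bool:
        return self.followup is not None


class PriceTable(BaseModel):
    """Unit prices (AUD) for the health-service-perspective costing.

    Defaults are the trial's outpatient tariff: $193 per face-to-face and
    $177 per phone/telehealth occupational-therapy appointment.  Specialist
    VLU appointments and admissions carry configurable unit prices (zero
    usage occurred in the pilot, so no default tariff is asserted).
    """

    model_config = ConfigDict(frozen=True)

    f2f_cost: float = Field(default=193.00, ge=0)
    phone_cost: float = Field(default=177.00, ge=0)
    specialist_cost: float = Field(default=0.0, ge=0)
    admission_cost: float = Field(default=0.0, ge=0)
    material_catalogue: dict[str, float] = Field(default_factory=dict)

    @field_validator("material_catalogue")
    @classmethod
    def _prices(cls, v: dict[str, float]) -> dict[str, float]:
        for label, price in v.items():
            if price < 0:
                raise ValueError(f"material {label!r}: price {price} < 0")
        return v


def default_price_table() -> PriceTable:
    """Pilot price table: appointment tariffs plus a small supplier catalogue
    spanning the observed materials price range (AUD 19.99-891.92)."""
    return PriceTable(
        material_catalogue={
            "compression_stocking_pair": 89.95,
            "stocking_applicator_basic": 19.99,
            "stocking_applicator_powered": 891.92,
            "postage": 19.99,
        }
    )
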