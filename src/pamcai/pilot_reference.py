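"""Published summary statistics of the pilot trial, used as inputs.

These are the printed per-arm summaries and per-participant usual-care
values from the pilot report: they parameterize the synthetic-cohort
generator, seed the sample-size and effect-size calculations, and serve as
worked-number inputs for the ICER arithmetic.

``usual_care_barrier_outcomes`` is a *reconstruction*: the report prints
each usual-care participant's mean barrier resolution score and barrier
count, plus the pooled category counts (1 addressed-and-resolved,
7 addressed-not-resolved, 20 neither, 0 resolved-without-being-addressed).
Given that the 2-point category (not addressed, resolved) has a zero
count, the per-participant flag combinations are uniquely determined by
the printed means and counts; the reconstruction below reproduces both
the per-participant scores and the pooled table exactly.
"""

from __future__ import annotations

from .types import BarrierOutcome

# --- arm sizes ------------------------------------------------------------
N_RANDOMISED_PER_ARM = 10
N_ANALYSED = {"usual_care": 10, "intervention": 9}  # one withdrawal

# --- baseline characteristics (mean, sd) per arm --------------------------
AGE = {"usual_care": (69.33, 17.41), "intervention": (71.50, 11.36)}
BMI = {"usual_care": (28.84, 5.91), "intervention": (36.79, 15.02)}
P_FEMALE = {"usual_care": 0.5, "intervention": 0.4}
EDUCATION_PROBS = {
    "usual_care": {"less_than_grade10": 0.2, "grade10_to_12": 0.5, "trade_cert_diploma": 0.2, "degree": 0.1},
    "intervention": {"less_than_grade10": 0.2, "grade10_to_12": 0.2, "trade_cert_diploma": 0.3, "degree": 0.3},
}
MARITAL_PROBS = {
    "usual_care": {"single": 0.3, "partnered": 0.7},
    "intervention": {"single": 0.6, "partnered": 0.4},
}
SMOKER_PROBS = {
    "usual_care": {"never": 0.4, "previous": 0.5, "current": 0.1},
    "intervention": {"never": 0.2, "previous": 0.6, "current": 0.2},
}

# adherence percentage (% of waking hours), baseline and change
ADHERENCE_PCT_BASELINE = {"usual_care": (52.09, 11.74), "intervention": (19.51, 7.23)}
ADHERENCE_PCT_CHANGE = {"usual_care": (-24.82, 37.42), "intervention": (38.574, 23.47)}

# clinician-assigned (unmodified) VCSS Q10, baseline and change
VCSS_Q10_BASELINE = {"usual_care": (1.80, 1.13), "intervention": (1.00, 0.86)}
VCSS_Q10_CHANGE = {"usual_care": (-0.9, 1.28), "intervention": (0.777, 1.20)}

# modified Q10 change score summaries (n = 10 usual care, 9 intervention)
MODIFIED_Q10_CHANGE = {"usual_care": (-0.60, 1.07), "intervention": (1.00, 0.86)}

VCSS_TOTAL_BASELINE = {"usual_care": (7.30, 2.90), "intervention": (6.44, 1.94)}
CIVIQ_BASELINE = {"usual_care": (38.00, 12.54), "intervention": (39.00, 16.12)}
CIVIQ_CHANGE = {"usual_care": (-1.42, 35.39), "intervention": (1.23, 44.02)}
EQ5D_UTILITY_BASELINE = {"usual_care": (0.70, 0.34), "intervention": (0.59, 0.42)}
EQ5D_UTILITY_CHANGE = {"usual_care": (-0.054, 0.19), "intervention": (0.17, 0.30)}
EQ5D_VAS_BASELINE = {"usual_care": (56.00, 20.92), "intervention": (55.66, 30.75)}
EQ5D_VAS_CHANGE = {"usual_care": (-7.22, 22.79), "intervention": (1.44, 45.25)}

# --- barrier outcomes ------------------------------------------------------
TOTAL_BARRIERS = {"usual_care": 28, "intervention": 25}
#: pooled category counts: (addressed&resolved, addressed&not, not&not, not&resolved)
BARRIER_CATEGORY_COUNTS = {
    "usual_care": {
        "addressed_resolved": 1,
        "addressed_unresolved": 7,
        "unaddressed_unresolved": 20,
        "unaddressed_resolved": 0,
    },
    "intervention": {
        "addressed_resolved": 18,
        "addressed_unresolved": 7,
        "unaddressed_unresolved": 0,
        "unaddressed_resolved": 0,
    },
}

#: derived per-arm Bernoulli rates for the generator
P_ADDRESSED = {"usual_care": 8 / 28, "intervention": 1.0}
P_RESOLVED_GIVEN_ADDRESSED = {"usual_care": 1 / 8, "intervention": 18 / 25}
P_RESOLVED_GIVEN_NOT_ADDRESSED = {"usual_care": 0.0, "intervention": 0.0}

# --- usual-care per-participant table --------------------------------------
USUAL_CARE_IDS = ("P01", "P03", "P05", "P07", "P10", "P12", "P14", "P15", "P17", "P18")
#: modified Q10 change score per usual-care participant
USUAL_CARE_Q10_CHANGES = (-3, 0, 0, 0, 0, -1, -2, 0, 0, 0)
#: printed mean barrier resolution scores (2 dp)
USUAL_CARE_MEAN_RESOLUTION = (1.00, 1.00, 1.67, 2.33, 2.00, 1.67, 1.67, 1.00, 2.33, 1.00)
#: active barriers per participant ('Nil' rows excluded)
USUAL_CARE_BARRIER_COUNTS = (1, 3, 3, 3, 3, 3, 3, 3, 3, 3)

#: reconstructed per-participant (addressed, resolved) flags; see module docstring
_USUAL_CARE_FLAGS = (
    ((False, False),),
    ((False, False), (False, False), (False, False)),
    ((True, False), (False, False), (False, False)),
    ((True, False), (True, False), (False, False)),
    ((True, True), (False, False), (False, False)),
    ((True, False), (False, False), (False, False)),
    ((True, False), (False, False), (False, False)),
    ((False, False), (False, False), (False, False)),
    ((True, False), (True, False), (False, False)),
    ((False, False), (False, False), (False, False)),
)


def usual_care_barrier_outcomes() -> list[list[BarrierOutcome]]:
    """Reconstructed usual-care barrier outcomes, one list per participant."""
    return [
        [BarrierOutcome(barrier_id=j + 1, addressed=a, resolved=r) for j, (a, r) in enumerate(flags)]
        for flags in _USUAL_CARE_FLAGS
    ]


def intervention_barrier_outcomes() -> list[list[BarrierOutcome]]:
    """Pooled intervention-arm outcomes (18 resolved + 7 addressed-only);
    the per-participant split was not published, so they are returned as a
    single pooled pseudo-participant list per category count."""
    pooled = [BarrierOutcome(barrier_id=(i % 24) + 1, addressed=True, resolved=i < 18) for i in range(25)]
    return [pooled]


# --- costs (Table of appointments and costs) -------------------------------
APPOINTMENT_RATE_F2F = {"usual_care": 1.9, "intervention": 2.89}
APPOINTMENT_RATE_PHONE = {"usual_care": 0.5, "intervention": 1.22}
MATERIALS_COST_MEAN = {"usual_care": 202.36, "intervention": 323.81}
TOTAL_COST_MEAN = {"usual_care": 675.28, "intervention": 1097.70}
TOTAL_COST_SD = {"usual_care": 381.01, "intervention": 451.95}

F2F_UNIT_COST = 193.00
PHONE_UNIT_COST = 177.00
MATERIALS_PRICE_RANGE = (19.99, 891.92)

#: printed health-economic headline numbers
DELTA_COST = 422.42
ADJUSTED_DELTA_QALY = 0.125
WTP_THRESHOLD = 28033.0

# --- sample-size planning inputs -------------------------------------------
PLAN_DELTA = 1.0
PLAN_SD = 1.14
PLAN_ALPHA = 0.05
PLAN_POWER = 0.8
PLAN_DROPOUT = 0.20
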