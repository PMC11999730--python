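"""Costing, QALY area-under-curve, and the cost-utility analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pamcai.econ import (
    Dominance,
    MaterialPriceError,
    compute_icer,
    cost_participant,
    cost_utility_analysis,
    qaly_auc,
)
from pamcai.simulate import default_pilot_config, generate_cohort
from pamcai.types import (
    Arm,
    Interval,
    ParticipantRecord,
    PriceTable,
    ResourceUse,
    TimepointData,
    WearTimeReport,
    default_price_table,
)


class TestCostParticipant:
    def test_zero_use_costs_nothing(self):
        c = cost_participant(ResourceUse(), PriceTable())
        assert c.total == 0.0

    def test_appointments_at_printed_tariffs(self):
        use = ResourceUse(n_f2f_appointments=2, n_phone_appointments=1)
        c = cost_participant(use, PriceTable())
        assert c.appointment_cost == pytest.approx(563.00)  # 2x193 + 177

    def test_materials_with_explicit_unit_cost(self):
        use = ResourceUse(n_f2f_appointments=1, materials=(("powered_applicator", 891.92),))
        c = cost_participant(use, PriceTable())
        assert c.total == pytest.approx(1084.92)

    def test_materials_priced_from_catalogue(self):
        use = ResourceUse(materials=(("stocking_applicator_basic", None),))
        c = cost_participant(use, default_price_table())
        assert c.materials_cost == pytest.approx(19.99)

    def test_unknown_material_is_configuration_error(self):
        use = ResourceUse(materials=(("mystery_item", None),))
        with pytest.raises(MaterialPriceError, match="mystery_item"):
            cost_participant(use, PriceTable())

    def test_specialist_and_admission_unit_prices(self):
        use = ResourceUse(n_specialist_vlu_appointments=2, n_vlu_admissions=1)
        prices = PriceTable(specialist_cost=250.0, admission_cost=1000.0)
        c = cost_participant(use, prices)
        assert c.specialist_cost == 500.0 and c.admission_cost == 1000.0

    def test_additive_over_concatenated_records(self):
        prices = PriceTable()
        u1 = ResourceUse(n_f2f_appointments=1, materials=(("a", 10.0),))
        u2 = ResourceUse(n_phone_appointments=2, materials=(("b", 5.5),))
        combined = ResourceUse(
            n_f2f_appointments=1, n_phone_appointments=2, materials=(("a", 10.0), ("b", 5.5))
        )
        assert cost_participant(combined, prices).total == pytest.approx(
            cost_participant(u1, prices).total + cost_participant(u2, prices).total
        )


class TestQalyAuc:
    def test_perfect_health_for_one_year(self):
        assert qaly_auc(1.0, 1.0) == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-0.6, 1.0))
    def test_constant_utility_identity(self, u):
        assert qaly_auc(u, u) == pytest.approx(u)

    def test_trapezoid_then_flat_tail(self):
        assert qaly_auc(0.70, 0.60) == pytest.approx(0.625)  # 0.5*0.65 + 0.5*0.60

    def test_linear_trend_extrapolation(self):
        # slope -0.2/yr continues: u12 = 0.5; tail (0.6+0.5)/2 * 0.5
        assert qaly_auc(0.70, 0.60, extrapolation="linear") == pytest.approx(0.6)

    def test_missing_followup_carries_baseline(self):
        assert qaly_auc(0.70, None) == pytest.approx(0.70)

    def test_missing_baseline_is_error(self):
        with pytest.raises(ValueError):
            qaly_auc(None, 0.5)

    def test_out_of_range_utility_rejected(self):
        with pytest.raises(ValueError):
            qaly_auc(1.2, 0.5)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(-0.6, 1.0), st.floats(-0.6, 1.0), st.floats(0, 0.2), st.floats(0, 0.2))
    def test_monotone_in_each_utility(self, u0, u6, e0, e6):
        base = qaly_auc(u0, u6)
        assert qaly_auc(min(u0 + e0, 1.0), u6) >= base - 1e-12
        assert qaly_auc(u0, min(u6 + e6, 1.0)) >= base - 1e-12
        assert min(u0, u6) - 1e-12 <= base <= max(u0, u6) + 1e-12


class TestIcer:
    def test_pilot_arithmetic(self):
        assert compute_icer(422.42, 0.125) == pytest.approx(3379.36)

    def test_zero_delta_qaly_undefined(self):
        with pytest.raises(ZeroDivisionError):
            compute_icer(100.0, 0.0)


def _participant(pid, arm, u0, u6, n_f2f=0, materials=()):
    wear = WearTimeReport(
        hours_awake=Interval.point(16),
        hours_worn_left=Interval.point(8),
        days_per_week=Interval.point(7),
    )
    return ParticipantRecord(
        participant_id=pid,
        arm=arm,
        age=70,
        gender="female",
        bmi=28,
        education="grade10_to_12",
        marital="single",
        smoker="never",
        baseline=TimepointData(wear_report=wear, eq5d_utility=u0),
        followup=TimepointData(wear_report=wear, eq5d_utility=u6),
        resource_use=ResourceUse(n_f2f_appointments=n_f2f, materials=materials),
    )


def _toy_cohort(cost_i=2, cost_c=1, u6_i=0.9, u6_c=0.5):
    return [
        _participant("C1", Arm.usual_care, 0.6, u6_c, n_f2f=cost_c),
        _participant("C2", Arm.usual_care, 0.7, u6_c, n_f2f=cost_c),
        _participant("I1", Arm.intervention, 0.6, u6_i, n_f2f=cost_i),
        _participant("I2", Arm.intervention, 0.7, u6_i, n_f2f=cost_i),
    ]


class TestCostUtilityAnalysis:
    def test_tradeoff_ne_quadrant_and_wtp(self):
        res = cost_utility_analysis(_toy_cohort())
        assert res.dominance is Dominance.tradeoff_ne
        assert res.delta_cost == pytest.approx(193.0)
        assert res.icer is not None and res.cost_effective

    def test_dominant_when_cheaper_and_better(self):
        res = cost_utility_analysis(_toy_cohort(cost_i=0, cost_c=3))
        assert res.dominance is Dominance.dominant
        assert res.cost_effective

    def test_dominated_when_dearer_and_worse(self):
        res = cost_utility_analysis(_toy_cohort(u6_i=0.2, u6_c=0.9))
        assert res.dominance is Dominance.dominated
        assert not res.cost_effective

    def test_not_cost_effective_beyond_wtp(self):
        res = cost_utility_analysis(_toy_cohort(), wtp=1.0)
        assert res.dominance is Dominance.tradeoff_ne and not res.cost_effective

    def test_icer_scales_linearly_with_costs(self):
        cohort = _toy_cohort()
        base = cost_utility_analysis(cohort, PriceTable())
        scaled = cost_utility_analysis(
            cohort, PriceTable(f2f_cost=3 * 193.0, phone_cost=3 * 177.0)
        )
        # reported figures are rounded to cents, hence the absolute slack
        assert scaled.icer == pytest.approx(3 * base.icer, abs=0.05)
        assert scaled.delta_qaly_adjusted == base.delta_qaly_adjusted

    def test_missing_followup_utility_flagged_and_carried(self):
        cohort = _toy_cohort()
        cohort[0] = cohort[0].model_copy(update={"followup": None})
        res = cost_utility_analysis(cohort)
        assert any("carried forward" in n for n in res.notes)

    def test_single_arm_rejected(self):
        cohort = [p for p in _toy_cohort() if p.arm is Arm.usual_care]
        with pytest.raises(ValueError):
            cost_utility_analysis(cohort)

    def test_delta_cost_converges_to_configured_difference(self):
        """At n=2000/arm the empirical cost difference matches the
        difference implied by the configured appointment rates and
        materials ranges within 3 standard errors."""
        cfg = default_pilot_config(seed=6, n_per_arm=2000)
        cohort = generate_cohort(cfg)
        prices = PriceTable()
        configured = (
            (cfg.appointment_rate_f2f[Arm.intervention] - cfg.appointment_rate_f2f[Arm.usual_care]) * prices.f2f_cost
            + (cfg.appointment_rate_phone[Arm.intervention] - cfg.appointment_rate_phone[Arm.usual_care]) * prices.phone_cost
            + (np.mean(cfg.materials_cost_range[Arm.intervention]) - np.mean(cfg.materials_cost_range[Arm.usual_care]))
        )
        from pamcai.econ import cost_participant as cp

        totals = {
            arm: np.array([cp(r.resource_use, prices).total for r in cohort if r.arm is arm])
            for arm in Arm
        }
        se = np.sqrt(sum(t.var(ddof=1) / len(t) for t in totals.values()))
        res = cost_utility_analysis(cohort, prices)
        assert abs(res.delta_cost - configured) < 3 * se
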