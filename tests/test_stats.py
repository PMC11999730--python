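"""Trial statistics against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pamcai.stats import TestMethod as MWMethod
from pamcai.stats import (
    MIN_ARE,
    adjusted_group_effect,
    cohens_d_pooled,
    mann_whitney,
    sample_size_mann_whitney_are,
    sample_size_two_arm_t,
    somers_d,
)

# ---------------------------------------------------------------------------
# oracles


def mw_enumeration_p(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of all group
    assignments of the pooled values (midranks for generality)."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u1(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(
            (1.0 if a > b else 0.5 if a == b else 0.0) for a in xs for b in ys
        )

    obs = u1(tuple(range(n1)))
    us = [u1(idx) for idx in itertools.combinations(range(len(pooled)), n1)]
    total = len(us)
    le = sum(u <= obs for u in us)
    ge = sum(u >= obs for u in us)
    return min(1.0, 2.0 * min(le, ge) / total)


def somers_pair_counting(x, y):
    """D(Y|X) by explicit pair enumeration."""
    c = d = tied_x = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            if x[i] == x[j]:
                tied_x += 1
            elif (x[i] - x[j]) * (y[i] - y[j]) > 0:
                c += 1
            elif (x[i] - x[j]) * (y[i] - y[j]) < 0:
                d += 1
    denom = n * (n - 1) // 2 - tied_x
    return (c - d) / denom


# ---------------------------------------------------------------------------
# Mann-Whitney


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_complete_separation_small_sample(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.method is MWMethod.exact_enumeration
        assert res.p_value == pytest.approx(0.1)

    def test_two_one_split(self):
        res = mann_whitney([1, 2], [3])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(2 / 3)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1])

    def test_ties_switch_to_normal_approximation(self):
        res = mann_whitney([1, 1, 2], [2, 3, 3])
        assert res.method is MWMethod.normal_approx
        assert 0 < res.p_value <= 1

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        res = mann_whitney(rng.normal(size=15), rng.normal(size=15))
        assert res.method is MWMethod.normal_approx

    def test_exact_p_matches_enumeration_for_all_small_splits(self):
        """Property: exact p equals brute-force enumeration over all group
        assignments for every untied input with n1 + n2 <= 8."""
        rng = np.random.default_rng(1)
        for n1 in range(1, 7):
            for n2 in range(1, 8 - n1 + 1):
                for _ in range(3):
                    pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
                    x, y = pooled[:n1], pooled[n1:]
                    res = mann_whitney(x, y)
                    assert res.method is MWMethod.exact_enumeration
                    assert res.p_value == pytest.approx(mw_enumeration_p(x, y), abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=4, unique=True),
        st.lists(st.floats(5.001, 10, exclude_min=True), min_size=1, max_size=4, unique=True),
    )
    def test_exact_p_matches_enumeration_random_values(self, x, y):
        res = mann_whitney(x, y)
        assert res.p_value == pytest.approx(mw_enumeration_p(x, y), abs=1e-12)


# ---------------------------------------------------------------------------
# Somers' D


class TestSomersD:
    def test_perfect_concordance(self):
        d, _ = somers_d([1, 2, 3], [1, 2, 3])
        assert d == 1.0

    def test_perfect_discordance(self):
        d, _ = somers_d([1, 2, 3], [3, 2, 1])
        assert d == -1.0

    def test_balanced_pairs_give_zero(self):
        d, _ = somers_d([1, 1, 2, 2], [1, 2, 1, 2])
        assert d == 0.0

    def test_all_tied_predictor_undefined(self):
        with pytest.raises(ValueError, match="tied"):
            somers_d([2, 2, 2], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            somers_d([1, 2], [1, 2, 3])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 4), st.integers(0, 3)), min_size=2, max_size=12))
    def test_matches_pair_counting_oracle(self, pairs):
        x = [p for p, _ in pairs]
        y = [r for _, r in pairs]
        if all(v == x[0] for v in x):
            return
        d, p = somers_d(x, y)
        assert d == pytest.approx(somers_pair_counting(x, y), abs=1e-12)
        assert -1 <= d <= 1 and 0 <= p <= 1

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 4), st.integers(0, 3)), min_size=2, max_size=10))
    def test_antisymmetric_under_response_reversal(self, pairs):
        x = [p for p, _ in pairs]
        y = [r for _, r in pairs]
        if all(v == x[0] for v in x):
            return
        d, _ = somers_d(x, y)
        d_rev, _ = somers_d(x, [-v for v in y])
        assert d_rev == pytest.approx(-d, abs=1e-12)


# ---------------------------------------------------------------------------
# baseline-adjusted regression


class TestAdjustedGroupEffect:
    def test_null_case(self):
        res = adjusted_group_effect([1, 1, 1, 1], [0, 0, 1, 1], [2, 3, 2, 3])
        assert res.group_effect == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_covariate(self):
        baseline = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        arm = [0, 1, 0, 1, 0, 1]
        res = adjusted_group_effect(baseline, arm, baseline)
        assert res.group_effect == pytest.approx(0.0, abs=1e-10)
        assert res.covariate_effects["baseline"] == pytest.approx(1.0, abs=1e-10)

    def test_recovers_known_effect_with_baseline_confounding(self):
        """n=2000 simulated design with arm-imbalanced baselines: the arm
        coefficient recovers the generating effect 0.224 within 3 SE."""
        rng = np.random.default_rng(4)
        n = 2000
        arm = np.repeat([0, 1], n // 2)
        baseline = np.where(arm == 0, rng.normal(0.70, 0.34, n), rng.normal(0.59, 0.42, n))
        effect = 0.17 - (-0.054)
        change = effect * arm + 0.3 * baseline + rng.normal(0, 0.25, n)
        res = adjusted_group_effect(change, arm, baseline)
        assert abs(res.group_effect - effect) < 3 * res.standard_error

    def test_one_arm_rejected(self):
        with pytest.raises(ValueError, match="both arms"):
            adjusted_group_effect([1, 2, 3, 4], [1, 1, 1, 1], [1, 2, 3, 4])

    def test_singular_design_rejected(self):
        # baseline constant within each arm and equal to the arm indicator
        with pytest.raises(ValueError, match="singular|collinear"):
            adjusted_group_effect([1, 2, 3, 4], [0, 0, 1, 1], [0, 0, 1, 1])


# ---------------------------------------------------------------------------
# effect size and sample size


class TestCohensD:
    def test_zero_when_means_equal(self):
        assert cohens_d_pooled(1.0, 0.5, 5, 1.0, 0.7, 5) == 0.0

    def test_pilot_effect_size(self):
        d = cohens_d_pooled(-0.60, 1.07, 10, 1.00, 0.86, 9)
        assert round(d, 2) == 1.64

    def test_unit_pooled_sd(self):
        assert cohens_d_pooled(0, 1, 2, 1, 1, 2) == pytest.approx(1.0)

    def test_zero_pooled_sd_with_unequal_means(self):
        with pytest.raises(ZeroDivisionError):
            cohens_d_pooled(0, 0, 5, 1, 0, 5)


class TestSampleSize:
    def test_pilot_plan(self):
        plan = sample_size_two_arm_t(delta=1, sd=1.14, alpha=0.05, power=0.8)
        assert plan.n_total == 44
        assert plan.n_per_group == 22

    def test_dropout_inflation_rounds_to_even(self):
        plan = sample_size_two_arm_t(delta=1, sd=1.14, dropout_rate=0.2)
        assert plan.n_total_inflated == 56

    def test_huge_effect_hits_floor(self):
        plan = sample_size_two_arm_t(delta=10, sd=1, alpha=0.05, power=0.8)
        assert plan.n_per_group == 2

    def test_monotone_in_power_delta_sd(self):
        n = lambda **kw: sample_size_two_arm_t(**kw).n_per_group
        assert n(delta=1, sd=1, power=0.9) >= n(delta=1, sd=1, power=0.8)
        assert n(delta=0.5, sd=1) >= n(delta=1, sd=1)
        assert n(delta=1, sd=2) >= n(delta=1, sd=1)

    @pytest.mark.parametrize("effect", [0.3, 0.5, 1 / 1.14, 1.64])
    def test_cross_check_against_statsmodels(self, effect):
        from statsmodels.stats.power import TTestIndPower

        nobs = TTestIndPower().solve_power(
            effect_size=effect, alpha=0.05, power=0.8, alternative="two-sided"
        )
        ours = sample_size_two_arm_t(delta=effect, sd=1.0).n_per_group
        assert ours == max(math.ceil(nobs - 1e-9), 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sample_size_two_arm_t(delta=0, sd=1)
        with pytest.raises(ValueError):
            sample_size_two_arm_t(delta=1, sd=1, dropout_rate=1.0)


class TestMannWhitneyPlan:
    def test_pilot_definitive_trial(self):
        plan = sample_size_mann_whitney_are(d=1.64, alpha=0.05, power=0.8, are=MIN_ARE)
        assert plan.n_total == 18

    def test_are_one_reduces_to_t_plan(self):
        t_plan = sample_size_two_arm_t(delta=1.64, sd=1.0)
        mw_plan = sample_size_mann_whitney_are(d=1.64, are=1.0)
        assert mw_plan.n_per_group == t_plan.n_per_group

    def test_halving_are_doubles_per_group_n(self):
        base = sample_size_mann_whitney_are(d=1.64, are=1.0)
        halved = sample_size_mann_whitney_are(d=1.64, are=0.5)
        assert halved.n_per_group == 2 * base.n_per_group

    def test_are_bounds(self):
        with pytest.raises(ValueError):
            sample_size_mann_whitney_are(d=1.0, are=0.0)
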