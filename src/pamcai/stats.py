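"""Statistical machinery for the two-arm trial analysis.

Between-arm comparisons of the ordinal primary outcome use the
Mann-Whitney U test: exact permutation p-value for small untied samples
(n1 + n2 <= 20), otherwise the normal approximation with midranks, tie
correction and continuity correction — the trial's ordinal data are
heavily tied, so the exact path mostly serves small clean samples.

Somers' D quantifies the directed ordinal association of an outcome with
a predictor: D(Y|X) = (concordant - discordant) / (pairs untied on X).

Baseline imbalance in secondary outcomes is handled ANCOVA-style: OLS of
the change score on an arm indicator plus the baseline value; the arm
coefficient is the adjusted between-arm effect.

Sample-size planning: the two-sample t-test plan iterates the noncentral-t
power over the per-group n (noncentrality (delta/sd) * sqrt(n/2), df
2n - 2) until the target power is reached; the Mann-Whitney plan divides
that per-group n by an asymptotic relative efficiency (default 0.864, the
distribution-free minimum) and rounds up.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "TestResult",
    "RegressionResult",
    "SampleSizePlan",
    "MIN_ARE",
    "mann_whitney",
    "somers_d",
    "adjusted_group_effect",
    "cohens_d_pooled",
    "sample_size_two_arm_t",
    "sample_size_mann_whitney_are",
]

#: Distribution-free lower bound on the ARE of the Mann-Whitney test
#: relative to the t test (3/pi is the normal-shift value 0.955; 0.864 is
#: the worst case over all distributions).
MIN_ARE = 0.864


class TestMethod(str, enum.Enum):
    exact_enumeration = "exact_enumeration"
    normal_approx = "normal_approx"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: TestMethod
    n1: int
    n2: int

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class RegressionResult:
    group_effect: float  # intervention minus usual care, baseline-adjusted
    standard_error: float
    p_value: float
    covariate_effects: dict[str, float]

    def __post_init__(self):
        if self.standard_error < 0:
            raise ValueError("standard_error must be >= 0")


@dataclass(frozen=True)
class SampleSizePlan:
    delta: float
    sd: float
    alpha: float
    power: float
    n_per_group: int
    n_total: int
    dropout_rate: float = 0.0
    n_total_inflated: int = 0
    are_correction: Optional[float] = None

    def __post_init__(self):
        if self.n_total != 2 * self.n_per_group:
            raise ValueError("n_total must equal 2 * n_per_group")
        if self.n_total_inflated < self.n_total:
            raise ValueError("n_total_inflated must be >= n_total")


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Returns the classical statistic U = min(U1, U2). Exact enumeration is
    used when the pooled sample is small (n1 + n2 <= 20) and untied;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if n1 + n2 <= 20 and not has_ties:
        method = TestMethod.exact_enumeration
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = TestMethod.normal_approx
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    u1 = float(res.statistic)
    u = min(u1, n1 * n2 - u1)
    return TestResult(statistic=u, p_value=float(min(res.pvalue, 1.0)), method=method, n1=n1, n2=n2)


def somers_d(predictor: Sequence[float], response: Sequence[float]) -> tuple[float, float]:
    """Somers' D of the response given the predictor, with asymptotic p.

    D(Y|X) = (concordant - discordant) / (pairs untied on the predictor).
    For the trial's headline association the predictor is the Mean Barrier
    Resolution Score and the response the modified-Q10 change score.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(response, dtype=float)
    if len(x) != len(y):
        raise ValueError("predictor and response must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 paired observations")
    if np.all(x == x[0]):
        raise ValueError("Somers' D undefined: all predictor values are tied")
    if np.all(y == y[0]):
        # every pair is tied on the response: no concordant or discordant
        # pairs, but the denominator (pairs untied on x) is positive
        return 0.0, 1.0
    res = sps.somersd(x, y)  # first argument is the predictor (D of y given x)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def adjusted_group_effect(
    outcome: Sequence[float],
    arm: Sequence[int],
    baseline: Sequence[float],
) -> RegressionResult:
    """ANCOVA-style adjusted between-arm effect.

    OLS of the outcome (typically a change score, or a QALY) on an
    intervention indicator (1 = intervention) and the baseline value.
    The arm coefficient is the baseline-adjusted group effect; its p-value
    comes from the coefficient t statistic.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(arm, dtype=float)
    b = np.asarray(baseline, dtype=float)
    if not (len(y) == len(g) == len(b)):
        raise ValueError("outcome, arm and baseline must have equal length")
    if len(y) < 4:
        raise ValueError("need at least 4 observations to fit arm + baseline + intercept")
    if len(np.unique(g)) < 2:
        raise ValueError("both arms must be represented")
    X = sm.add_constant(np.column_stack([g, b]), has_constant="add")
    model = sm.OLS(y, X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design: baseline is collinear with the arm indicator")
    fit = model.fit()
    return RegressionResult(
        group_effect=float(fit.params[1]),
        standard_error=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        covariate_effects={"intercept": float(fit.params[0]), "baseline": float(fit.params[2])},
    )


def cohens_d_pooled(m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int) -> float:
    """Pooled-SD standardized mean difference (m2 - m1)/s_pooled.

    Raises on a zero pooled SD with unequal means (infinite effect).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in each group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if pooled_var == 0:
        if m1 == m2:
            return 0.0
        raise ZeroDivisionError("pooled SD is 0 with unequal means: effect size infinite")
    return (m2 - m1) / math.sqrt(pooled_var)


def _t_power(n_per_group: int, effect: float, alpha: float) -> float:
    """Power of the two-sided two-sample t test at per-group size n."""
    df = 2 * n_per_group - 2
    nc = effect * math.sqrt(n_per_group / 2.0)
    t_crit = sps.t.ppf(1 - alpha / 2, df)
    return float(1 - sps.nct.cdf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc))


_N_CAP = 1_000_000
_N_FLOOR = 2  # variance estimability


def sample_size_two_arm_t(
    delta: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.8,
    dropout_rate: float = 0.0,
) -> SampleSizePlan:
    """Smallest balanced two-arm plan achieving the target power.

    Iterates the noncentral-t power over per-group n (floor 2). Dropout
    inflation divides the total by (1 - dropout_rate) and rounds up to the
    next even integer so arms stay balanced.
    """
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    effect = delta / sd
    n = _N_FLOOR
    while _t_power(n, effect, alpha) < power:
        n += 1
        if n > _N_CAP:
            raise RuntimeError("target power unattainable within iteration cap")
    n_total = 2 * n
    inflated = n_total / (1.0 - dropout_rate)
    n_total_inflated = int(math.ceil(inflated / 2.0)) * 2  # next even integer
    return SampleSizePlan(
        delta=delta,
        sd=sd,
        alpha=alpha,
        power=power,
        n_per_group=n,
        n_total=n_total,
        dropout_rate=dropout_rate,
        n_total_inflated=n_total_inflated,
    )


def sample_size_mann_whitney_are(
    d: float,
    alpha: float = 0.05,
    power: float = 0.8,
    are: float = MIN_ARE,
    dropout_rate: float = 0.0,
) -> SampleSizePlan:
    """Mann-Whitney plan via the ARE correction of the t-test plan.

    The per-group t-test n at standardized effect ``d`` is divided by the
    asymptotic relative efficiency and rounded up.
    """
    if not 0 < are <= 1:
        raise ValueError("are must be in (0, 1]")
    t_plan = sample_size_two_arm_t(delta=d, sd=1.0, alpha=alpha, power=power)
    n = max(int(math.ceil(t_plan.n_per_group / are)), _N_FLOOR)
    n_total = 2 * n
    inflated = n_total / (1.0 - dropout_rate) if dropout_rate else n_total
    n_total_inflated = int(math.ceil(inflated / 2.0)) * 2
    return SampleSizePlan(
        delta=d,
        sd=1.0,
        alpha=alpha,
        power=power,
        n_per_group=n,
        n_total=n_total,
        dropout_rate=dropout_rate,
        n_total_inflated=n_total_inflated,
        are_correction=are,
    )
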