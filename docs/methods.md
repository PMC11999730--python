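# Methods

This note records the scientific and numerical choices behind the
package: what each stage computes, the assumptions it makes, and where a
design question had more than one defensible answer.

## Study design being modelled

A two-arm, parallel-group pilot randomised trial (10 randomised per arm)
comparing a multidimensional adherence decision aid against usual
occupational-therapy care for compression-stocking wear in people with a
history of venous leg ulceration. Measurements are taken at baseline and
at a 6-month review. Analysis is by intention to treat: participants are
analysed in their randomised arm, and anyone missing the review
contributes available baseline data only.

## Decision-aid scoring

**Eligibility screen.** Five questions, each scored 0–4, summed;
eligibility requires a total *strictly greater* than 3. The strict
inequality matters at the boundary: a total of exactly 3 is ineligible.

**Top-3 barrier selection.** The questionnaire returns a severity 1
(mild) to 5 (severe) for each applicable barrier from a 24-item
catalogue; absent responses are treated as severity 0 and are never
selected. Selection takes the three highest raw severities — no
re-weighting is applied, since none is specified by the instrument. The
clinical tool leaves equal-severity ties at the cutoff to clinician
discretion; for reproducibility the implementation breaks ties by
ascending barrier id and raises a `tie_flag` with a discretion note, so
the judgement point is surfaced rather than silently decided. The three
selected barriers are contractually *unordered* for display; the internal
order exists only to make output deterministic. Twelve catalogue items
carry the labels observed in the trial tables; the remaining twelve are
placeholders, since the full item text is outside this package's scope.

**Resource recommendation.** A pure lookup from barrier id to configured
resource labels (information sheets, video links, clinical
considerations). The map must cover the catalogue; a missing entry is a
configuration error, not a silent skip.

## Adherence measurement

The primary quantity is the percentage of waking hours stockings are
worn:

```
pct = (hours worn / hours awake) × (days per week / 7) × 100
```

computed per leg and averaged when both legs are reported, clamped to
[0, 100].

Self-reported times often arrive as ranges ("12–14 hours"). Scalar
resolution is **conservative by default**: worn hours resolve to the
lower bound, awake hours to the upper bound, days per week to the lowest
reported value. The bias direction is therefore uniform (adherence is
never overstated), and the full `[min %, max %]` interval over all
admissible resolutions is exposed for sensitivity auditing. A `midpoint`
mode (range midpoints for the hour quantities) is provided as the
alternative reading; days always resolve to the minimum in both modes.

Degenerate inputs: worn hours exceeding awake hours are clamped to awake
hours with a warning (self-report noise should not produce > 100 %);
awake = 0 with worn = 0 scores 0; awake = 0 with worn > 0 raises an
undefined-ratio error.

**Four-level banding.** The percentage is rounded half-up to a whole
percent and banded: ≤ 10 → 0, 11–50 → 1, 51–90 → 2, ≥ 91 → 3. The
printed band nominally starts at 1 %, but 0 % is assigned to category 0
so the function is total on [0, 100]. The clinician-assigned four-level
score (0 None, 1 Intermittent, 2 Most Days, 3 Fully Comply) is an input
carried through unchanged, never derived from wear data.

**Barrier resolution.** Each identified barrier earns points at 6 months:
1 — not addressed, not resolved; 2 — not addressed but resolved; 3 —
addressed, not resolved (an attempt was made); 4 — addressed and
resolved. A participant's Mean Barrier Resolution Score is the arithmetic
mean over their barriers (to 2 decimals), which normalises across
participants with fewer than three barriers. Group summaries pool
category counts; the bookkeeping identity
`Σ_participants (mean score × barrier count) = Σ_categories points × count`
is enforced by test.

## Trial statistics

**Mann–Whitney U** (two-sided) compares the ordinal adherence changes
between arms. For pooled samples of at most 20 with no ties the p-value
is exact (full permutation null); otherwise the midrank normal
approximation with tie and continuity corrections is used — the trial's
four-level data are heavily tied, so the asymptotic path is the practical
one. The reported statistic is the classical U = min(U₁, U₂). The test
suite checks the exact path against an independent brute-force
enumeration of all group assignments.

**Somers' D.** The directed association D(Y|X) = (C − D) / (pairs untied
on X), with the Mean Barrier Resolution Score as predictor X and the
four-level adherence change as response Y, pooled across both arms.
Asymptotic p-value. A constant predictor leaves D undefined (error); a
constant response gives D = 0 exactly. Checked against an explicit
pair-counting oracle.

**Baseline-adjusted group effects.** Secondary outcomes are analysed
ANCOVA-style: ordinary least squares of the change score on an
intervention indicator plus the baseline value; the arm coefficient is
the adjusted effect and its t statistic supplies the p-value. Modelling
the change score with a baseline covariate (rather than the follow-up
level) is one admissible reading of "univariate regression adjusting for
baseline"; it is algebraically equivalent to the follow-up-level model up
to a shift of the baseline coefficient by 1 and yields the identical arm
coefficient.

**Effect size.** Pooled-SD Cohen's d,
`d = (m₂ − m₁) / s_p`, `s_p² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)`.
The per-arm four-level change summaries (−0.60 ± 1.07, n = 10 vs
1.00 ± 0.86, n = 9) give d = 1.64 to two decimals.

**Sample size.** The two-arm t-test plan finds the smallest per-group n
(floor 2, for variance estimability) whose two-sided noncentral-t power
at noncentrality (δ/σ)√(n/2) with 2n − 2 degrees of freedom reaches the
target; δ = 1, σ = 1.14, α = 0.05, power 0.8 gives 22 per group, 44
total. Dropout inflation divides the total by (1 − rate) and rounds up to
the next *even* integer to keep arms balanced (44 / 0.8 = 55 → 56). The
Mann–Whitney plan divides the t-test per-group n by an asymptotic
relative efficiency and rounds up; the default ARE is 0.864, the
distribution-free minimum, chosen because the parent distribution behind
the method is unspecified (the normal-shift value would be 3/π ≈ 0.955).
At d = 1.64 this gives ⌈7 / 0.864⌉ = 9 per group, 18 total. The t-test
iteration is cross-checked against `statsmodels`' independent power
solver in the tests.

## Cost-utility analysis

Costing is from the health-service perspective over the 6-month trial
window: appointments at AUD 193 (face-to-face) and AUD 177
(phone/telehealth), materials (stockings, applicators, postage) at
explicit unit costs or catalogue prices, and configurable unit prices for
specialist VLU appointments and admissions (zero usage in the pilot).
Currency is reported to 2 decimals; internal arithmetic keeps full
precision. No discounting is applied — the horizon never exceeds one
year.

QALYs are the area under the EQ-5D-5L utility curve over a 1-year
horizon: a trapezoid from baseline to the 6-month measurement, then the
6-month value extrapolated over the second half-year. The default
extrapolation is last-observation-carried-forward; a linear-trend
continuation (clamped to the utility bounds [−0.6, 1.0]) is available,
since "extrapolated to one year" admits either reading. A missing
6-month utility carries baseline forward and is flagged; a missing
baseline utility excludes the participant from the QALY analysis with a
note.

Because the arms were imbalanced in baseline utility, the incremental
QALY is the arm coefficient of an OLS fit of participant QALY on arm +
baseline utility — this adjusted Δ QALY can differ in sign and magnitude
from the raw per-arm difference. ICER = Δ cost / adjusted Δ QALY, with
the (Δ cost, Δ QALY) sign pair classified on the cost-effectiveness
plane: dominant (cheaper, more effective), dominated (dearer, less
effective), or a trade-off quadrant where the north-east case is
cost-effective iff ICER ≤ the willingness-to-pay threshold (default
AUD 28,033 per QALY).

## Synthetic cohort generator

The generator emulates the pilot's data structure so the pipeline is
fully testable without participant-level data. Its defaults are the
pilot's printed per-arm summaries: adherence percentage baseline
52.09 ± 11.74 (usual care) and 19.51 ± 7.23 (intervention) with changes
−24.82 ± 37.42 and +38.574 ± 23.47; EQ-5D-5L utility baselines
0.70 ± 0.34 and 0.59 ± 0.42 with changes −0.054 ± 0.19 and
+0.17 ± 0.30; barrier counts of 1–3 per participant (0.1/0.0/0.9,
matching one single-barrier participant in ten); per-arm
addressed/resolved rates 8/28 and 1/8 (usual care) versus 1.0 and 18/25
(intervention), with nothing resolving unaddressed; Poisson appointment
counts at rates 1.9/0.5 and 2.89/1.22 (face-to-face/phone); and uniform
materials costs with per-arm means 202.36 and 323.81 (range 0 to twice
the mean — the summaries report only means, and the uniform is the
simplest bounded distribution consistent with them). Severities are
uniform over 1–5 (the severity distribution was not reported).

**Moment-matched truncation.** Percentages must lie in [0, 100] and
utilities in [−0.6, 1.0], yet the configured means are moments of
bounded data — at these parameter values a naive sample-then-clamp
scheme is visibly biased (roughly a quarter of naive usual-care
follow-up percentage draws would fall below zero, shifting the realized
change mean by several points). The generator therefore treats
configured means as realized moments: the baseline's truncated-normal
location is solved (Brent's method on the truncated mean) so the
truncated mean equals the configured mean, and the change draw's latent
location is solved so that the clamped follow-up (baseline + change)
reproduces the configured change mean, integrating the censored-normal
mean over the baseline density by 200-point Gauss–Legendre quadrature.
Realized SDs are consequently slightly below the configured latent
scales. Truncated sampling itself is by rejection, which respects the
bounds exactly.

Wear reports are back-solved from the target percentage with hours
awake fixed at 16 h/day, wear on 7 days/week, and equal wear on both
legs (worn = pct/100 × 16, rounded to 0.001 h), making the generator
exactly invertible through the adherence formula.

**What the generator does not emulate**, and hence what passing tests do
not establish about real data: within-person correlation between
baseline and change (changes are drawn independently; the pilot's
correlation is unreported), correlation between barrier resolution and
adherence change (drawn independently, so the generator is a null model
for the Somers' D association, not a replica of the observed 0.471),
ranged or per-leg-asymmetric wear reports, clinician scoring behaviour
for the unmodified four-level item, and VLU recurrence events (none
occurred in the pilot; specialist and admission counts are fixed at
zero). Follow-up missingness is off by default (`p_missing_followup`),
so the default cohort corresponds to the analysed, not the randomised,
population.

## Problem sizes in the test suite

Deterministic worked numbers run at their natural size. Stochastic
parameter-recovery checks use 500–2000 participants per arm — large
enough that a 3-standard-error criterion is sharp, small enough that the
whole suite runs in seconds. Brute-force oracles run where enumeration
is cheap: all Mann–Whitney group assignments up to pooled n = 8, Somers'
D pair counting up to n = 12.

## Known limitations

- The usual-care per-participant barrier outcomes used in the worked
  summaries are a reconstruction from published per-participant means
  and pooled category counts; the reconstruction is unique given the
  zero count in the 2-point category, but it is not source data.
- The printed per-arm mean QALYs in the source tables are not
  reproducible from the printed group-mean utilities because effective
  ns differ across timepoints; the pipeline reports per-participant
  QALYs and their adjusted difference instead of matching those cells.
- Clamping at the utility ceiling induces a small negative within-arm
  correlation between baseline and change in the generator, which
  attenuates baseline-adjusted (ANCOVA) estimates on generated data by
  ≈ 0.02 QALY at the pilot's parameter values; raw change differences
  are unbiased. Regression recovery is therefore verified on direct
  unbounded simulated designs.
- The exact Mann–Whitney path covers only untied samples; tied small
  samples use the tie-corrected asymptotic approximation (an
  exact-with-ties enumeration exists in the test suite as an oracle
  only).
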