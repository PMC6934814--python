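# Methods

`dietlag` implements a distributed-lag "calculator" linking yearly
macronutrient availability to a yearly ecological correlation series, a
confidence-sequencing procedure for the estimated lags, and a
diet-composition optimizer driven by the fitted equation. This note records
the model, the algorithmic and numerical choices, what the synthetic
generator does and does not emulate, and the known limitations.

## The model

The response series R(t) is, for each calendar year t, the Pearson
correlation across US states between that year's per-capita personal income
(PCPI) and the state's fixed 2005 age-adjusted Alzheimer's death rate
(AADR). The predictors are five per-capita availability series x_i(t) in
grams/day — carbohydrates, protein, saturated, monounsaturated and
polyunsaturated fat — each acting with an unknown whole-year delay l_i
("precedence period"):

    R(t) = α + Σ_i f_i( x_i(t − l_i) ) + ε(t)

The smooth additive terms f_i are linearized, so each fit is ordinary least
squares of R(t) on an intercept and the five lag-shifted columns. The fit
statistic is the non-negative multiple correlation r = √R², unadjusted; for
a constant response it is defined as 0 with zero coefficients. Within a
life period (youth 1929–1949, early middle age 1949–1970, late middle age
1970–1990, late age 1990–2005 — boundary years inclusive on both ends, so
adjacent periods share a year), every lag vector on the grid
{0,…,max_lag}⁵ is fitted and the vector with the highest r is selected
("global optimization"); max_lag = 20 gives 21⁵ = 4,084,101 fits per
period.

Assumptions inherited from the study design: availability is proportional
to mean consumption; the response's oscillations are attributable to
lagged consumption; effects are additive and linear in grams over the
fitted range; one lag per nutrient, constant within a life period.

## Exhaustive scan: algorithm

A naive scan performs 4,084,101 separate least-squares fits. The package
exploits two structural facts:

1. With contiguous years, a response year t is usable for lag vector l iff
   t − max(l) does not precede the availability span; the usable window
   therefore depends only on m = max(l). Vectors are grouped by m, and each
   group shares one response window.
2. Within a group, the R² of a vector depends only on centered inner
   products of lagged columns. The scan precomputes, per group, the Gram
   table C[i,k,j,k′] = ⟨x̃_i(·−k), x̃_j(·−k′)⟩ and the response products
   c[i,k] = ⟨x̃_i(·−k), R̃⟩ over the shared window (tildes denote centering),
   then evaluates each vector by a batched 5×5 normal-equation solve:
   R² = sᵀ S⁻¹ s / s_yy with S and s gathered from the tables.

This is algebraically identical to per-vector OLS; the equivalence is
enforced by tests against direct fits (exact agreement on small grids,
≤ 1e-9 on a random 1% subsample of the full grid). Near-singular systems
fall back to the Moore–Penrose pseudoinverse, which leaves R² unchanged
(same fitted subspace); R² is finally clipped to [0, 1] to absorb
round-off. Vectors whose window has fewer than `min_rows` = 7 usable years
(parameters + 1) are recorded as unusable, never silently skipped, and the
usable/unusable counts always sum to the grid size. Ties on r are broken
by the lexicographically smallest lag vector, making the result
deterministic and independent of evaluation order. One full 21⁵ scan on a
77-year window takes a few seconds on one CPU.

Coverage policy: by default years lacking lagged coverage are dropped per
vector (complete case within combination); a `common_window` option
restricts every vector to the window usable at max_lag instead. The
historical record does not state which convention the original analysis
used; the default maximizes data use and is configurable.

## Confidence sequencing

For each nutrient, the scan grid is regrouped by that nutrient's lag k:
pooling r over all combinations of the other nutrients' lags gives Rmean(k)
and its sample SD. Three criteria nominate a lag — the component of the
globally optimal vector, argmax Rmean, argmin SD of Rmean (ties toward the
smaller lag; lags with no usable combination are excluded) — and the sample
(n−1) SD of the three nominations is mapped to stars: [0,2) → ***, [2,5) →
**, [5,8) → *, [8,∞) → none. The half-open lower-inclusive boundaries are a
package choice; the printed ranges ("from 0 to 2", "from 2 to 5") are
ambiguous at the joints. Sample rather than population SD is likewise a
choice, the conservative one.

Empirical behaviour worth knowing: the Roptimal criterion is sharp — on
noiseless synthetic data it recovers the true lag exactly — but the two
auxiliary criteria are driven by averages over mostly-wrong lag
combinations and carry finite-sample fluctuation of order 1/√n per lag
column. All three criteria agree at the truth only when every nutrient's
contribution to response variance clearly exceeds that fluctuation and
lag-shifted columns are statistically distinguishable. Under the stationary
validation generator (below) the all-nutrient top-confidence property holds
for ≈96–98% of random ground truths; the argmin-SD criterion accounts for
the remainder. With realistic slowly-trending availability the auxiliary
criteria disagree more often — which is precisely the gradation the star
scale is designed to express.

## Diet optimization

Candidate diets live on a per-nutrient gram grid; the default bounds are
[0.5·min, 1.5·max] of the period's observed grams snapped outward to the
step, with steps (5, 5, 5, 5, 1) g — polyunsaturated fat gets the finer
step because its realistic range is narrower than one 5 g step. Each diet
g is scored by the linear calculator prediction α + Σ β_i g_i, deliberately
not clamped to [−1, 1]: it is a model extrapolation and clamping would
hide how far outside the fitted range a diet sits.

Selection is two-stage: diets within `r_tolerance` (default 0.01) of the
grid optimum of the objective form the candidate band; within the band the
diet minimizing the energy difference from the period's mean availability
wins, ties broken by the lexicographically smallest gram vector. The energy
difference between diets a and b is Σ_i κ_i |a_i − b_i| with κ = (4, 4, 9,
9, 9) kcal/g — the absolute convention, which makes it a metric; a signed
variant (surpluses cancel deficits) is available by flag. The mean
availability uses no lag shifting. Reported diets (predicted and mean) are
rescaled to a common 2000 kcal after optimization, and grams/percents are
rounded half-up to integers at report time only.

Two objectives are provided. The default minimizes the signed prediction
(most negative wins, consistent with the goal of weakening the
income–mortality coupling); an alternative drives the prediction toward
zero (|R| → 0). With a linear equation the signed objective is minimized at
a corner of the grid box, so on wide default bounds it produces extreme
compositions far from the historical mean; the |R| → 0 objective selects
from an interior slice and lands close to the mean (see
`examples/04_diet_optimization.py` for the contrast). The exact rule used
to produce the published diet tables is not restated in the available
description; the two-stage band policy is this package's documented,
deterministic surrogate, and both objectives are exposed.

The grid scan is chunked and two-pass (first the objective optimum, then
the band/energy selection), enumerates in lexicographic order for
deterministic tie-breaking, and matches a naive materialize-everything
enumeration exactly on grids up to 10⁵ diets (tested); ~10⁸-diet grids run
in seconds.

## Synthetic data

The generator exists so every stage can be validated against known ground
truth. Availability panels are per-nutrient trend curves (baseline + linear
slope + one sinusoid) plus iid Gaussian noise, clipped at zero; the
response is α + Σ β_i x_i(t − l_i) + ε with iid Gaussian ε, clamped to
[−1, 1]. All randomness flows through numpy's seeded PCG64 generator, so
every dataset is reproducible cross-platform from its seed.

Two configurations are distinguished:

- `DEFAULT_TRENDS` (+ noise SD 5 g) emulates the look of the historical
  series: slow multi-decade swings in the hundreds-of-grams range for
  carbohydrates, tens for protein and fats.
- `VALIDATION_TRENDS` (+ noise SD 10 g) is stationary: constant baselines
  with iid variation. Ground-truth studies use it because lag
  identifiability requires year-to-year variation to dominate the smooth
  trend within a fitting window — under a slow trend, x(t−k) and x(t−k±1)
  are near-duplicates and no estimator can separate them.

Random ground truths balance the per-nutrient coefficients by the inverse
of each column's expected variability, so each nutrient contributes a
comparable share (~0.08 correlation units SD, ±10%) of response variance;
gram-for-gram equal coefficients would let carbohydrates dominate and make
the weak nutrients' lags unidentifiable in principle. The intercept is
calibrated against the trend baselines so the noiseless response stays
within [−1, 1] (the validation configuration uses extra head-room); a
clamped year would make an otherwise exact linear response inexact.

What passing validation shows — and does not show. It shows the machinery
is correct: exact recovery with R = 1 on exactly-linear responses, ±1-year
recovery under response noise of SD 0.05 over 77 years, oracle-identical
aggregation and selection. It does not show that the historical series
identify their lags with comparable sharpness: the real availability
series are smoother, their effective per-period sample sizes smaller
(16–22 years), and the true response need not be linear or additive. The
star procedure, not the point estimates, is the instrument the method
offers for that uncertainty.

The state-panel generator emulates the construction of the response from
raw state data: state incomes follow heterogeneous exponential growth with
log-normal levels; the per-state death rate is a mixture coupling·z +
√(1−coupling²)·noise with z the standardized final-year income, so the
cross-state correlation in the coupled year equals `coupling` in
expectation. The per-year cross-state Pearson helper emits NaN with a
warning for years where income is degenerate (constant across states).

## Validation problem sizes

The shipped studies use: max_lag 5 (7,776-vector grids) for recovery and
confidence studies over the full 77-year window — 10 noiseless truths, 50
noisy replicates, 25 nutrient-confidence summaries; one full max_lag 20
scan (4,084,101 vectors) cross-checked against direct fits on a random 1%
subsample (40,841 vectors); diet-optimizer equivalence on a 10⁵-diet grid
and pipeline runs on ~10⁸-diet default grids. These sizes were chosen so
the entire validation suite completes in well under a minute per study
while exercising every code path at full scale at least once.

## Known limitations

- The linear calculator extrapolates freely; predictions far from the
  fitted range (notably under the signed objective on wide grids) should
  be read as directions, not attainable correlations.
- The confidence procedure's auxiliary criteria are finite-sample noisy;
  even on ideal data the argmin-SD criterion occasionally nominates a
  far-off lag (~2–4% of random truths under the validation generator).
- Per-period windows of 16–22 years with six estimated parameters leave
  10–16 residual degrees of freedom; r values near 1 on real data partly
  reflect in-sample absorption by five free lag choices, which the
  Rmean/SD machinery only partially discounts.
- The 1 g polyunsaturated step and the [0.5·min, 1.5·max] grid bounds are
  package defaults for an under-specified part of the original procedure;
  results in the corner-seeking regime are sensitive to the bounds.
- No alcohol term, no animal/plant protein split, no micronutrients; five
  aggregate macronutrients only.
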