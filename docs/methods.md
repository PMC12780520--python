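# Methods

This note documents the models, the parameter choices that matter, the
numerical decisions, and what the synthetic generator does and does not
emulate.

## z-score engine

Measurements convert to z-scores by the LMS parameterisation of the WHO
child growth standards: for a measurement `y` with reference Box-Cox
power `L`, median `M` and coefficient of variation `S` at the child's
axis value,

    z = ((y/M)^L − 1) / (L·S),        z = ln(y/M)/S  when |L| < 1e−8.

The inverse is `y = M·(1 + L·S·z)^(1/L)` (or `M·exp(S·z)`); the pair
round-trips to < 1e−10 SD, which the tests enforce over randomized valid
parameters.

* **Axes.** HAZ and WAZ key on age in months (decimal; day-keyed tables
  are converted at load with 30.4375 days/month, matching how DHS stores
  completed months). WHZ keys on recumbent length below 24 months and
  standing height from 24 months.
* **Position correction.** When the measurement position is known and
  disagrees with the age convention, 0.7 cm is added to a standing
  measurement under 24 months and subtracted from a recumbent one at 24
  months or older, before any lookup (the corrected stature feeds both
  HAZ and WHZ). Unknown position assumes the convention. The correction
  can be disabled.
* **Interpolation.** L, M and S interpolate piecewise-linearly and
  independently between knots; knot values reproduce exactly; no
  extrapolation — out-of-range lookups yield a missing component, never a
  guess.
* **Restricted adjustment.** WAZ and WHZ (never HAZ) are linearised
  beyond |z| = 3: for z > 3, `z* = 3 + (y − SD3)/(SD3 − SD2)` with SD2,
  SD3 the measurements at z = 2, 3 from the inverse transform (mirrored
  below −3). It is the identity on [−3, 3] and continuous at the edges.
  Category thresholds sit at ±2, so classification is unaffected; only
  extreme-value handling and the plausibility screen see adjusted values.

## Plausibility screen and taxonomy

Records need all three indices to enter the taxonomy; incomplete records
receive an `excluded_incomplete` disposition, mirroring complete-case
anthropometric eligibility. Outlier bounds are inclusive: a record is
excluded only strictly beyond |HAZ| = 6, |WHZ| = 5, WAZ = −6 or WAZ = +5.

Deficit predicates are HAZ ≤ −2 (stunted), WHZ ≤ −2 (wasted), WAZ ≤ −2
(underweight); the excess predicate is WAZ ≥ +2 or WHZ ≥ +2. The printed
convention describing normal as "−1.99 to +1.99" is read as the open
interval (−2, +2). Category resolution, in priority order: CUWS, CUS,
CUW, CSO (stunted + excess, not underweight), then the flagged or
standalone cells, then normal. Three z-space cells fall outside the
underweight- and stunting-anchored taxonomy and are resolved
deterministically with a conflict flag so users can tabulate them:

| pattern | category | flag |
|---|---|---|
| stunted + wasted, not underweight | stunting | `stunted_wasted_not_underweight` |
| underweight with WHZ ≥ +2 | CUS if stunted, else underweight | `underweight_with_overfeeding_pattern` |
| wasted with WAZ ≥ +2 (or stunted+wasted+WAZ ≥ +2) | wasting / CSO | `multiple_standalone` |

These precedence rules are this package's documented choices for cells
the taxonomy leaves unnamed, not inferred intent; flags let any
alternative tabulation be reconstructed. The classifier is verified cell
by cell against an independent hand-written predicate lookup table over
a dense z-grid.

## Survey estimation

Prevalence is the Horvitz–Thompson ratio `100·Σw·1[case]/Σw`. The CI
method in the surveillance literature is typically unstated and CIs are
not reproducible from n and p alone, so the package makes its own
documented choice: a Wilson score interval evaluated at the Kish
effective sample size `(Σw)²/Σw²`, with Wald as an option. This absorbs
weight variability but not cluster correlation — full Taylor-linearised
design variance is out of scope, so intervals should be read as
approximate under strong clustering.

Survey weights are only relatively scaled within a survey, so pooled
(regional/global) estimates rescale each country's weights; the default
"sample-size pooling" gives each country mass equal to its unweighted n
(making pooled estimates invariant to any country's arbitrary weight
scale, which the tests check); "population pooling" accepts explicit
country shares when true population weighting is wanted.

## Association models

Chi-square screening uses Pearson's X² on complete pairs (unweighted
counts), passing covariates at p ≤ 0.05. The multinomial logit is fitted
by Newton–Raphson on the stacked score: convergence at max |score| <
1e−8 or relative log-likelihood change < 1e−10, at most 100 iterations,
with step-halving so the log-likelihood never decreases. A two-level
outcome reduces exactly to binary logistic regression (verified against
an independently coded IRLS and against statsmodels). Coefficients
exceeding 15 in absolute value are treated as separation; the fit is
redone with a ridge penalty of 1e−6 and flagged. Wald 95% CIs are
`exp(β ± 1.96·se)` from the inverse observed information.

Model structure: one 4-level multinomial {underweight (ref), CUW, CUS,
CUWS} on the underweight-anchored subpopulation, and one binary
{stunted (ref), CSO} on the stunting-anchored one. Which records form
each risk set is configurable; the default uses exactly the children in
the named categories. Backward elimination removes whole covariate
blocks (all dummy levels, jointly across outcome equations) by
likelihood-ratio test, worst p-value first, until every remaining block
has p ≤ α = 0.05; the elimination order is recorded. Regressions are
unweighted by default with a weighted option. VIFs are computed on the
dummy-coded matrix and reported as diagnostics (the conventional < 2
reading is not enforced); exact collinearity reports an infinite
sentinel rather than raising.

## Synthetic generator

Each child's latent (HAZ, WAZ, WHZ) is trivariate normal: baseline mean
plus country shift plus additive covariate shifts, with WAZ structurally
coupled as `0.55·HAZ + 0.55·WHZ + ε`, sd(ε) = 0.4 — loadings chosen to
mimic the arithmetic dependence of weight-for-age on the other two
indices; the default marginals (HAZ sd 1.3, WHZ sd 1.1, HAZ–WHZ
correlation −0.1, baseline means (−1.1, −1.05, −0.35)) are in the range
typical of LMIC child surveys. Sampling weights are gamma(4, 0.25)
(mean 1, moderate variability); clusters are equal-sized within country.
The default six-region scenario's country shifts make the regional
ordering qualitatively echo published LMIC patterns (South/Southeast
Asia worst off, Latin America and Central Asia best); the magnitudes are
illustrative only and never a target.

**Two emission modes.** In `zscores` mode records carry the latent triple
directly (as a survey with precomputed z-scores). In `measurements` mode
the latent (HAZ, WHZ) pair is inverted through the toy growth reference
to stature and weight, and WAZ is then *derived* from weight and age
through the weight-for-age table — exactly as the pipeline recomputes it,
and exactly as in real data, where three indices share two free
measurements. The structural noise ε is therefore inactive in
measurement mode.

**Toy reference construction.** The bundled reference uses the
log-normal LMS limit (L = 0 at every knot, 0.5-month/0.5-cm knots) with
a logarithmic height-for-age median, a power-law median weight-for-
stature curve (`M_w ∝ h^2.2`) and the weight-for-age median defined as
their composition. In log-space a power law composes linearly, so the
table-derived WAZ equals `0.55·HAZ + 0.55·WHZ` by construction (knot
interpolation keeps the deviation below ~2e−3 SD inside the
classification band), and the trivariate-normal oracle applies to both
modes. This is why L = 0 was chosen over a varying L: any curvature in L
would introduce an interaction term between HAZ and WHZ in the derived
WAZ and break the closed-form oracle. Randomized-L correctness of the
LMS engine is tested directly on the transform functions instead.

**Truth.** Stored truth is produced by the package's own forward chain
(in measurement mode including the z-score engine), so the end-to-end
test "pipeline reproduces generator truth exactly" is well-posed; the
*distributional* correctness of that chain is established separately by
comparing realized prevalences with the latent-normal oracle.

**Oracle.** `expected_category_probabilities` has two independent
numerical routes: plain Monte-Carlo (default 1e6 draws, binomial SE;
works for singular covariances) and an exact decomposition of every
category region into at most two axis-aligned boxes integrated with the
multivariate normal CDF (accuracy ~1e−5). The tests compare the two
routes and a third, independently coded dense Riemann grid. Planted
odds-ratio calibration bisects on the CDF route for the latent mean
shift (default direction: a structural HAZ shift, which drags WAZ along
by its 0.55 loading) whose implied category odds ratio equals the
target; resolution is limited by the CDF accuracy, roughly 1e−4 in the
shift.

**What the generator does not emulate.** Real z-distributions are
skewed and heavier-tailed than a normal; digit preference, age heaping
and measurement error are absent; clusters carry no intra-cluster
correlation beyond labels; covariates are drawn independently of each
other. Passing tests therefore demonstrate correctness of the analytic
chain under its stated assumptions, not robustness to real-data
artefacts.

## Problem sizes and determinism

Default verification sizes: the classifier grid uses ~91k triples; the
planted-OR recovery runs at n = 50,000 over five seeds; elimination
operating characteristics use 200 simulations at n = 5,000; the
end-to-end chain uses a 12,000-child six-country scenario against a
1e6-draw oracle. These sizes make Monte-Carlo error small relative to
the assertions while keeping the default suite fast. Every random draw
flows from an explicit integer seed through `numpy.random.default_rng`;
re-running with the same seed reproduces records, reports and fitted
models byte for byte.

## Known limitations

* No severity grading (severe vs moderate) and no separation of
  overweight from obesity; no MUAC, head-circumference or BMI-for-age
  standards.
* CIs ignore cluster-level design effects (see above).
* The DHS dialect covers the variable/sentinel conventions of a
  child-recode CSV export, not proprietary container formats.
* Whether the published excess criterion for standalone
  overweight/obesity uses WHZ only or WAZ-or-WHZ is ambiguous in the
  surveillance literature; this package generalises the CSO "and/or"
  rule to the standalone category as well, and flags the contradictory
  cells it creates.
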