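# Methods notes

Design and modelling choices, their rationale, and known limits. Everything
here is implemented in `src/illusiongame/`; all numbers are defaults that can
be overridden through `DesignConfig` / `PopulationConfig` or function
arguments.

## Stimulus geometry

Each illusion is generated as a *geometry plan*: a tuple of vector primitives
(segments, circles, rectangles) tagged `target` or `context`, plus the correct
2AFC response. Two parameters control every plan:

- **difficulty** — the objective physical difference between the two targets
  in the illusion's native units (relative radius difference, length ratio,
  angle, luminance gap). Larger = easier.
- **strength** — signed context intensity. Positive = incongruent (context
  biases against the correct answer), negative = congruent, 0 = neutral.

Invariants enforced by construction and covered by tests:

- *Neutral symmetry*: at strength 0 the context is mirror-symmetric, so the
  stimulus carries no directional bias. For Poggendorff the neutral transversal
  slope keeps the sign it has in the limit strength → 0⁺, so the family is
  continuous in strength.
- *Round-trip*: difficulty and |strength| are recoverable from the primitives
  to 1e-9, which keeps the generator honest (no hidden renormalisation).
- *Canvas bounds*: all coordinates stay inside the unit canvas.

The White-illusion grating uses **10 stripes** (an even count). With an odd
count, mirror-symmetric bar positions land on same-luminance stripes, which
makes it impossible to put the two bars on opposite phases while keeping the
neutral mirror-symmetry invariant.

## Study design

134 stimuli per illusion: series A (even-index difficulty levels × odd-index
strength levels, 56 trials), series B (odd-index difficulties × even-index
strengths plus the neutral level, 72 trials), and 6 practice items; 1340 trials
per participant over 10 illusions. Strength grids have 15 levels (7 congruent,
neutral, 7 incongruent); difficulty grids have 16 levels.

Level spacing supports linear, square, cubic and an "exponential" warp
g(t) = 0.7·t + 0.3·t², chosen because it maps the documented worked example
[0.1, 0.4, 0.7, 1.0] → [0.1, 0.34, 0.64, 1.0] exactly (constant second
differences; a true geometric progression does not reproduce that sequence).

## Response simulator

Per participant *p* and illusion *i*, the error probability on a trial is a
lapse-mixed logistic:

```
eta = alpha_p - beta_d,p · f_d + beta_s,p,i · f_s + beta_sd,p,i · f_d·f_s - c_p · f_congruent
P(error) = lapse/2 + (1 - lapse) · logistic(eta)
```

where `f_d`, `f_s` are the illusion's documented transforms of difficulty and
strength (log/sqrt/cbrt/identity per illusion), min–max normalised on the
positive design grid and **anchored at the smallest positive design strength**
(`f_s = 0` for all s ≤ s_min, so the log transform stays finite and the neutral
level is the reference). Because the transforms are affine on the positive
grid, the scoring module's standardized design spans the generative model
exactly — recovery tests can compute noise-free true coefficients by linear
projection.

Individual differences: `beta_s` loads on a latent general factor g with
per-illusion loadings λ_i (uniform in [0.3, 0.8] by default), and the
interaction coefficient loads at 0.7·λ_i. Reaction times are ex-Gaussian with
difficulty and strength effects, including a quadratic strength term (fast,
confidently wrong answers at extreme strengths).

Defaults: `alpha ~ N(-3.0, 0.5)`, `beta_d ~ N(2.2, 0.4)`,
`beta_s = 2.8 + 2.0·(λ_i·g + sqrt(1-λ_i²)·e)`, `beta_sd ~ N(-1.0, 0.6)`,
lapse 0.02, ex-Gaussian (600, 80, 250) ms. The average participant's errors run
from a few percent on easy neutral trials to ~45% on the hardest, strongest
incongruent trials. The between-person spread `beta_s_sd = 2.0` was sized by a
forward design calculation (Fisher information of the per-participant logistic
over the 56 incongruent design trials plus a Monte-Carlo population draw):
smaller spreads leave per-participant slopes unidentifiable from one session
(reliability ceiling < 0.6² for the worst illusion), wider spreads imply an
implausibly large reverse-susceptible tail. Large individual differences in
illusion susceptibility — including occasional reversed effects — are
consistent with the individual-differences literature.

`inject_artifacts` adds three contaminant types for pipeline validation
(random responders, inverted-instruction blocks, implausibly fast trials) and
returns an audit of what was injected.

## Preprocessing

Mirrors standard practice for this task family:

1. **Participant screening**: error rate ≥ 0.45 (near-chance responding) or
   mean RT implausibly fast relative to the sample (4 robust spreads below
   center).
2. **Block exclusion**: blocks (participant × illusion × series) with
   strictly more than 50% errors — the signature of inverted instructions.
3. **Trial exclusion**: RT < 125 ms, and RT above mean + 4 SD. The slow-tail
   rule is iterated to a fixed point so the result does not depend on how many
   extreme outliers were present initially; exclusion thresholds are computed
   per participant.

The cleaning report is JSON-serialisable and the pipeline is idempotent
(cleaning cleaned data changes nothing).

## Scoring

Incongruent, non-practice trials only (56 per illusion). For each participant
and illusion, a logistic model with standardized transformed difficulty,
transformed strength and their product is fitted by Newton iterations with a
ridge penalty (0.5) on the slopes only; step-halving guarantees monotone
objective ascent. The reported covariance is the **sandwich form**
`inv(F+P)·F·inv(F+P)` (F = Fisher information, P = penalty), the asymptotic
covariance of the penalized estimator; the naive `inv(F+P)` overstates the
sampling variance of a shrunk estimate, which would drive the downstream
moment estimate of population variance to zero.

Empirical-Bayes shrinkage pulls each raw slope toward the population mean with
weight `tau² / (tau² + se²)`, where `tau²` is the method-of-moments estimate
`max(var(estimates) - mean(se²), 0)`. If `tau² = 0` the scores degenerate to
the grand mean (the data carry no evidence of individual differences on that
coefficient). Shrunk scores beat raw scores in RMSE against simulator truth.

Orientation checks (Spearman correlation of each score with the participant's
incongruent error rate) flip signs where necessary so that higher scores mean
more illusion-sensitive.

`compare_transforms` fits all 16 transform pairs as pooled unpenalized
binomial GLMs and ranks them by BIC, breaking ties toward simpler transforms.
**Known limit**: on the default design grids adjacent warps are nearly affine
(corr(sqrt, cbrt) ≈ 0.998 over the 16 difficulty levels), so the exact winner
between neighbouring transforms is not decidable at study size — the
generating pair reliably sits inside the conventional ΔBIC < 10 indecision
band but wins outright only when the grids span a wide (geometric) range.
Tests assert exactly that.

## Factor analysis

Principal-axis factoring with iterated communalities (SMC start from the
inverse correlation matrix; tolerance 1e-6, 200 iterations), varimax or
oblimin (direct quartimin, γ = 0) rotation via
`statsmodels.multivariate.factor_rotation`, and sign alignment so each
factor's dominant loading is positive. A singular correlation matrix raises an
error in `efa`; the level-2 extraction inside `hierarchical_factor_scores`
falls back to the largest absolute off-diagonal correlation per row as the
communality start, so degenerate small-sample score tables degrade gracefully
instead of crashing.

The number-of-factors suggestion is a majority vote of Horn's parallel
analysis (sequential rule: the count of leading eigenvalues before the first
one that drops below its resampled-null mean), the Kaiser criterion, and an
acceleration-factor scree reading; ties break toward parallel analysis.

Hierarchical scores: level-1 composites average the two standardized
indicators per illusion (sign-aware, rescaled to unit variance); Factor *i* is
the first principal factor of the 10 composites, scored by the regression
method and oriented so higher = more sensitive. `variance_explained` is the
mean squared correlation of the 20 original columns with the Factor *i* score.
Constant (fully shrunk) columns are defined to carry zero correlation rather
than NaN.

## Bayes factors

- **Correlation**: Jeffreys' approximate marginal likelihood
  `L(ρ; r, n) ∝ (1-ρ²)^((n-1)/2) / (1-ρr)^(n-3/2)` normalized at ρ = 0,
  integrated against a stretched beta(1/κ, 1/κ) prior on (−1, 1) with κ = 1/3
  (narrow, appropriate for individual-difference effects). Rank-based variant:
  the same machinery on average ranks. Reported r is the unclipped sample
  value; the likelihood clips at ±0.999999 only inside the integrand for
  numerical stability, and the quadrature gets the sample r as an interior
  break point.
- **Two-sample**: JZS Bayes factor with a Cauchy prior (scale √2/2) on the
  standardized effect, computed by quadrature over the inverse-gamma(1/2,
  scale²/2) mixing parameter. Δ is the pooled standardized mean difference of
  the first group (label sort order) minus the second, with a t-based 95%
  interval.

Both are validated against independent Simpson-rule quadrature oracles in the
test suite (the JZS integral under the substitution g = tan²θ, which makes the
integrand smooth and bounded on (0, π/2)).

## Problem sizes and budgets

The full pipeline at study size (250 participants × 1340 trials ≈ 335k trials)
simulates, cleans and scores in well under a minute on one CPU; the complete
test suite, including recovery experiments and numerical oracles, runs in
under a minute. All randomness flows through explicit integer seeds; no
network or file-system state outside the given paths is touched.
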