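# Methods

## Performance surfaces and the concave-cost theorem

Whole-organism performance is approximated by the bivariate quadratic

    w(x1, x2) = ½γ₁₁x₁² + β₁x₁ + ½γ₂₂x₂² + β₂x₂ + γ₁₂x₁x₂ + α

with `x1` the ornament and `x2` the compensatory trait. The linear
gradients β₁, β₂ are kept throughout (the general Lande–Arnold form) even
though the canonical hill-centred-at-origin case sets them to zero; all
origin-centred results are recovered with β = 0. On a hill
(γ₁₁ < 0, γ₂₂ < 0) the discriminant γ₁₂² − γ₁₁γ₂₂ separates an elliptical
peak (negative) from a saddle (positive); equality is the
perfect-compensation ridge along which performance is constant. Because
exact equality is measure-zero in floating point, the ridge case is
detected with a configurable relative tolerance (default 1e−9).

Freezing compensation at `k` (what a manipulation experiment does) gives
the conditional quadratic with maximizer

    x1_peak = −(γ₁₂·k + β₁) / γ₁₁.

Completing the square shows the bracketed shift is `+kγ₁₂/γ₁₁`, so the
*maximizer* is its negative; with γ₁₂ > 0, k > 0, γ₁₁ < 0 (and β₁ = 0) it
is strictly positive. Combined with a linear sexual-selection surface
`s·x1` (s > 0), the evolved state satisfies
`x1_peak = (γ₁₂²/γ₁₁γ₂₂)·x1*`, strictly inside (0, x1*): a concave cost
function is *guaranteed* in this regime, which is the package's central
property-tested claim. With k = 0 or γ₁₂ ≤ 0 the peak is ≤ 0 and the cost
is incremental.

Cost is reported as best achievable performance minus performance at the
focal phenotype (so cost ≥ 0, zero at the surface optimum). The
cost-shape classifier returns `concave`, `incremental`, `flat`, or —
for a peak at or beyond the current ornament value, a case outside the
compensated regime — `decreasing`.

Saddle surfaces are refused by `current_state` (fitness would be
unbounded) rather than silently returning a critical point.

## The balancing-toy generator

The synthetic stage replaces a physical balancing-toy experiment: a toy
with a straw tail (0.4 g per 160 mm, uniform density) glued behind the
pivot and optional clay wings (0.8 g each) ahead of it. The model is a
small-angle torque balance,

    tilt  = angle_scale · (tail_moment − wing_moment + baseline_moment)
            + individual_effect + photo_noise
    angle = min(|tilt|, 90°)

* `tail_moment` = remaining straw mass × `tail_arm_mm`. The lumped lever
  arm is held **fixed** as the tail is shortened. An alternative with the
  arm tracking the tail midpoint (offset + L/2) was considered and
  rejected: under the three calibration anchors it forces a response gain
  large enough to clip the winged manipulation curve at 90°, destroying
  the interior minimum the real experiment shows. With a fixed arm the
  interior minimum holds for *every* arm choice, so `tail_arm_mm`
  (default 40 mm) is a pure scale convention.
* `baseline_moment` is a constant offset representing the unmodified
  toy's imperfect balance (the ancestral toy does not hang exactly
  level). Representing it as a moment rather than an angle makes
  calibration exactly linear in the anchors.
* `individual_effect` ~ N(0, σ_ind) per toy, in degrees, additively —
  matching the random-intercept structure of the statistical model.
  Default σ_ind = 0.45° (variance ≈ 0.2, the scale of the between-toy
  component the analysis reports).
* `photo_noise` ~ N(0, σ_meas) per photograph. Default σ_meas = 2.3°,
  chosen so that duplicate-photo repeatability on the default design is
  ≈ 0.99 (measurement noise small relative to between-treatment spread).

### Calibration

Three reference morphs anchor the free parameters (`angle_scale`,
`wing_arm_mm`, `baseline_moment`): the ancestral toy (mean tilt 4.87°),
the fully elongated winged form (22.37°) and the wingless form with 30 mm
of tail (36.60°). The three noise-free conditions are linear and
triangular in the unknowns, so the least-squares problem has an exact
closed-form solution; calibration solves it and verifies every anchor to
within 5% relative error (the fit is exact for feasible anchors).
Degenerate anchor sets — no tilt gain from tail mass, or a winged anchor
that would require a negative wing arm — raise a calibration error with
the residuals.

The resulting noise-free tilt over the shortening design
{0, −20, −40, −60, −80} mm is 22.4°, 1.2°, 19.9°, 41.1°, 62.2°: convex
with an interior minimum near −20 mm, never clipped. The ESS game on the
default 0–110 mm × {wings, no wings} grid then has a *unique* solution,
the 110 mm winged morph (tilt 22.4° < 30° cutoff), while every wingless
morph beyond 20 mm of tail exceeds the cutoff.

### What the generator does and does not emulate

It reproduces the three anchor means, the design layout, the
random-intercept + photo-noise error structure, high replicate
repeatability, and the qualitative convex (concave-cost) response with an
interior minimum. It does **not** reproduce the measured response *curve*:
a linear-in-moment model pinned to the three anchors necessarily puts the
interior minimum near −20 mm, whereas the real toy's fitted minimum sits
near −40 mm with a shallower right branch — the physical toy's angle
response is evidently nonlinear in the net moment. Passing tests
therefore show that the pipeline recovers the *shape class* (positive
quadratic coefficient, interior vertex, concave-cost verdict) from data
with realistic noise, not that the torque model predicts the toy's exact
angles. Pivot geometry and lever arms are calibration parameters, not
measurements.

Over-shortening past the bare tail clamps to the ancestral tail with a
warning; treatments must be ≤ 0; angles are absolute and clipped at 90°.

## Data reduction

Replicates are averaged per (individual, treatment) cell; a missing cell
is an error, never imputed. Repeatability is the one-way ANOVA intraclass
correlation with groups = cells (20 groups of 2 for the default design,
df 19, 20): s²_A = (MS_A − MS_W)/n₀ with n₀ the average-group-size
correction, r = s²_A/(s²_A + MS_W); for balanced groups this reduces to
r = (F−1)/(F−1+n₀). Grouping by individual only is available but
non-default. If MS_W = 0 exactly, r = 1 and F = ∞.

The manipulation predictor is z-scored by default using the mean and SD
(ddof = 1) of the **distinct design levels** (five levels ⇒ SD = √1000 ≈
31.62, values {±1.2649, ±0.6325, 0}), so replication does not change the
predictor scale; `center` and `raw` scalings are available behind a flag
since the original analysis does not state its transformation. The design
matrix is [1, z, z²] with individual identity as the grouping factor.

## Bayesian mixed model

`y = Xβ + u_j + e` with u_j ~ N(0, σ²_u), e ~ N(0, σ²_e). Priors emulate
the MCMCglmm defaults: β ~ N(0, 10¹⁰·I); each variance gets an
inverse-gamma prior parameterized as (V = 1, ν = 0.002), i.e. shape ν/2
and rate νV/2. All full conditionals are conjugate (multivariate normal
for β, independent normals for u, inverse-gammas for the variances), so
the sampler is an exact Gibbs cycle. Defaults: 13 000 iterations, 3 000
burn-in, thinning 10 (1 000 draws per chain), and 3 chains — a single
chain matches the original default but leaves Rhat undefined, so
multi-chain is the package default; chain count is configurable.
Identical seeds give identical draws (chains use SeedSequence-spawned
independent streams).

Diagnostics and summaries:

* **Rhat**: √(((n−1)/n·W + B/n)/W) from within- and between-chain
  variances; duplicated chains give √((n−1)/n) ≤ 1. Convergence requires
  Rhat < 1.2 for all parameters; the pipeline flags (and the CLI exits
  nonzero on) violations.
* **pMCMC**: 2·min(Pr(draws > 0), Pr(draws < 0)), floored at 1/n_draws
  (a finite chain cannot certify an exact zero); reported for fixed
  effects only.
* **Cost-shape verdict**: per posterior draw the fitted angle parabola
  a + b·z + c·z² has vertex −b/2c; a draw supports a concave cost when
  c > 0 with the vertex strictly inside the manipulated predictor range.
  `concave_cost` (or `incremental_cost`) requires ≥ 0.95 posterior
  probability; otherwise `inconclusive`. The 0.95 vertex rule is a
  package convention (the original analysis reports only coefficient
  significance).

## Numerical and design choices

* Peak locations and optima use closed-form linear algebra; the test
  suite checks them against dense-grid + Nelder–Mead oracles (agreement
  to 1e−6) and brute-force enumeration for the game.
* ESS ties return the full tie set rather than an arbitrary winner.
* Simulation sizes: the parameter-recovery study uses the five-level
  design replicated to 20 individuals (100 observations), 100
  simulated datasets, single-chain fits at the default 13 000 iterations;
  the false-positive (flat-truth) check uses 100 datasets with shortened
  chains (2 000 iterations). These sizes give stable Monte-Carlo
  estimates of coverage and error rates while keeping the default suite
  quick to run.
* Seeds: one pipeline seed deterministically derives per-stage substreams
  via `numpy.random.SeedSequence`, so stages can be re-run in isolation.

## Known limitations

* Two traits only; no canonical rotation of the γ-matrix, no estimation
  of γ from field data, no multi-trait compensation.
* The discrete game has fixed payoff structure (survive the cutoff, then
  longest tail reproduces); no frequency dependence or dynamics.
* The tilt model is linear in net moment; see the generator caveats
  above.
* Gaussian response only; no random slopes; no model comparison.
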