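# compcost

Tools for asking whether a **concave cost function** in an
ornament-manipulation experiment really proves viability selection — or
whether it is exactly what coevolved **compensatory traits** would produce
under purely sexual selection.

Shortening experiments (classically, the outermost tail feathers of barn
swallows) find that performance first improves and then worsens as the
ornament is reduced, and conclude that the ornament sits just beyond a
viability optimum. But if a compensatory trait (longer wings, a
counterweight) coevolved with the ornament and stays fixed during the
manipulation, the *unchanged* compensation itself degrades performance once
too much ornament is removed — **overcompensation** — and the same concave
cost curve appears with no viability advantage of the ornament at all.

`compcost` packages that argument end to end:

* **Quadratic performance surfaces** (`compcost.surfaces`). Performance is
  the Lande–Arnold quadratic form
  `w(x1,x2) = ½γ₁₁x₁² + β₁x₁ + ½γ₂₂x₂² + β₂x₂ + γ₁₂x₁x₂ + α` over ornament
  `x1` and compensatory trait `x2`. Geometry classification (elliptical
  peak / saddle / perfect-compensation ridge), ridge lines, and the
  conditional curve `w(x1, k)` obtained by freezing compensation at `k`,
  whose peak `−(γ₁₂k+β₁)/γ₁₁` is strictly positive whenever `γ₁₂>0`,
  `k>0`, `γ₁₁<0` — the concave-cost theorem.
* **The evolved state and the toy game** (`compcost.selection`). The
  "current state" maximizes `w + s·x1` for a sexual-selection gradient
  `s ≥ 0`; `manipulation_path` traces a shortening experiment from it.
  `solve_toy_game` solves the discrete survive-(|tilt| < cutoff)-then-
  longest-tail-reproduces game for a balancing-toy model organism.
* **A synthetic manipulation experiment** (`compcost.toy`). A torque-balance
  model of a traditional balancing toy ("chuonchuon") with a straw tail
  (ornament) and clay wings (compensation), calibrated so three reference
  morphs hit the study's printed mean tilts, generating long-format
  measurement tables (4 individuals × 5 shortenings × 2 photos).
* **Data reduction** (`compcost.pipeline`): replicate averaging, one-way
  ANOVA repeatability (intraclass correlation), and design assembly with a
  z-scored manipulation predictor.
* **Bayesian inference** (`compcost.inference`): a conjugate Gibbs sampler
  for the Gaussian random-intercept mixed model with linear + quadratic
  fixed effects, Brooks–Gelman–Rubin Rhat, pMCMC, and a posterior verdict
  on whether the fitted response is concave-cost shaped.

## Worked example

The illustrative surface `−4x² − 4y² + 7xy` (so γ₁₁ = γ₂₂ = −8, γ₁₂ = 7)
with sexual selection surface `10·x1`:

```python
>>> import compcost as cc
>>> surface = cc.QuadraticPerformanceSurface(gamma11=-8, gamma22=-8, gamma12=7)
>>> cc.classify_geometry(surface)
<SurfaceGeometry.ELLIPTICAL_PEAK: 'elliptical_peak'>
>>> cc.current_state(surface, cc.SexualSelectionGradient(10.0))
(5.333333333333334, 4.666666666666667)
>>> cc.conditional_cost_curve(surface, 14/3).peak_x1
4.083333333333334
```

The evolved phenotype sits at (16/3, 14/3): right of the ridge line, held
there by mating advantage. Shortening the ornament with compensation frozen
at 14/3 *raises* performance until x1 = 49/12 ≈ 4.08 and lowers it
afterwards — a concave cost function from purely sexual selection.

The full pipeline (calibrate toy → ESS game → simulate → average →
repeatability → Gibbs fit → verdict):

```python
>>> report = cc.run_pipeline(cc.PipelineConfig(seed=1))
>>> report["ess"]["strategies"]
[{'tail_elongation_mm': 110.0, 'wings': True}]
>>> round(report["repeatability"]["r"], 3)
0.987
>>> report["verdict"]
{'cost_shape': 'concave_cost', 'prob_concave': 0.9996666666666667,
 'prob_incremental': 0.0003333333333332966}
```

The evolutionarily stable morph is the fully elongated (110 mm) winged
form; duplicate photos are highly repeatable (r ≈ 0.99); and the Bayesian
quadratic mixed model of tilt angle on the shortening treatment returns a
decisively positive quadratic coefficient with an interior vertex —
the synthetic experiment exhibits the concave cost signature even though
its tail is, by construction, purely sexually selected.

The same stages are available from the shell:

```bash
compcost generate-data --seed 1 --out table.csv
compcost average table.csv --out avg.csv
compcost repeatability table.csv
compcost fit avg.csv --seed 1 --out fit.json
compcost run --seed 1 --out results/
```

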