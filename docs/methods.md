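# Methods

## Model and assumptions

The model treats drinking and smoking as socially transmitted states in a
well-mixed population of seven compartments (S, D, M, Dm, R_d, R_m, R_dm).
Its structural assumptions:

* uptake is proportional to contact with the behaving classes through the
  forces α₁ = a₁(D + Dm), α₂ = a₂(M + Dm) — co-dependent individuals exert
  both forces;
* a drinker exposed to α₂ becomes co-dependent (and symmetrically a smoker
  exposed to α₁); there is no direct S → Dm route;
* recovery is temporary: recovered individuals relapse to susceptibility at
  rates γ₁, γ₂, γ₃, never directly back into a behaving class;
* co-dependence mortality adds the single-behaviour excess risks,
  φ₃ = φ₁ + φ₂, and the co-dependent relapse rate is estimated as the mean
  γ₃ = (γ₁ + γ₂)/2 ("paper mode"; both identities can be switched off);
* all rates are constant; no age structure, stochasticity or spatial
  structure.

Summing the equations gives N' = ξ − μN − φ₁D − φ₂M − φ₃Dm ≤ ξ − μN, so
0 ≤ N ≤ ξ/μ is forward-invariant and solutions from nonnegative data stay
nonnegative. Both properties are enforced as numerical tests (tolerance
1e−9 on positivity at step 0.01), not assumed.

Units: all rates are week⁻¹; compartment values are dimensionless
population units (the baseline initial state sums to 0.98 and the model is
agnostic to whether these are proportions or absolute counts).

## Baseline parameters

`table2_preset()` ships the literature-sourced rates: ξ = 0.8, a₁ = 0.00479,
a₂ = 0.035, δ₁ = 0.00767, δ₂ = 0.217, k₁ = 0.01923, μ = 0.0952,
φ₁ = 9e−6, φ₂ = 0.175, γ₁ = 0.7, γ₂ = 0.00575 (week⁻¹), with φ₃ and γ₃
derived. At these rates R0D ≈ 0.391 and R0M ≈ 0.604: both behaviours are
subcritical and the behaviour-free equilibrium S* = ξ/μ ≈ 8.403 attracts.

## Numerics

* **Integrator.** Classical fixed-step RK4, default step 0.01 weeks (5,200
  steps over the 52-week horizon); at this step the step-halving change in
  the endpoint is below 1e−6, negligible against every tolerance used. The
  forces α₁, α₂ are recomputed at every RK4 stage, not frozen per step.
  States are never clipped during integration; positivity is asserted
  post hoc (clipping would mask integrator defects). A state magnitude
  above 1e12 raises a blow-up error. Long-horizon attraction probes use
  step 0.1 over 2,000 weeks (the slowest relevant rate, μ ≈ 0.095/week,
  makes this amply resolved) and integrate batches of initial states in
  lockstep through the vectorised right-hand side.
* **Equilibria.** Submodel equilibria use the closed forms; every reported
  equilibrium carries a residual (max-norm of the right-hand side) with
  contract ≤ 1e−10. The full seven-compartment endemic state has no closed
  form and is located by damped Newton on the RHS with the analytic
  Jacobian, seeded from a long simulation endpoint. Eigenvalues come from
  the dense eigensolver; a leading real part within ±1e−10 of zero yields a
  "marginal" verdict (neither stable nor unstable) rather than a sign call.
* **Jacobian.** Analytic throughout (the RHS is bilinear); the derivative
  terms ∂α₁/∂D = ∂α₁/∂Dm = a₁ and ∂α₂/∂M = ∂α₂/∂Dm = a₂ are included and
  the matrix is verified against central finite differences.

## Sensitivity analysis

* **Elasticities.** W_x(R) = (∂R/∂x)(x/R), coded analytically from the R0
  closed forms and cross-checked by central differences (agreement ≤ 1e−6).
  At the baseline rates the self-consistent values are a₁: +1, μ: −1.9254,
  φ₁: −0.000087, δ₁: −0.0746 for R0D and a₂: +1, μ: −1.1954, φ₂: −0.3592,
  δ₂: −0.4454 for R0M. Note: some published tabulations transpose the δ₁
  and δ₂ entries (−0.4454 for δ₁, −0.075 for δ₂); the two printed numbers
  match each other's formula and not their own, so this package reports the
  analytic values. For R0 = max(R0D, R0M) the elasticity of the dominant
  branch is reported (the max is not differentiable at a tie; ties follow
  the drinkers branch).
* **Global design.** The LHS ranges behind published global-sensitivity
  figures are not stated anywhere usable, so the default design samples
  each rate uniformly on ±25% of its baseline value — a symmetric
  perturbation that preserves the qualitative sign structure — with n =
  2000 samples and seed 20241219, all exposed in config. Sampling uses
  scipy's LatinHypercube (one draw per equal-probability stratum, stratum
  order permuted per parameter, bit-reproducible under the seed).
* **PRCC.** Implemented as rank-residual correlation: rank-transform all
  columns (average ranks on ties), regress the parameter's and the output's
  ranks on the ranks of all other parameters, correlate the residuals. A
  numerically zero residual (e.g. the output is an exact copy of another
  parameter) yields coefficient 0 — no partial association remains. The
  construction is cross-checked against an independent partial-Spearman
  implementation in the tests. Trajectory-referenced PRCCs use D, M, Dm at
  t = 52 weeks as scalar outputs when requested; the reproduction-number
  PRCCs need no integration.
* The sampled-R0 95% interval is reported descriptively only; it depends
  entirely on the chosen ranges.

## Optimal control

Controls: u₁, u₂ scale the α₁-, α₂-driven uptake terms by (1−u); u₃, u₄,
u₅ add to the recovery rates of Dm, D, M. Objective
J = ∫₀ᵀ [A₁D + A₂M + A₃Dm + ½Σ wᵢuᵢ²] dt, defaults A = 100, w = 0.5,
T = 52 weeks. State costs may be zero (then no action is optimal); control
costs must be strictly positive since they divide the characterization.

The adjoint system and control characterizations are **derived from the
implemented Hamiltonian** H = running cost + λ·f(x, u), not transcribed
from any printed system: dλ/dt = −∇g − J_fᵀλ with the analytic controlled
Jacobian (including the ∂α/∂state terms), λ(T) = 0, and the clamped
stationary points

```
Φ₁ = α₁[(λ₂−λ₁)S + (λ₄−λ₃)M]/w₁      Φ₂ = α₂[(λ₃−λ₁)S + (λ₄−λ₂)D]/w₂
Φ₃ = (λ₄−λ₇)Dm/w₃    Φ₄ = (λ₂−λ₅)D/w₄    Φ₅ = (λ₃−λ₆)M/w₅
```

Central finite differences of H are the arbiter for both: the test suite
requires the coded adjoint RHS to equal −∂H/∂x and each interior control to
be a stationary point of H to ≤ 1e−8 (H is quadratic in each uₖ, so wide
central differences are exact to roundoff).

**Solver.** Forward–backward sweep: RK4 forward in the state with the
current control path (controls and stored states interpolated linearly at
the RK4 half-steps), RK4 backward in the adjoints from λ(T) = 0, then the
relaxed update u ← 0.5·u_char + 0.5·u. Convergence requires, per control,
‖u_new − u_old‖₁ ≤ tol·‖u_new‖₁ (absolute fallback for identically zero
controls), default tol 1e−3, max 200 iterations; non-convergence is
reported in the solution object, not raised. On the baseline scenario the
sweep converges in 17 iterations and the converged path is first-order
optimal: no ±0.01 single-control perturbation on any quarter of the horizon
lowers J by more than 1e−6. Control bounds default to [0, 1] per control;
disabled controls are pinned to (0, 0), which reproduces the uncontrolled
trajectory exactly.

**Efficacy.** E(t) = 1 − X_controlled(t)/X_baseline(t) per compartment, the
standard fractional-reduction construction; grid points where the baseline
is zero are reported as NaN. On the baseline scenario drinker efficacy
passes 0.99 before week 5 and stays there.

## Scope of the synthetic conditions

All inputs are parameter-level: the baseline rates, the §-style initial mix
(0.6, 0.2, 0.1, 0.06, 0.02, 0, 0) and the objective weights constitute the
study conditions; no empirical time series is fitted. Passing tests
therefore demonstrate internal mathematical consistency (thresholds,
equilibria, optimality conditions, reproducibility) and faithfulness to the
stated rates — not predictive validity for any real population. Known
limitations: homogeneous mixing, constant rates, no direct S → Dm uptake,
quadratic control costs chosen for tractability, and a bang-off terminal
dip in the controls forced by λ(T) = 0.

## Problem sizes used by the test and acceptance runs

Sweep: 5,201-point grid (52 weeks at step 0.01). Threshold property: 200
log-uniform random parameter sets on [0.2×, 5×] baseline. Attraction
probes: 20 random initial states, 2,000 weeks at step 0.1. Global
sensitivity: n = 2000 LHS samples. These sizes make every stochastic check
stable under its fixed seed while keeping a full run of suite plus
acceptance script around a minute.
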