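# drinksmoke

Compartmental dynamics of drinking–smoking co-dependence: simulation,
stability analysis, sensitivity analysis and optimal control.

Alcohol drinking and tobacco smoking spread through social contact and
frequently co-occur: smokers take up drinking (and vice versa) at elevated
rates, recovery from either is temporary, and relapse returns people to the
susceptible pool. This package implements a seven-compartment
social-contagion ODE model of that joint dynamic for researchers in
behavioural epidemiology and public-health modelling: it answers whether the
behaviours die out or persist (reproduction numbers, equilibria, stability),
which rates matter most (local elasticities, Latin-hypercube + PRCC), and
how five bounded interventions are best scheduled over a planning horizon
(a Pontryagin optimal-control problem solved by forward–backward sweep).

## The model

The population splits into susceptibles S, drinkers D, smokers M,
co-dependent individuals Dm, and recovered classes R_d, R_m, R_dm. Uptake is
driven by the state-dependent forces α₁ = a₁(D + Dm) and α₂ = a₂(M + Dm):

```
S'   = ξ + γ₁R_d + γ₂R_m + γ₃R_dm − (α₁ + α₂ + μ)S
D'   = α₁S − (μ + φ₁ + δ₁ + α₂)D
M'   = α₂S − (μ + φ₂ + δ₂ + α₁)M
Dm'  = α₂D + α₁M − (μ + φ₃ + k₁)Dm
R_d' = δ₁D − (μ + γ₁)R_d
R_m' = δ₂M − (μ + γ₂)R_m
R_dm'= k₁Dm − (μ + γ₃)R_dm
```

with recruitment ξ, natural mortality μ, behaviour-induced mortality
φ₁, φ₂, φ₃ = φ₁+φ₂, recovery δ₁, δ₂, k₁ and relapse γ₁, γ₂, γ₃ (all rates
in week⁻¹). The next-generation matrix at the behaviour-free equilibrium
S* = ξ/μ gives

```
R0D = a₁ξ / (μ(μ + φ₁ + δ₁)),   R0M = a₂ξ / (μ(μ + φ₂ + δ₂)),
R0  = max(R0D, R0M),
```

and the behaviour-free state is locally (and, numerically probed, globally)
stable exactly when R0 < 1. The optimal-control variant adds prevention
controls u₁, u₂ scaling the uptake terms by (1−u) and treatment controls
u₃, u₄, u₅ boosting recovery, minimising
J = ∫₀ᵀ [A₁D + A₂M + A₃Dm + ½Σ wᵢuᵢ²] dt subject to 0 ≤ uᵢ ≤ 1.

## Worked example

```python
import numpy as np
from drinksmoke import (table2_preset, ngm_codependence, forward_backward_sweep,
                        ObjectiveWeights, DEFAULT_INITIAL_STATE)

params = table2_preset()                      # literature rates, week^-1
rn = ngm_codependence(params)
print(f"R0D = {rn.r0_drinkers:.5f}  R0M = {rn.r0_smokers:.5f}")

sol = forward_backward_sweep(params, np.array(DEFAULT_INITIAL_STATE),
                             ObjectiveWeights(), t1=52.0, step=0.01)
print(f"J = {sol.objective:.3f} vs no-control J0 = {sol.objective_uncontrolled:.3f}")
print(f"week 4: D = {sol.trajectory.at(4.0)[1]:.5f}, Dm = {sol.trajectory.at(4.0)[3]:.5f}")
```

prints

```
R0D = 0.39126  R0M = 0.60369
J = 33.388 vs no-control J0 = 297.620
week 4: D = 0.00254, Dm = 0.00068
```

Both reproduction numbers are below one, so the behaviours decay even
untreated — but slowly; the optimal controls cut the 52-week burden almost
nine-fold and push drinking from 0.2 to below 0.01 population units within
four weeks. The `examples/` directory holds one narrative script per
capability (simulation, stability, sensitivity, optimal control), and the
`drinksmoke` CLI exposes the same pipelines
(`drinksmoke simulate | stability | indices | lhs-prcc | surface |
optimal-control`).

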