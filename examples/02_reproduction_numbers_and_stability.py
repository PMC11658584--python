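"""Reproduction numbers, equilibria and stability verdicts.

Computes R0D (drinkers), R0M (smokers) and the co-dependence R0 via the
next-generation matrix, diagnoses the behaviour-free equilibrium, and shows
the endemic closed form taking over once the drinking contact rate is large
enough to push R0D above one.
"""

from drinksmoke import (
    equilibria_drinkers,
    ngm_codependence,
    stability_verdict,
    table2_preset,
)

params = table2_preset()
rn = ngm_codependence(params)
print(f"R0D = {rn.r0_drinkers:.5f}   R0M = {rn.r0_smokers:.5f}")
print(f"co-dependence R0 = {rn.r0_codependence:.5f} (NGM spectral radius)")

rep = stability_verdict(params)
print(
    f"behaviour-free equilibrium: locally_stable={rep.locally_stable}, "
    f"leading eigenvalue {rep.leading_real_part:.5f}, residual {rep.residual:.1e}"
)

# push the drinking contact rate above threshold (R0D = 2)
endemic_params = params.replace(a1=0.024485)
dfe, ee = equilibria_drinkers(endemic_params)
print(f"\nwith a1 = 0.024485 (R0D = 2): endemic drinkers level D* = {ee.state[1]:.5f}")
print(f"closed-form residual against the dynamics: {ee.residual:.1e}")
print(f"endemic state locally stable: {ee.locally_stable}")

# R0 below one means each drinker/smoker recruits less than one successor
# and the behaviour dies out; above one the endemic state exists and attracts.
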