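"""Equilibria, reproduction numbers and stability verdicts.

Three nested models are analysed:

* the drinkers-only submodel (S, D, Rd) obtained by switching off smoking
  (a2 = gamma2 = gamma3 = 0 and empty smoking compartments),
* the smokers-only submodel (S, M, Rm), symmetric,
* the full seven-compartment co-dependence model.

Each submodel has a behaviour-free equilibrium at S* = xi/mu and a closed-form
endemic equilibrium that is admissible exactly when its reproduction number
exceeds one.  The full model's behaviour-free equilibrium (DMFE) is
(xi/mu, 0, ..., 0); its next-generation matrix FV^-1 has eigenvalues
{R0D, R0M, 0}, so the co-dependence reproduction number is
R0 = max(R0D, R0M) with

    R0D = a1*xi / (mu*(mu + phi1 + delta1)),
    R0M = a2*xi / (mu*(mu + phi2 + delta2)).

Local stability is decided from the spectrum of the analytic Jacobian; the
threshold theorem (DMFE stable iff R0 < 1) is exercised numerically rather
than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import rhs_uncontrolled, simulate
from .params import ModelParameters

__all__ = [
    "ReproductionNumbers",
    "EquilibriumReport",
    "InadmissibleEquilibriumError",
    "r0_drinkers",
    "r0_smokers",
    "reproduction_numbers",
    "ngm_matrices",
    "ngm_codependence",
    "jacobian",
    "dmfe_state",
    "equilibria_drinkers",
    "equilibria_smokers",
    "stability_verdict",
    "endemic_equilibrium_full",
]

#: |max real eigenvalue| below this is reported as a marginal verdict
MARGINAL_BAND = 1e-10

#: residual contract for every reported equilibrium
RESIDUAL_TOL = 1e-10


class InadmissibleEquilibriumError(ValueError):
    """An endemic closed form with a negative component (R0 <= 1 regime)."""


@dataclass(frozen=True)
class ReproductionNumbers:
    """The three basic reproduction numbers (dimensionless)."""

    r0_drinkers: float
    r0_smokers: float
    r0_codependence: float
    #: eigenvalues of FV^-1 at the DMFE (only set by the NGM route)
    ngm_eigenvalues: tuple[float, ...] = ()


@dataclass(frozen=True)
class EquilibriumReport:
    """An equilibrium state with its local-stability diagnosis.

    ``locally_stable`` is True/False from the eigenvalue sign test, or None
    when the leading real part sits inside the marginal band around zero.
    ``r0_consistent`` records whether that verdict agrees with the R0 < 1
    threshold criterion (None verdicts are consistent with R0 = 1 only).
    """

    label: str
    state: np.ndarray
    residual: float
    eigenvalues: np.ndarray
    locally_stable: bool | None
    r0_consistent: bool | None = None

    @property
    def leading_real_part(self) -> float:
        return float(np.max(self.eigenvalues.real))


# -- reproduction numbers ----------------------------------------------------


def r0_drinkers(params: ModelParameters) -> float:
    """R0D = a1*xi / (mu*(mu + phi1 + delta1))."""
    denom = params.mu * (params.mu + params.phi1 + params.delta1)
    if denom == 0.0:
        raise ZeroDivisionError("mu*(mu + phi1 + delta1) is zero")
    return params.a1 * params.xi / denom


def r0_smokers(params: ModelParameters) -> float:
    """R0M = a2*xi / (mu*(mu + phi2 + delta2))."""
    denom = params.mu * (params.mu + params.phi2 + params.delta2)
    if denom == 0.0:
        raise ZeroDivisionError("mu*(mu + phi2 + delta2) is zero")
    return params.a2 * params.xi / denom


def reproduction_numbers(params: ModelParameters) -> ReproductionNumbers:
    """Closed-form R0D, R0M and their supremum (the co-dependence R0)."""
    r0d = r0_drinkers(params)
    r0m = r0_smokers(params)
    return ReproductionNumbers(r0d, r0m, max(r0d, r0m))


def ngm_matrices(params: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """New-recruitment (F) and transfer (V) matrices at the DMFE.

    The infective subsystem is (D, M, Dm).  Linearising the uptake terms and
    the transfer terms at the DMFE (where alpha1 = alpha2 = 0, so the
    alpha2*D / alpha1*M cross-couplings vanish) gives::

        F = [[a1*S0, 0, a1*S0], [0, a2*S0, a2*S0], [0, 0, 0]]
        V = diag(mu+phi1+delta1, mu+phi2+delta2, mu+phi3+k1)

    with S0 = xi/mu.
    """
    p = params
    s0 = p.xi / p.mu
    F = np.array(
        [
            [p.a1 * s0, 0.0, p.a1 * s0],
            [0.0, p.a2 * s0, p.a2 * s0],
            [0.0, 0.0, 0.0],
        ]
    )
    V = np.diag(
        [
            p.mu + p.phi1 + p.delta1,
            p.mu + p.phi2 + p.delta2,
            p.mu + p.phi3 + p.k1,
        ]
    )
    return F, V


def ngm_codependence(params: ModelParameters) -> ReproductionNumbers:
    """R0 of the full model as the spectral radius of FV^-1.

    The eigenvalues of FV^-1 reduce to {R0D, R0M, 0}; the closed forms are
    therefore also returned for convenience.
    """
    F, V = ngm_matrices(params)
    if np.any(np.diag(V) == 0.0):
        raise ZeroDivisionError("singular transfer matrix V (zero diagonal entry)")
    K = F @ np.linalg.inv(V)
    eig = np.linalg.eigvals(K)
    # FV^-1 is upper-triangular here, so the spectrum is real
    eig = np.sort(eig.real)[::-1]
    return ReproductionNumbers(
        r0_drinkers=r0_drinkers(params),
        r0_smokers=r0_smokers(params),
        r0_codependence=float(np.max(eig)),
        ngm_eigenvalues=tuple(float(v) for v in eig),
    )


# -- Jacobian ----------------------------------------------------------------


def jacobian(state: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Analytic 7x7 Jacobian of the uncontrolled vector field.

    The right-hand side is polynomial (bilinear through alpha1, alpha2), so
    the partial derivatives are exact; note d(alpha1)/dD = d(alpha1)/dDm = a1
    and d(alpha2)/dM = d(alpha2)/dDm = a2.
    """
    from .control import jacobian_controlled  # shares the controlled form

    return jacobian_controlled(state, np.zeros(5), params)


def dmfe_state(params: ModelParameters) -> np.ndarray:
    """The drinking-and-smoking-free equilibrium (xi/mu, 0, ..., 0)."""
    s = np.zeros(7)
    s[0] = params.xi / params.mu
    return s


# -- equilibrium reports -----------------------------------------------------


def _report(
    label: str,
    state: np.ndarray,
    params: ModelParameters,
    eigenvalues: np.ndarray,
    r0: float | None,
) -> EquilibriumReport:
    residual = float(np.max(np.abs(rhs_uncontrolled(0.0, state, params))))
    lead = float(np.max(eigenvalues.real))
    if abs(lead) < MARGINAL_BAND:
        stable: bool | None = None
    else:
        stable = lead < 0.0
    consistent: bool | None = None
    if r0 is not None and stable is not None:
        consistent = bool(stable == (r0 < 1.0))
    return EquilibriumReport(
        label=label,
        state=state,
        residual=residual,
        eigenvalues=eigenvalues,
        locally_stable=stable,
        r0_consistent=consistent,
    )


def _submodel_reports(
    params: ModelParameters,
    *,
    drinkers: bool,
) -> tuple[EquilibriumReport, EquilibriumReport]:
    """Shared closed-form machinery for the two structurally symmetric
    submodels; ``drinkers`` selects (a1, phi1, delta1, gamma1) vs
    (a2, phi2, delta2, gamma2)."""
    p = params
    if drinkers:
        a, phi, delta, gamma = p.a1, p.phi1, p.delta1, p.gamma1
        idx_b, idx_r = 1, 4  # D, Rd slots in the 7-vector
        free_label, ee_label = "DFE-drinkers", "EE-drinkers"
        r0 = r0_drinkers(p)
        # the submodel is the full model with smoking switched off
        sub = p.replace(a2=0.0, gamma2=0.0, gamma3=0.0)
    else:
        a, phi, delta, gamma = p.a2, p.phi2, p.delta2, p.gamma2
        idx_b, idx_r = 2, 5  # M, Rm slots
        free_label, ee_label = "MFE-smokers", "EE-smokers"
        r0 = r0_smokers(p)
        sub = p.replace(a1=0.0, gamma1=0.0, gamma3=0.0)

    out = p.mu + phi + delta  # outflow from the behaviour compartment
    sub_idx = np.array([0, idx_b, idx_r])

    def padded(s: float, b: float, r: float) -> np.ndarray:
        full = np.zeros(7)
        full[0], full[idx_b], full[idx_r] = s, b, r
        return full

    def sub_eigs(state: np.ndarray) -> np.ndarray:
        J = jacobian(state, sub)[np.ix_(sub_idx, sub_idx)]
        return np.linalg.eigvals(J)

    # behaviour-free equilibrium
    free_state = padded(p.xi / p.mu, 0.0, 0.0)
    free_rep = _report(free_label, free_state, sub, sub_eigs(free_state), r0)

    # endemic closed form: S* = out/a, B* from S'=0, R* = delta*B*/(mu+gamma)
    if a == 0.0:
        raise InadmissibleEquilibriumError(
            f"{ee_label}: contact rate is zero, no endemic state exists"
        )
    den = (p.mu + gamma) * out - gamma * delta
    if den == 0.0:
        raise ZeroDivisionError(f"{ee_label}: degenerate denominator")
    s_star = out / a
    b_star = (p.xi * a * (p.mu + gamma) - p.mu * (p.mu + gamma) * out) / (a * den)
    r_star = delta * b_star / (p.mu + gamma)
    ee_state = padded(s_star, b_star, r_star)
    if np.any(ee_state < 0.0):
        neg = {n: v for n, v in zip(("S", "B", "R"), (s_star, b_star, r_star)) if v < 0}
        raise InadmissibleEquilibriumError(
            f"{ee_label}: negative component(s) {neg} (R0 = {r0:.6g} <= 1)"
        )
    ee_rep = _report(ee_label, ee_state, sub, sub_eigs(ee_state), None)
    return free_rep, ee_rep


def equilibria_drinkers(
    params: ModelParameters,
) -> tuple[EquilibriumReport, EquilibriumReport]:
    """Behaviour-free and endemic equilibria of the drinkers-only submodel.

    The endemic branch raises :class:`InadmissibleEquilibriumError` when
    R0D <= 1 forces a negative component.
    """
    return _submodel_reports(params, drinkers=True)


def equilibria_smokers(
    params: ModelParameters,
) -> tuple[EquilibriumReport, EquilibriumReport]:
    """Mirror of :func:`equilibria_drinkers` for the smokers-only submodel."""
    return _submodel_reports(params, drinkers=False)


def stability_verdict(params: ModelParameters) -> EquilibriumReport:
    """Local-stability diagnosis of the full model's DMFE.

    Computes the 7x7 Jacobian spectrum at (xi/mu, 0, ..., 0) and reports both
    the eigenvalue verdict and its agreement with max(R0D, R0M) < 1.
    """
    state = dmfe_state(params)
    eig = np.linalg.eigvals(jacobian(state, params))
    r0 = max(r0_drinkers(params), r0_smokers(params))
    return _report("DMFE-full", state, params, eig, r0)


# -- full-model endemic equilibrium (numerical) ------------------------------


def endemic_equilibrium_full(
    params: ModelParameters,
    *,
    state0: np.ndarray | None = None,
    sim_horizon: float = 2000.0,
    sim_step: float = 0.1,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> EquilibriumReport:
    """Locate an interior equilibrium of the full model numerically.

    No closed form exists for the seven-compartment endemic state, so a long
    simulation endpoint seeds a damped Newton iteration on the right-hand
    side; the report carries the same residual contract as the closed forms.
    """
    if state0 is None:
        state0 = np.array([0.6, 0.2, 0.1, 0.06, 0.02, 0.0, 0.0])
    y = simulate(params, state0, sim_horizon, step=sim_step).states[-1]
    for _ in range(max_iter):
        f = rhs_uncontrolled(0.0, y, params)
        if np.max(np.abs(f)) < tol:
            break
        delta = np.linalg.solve(jacobian(y, params), -f)
        lam = 1.0
        base = np.max(np.abs(f))
        while lam > 1e-6:
            trial = y + lam * delta
            if np.max(np.abs(rhs_uncontrolled(0.0, trial, params))) < base:
                y = trial
                break
            lam *= 0.5
        else:
            break
    eig = np.linalg.eigvals(jacobian(y, params))
    return _report("EE-full", y, params, eig, None)
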