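"""Optimal control of the drinking-smoking co-dependence model.

Five bounded controls act on the dynamics:

* ``u1`` — drinking prevention (scales the alpha1 uptake terms by 1-u1),
* ``u2`` — smoking prevention (scales the alpha2 uptake terms by 1-u2),
* ``u3`` — extra recovery effort on the co-dependent class (Dm -> Rdm),
* ``u4`` — extra recovery effort on drinkers (D -> Rd),
* ``u5`` — extra recovery effort on smokers (M -> Rm).

The objective balances the burden of the three behaviour compartments
against quadratic control costs::

    J = int_0^T [ A1*D + A2*M + A3*Dm + 1/2 sum_k w_k u_k^2 ] dt.

The Pontryagin apparatus is derived from the implemented Hamiltonian
H = running cost + lambda . f(x, u): the adjoint system is
dlambda/dt = -dH/dx = -grad(g) - J_f^T lambda with lambda(T) = 0, where J_f
is the analytic controlled Jacobian (including the dalpha/dstate terms), and
each control characterization is the clamped stationary point of H in u_k:

    Phi1 = alpha1*[(l2 - l1)*S + (l4 - l3)*M] / w1
    Phi2 = alpha2*[(l3 - l1)*S + (l4 - l2)*D] / w2
    Phi3 = (l4 - l7)*Dm / w3
    Phi4 = (l2 - l5)*D  / w4
    Phi5 = (l3 - l6)*M  / w5

The two-point boundary-value problem is solved by a forward-backward sweep:
RK4 forward in the state, RK4 backward in the adjoints, relaxed control
update, iterated to a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import BlowUpError, Trajectory, _BLOWUP_LIMIT, _time_grid
from .params import ModelParameters

__all__ = [
    "ObjectiveWeights",
    "ControlPath",
    "OCSolution",
    "ControlBoundsError",
    "rhs_controlled",
    "jacobian_controlled",
    "objective",
    "hamiltonian",
    "adjoint_rhs",
    "control_update",
    "forward_backward_sweep",
    "efficacy",
]

CONTROL_NAMES: tuple[str, ...] = ("u1", "u2", "u3", "u4", "u5")


class ControlBoundsError(ValueError):
    """A control value outside [0, 1] (or invalid bounds)."""


@dataclass(frozen=True)
class ObjectiveWeights:
    """Positive weights of the objective: state costs A1..A3, control costs w1..w5."""

    A1: float = 100.0
    A2: float = 100.0
    A3: float = 100.0
    w1: float = 0.5
    w2: float = 0.5
    w3: float = 0.5
    w4: float = 0.5
    w5: float = 0.5

    def __post_init__(self) -> None:
        # state costs may be zero (no incentive to act); control costs divide
        # the stationarity condition and must stay strictly positive
        for name in ("A1", "A2", "A3"):
            if getattr(self, name) < 0:
                raise ValueError(f"state cost {name} must be >= 0")
        for name in ("w1", "w2", "w3", "w4", "w5"):
            if getattr(self, name) <= 0:
                raise ValueError(f"control cost {name} must be > 0")

    @property
    def state_costs(self) -> np.ndarray:
        return np.array([self.A1, self.A2, self.A3])

    @property
    def control_costs(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3, self.w4, self.w5])


@dataclass(frozen=True)
class ControlPath:
    """The five controls sampled on a shared time grid; each value in [0, 1]."""

    times: np.ndarray
    values: np.ndarray  # shape (len(times), 5)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(times), 5):
            raise ValueError("controls must have shape (len(times), 5)")
        if np.any(values < -1e-12) or np.any(values > 1.0 + 1e-12):
            raise ControlBoundsError("control values must lie in [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    @classmethod
    def zeros(cls, times: np.ndarray) -> "ControlPath":
        return cls(times=np.asarray(times, float), values=np.zeros((len(times), 5)))

    def component(self, name: str) -> np.ndarray:
        return self.values[:, CONTROL_NAMES.index(name)]


@dataclass(frozen=True)
class OCSolution:
    """Converged output of the forward-backward sweep."""

    trajectory: Trajectory
    adjoints: np.ndarray  # shape (n_times, 7)
    controls: ControlPath
    objective: float
    iterations: int
    converged: bool
    iteration_log: list[tuple[float, float]] = field(default_factory=list)
    objective_uncontrolled: float | None = None


def _check_controls(controls: np.ndarray) -> np.ndarray:
    u = np.asarray(controls, dtype=float)
    if np.any(u < -1e-12) or np.any(u > 1.0 + 1e-12):
        raise ControlBoundsError(f"controls outside [0, 1]: {u}")
    return u


def rhs_controlled(
    t: float,
    state: np.ndarray,
    controls: Sequence[float] | np.ndarray,
    params: ModelParameters,
) -> np.ndarray:
    """Controlled vector field; with all controls zero it coincides with the
    uncontrolled dynamics."""
    u1, u2, u3, u4, u5 = _check_controls(controls)
    S, D, M, Dm, Rd, Rm, Rdm = np.asarray(state, dtype=float)
    p = params
    alpha1 = p.a1 * (D + Dm)
    alpha2 = p.a2 * (M + Dm)
    c1 = 1.0 - u1
    c2 = 1.0 - u2
    return np.array(
        [
            p.xi + p.gamma1 * Rd + p.gamma2 * Rm + p.gamma3 * Rdm
            - c1 * alpha1 * S - c2 * alpha2 * S - p.mu * S,
            c1 * alpha1 * S - (p.mu + p.phi1 + p.delta1 + u4) * D - c2 * alpha2 * D,
            c2 * alpha2 * S - (p.mu + p.phi2 + p.delta2 + u5) * M - c1 * alpha1 * M,
            c2 * alpha2 * D + c1 * alpha1 * M - (p.mu + p.phi3 + p.k1 + u3) * Dm,
            (p.delta1 + u4) * D - (p.mu + p.gamma1) * Rd,
            (p.delta2 + u5) * M - (p.mu + p.gamma2) * Rm,
            (p.k1 + u3) * Dm - (p.mu + p.gamma3) * Rdm,
        ]
    )


def jacobian_controlled(
    state: np.ndarray,
    controls: Sequence[float] | np.ndarray,
    params: ModelParameters,
) -> np.ndarray:
    """Exact 7x7 Jacobian d f / d state of the controlled vector field.

    The forces alpha1 = a1*(D+Dm) and alpha2 = a2*(M+Dm) are state functions,
    so rows 1-4 carry extra a1/a2 terms beyond the per-compartment rates.
    """
    u1, u2, u3, u4, u5 = np.asarray(controls, dtype=float)
    S, D, M, Dm, Rd, Rm, Rdm = np.asarray(state, dtype=float)
    p = params
    alpha1 = p.a1 * (D + Dm)
    alpha2 = p.a2 * (M + Dm)
    c1 = 1.0 - u1
    c2 = 1.0 - u2
    J = np.zeros((7, 7))
    # S' row
    J[0, 0] = -c1 * alpha1 - c2 * alpha2 - p.mu
    J[0, 1] = -c1 * p.a1 * S
    J[0, 2] = -c2 * p.a2 * S
    J[0, 3] = -c1 * p.a1 * S - c2 * p.a2 * S
    J[0, 4] = p.gamma1
    J[0, 5] = p.gamma2
    J[0, 6] = p.gamma3
    # D' row
    J[1, 0] = c1 * alpha1
    J[1, 1] = c1 * p.a1 * S - (p.mu + p.phi1 + p.delta1 + u4) - c2 * alpha2
    J[1, 2] = -c2 * p.a2 * D
    J[1, 3] = c1 * p.a1 * S - c2 * p.a2 * D
    # M' row
    J[2, 0] = c2 * alpha2
    J[2, 1] = -c1 * p.a1 * M
    J[2, 2] = c2 * p.a2 * S - (p.mu + p.phi2 + p.delta2 + u5) - c1 * alpha1
    J[2, 3] = c2 * p.a2 * S - c1 * p.a1 * M
    # Dm' row
    J[3, 1] = c2 * alpha2 + c1 * p.a1 * M
    J[3, 2] = c2 * p.a2 * D + c1 * alpha1
    J[3, 3] = c2 * p.a2 * D + c1 * p.a1 * M - (p.mu + p.phi3 + p.k1 + u3)
    # recovered rows
    J[4, 1] = p.delta1 + u4
    J[4, 4] = -(p.mu + p.gamma1)
    J[5, 2] = p.delta2 + u5
    J[5, 5] = -(p.mu + p.gamma2)
    J[6, 3] = p.k1 + u3
    J[6, 6] = -(p.mu + p.gamma3)
    return J


def objective(
    trajectory: Trajectory,
    controls: ControlPath,
    weights: ObjectiveWeights,
) -> float:
    """Composite-trapezoid quadrature of the running cost over the grid."""
    if trajectory.times.shape != controls.times.shape or np.any(
        trajectory.times != controls.times
    ):
        raise ValueError("trajectory and controls must share the same time grid")
    D = trajectory.states[:, 1]
    M = trajectory.states[:, 2]
    Dm = trajectory.states[:, 3]
    w = weights.control_costs
    integrand = (
        weights.A1 * D
        + weights.A2 * M
        + weights.A3 * Dm
        + 0.5 * (controls.values**2 @ w)
    )
    return float(np.trapezoid(integrand, trajectory.times))


def _running_cost(
    state: np.ndarray, controls: np.ndarray, weights: ObjectiveWeights
) -> float:
    w = weights.control_costs
    u = np.asarray(controls, dtype=float)
    return float(
        weights.A1 * state[1]
        + weights.A2 * state[2]
        + weights.A3 * state[3]
        + 0.5 * np.dot(w, u**2)
    )


def hamiltonian(
    state: np.ndarray,
    controls: Sequence[float] | np.ndarray,
    adjoints: np.ndarray,
    params: ModelParameters,
    weights: ObjectiveWeights,
) -> float:
    """H = running cost + adjoint-weighted controlled dynamics."""
    u = np.asarray(controls, dtype=float)
    lam = np.asarray(adjoints, dtype=float)
    f = rhs_controlled(0.0, state, u, params)
    return _running_cost(np.asarray(state, float), u, weights) + float(np.dot(lam, f))


def adjoint_rhs(
    state: np.ndarray,
    controls: Sequence[float] | np.ndarray,
    adjoints: np.ndarray,
    params: ModelParameters,
    weights: ObjectiveWeights,
) -> np.ndarray:
    """dlambda/dt = -dH/dstate, assembled from the analytic Jacobian.

    Only the D, M, Dm slots of the running cost survive in grad(g), so at the
    origin with zero adjoints the derivative is (0, -A1, -A2, -A3, 0, 0, 0).
    """
    lam = np.asarray(adjoints, dtype=float)
    grad_g = np.zeros(7)
    grad_g[1:4] = weights.state_costs
    J = jacobian_controlled(state, controls, params)
    return -(grad_g + J.T @ lam)


def control_update(
    state: np.ndarray,
    adjoints: np.ndarray,
    params: ModelParameters,
    weights: ObjectiveWeights,
    bounds: np.ndarray | None = None,
) -> np.ndarray:
    """Clamped stationary point of H in each control (dH/du_k = 0).

    ``bounds`` is a (5, 2) array of per-control (lower, upper) within [0, 1];
    the default is the full box.
    """
    S, D, M, Dm = np.asarray(state, dtype=float)[:4]
    l1, l2, l3, l4, l5, l6, l7 = np.asarray(adjoints, dtype=float)
    p = params
    w = weights.control_costs
    if np.any(w == 0.0):
        raise ZeroDivisionError("zero control-cost weight")
    alpha1 = p.a1 * (D + Dm)
    alpha2 = p.a2 * (M + Dm)
    phi = np.array(
        [
            alpha1 * ((l2 - l1) * S + (l4 - l3) * M) / w[0],
            alpha2 * ((l3 - l1) * S + (l4 - l2) * D) / w[1],
            (l4 - l7) * Dm / w[2],
            (l2 - l5) * D / w[3],
            (l3 - l6) * M / w[4],
        ]
    )
    if bounds is None:
        lo, hi = np.zeros(5), np.ones(5)
    else:
        b = np.asarray(bounds, dtype=float)
        lo, hi = b[:, 0], b[:, 1]
        if np.any(lo < 0) or np.any(hi > 1) or np.any(lo > hi):
            raise ControlBoundsError(f"invalid control bounds {b}")
    return np.clip(phi, lo, hi)


# -- forward-backward sweep --------------------------------------------------


def _integrate_forward(
    times: np.ndarray,
    state0: np.ndarray,
    u: np.ndarray,
    params: ModelParameters,
) -> np.ndarray:
    """RK4 forward pass; controls are piecewise linear between grid nodes
    (midpoint value at the RK4 half-steps)."""
    n = len(times)
    out = np.empty((n, 7))
    y = np.array(state0, dtype=float)
    out[0] = y
    for i in range(n - 1):
        h = times[i + 1] - times[i]
        u0 = u[i]
        u1 = u[i + 1]
        um = 0.5 * (u0 + u1)
        k1 = rhs_controlled(times[i], y, u0, params)
        k2 = rhs_controlled(times[i] + 0.5 * h, y + 0.5 * h * k1, um, params)
        k3 = rhs_controlled(times[i] + 0.5 * h, y + 0.5 * h * k2, um, params)
        k4 = rhs_controlled(times[i] + h, y + h * k3, u1, params)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(y)) or np.max(np.abs(y)) > _BLOWUP_LIMIT:
            raise BlowUpError(f"forward sweep blew up at t={times[i + 1]:g}")
        out[i + 1] = y
    return out


def _integrate_backward(
    times: np.ndarray,
    states: np.ndarray,
    u: np.ndarray,
    params: ModelParameters,
    weights: ObjectiveWeights,
) -> np.ndarray:
    """RK4 backward pass from the transversality condition lambda(T) = 0;
    the stored forward state (and the controls) are interpolated linearly at
    the half-steps."""
    n = len(times)
    lam = np.zeros(7)
    out = np.empty((n, 7))
    out[-1] = lam
    for i in range(n - 1, 0, -1):
        h = times[i] - times[i - 1]
        x1, x0 = states[i], states[i - 1]
        xm = 0.5 * (x0 + x1)
        u1, u0 = u[i], u[i - 1]
        um = 0.5 * (u0 + u1)
        # integrating in -t direction: lambda' = -dH/dx evaluated backwards
        k1 = adjoint_rhs(x1, u1, lam, params, weights)
        k2 = adjoint_rhs(xm, um, lam - 0.5 * h * k1, params, weights)
        k3 = adjoint_rhs(xm, um, lam - 0.5 * h * k2, params, weights)
        k4 = adjoint_rhs(x0, u0, lam - h * k3, params, weights)
        lam = lam - (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(lam)) or np.max(np.abs(lam)) > _BLOWUP_LIMIT:
            raise BlowUpError(f"backward sweep blew up at t={times[i - 1]:g}")
        out[i - 1] = lam
    return out


def forward_backward_sweep(
    params: ModelParameters,
    state0: Sequence[float] | np.ndarray,
    weights: ObjectiveWeights,
    *,
    t1: float = 52.0,
    t0: float = 0.0,
    step: float = 0.01,
    bounds: np.ndarray | None = None,
    tol: float = 1e-3,
    max_iter: int = 200,
    relaxation: float = 0.5,
) -> OCSolution:
    """Iterate forward state / backward adjoint / relaxed control update.

    Convergence requires, for every control, ||u_new - u_old||_1 <=
    tol * ||u_new||_1 (absolute fallback when the control is identically
    zero).  Non-convergence is reported via ``converged=False`` rather than
    raised.
    """
    if tol <= 0 or max_iter < 1 or not (0.0 < relaxation <= 1.0):
        raise ValueError("need tol > 0, max_iter >= 1, 0 < relaxation <= 1")
    times = _time_grid(t0, t1, step)
    n = len(times)
    state0 = np.asarray(state0, dtype=float)
    u = np.zeros((n, 5))
    if bounds is not None:
        b = np.asarray(bounds, dtype=float)
        u = np.clip(u, b[:, 0], b[:, 1])
    log: list[tuple[float, float]] = []
    converged = False
    states = adjoints = None
    iterations = 0
    for iterations in range(1, max_iter + 1):
        states = _integrate_forward(times, state0, u, params)
        adjoints = _integrate_backward(times, states, u, params, weights)
        u_char = np.empty_like(u)
        for i in range(n):
            u_char[i] = control_update(states[i], adjoints[i], params, weights, bounds)
        u_new = relaxation * u_char + (1.0 - relaxation) * u
        diff = np.abs(u_new - u).sum(axis=0)
        scale = np.abs(u_new).sum(axis=0)
        ok = np.where(scale > 0.0, diff <= tol * scale, diff <= tol)
        traj = Trajectory(times=times, states=states)
        J = objective(traj, ControlPath(times=times, values=np.clip(u, 0, 1)), weights)
        log.append((J, float(diff.max())))
        u = u_new
        if bool(np.all(ok)):
            converged = True
            break
    # final forward pass so trajectory, adjoints and controls are consistent
    states = _integrate_forward(times, state0, u, params)
    adjoints = _integrate_backward(times, states, u, params, weights)
    traj = Trajectory(times=times, states=states)
    path = ControlPath(times=times, values=np.clip(u, 0.0, 1.0))
    J = objective(traj, path, weights)
    base_states = _integrate_forward(times, state0, np.zeros((n, 5)), params)
    J0 = objective(
        Trajectory(times=times, states=base_states),
        ControlPath.zeros(times),
        weights,
    )
    return OCSolution(
        trajectory=traj,
        adjoints=adjoints,
        controls=path,
        objective=J,
        iterations=iterations,
        converged=converged,
        iteration_log=log,
        objective_uncontrolled=J0,
    )


def efficacy(
    controlled: Trajectory,
    baseline: Trajectory,
    compartment: str,
) -> np.ndarray:
    """Fractional reduction E(t) = 1 - X_controlled(t)/X_baseline(t).

    Grid points where the baseline hits zero are reported as NaN (undefined
    efficacy) rather than raising.
    """
    if compartment not in ("D", "M", "Dm"):
        raise ValueError(f"compartment must be one of D, M, Dm, got {compartment!r}")
    if controlled.times.shape != baseline.times.shape or np.any(
        controlled.times != baseline.times
    ):
        raise ValueError("trajectories must share the same time grid")
    xc = controlled.component(compartment)
    xb = baseline.component(compartment)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = 1.0 - xc / xb
    e[xb == 0.0] = np.nan
    return e
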