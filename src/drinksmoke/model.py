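"""Uncontrolled dynamics of the drinking-smoking co-dependence model.

Seven compartments, in fixed order: susceptible S, drinkers D, smokers M,
co-dependent Dm, recovered drinkers Rd, recovered smokers Rm, recovered
co-dependent Rdm.  Recruitment enters S at rate xi; susceptibles take up
drinking at the state-dependent force alpha1 = a1*(D + Dm) and smoking at
alpha2 = a2*(M + Dm); drinkers exposed to alpha2 (and smokers to alpha1)
move into the co-dependent class; recovery and relapse close the loops.

The vector field::

    S'   = xi + g1*Rd + g2*Rm + g3*Rdm - (alpha1 + alpha2 + mu)*S
    D'   = alpha1*S - (mu + phi1 + d1 + alpha2)*D
    M'   = alpha2*S - (mu + phi2 + d2 + alpha1)*M
    Dm'  = alpha2*D + alpha1*M - (mu + phi3 + k1)*Dm
    Rd'  = d1*D - (mu + g1)*Rd
    Rm'  = d2*M - (mu + g2)*Rm
    Rdm' = k1*Dm - (mu + g3)*Rdm

Summing the seven equations gives N' = xi - mu*N - phi1*D - phi2*M - phi3*Dm,
so N' <= xi - mu*N and the region 0 <= N <= xi/mu is forward-invariant.

All right-hand sides accept a state of shape ``(7,)`` or ``(7, k)`` (k
independent states integrated in lockstep), which the fixed-step RK4
integrator exploits for batched stability probes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .params import ModelParameters

__all__ = [
    "STATE_NAMES",
    "Trajectory",
    "BlowUpError",
    "force_of_codependence",
    "rhs_uncontrolled",
    "rk4_integrate",
    "simulate",
]

STATE_NAMES: tuple[str, ...] = ("S", "D", "M", "Dm", "Rd", "Rm", "Rdm")

#: mid-integration magnitude above which the integrator declares blow-up
_BLOWUP_LIMIT = 1e12


class BlowUpError(RuntimeError):
    """Raised when an integrated state leaves the numerically sane region."""


@dataclass(frozen=True)
class Trajectory:
    """A time grid (weeks) and the state at each grid point.

    ``states`` has shape ``(len(times), 7)`` for a single run, or
    ``(len(times), 7, k)`` for a batch of k runs.
    """

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        if times.ndim != 1 or len(times) != len(states):
            raise ValueError("times and states must have matching leading length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)

    def component(self, name: str) -> np.ndarray:
        """Time series of one compartment by name."""
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def total(self) -> np.ndarray:
        """Total population N(t) = sum of the seven compartments."""
        return self.states.sum(axis=1)

    def at(self, t: float) -> np.ndarray:
        """State at time ``t``, linearly interpolated between grid points."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(f"t={t} outside the trajectory span")
        i = int(np.searchsorted(self.times, t))
        if i < len(self.times) and self.times[i] == t:
            return self.states[i].copy()
        t0, t1 = self.times[i - 1], self.times[i]
        w = (t - t0) / (t1 - t0)
        return (1.0 - w) * self.states[i - 1] + w * self.states[i]


def force_of_codependence(
    state: np.ndarray, params: ModelParameters
) -> tuple[np.ndarray, np.ndarray]:
    """State-dependent per-capita uptake rates (alpha1, alpha2).

    alpha1 = a1*(D + Dm) drives recruitment into drinking, alpha2 =
    a2*(M + Dm) into smoking; co-dependent individuals exert both forces.
    """
    state = np.asarray(state, dtype=float)
    alpha1 = params.a1 * (state[1] + state[3])
    alpha2 = params.a2 * (state[2] + state[3])
    return alpha1, alpha2


def rhs_uncontrolled(
    t: float, state: np.ndarray, params: ModelParameters
) -> np.ndarray:
    """Time derivative of the seven compartments (autonomous; t is unused)."""
    y = np.asarray(state, dtype=float)
    S, D, M, Dm, Rd, Rm, Rdm = y
    p = params
    alpha1 = p.a1 * (D + Dm)
    alpha2 = p.a2 * (M + Dm)
    return np.array(
        [
            p.xi + p.gamma1 * Rd + p.gamma2 * Rm + p.gamma3 * Rdm
            - (alpha1 + alpha2 + p.mu) * S,
            alpha1 * S - (p.mu + p.phi1 + p.delta1 + alpha2) * D,
            alpha2 * S - (p.mu + p.phi2 + p.delta2 + alpha1) * M,
            alpha2 * D + alpha1 * M - (p.mu + p.phi3 + p.k1) * Dm,
            p.delta1 * D - (p.mu + p.gamma1) * Rd,
            p.delta2 * M - (p.mu + p.gamma2) * Rm,
            p.k1 * Dm - (p.mu + p.gamma3) * Rdm,
        ]
    )


def _time_grid(t0: float, t1: float, step: float) -> np.ndarray:
    """Uniform grid from t0 to t1; a shortened last step absorbs remainders."""
    if t1 <= t0:
        raise ValueError(f"t1={t1} must exceed t0={t0}")
    if step <= 0:
        raise ValueError(f"step={step} must be positive")
    n = (t1 - t0) / step
    n_round = round(n)
    if n_round >= 1 and abs(n - n_round) <= 1e-9 * max(1.0, n):
        grid = t0 + step * np.arange(n_round + 1)
        grid[-1] = t1
        return grid
    n_full = int(np.floor(n))
    grid = t0 + step * np.arange(n_full + 1)
    return np.append(grid, t1)


def rk4_integrate(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    state0: Sequence[float] | np.ndarray,
    t0: float,
    t1: float,
    step: float,
) -> Trajectory:
    """Classical fixed-step 4th-order Runge-Kutta integration.

    ``rhs(t, y)`` must return an array of the shape of ``y``; ``y`` may be
    ``(7,)`` or ``(7, k)``.  The returned trajectory contains both endpoints.
    Raises :class:`BlowUpError` if any state magnitude exceeds 1e12.
    """
    y = np.array(state0, dtype=float)
    times = _time_grid(t0, t1, step)
    out = np.empty((len(times),) + y.shape)
    out[0] = y
    for i in range(1, len(times)):
        h = times[i] - times[i - 1]
        t = times[i - 1]
        k1 = rhs(t, y)
        k2 = rhs(t + 0.5 * h, y + 0.5 * h * k1)
        k3 = rhs(t + 0.5 * h, y + 0.5 * h * k2)
        k4 = rhs(t + h, y + h * k3)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(y)) or np.max(np.abs(y)) > _BLOWUP_LIMIT:
            raise BlowUpError(f"state magnitude exceeded {_BLOWUP_LIMIT:g} at t={times[i]:g}")
        out[i] = y
    return Trajectory(times=times, states=out)


def simulate(
    params: ModelParameters,
    state0: Sequence[float] | np.ndarray,
    t1: float,
    *,
    t0: float = 0.0,
    step: float = 0.01,
) -> Trajectory:
    """Integrate the uncontrolled model from ``state0`` over ``[t0, t1]``."""
    return rk4_integrate(
        lambda t, y: rhs_uncontrolled(t, y, params), state0, t0, t1, step
    )
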