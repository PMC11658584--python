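"""Model parameters for the drinking-smoking co-dependence model.

The model is parameterised by 13 nonnegative rate constants, all in units of
week^-1:

* ``xi`` — recruitment into the susceptible pool (birth / peer influx),
* ``a1``, ``a2`` — contact rates through which susceptibles become drinkers
  and smokers respectively (the forces of co-dependence are
  ``alpha1 = a1*(D + Dm)`` and ``alpha2 = a2*(M + Dm)``),
* ``delta1``, ``delta2``, ``k1`` — recovery rates of drinkers, smokers and
  co-dependent individuals,
* ``mu`` — natural death rate (acts on every compartment),
* ``phi1``, ``phi2``, ``phi3`` — drinking-, smoking- and
  co-dependence-induced death rates,
* ``gamma1``, ``gamma2``, ``gamma3`` — relapse rates Rd->S, Rm->S, Rdm->S.

"Paper mode" enforces the two modelling assumptions used to estimate the
composite rates: ``phi3 = phi1 + phi2`` and ``gamma3 = (gamma1 + gamma2)/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "ModelParameters",
    "PARAM_NAMES",
    "table2_preset",
    "InvalidParameterError",
]

PARAM_NAMES: tuple[str, ...] = (
    "xi",
    "a1",
    "a2",
    "delta1",
    "delta2",
    "k1",
    "mu",
    "phi1",
    "phi2",
    "phi3",
    "gamma1",
    "gamma2",
    "gamma3",
)

#: relative tolerance for the paper-mode composite-rate identities
_PAPER_MODE_RTOL = 1e-12


class InvalidParameterError(ValueError):
    """Raised when a rate constant violates the model's sign constraints."""


@dataclass(frozen=True)
class ModelParameters:
    """The 13 rate constants of the co-dependence model (week^-1).

    All rates must be >= 0, and ``mu`` and ``xi`` strictly positive (a
    closed population with no recruitment or no mortality has no finite
    demographic steady state S* = xi/mu).
    """

    xi: float
    a1: float
    a2: float
    delta1: float
    delta2: float
    k1: float
    mu: float
    phi1: float
    phi2: float
    phi3: float
    gamma1: float
    gamma2: float
    gamma3: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise InvalidParameterError(f"{f.name} must be finite, got {v!r}")
            if v < 0:
                raise InvalidParameterError(f"{f.name} must be >= 0, got {v!r}")
        if self.mu <= 0:
            raise InvalidParameterError(f"mu must be > 0, got {self.mu!r}")
        if self.xi <= 0:
            raise InvalidParameterError(f"xi must be > 0, got {self.xi!r}")

    # -- constructors ----------------------------------------------------

    @classmethod
    def paper_mode(
        cls,
        *,
        xi: float,
        a1: float,
        a2: float,
        delta1: float,
        delta2: float,
        k1: float,
        mu: float,
        phi1: float,
        phi2: float,
        gamma1: float,
        gamma2: float,
    ) -> "ModelParameters":
        """Build parameters with the composite rates derived from the
        modelling assumptions phi3 = phi1 + phi2, gamma3 = (gamma1+gamma2)/2."""
        return cls(
            xi=xi,
            a1=a1,
            a2=a2,
            delta1=delta1,
            delta2=delta2,
            k1=k1,
            mu=mu,
            phi1=phi1,
            phi2=phi2,
            phi3=phi1 + phi2,
            gamma1=gamma1,
            gamma2=gamma2,
            gamma3=(gamma1 + gamma2) / 2.0,
        )

    @classmethod
    def from_dict(
        cls, values: Mapping[str, float], *, paper_mode: bool = True
    ) -> "ModelParameters":
        """Build parameters from a flat name->value mapping.

        Unknown keys are rejected.  In paper mode, ``phi3``/``gamma3`` may be
        omitted (they are derived) and, if supplied, must satisfy the
        composite-rate identities to relative tolerance 1e-12.
        """
        unknown = set(values) - set(PARAM_NAMES)
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter name(s): {sorted(unknown)}"
            )
        vals = dict(values)
        if paper_mode:
            required = set(PARAM_NAMES) - {"phi3", "gamma3"}
            missing = required - set(vals)
            if missing:
                raise InvalidParameterError(f"missing parameter(s): {sorted(missing)}")
            phi3 = vals["phi1"] + vals["phi2"]
            gamma3 = (vals["gamma1"] + vals["gamma2"]) / 2.0
            for name, derived in (("phi3", phi3), ("gamma3", gamma3)):
                if name in vals and not np.isclose(
                    vals[name], derived, rtol=_PAPER_MODE_RTOL, atol=0.0
                ):
                    raise InvalidParameterError(
                        f"{name}={vals[name]!r} violates the paper-mode identity "
                        f"(expected {derived!r})"
                    )
            vals["phi3"] = phi3
            vals["gamma3"] = gamma3
        else:
            missing = set(PARAM_NAMES) - set(vals)
            if missing:
                raise InvalidParameterError(f"missing parameter(s): {sorted(missing)}")
        return cls(**vals)

    # -- views -----------------------------------------------------------

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given rates overridden (no re-derivation)."""
        return replace(self, **changes)

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_array())


def table2_preset() -> ModelParameters:
    """The literature-sourced baseline parameter set (week^-1).

    With these rates the drinkers-only reproduction number is ~0.391 and the
    smokers-only one ~0.604, so the behaviour-free equilibrium is stable.
    """
    return ModelParameters.paper_mode(
        xi=0.8,
        gamma1=0.7,
        a1=0.00479,
        mu=0.0952,
        phi1=0.000009,
        delta1=0.00767,
        gamma2=0.00575,
        a2=0.035,
        phi2=0.175,
        delta2=0.217,
        k1=0.01923,
    )
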