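"""Local and global sensitivity analysis of the reproduction numbers.

Local: the normalised forward sensitivity index (elasticity) of a target
quantity R with respect to a parameter x,

    W_x(R) = (dR/dx) * (x / R),

coded analytically from the closed forms R0D = a1*xi/(mu*(mu+phi1+delta1))
and R0M = a2*xi/(mu*(mu+phi2+delta2)), with a central-difference fallback.
R0D is exactly linear in a1 and xi (index +1) and its mu-elasticity is
-1 - mu/(mu+phi1+delta1).

Global: Latin hypercube sampling over per-parameter ranges combined with
partial rank correlation coefficients (PRCC) — the correlation between the
rank-residuals of a parameter and of an output after regressing out the
ranks of all other parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .equilibria import r0_drinkers, r0_smokers
from .params import PARAM_NAMES, ModelParameters

__all__ = [
    "SensitivityIndex",
    "PRCCResult",
    "TARGETS",
    "forward_index",
    "forward_index_table",
    "forward_index_fd",
    "lhs_sample",
    "default_lhs_ranges",
    "prcc",
    "r0_surface",
    "r0_uncertainty_summary",
    "DEFAULT_LHS_SEED",
    "DEFAULT_LHS_N",
]

#: default design of the global-sensitivity study
DEFAULT_LHS_N = 2000
DEFAULT_LHS_SEED = 20241219
DEFAULT_LHS_REL_HALFWIDTH = 0.25


@dataclass(frozen=True)
class SensitivityIndex:
    target: str
    parameter: str
    index: float


@dataclass(frozen=True)
class PRCCResult:
    parameter: str
    coefficient: float
    output: str
    n_samples: int
    seed: int | None = None


def _r0_codependence(p: ModelParameters) -> float:
    return max(r0_drinkers(p), r0_smokers(p))


TARGETS: dict[str, Callable[[ModelParameters], float]] = {
    "R0D": r0_drinkers,
    "R0M": r0_smokers,
    "R0": _r0_codependence,
}


def _analytic_index(target: str, parameter: str, p: ModelParameters) -> float:
    """Closed-form elasticities; parameters absent from a formula have
    index exactly 0."""
    dD = p.mu + p.phi1 + p.delta1
    dM = p.mu + p.phi2 + p.delta2
    r0d = {
        "a1": 1.0,
        "xi": 1.0,
        "mu": -1.0 - p.mu / dD,
        "phi1": -p.phi1 / dD,
        "delta1": -p.delta1 / dD,
    }
    r0m = {
        "a2": 1.0,
        "xi": 1.0,
        "mu": -1.0 - p.mu / dM,
        "phi2": -p.phi2 / dM,
        "delta2": -p.delta2 / dM,
    }
    if target == "R0D":
        return r0d.get(parameter, 0.0)
    if target == "R0M":
        return r0m.get(parameter, 0.0)
    # R0 = max(R0D, R0M): elasticity of the dominant branch (the max is not
    # differentiable at a tie; the drinkers branch wins ties by convention)
    if r0_drinkers(p) >= r0_smokers(p):
        return r0d.get(parameter, 0.0)
    return r0m.get(parameter, 0.0)


def forward_index(
    target: str, parameter: str, params: ModelParameters
) -> SensitivityIndex:
    """Normalised forward sensitivity index W_x(R) = (dR/dx)(x/R)."""
    if target not in TARGETS:
        raise KeyError(f"unknown target {target!r}; expected one of {list(TARGETS)}")
    if parameter not in PARAM_NAMES:
        raise KeyError(f"unknown parameter {parameter!r}")
    return SensitivityIndex(
        target=target, parameter=parameter,
        index=_analytic_index(target, parameter, params),
    )


def forward_index_fd(
    target: str,
    parameter: str,
    params: ModelParameters,
    *,
    rel_step: float = 1e-6,
) -> float:
    """Central-difference elasticity, the independent check on the analytic
    forms.  Parameters with value zero are perturbed absolutely."""
    if target not in TARGETS:
        raise KeyError(f"unknown target {target!r}")
    if parameter not in PARAM_NAMES:
        raise KeyError(f"unknown parameter {parameter!r}")
    f = TARGETS[target]
    x = getattr(params, parameter)
    h = rel_step * x if x != 0.0 else rel_step
    hi = f(params.replace(**{parameter: x + h}))
    lo = f(params.replace(**{parameter: max(x - h, 0.0)}))
    deriv = (hi - lo) / (2.0 * h) if x - h >= 0 else (hi - f(params)) / h
    r = f(params)
    return deriv * x / r if x != 0.0 else 0.0


def forward_index_table(
    params: ModelParameters, targets: Sequence[str] = ("R0D", "R0M")
) -> pd.DataFrame:
    """Elasticity of every model parameter for each target, long format."""
    rows = [
        {"target": t, "parameter": name,
         "index": _analytic_index(t, name, params)}
        for t in targets
        for name in PARAM_NAMES
    ]
    return pd.DataFrame(rows)


# -- Latin hypercube sampling ------------------------------------------------


def default_lhs_ranges(
    params: ModelParameters,
    rel_halfwidth: float = DEFAULT_LHS_REL_HALFWIDTH,
) -> dict[str, tuple[float, float]]:
    """Symmetric +/-25% (by default) ranges around the baseline rates.

    Zero-valued rates get a degenerate range and are excluded from sampling.
    """
    out = {}
    for name in PARAM_NAMES:
        v = getattr(params, name)
        if v > 0:
            out[name] = ((1.0 - rel_halfwidth) * v, (1.0 + rel_halfwidth) * v)
    return out


def lhs_sample(
    ranges: Mapping[str, tuple[float, float]],
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Latin hypercube design: one draw per equal-probability stratum per
    parameter, stratum order permuted independently; deterministic in seed."""
    if n < 2:
        raise ValueError(f"need n >= 2 samples, got {n}")
    names = list(ranges)
    lows = np.array([ranges[k][0] for k in names])
    highs = np.array([ranges[k][1] for k in names])
    if np.any(lows >= highs):
        bad = [k for k in names if ranges[k][0] >= ranges[k][1]]
        raise ValueError(f"bad range (low >= high) for {bad}")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n=n)
    return pd.DataFrame(qmc.scale(unit, lows, highs), columns=names)


# -- PRCC --------------------------------------------------------------------


def prcc(
    samples: pd.DataFrame,
    outputs: Sequence[float] | np.ndarray,
    *,
    output_label: str = "output",
    seed: int | None = None,
) -> list[PRCCResult]:
    """Partial rank correlation of each sampled parameter with the output.

    All columns are rank-transformed (average ranks on ties); for each
    parameter the ranks of that parameter and of the output are regressed
    (with intercept) on the ranks of all other parameters, and the Pearson
    correlation of the two residual vectors is returned.
    """
    y = np.asarray(outputs, dtype=float)
    n = len(samples)
    if len(y) != n:
        raise ValueError("outputs length must equal the sample count")
    if n < 3:
        raise ValueError("need at least 3 samples")
    X = samples.to_numpy(dtype=float)
    if np.any(np.ptp(X, axis=0) == 0.0) or np.ptp(y) == 0.0:
        raise ValueError("degenerate input: constant column")
    ranks = np.column_stack(
        [stats.rankdata(X[:, j]) for j in range(X.shape[1])]
    )
    yr = stats.rankdata(y)
    results = []
    for j, name in enumerate(samples.columns):
        others = np.delete(ranks, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        beta_x, *_ = np.linalg.lstsq(design, ranks[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(design, yr, rcond=None)
        rx = ranks[:, j] - design @ beta_x
        ry = yr - design @ beta_y
        # a vanishing residual means the other parameters explain all rank
        # variation (e.g. the output is a copy of another parameter): no
        # partial association remains
        if np.linalg.norm(rx) < 1e-9 * n or np.linalg.norm(ry) < 1e-9 * n:
            coef = 0.0
        else:
            coef = float(np.corrcoef(rx, ry)[0, 1])
        results.append(
            PRCCResult(parameter=str(name), coefficient=coef,
                       output=output_label, n_samples=n, seed=seed)
        )
    return results


# -- surfaces and uncertainty summaries --------------------------------------


def r0_surface(
    target: str,
    x_param: str,
    y_param: str,
    x_grid: Sequence[float],
    y_grid: Sequence[float],
    params: ModelParameters,
) -> pd.DataFrame:
    """Target reproduction number on a Cartesian two-parameter grid, all
    other rates held at baseline.  Long format: x, y, value columns."""
    if target not in TARGETS:
        raise KeyError(f"unknown target {target!r}")
    for p in (x_param, y_param):
        if p not in PARAM_NAMES:
            raise KeyError(f"unknown parameter {p!r}")
    x_grid = np.asarray(x_grid, dtype=float)
    y_grid = np.asarray(y_grid, dtype=float)
    if x_grid.size == 0 or y_grid.size == 0:
        raise ValueError("grids must be nonempty")
    f = TARGETS[target]
    rows = []
    for xv in x_grid:
        for yv in y_grid:
            rows.append(
                {
                    x_param: float(xv),
                    y_param: float(yv),
                    target: f(params.replace(**{x_param: xv, y_param: yv})),
                }
            )
    return pd.DataFrame(rows)


def r0_uncertainty_summary(outputs: Sequence[float] | np.ndarray) -> pd.Series:
    """2.5/25/50/75/97.5 percentiles of a sampled output (the central 95%
    interval is the outer pair)."""
    y = np.asarray(outputs, dtype=float)
    if len(y) < 20:
        raise ValueError(f"need at least 20 samples, got {len(y)}")
    q = [2.5, 25.0, 50.0, 75.0, 97.5]
    return pd.Series(np.percentile(y, q), index=[f"p{v:g}" for v in q])
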