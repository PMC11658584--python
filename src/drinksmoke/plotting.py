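"""Minimal plotting helpers for the analysis tables.

The library's contract is the underlying data (surface grids, PRCC tables,
trajectories); these helpers are thin conveniences over matplotlib, which is
an optional dependency (``pip install drinksmoke[plot]``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _require_matplotlib():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "matplotlib is required for plotting (install the 'plot' extra)"
        ) from exc
    return plt


def plot_r0_surface(surface: pd.DataFrame, ax=None):
    """3-column long-format grid (x, y, value) as a filled contour plot."""
    plt = _require_matplotlib()
    if ax is None:
        _, ax = plt.subplots()
    x_name, y_name, z_name = surface.columns
    pivot = surface.pivot(index=y_name, columns=x_name, values=z_name)
    cs = ax.contourf(pivot.columns, pivot.index, pivot.to_numpy(), levels=20)
    ax.figure.colorbar(cs, ax=ax, label=z_name)
    ax.set_xlabel(x_name)
    ax.set_ylabel(y_name)
    return ax


def plot_tornado(prcc_table: pd.DataFrame, output: str | None = None, ax=None):
    """Horizontal bar chart of PRCC coefficients, sorted by magnitude."""
    plt = _require_matplotlib()
    df = prcc_table
    if output is not None:
        df = df[df["output"] == output]
    df = df.iloc[np.argsort(np.abs(df["prcc"].to_numpy()))]
    if ax is None:
        _, ax = plt.subplots()
    ax.barh(df["parameter"], df["prcc"])
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel("PRCC")
    if output is not None:
        ax.set_title(output)
    return ax


def plot_trajectory(trajectory, components=("D", "M", "Dm"), ax=None):
    """Time series of selected compartments."""
    plt = _require_matplotlib()
    if ax is None:
        _, ax = plt.subplots()
    for name in components:
        ax.plot(trajectory.times, trajectory.component(name), label=name)
    ax.set_xlabel("time (weeks)")
    ax.set_ylabel("compartment size")
    ax.legend()
    return ax
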