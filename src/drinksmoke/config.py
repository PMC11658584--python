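"""Scenario configuration and file I/O.

A scenario bundles everything a run needs: the 13 rate constants, the
initial compartment values, the time grid, the optimal-control weights and
bounds, and the LHS design.  Configs are flat YAML; every omitted field
falls back to the baseline study (literature rates, initial state
(0.6, 0.2, 0.1, 0.06, 0.02, 0, 0), 52-week horizon at step 0.01, A=100,
w=0.5, all five controls enabled).  Unknown keys are rejected so that a
mistyped parameter name fails loudly instead of silently using a default.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .control import CONTROL_NAMES, ControlPath, ObjectiveWeights
from .model import STATE_NAMES, Trajectory
from .params import PARAM_NAMES, ModelParameters, table2_preset
from .sensitivity import (
    DEFAULT_LHS_N,
    DEFAULT_LHS_SEED,
    default_lhs_ranges,
)

__all__ = [
    "ScenarioConfig",
    "ConfigError",
    "DEFAULT_INITIAL_STATE",
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "write_manifest",
]

#: baseline initial compartment values (S, D, M, Dm, Rd, Rm, Rdm)
DEFAULT_INITIAL_STATE: tuple[float, ...] = (0.6, 0.2, 0.1, 0.06, 0.02, 0.0, 0.0)

_TOP_LEVEL_KEYS = {
    "parameters",
    "paper_mode",
    "initial_state",
    "horizon",
    "step",
    "weights",
    "control_bounds",
    "enabled_controls",
    "lhs",
    "output_dir",
}
_WEIGHT_KEYS = {"A1", "A2", "A3", "w1", "w2", "w3", "w4", "w5"}
_LHS_KEYS = {"ranges", "n", "seed", "rel_halfwidth"}


class ConfigError(ValueError):
    """Invalid or unparsable scenario configuration."""


@dataclass(frozen=True)
class ScenarioConfig:
    """A fully resolved, validated scenario."""

    parameters: ModelParameters
    initial_state: np.ndarray
    horizon: float = 52.0
    step: float = 0.01
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    control_bounds: np.ndarray = field(
        default_factory=lambda: np.column_stack([np.zeros(5), np.ones(5)])
    )
    enabled_controls: tuple[str, ...] = CONTROL_NAMES
    lhs_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    lhs_n: int = DEFAULT_LHS_N
    lhs_seed: int = DEFAULT_LHS_SEED
    output_dir: Path = Path(".")

    def __post_init__(self) -> None:
        state = np.asarray(self.initial_state, dtype=float)
        if state.shape != (7,):
            raise ConfigError("initial_state must have 7 components")
        if np.any(state < 0):
            raise ConfigError("initial_state components must be >= 0")
        object.__setattr__(self, "initial_state", state)
        if self.horizon <= 0:
            raise ConfigError("horizon must be > 0")
        if self.step <= 0:
            raise ConfigError("step must be > 0")
        unknown = set(self.enabled_controls) - set(CONTROL_NAMES)
        if unknown:
            raise ConfigError(f"unknown control name(s): {sorted(unknown)}")
        if not self.lhs_ranges:
            object.__setattr__(
                self, "lhs_ranges", default_lhs_ranges(self.parameters)
            )

    def effective_bounds(self) -> np.ndarray:
        """Control bounds with disabled controls pinned to (0, 0)."""
        b = np.array(self.control_bounds, dtype=float)
        for i, name in enumerate(CONTROL_NAMES):
            if name not in self.enabled_controls:
                b[i] = (0.0, 0.0)
        return b


def _default_config() -> ScenarioConfig:
    return ScenarioConfig(
        parameters=table2_preset(),
        initial_state=np.array(DEFAULT_INITIAL_STATE),
    )


def load_config(path: str | Path | None = None) -> ScenarioConfig:
    """Load a YAML scenario; ``None`` (or an empty file) yields the baseline
    study.  Unknown keys anywhere raise :class:`ConfigError` naming them."""
    if path is None:
        return _default_config()
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        return _default_config()
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")

    paper_mode = bool(raw.get("paper_mode", True))
    overrides = dict(raw.get("parameters") or {})
    unknown = set(overrides) - set(PARAM_NAMES)
    if unknown:
        raise ConfigError(f"parameters: unknown name(s) {sorted(unknown)}")
    base = table2_preset().as_dict()
    merged = {**base, **{k: float(v) for k, v in overrides.items()}}
    if paper_mode:
        # re-derive composites unless explicitly pinned by the user
        if "phi3" not in overrides:
            merged["phi3"] = merged["phi1"] + merged["phi2"]
        if "gamma3" not in overrides:
            merged["gamma3"] = (merged["gamma1"] + merged["gamma2"]) / 2.0
    try:
        params = ModelParameters.from_dict(merged, paper_mode=paper_mode)
    except ValueError as exc:
        raise ConfigError(f"parameters: {exc}") from exc

    kwargs: dict[str, Any] = {"parameters": params}
    state = raw.get("initial_state", DEFAULT_INITIAL_STATE)
    if isinstance(state, Mapping):
        unknown = set(state) - set(STATE_NAMES)
        if unknown:
            raise ConfigError(f"initial_state: unknown name(s) {sorted(unknown)}")
        state = [float(state.get(n, 0.0)) for n in STATE_NAMES]
    kwargs["initial_state"] = np.asarray(state, dtype=float)
    for key in ("horizon", "step"):
        if key in raw:
            kwargs[key] = float(raw[key])
    if "weights" in raw:
        w = dict(raw["weights"])
        unknown = set(w) - _WEIGHT_KEYS
        if unknown:
            raise ConfigError(f"weights: unknown key(s) {sorted(unknown)}")
        kwargs["weights"] = ObjectiveWeights(**{k: float(v) for k, v in w.items()})
    if "control_bounds" in raw:
        cb = raw["control_bounds"]
        if isinstance(cb, Mapping):
            unknown = set(cb) - set(CONTROL_NAMES)
            if unknown:
                raise ConfigError(f"control_bounds: unknown name(s) {sorted(unknown)}")
            b = np.column_stack([np.zeros(5), np.ones(5)])
            for i, name in enumerate(CONTROL_NAMES):
                if name in cb:
                    b[i] = [float(x) for x in cb[name]]
        else:
            b = np.asarray(cb, dtype=float)
        if b.shape != (5, 2):
            raise ConfigError("control_bounds must resolve to shape (5, 2)")
        kwargs["control_bounds"] = b
    if "enabled_controls" in raw:
        kwargs["enabled_controls"] = tuple(raw["enabled_controls"])
    if "lhs" in raw:
        lhs = dict(raw["lhs"])
        unknown = set(lhs) - _LHS_KEYS
        if unknown:
            raise ConfigError(f"lhs: unknown key(s) {sorted(unknown)}")
        if "ranges" in lhs:
            ranges = {
                str(k): (float(v[0]), float(v[1])) for k, v in lhs["ranges"].items()
            }
            unknown = set(ranges) - set(PARAM_NAMES)
            if unknown:
                raise ConfigError(f"lhs ranges: unknown name(s) {sorted(unknown)}")
            kwargs["lhs_ranges"] = ranges
        elif "rel_halfwidth" in lhs:
            kwargs["lhs_ranges"] = default_lhs_ranges(
                params, float(lhs["rel_halfwidth"])
            )
        if "n" in lhs:
            kwargs["lhs_n"] = int(lhs["n"])
        if "seed" in lhs:
            kwargs["lhs_seed"] = int(lhs["seed"])
    if "output_dir" in raw:
        kwargs["output_dir"] = Path(raw["output_dir"])
    return ScenarioConfig(**kwargs)


# -- trajectory round-trip ---------------------------------------------------


def write_trajectory(
    trajectory: Trajectory,
    path: str | Path,
    controls: ControlPath | None = None,
) -> Path:
    """Write a delimited trajectory table; full float precision so it
    round-trips losslessly.  Written atomically: a failed write leaves no
    partial file behind."""
    path = Path(path)
    cols = {"time": trajectory.times}
    for i, name in enumerate(STATE_NAMES):
        cols[name] = trajectory.states[:, i]
    if controls is not None:
        if controls.times.shape != trajectory.times.shape or np.any(
            controls.times != trajectory.times
        ):
            raise ValueError("controls must share the trajectory grid")
        for i, name in enumerate(CONTROL_NAMES):
            cols[name] = controls.values[:, i]
    df = pd.DataFrame(cols)
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            df.to_csv(fh, index=False, float_format="%.17g")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def read_trajectory(path: str | Path) -> tuple[Trajectory, ControlPath | None]:
    """Inverse of :func:`write_trajectory`."""
    df = pd.read_csv(path, float_precision="round_trip")
    times = df["time"].to_numpy()
    states = df[list(STATE_NAMES)].to_numpy()
    traj = Trajectory(times=times, states=states)
    if set(CONTROL_NAMES) <= set(df.columns):
        path_ctrl = ControlPath(
            times=times, values=df[list(CONTROL_NAMES)].to_numpy()
        )
        return traj, path_ctrl
    return traj, None


def write_manifest(
    path: str | Path,
    *,
    config: ScenarioConfig,
    seed: int | None,
    command: str,
    extra: Mapping[str, Any] | None = None,
) -> Path:
    """Record everything needed to replay a run (config echo, seed, version)."""
    from . import __version__

    payload: dict[str, Any] = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "parameters": config.parameters.as_dict(),
        "initial_state": list(map(float, config.initial_state)),
        "horizon": config.horizon,
        "step": config.step,
        "weights": {
            k: getattr(config.weights, k) for k in sorted(_WEIGHT_KEYS)
        },
        "control_bounds": config.control_bounds.tolist(),
        "enabled_controls": list(config.enabled_controls),
        "lhs": {
            "ranges": {k: list(v) for k, v in config.lhs_ranges.items()},
            "n": config.lhs_n,
            "seed": config.lhs_seed,
        },
    }
    if extra:
        payload.update(dict(extra))
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
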