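"""Forward-Euler integration of the ecological system between evolutionary events."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import clonal_run
from .model import (
    ModelParams,
    QGrid,
    SystemState,
    TransmissionMode,
    cost_of_general_resistance,
    derivatives,
)

__all__ = ["IntegratorConfig", "Trajectory", "IntegrationError", "euler_step", "equilibrate"]


class IntegrationError(RuntimeError):
    """Raised when the integration produces non-finite densities."""


@dataclass(frozen=True)
class IntegratorConfig:
    """Settings for one ecological equilibration phase.

    ``clamp_threshold`` is applied once, at the end of the phase: any
    compartment below it is set to exactly zero, so that alleles or pathogens
    on an exponential decay are genuinely removed rather than lingering at
    astronomically small densities.
    """

    dt: float = 0.1
    t_end: float = 1000.0
    clamp_threshold: float = 1e-9

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.t_end < self.dt:
            raise ValueError(f"t_end must be >= dt, got {self.t_end}")
        if self.clamp_threshold < 0:
            raise ValueError("clamp_threshold must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


@dataclass
class Trajectory:
    """Sampled time course of one equilibration."""

    times: np.ndarray
    states: list  # list[SystemState], aligned with times

    def totals(self) -> np.ndarray:
        return np.array([s.total for s in self.states])


def _check_finite(state: SystemState) -> None:
    for name, value in (("S", state.S), ("R", state.R)):
        if not np.all(np.isfinite(value)):
            bad = int(np.flatnonzero(~np.isfinite(value))[0])
            raise IntegrationError(
                f"non-finite density in compartment {name}[{bad}]; reduce dt"
            )
    for name, value in (("I_e", state.I_e), ("I_f", state.I_f)):
        if not np.isfinite(value):
            raise IntegrationError(f"non-finite density in compartment {name}; reduce dt")


def euler_step(state: SystemState, params: ModelParams, grid: QGrid,
               dt: float) -> SystemState:
    """One forward-Euler step with projection onto non-negative densities."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    d = derivatives(state, params, grid)
    new = SystemState(
        np.maximum(state.S + dt * d.S, 0.0),
        np.maximum(state.R + dt * d.R, 0.0),
        max(state.I_e + dt * d.I_e, 0.0),
        max(state.I_f + dt * d.I_f, 0.0),
    )
    _check_finite(new)
    return new


def _run_kernel(state: SystemState, params: ModelParams, grid: QGrid,
                dt: float, n_steps: int) -> SystemState:
    S = state.S.copy()
    R = state.R.copy()
    cost = cost_of_general_resistance(grid.values, params.theta)
    freq = params.transmission_mode is TransmissionMode.frequency
    I_e, I_f = clonal_run(
        S, R, state.I_e, state.I_f, grid.values, cost,
        params.b, params.mu, params.gamma, params.beta_e, params.beta_f,
        params.r, params.c_r, freq, dt, n_steps,
    )
    return SystemState(S, R, I_e, I_f)


def equilibrate(state: SystemState, params: ModelParams, grid: QGrid,
                config: IntegratorConfig,
                record_every: float | None = None) -> SystemState | tuple[SystemState, Trajectory]:
    """Integrate to ``t_end``, then clamp sub-threshold compartments to zero.

    With ``record_every`` set, also returns a :class:`Trajectory` sampled at
    that stride (the initial state is the first sample).
    """
    if np.any(state.S < 0) or np.any(state.R < 0) or state.I_e < 0 or state.I_f < 0:
        raise ValueError("initial state must be non-negative")

    if record_every is None:
        out = _run_kernel(state, params, grid, config.dt, config.n_steps)
    else:
        stride = max(int(round(record_every / config.dt)), 1)
        times = [0.0]
        states = [state.copy()]
        out = state
        done = 0
        while done < config.n_steps:
            chunk = min(stride, config.n_steps - done)
            out = _run_kernel(out, params, grid, config.dt, chunk)
            done += chunk
            times.append(done * config.dt)
            states.append(out.copy())
        traj = Trajectory(np.array(times), states)
    _check_finite(out)

    thr = config.clamp_threshold
    out.S[out.S < thr] = 0.0
    out.R[out.R < thr] = 0.0
    if out.I_e < thr:
        out.I_e = 0.0
    if out.I_f < thr:
        out.I_f = 0.0
    return out if record_every is None else (out, traj)
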