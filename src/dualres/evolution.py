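"""Adaptive-dynamics loop: equilibrate, mutate, repeat, with scheduled introductions.

Each evolutionary iteration integrates the ecological system to its attractor
(t = 1000 by default), records the state, then moves a small fraction (5%) of
every occupied general-resistance bin to the adjacent bins, independently in
the S and R backgrounds.  The specific-resistance allele and the foreign
pathogen are seeded at prescribed iterations at density 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .integrate import IntegratorConfig, equilibrate
from .model import ModelParams, QGrid, SystemState

__all__ = [
    "EventSchedule",
    "EvolutionTrace",
    "OutcomeRecord",
    "SpecificFate",
    "Stability",
    "mutate",
    "run_evolution",
    "classify_stability",
    "summarize_outcome",
]


class SpecificFate(str, Enum):
    S_fixed = "S_fixed"
    R_fixed = "R_fixed"
    polymorphism = "polymorphism"
    hosts_extinct = "hosts_extinct"


class Stability(str, Enum):
    stable = "stable"
    cyclic = "cyclic"


@dataclass(frozen=True)
class EventSchedule:
    """When alleles and pathogens enter the population.

    ``introduce_R_at`` / ``introduce_If_at`` are mutation-iteration indices
    (``None`` = never; 0 = before the first equilibration).  Iterations before
    ``freeze_general_until`` skip the mutation step, which freezes the
    general-resistance distribution and supports the "specific resistance
    evolves first" variant (or, set to ``total_iterations``, fixes q entirely).
    """

    total_iterations: int = 150
    introduce_R_at: int | None = None
    introduce_If_at: int | None = None
    freeze_general_until: int = 0
    intro_R_density: float = 1.0
    intro_If_density: float = 1.0
    intro_R_q: float = 0.0  # R enters without general resistance by default

    def __post_init__(self):
        if self.total_iterations < 1:
            raise ValueError("total_iterations must be >= 1")
        for name in ("introduce_R_at", "introduce_If_at"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= self.total_iterations:
                raise ValueError(
                    f"{name}={v} outside [0, {self.total_iterations}]"
                )
        if not 0 <= self.freeze_general_until <= self.total_iterations:
            raise ValueError("freeze_general_until outside schedule range")


@dataclass
class EvolutionTrace:
    """Per-iteration record of the equilibrated system (pre-mutation)."""

    grid: QGrid
    params: ModelParams
    schedule: EventSchedule
    S_hist: np.ndarray  # (iterations, n) uninfected S densities
    R_hist: np.ndarray  # (iterations, n)
    I_e: np.ndarray
    I_f: np.ndarray
    hosts_extinct: bool = False
    final_state: SystemState | None = None

    @property
    def iterations(self) -> int:
        return self.S_hist.shape[0]

    @property
    def total_S(self) -> np.ndarray:
        return self.S_hist.sum(axis=1)

    @property
    def total_R(self) -> np.ndarray:
        return self.R_hist.sum(axis=1)

    @property
    def R_frequency(self) -> np.ndarray:
        tot = self.total_S + self.total_R
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.total_R / tot, np.nan)

    def q_mode(self, background: str) -> np.ndarray:
        """Modal q bin per iteration (NaN where the background is empty)."""
        hist = self.S_hist if background == "S" else self.R_hist
        tot = hist.sum(axis=1)
        modes = self.grid.values[hist.argmax(axis=1)].astype(float)
        return np.where(tot > 0, modes, np.nan)

    def q_mean(self, background: str) -> np.ndarray:
        """Density-weighted mean q per iteration (NaN where empty)."""
        hist = self.S_hist if background == "S" else self.R_hist
        tot = hist.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, hist @ self.grid.values / tot, np.nan)

    def to_frame(self) -> pd.DataFrame:
        tot = self.total_S + self.total_R + self.I_e + self.I_f
        with np.errstate(invalid="ignore", divide="ignore"):
            prev_e = np.where(tot > 0, self.I_e / tot, np.nan)
            prev_f = np.where(tot > 0, self.I_f / tot, np.nan)
        return pd.DataFrame(
            {
                "iteration": np.arange(self.iterations),
                "total_S": self.total_S,
                "total_R": self.total_R,
                "I_e": self.I_e,
                "I_f": self.I_f,
                "R_frequency": self.R_frequency,
                "q_mode_S": self.q_mode("S"),
                "q_mean_S": self.q_mean("S"),
                "q_mode_R": self.q_mode("R"),
                "q_mean_R": self.q_mean("R"),
                "prevalence_endemic": prev_e,
                "prevalence_foreign": prev_f,
            }
        )


@dataclass(frozen=True)
class OutcomeRecord:
    """Classification of a completed evolutionary run."""

    specific_fate: SpecificFate
    q_S_mode: float | None
    q_S_mean: float | None
    q_R_mode: float | None
    q_R_mean: float | None
    endemic_persists: bool
    foreign_persists: bool
    stability: Stability | None


def _mutate_vector(v: np.ndarray, fraction: float) -> np.ndarray:
    moved = fraction * v
    out = v - moved
    out[1] += moved[0]            # left boundary: all mass to the single neighbour
    out[-2] += moved[-1]          # right boundary likewise
    interior = moved[1:-1] * 0.5  # interior bins split equally
    out[:-2] += interior
    out[2:] += interior
    return out


def mutate(state: SystemState, grid: QGrid, fraction: float = 0.05) -> SystemState:
    """Move ``fraction`` of each occupied q bin to its adjacent bins.

    Applied independently to the S and R backgrounds; total density in each
    background is conserved.  Infected pools are untouched (pathogens do not
    carry the host trait).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    if fraction == 0.0:
        return state.copy()
    return SystemState(
        _mutate_vector(state.S, fraction),
        _mutate_vector(state.R, fraction),
        state.I_e,
        state.I_f,
    )


def run_evolution(params: ModelParams, grid: QGrid, schedule: EventSchedule,
                  config: IntegratorConfig | None = None,
                  initial_state: SystemState | None = None,
                  mutation_fraction: float = 0.05) -> EvolutionTrace:
    """Execute the full mutation/equilibration loop.

    Starts from a single S host at q = 0 plus one endemic-infected host
    (unless ``initial_state`` overrides).  Terminates early, flagging
    ``hosts_extinct``, if the uninfected population falls below the clamp
    threshold.
    """
    config = config or IntegratorConfig()
    if initial_state is None:
        state = SystemState.zeros(grid)
        state.S[grid.index_of(0.0)] = 1.0
        state.I_e = 1.0
    else:
        state = initial_state.copy()

    S_hist, R_hist, Ie_hist, If_hist = [], [], [], []
    extinct = False
    for it in range(schedule.total_iterations):
        if schedule.introduce_R_at is not None and it == schedule.introduce_R_at:
            state.R[grid.index_of(schedule.intro_R_q)] += schedule.intro_R_density
        if schedule.introduce_If_at is not None and it == schedule.introduce_If_at:
            state.I_f += schedule.intro_If_density

        state = equilibrate(state, params, grid, config)
        S_hist.append(state.S.copy())
        R_hist.append(state.R.copy())
        Ie_hist.append(state.I_e)
        If_hist.append(state.I_f)

        if state.total_uninfected <= config.clamp_threshold:
            extinct = True
            break
        if it >= schedule.freeze_general_until:
            state = mutate(state, grid, mutation_fraction)

    return EvolutionTrace(
        grid=grid,
        params=params,
        schedule=schedule,
        S_hist=np.array(S_hist),
        R_hist=np.array(R_hist),
        I_e=np.array(Ie_hist),
        I_f=np.array(If_hist),
        hosts_extinct=extinct,
        final_state=state,
    )


def classify_stability(trace: EvolutionTrace, window: int = 10,
                       tolerance: float = 0.001) -> Stability:
    """Stable iff the range of each total over the last ``window`` iterations
    stays below ``tolerance``; otherwise the end state is deemed cyclic."""
    if trace.iterations < window:
        raise ValueError(
            f"stability test needs >= {window} iterations, trace has {trace.iterations}"
        )
    for series in (trace.total_S, trace.total_R, trace.I_e, trace.I_f):
        tail = series[-window:]
        if tail.max() - tail.min() >= tolerance:
            return Stability.cyclic
    return Stability.stable


def summarize_outcome(trace: EvolutionTrace, eps: float = 0.01) -> OutcomeRecord:
    """Classify allele fate, evolved q per background and pathogen persistence.

    ``eps`` is the R-allele frequency (among uninfected hosts) below/above
    which the allele counts as lost/fixed; in between the outcome is a
    protected polymorphism.
    """
    tot_S = float(trace.total_S[-1])
    tot_R = float(trace.total_R[-1])
    uninfected = tot_S + tot_R

    stability = None
    if trace.iterations >= 10:
        stability = classify_stability(trace)

    if trace.hosts_extinct or uninfected <= 0.0:
        return OutcomeRecord(
            SpecificFate.hosts_extinct, None, None, None, None,
            endemic_persists=float(trace.I_e[-1]) > 0.0,
            foreign_persists=float(trace.I_f[-1]) > 0.0,
            stability=stability,
        )

    freq_R = tot_R / uninfected
    if freq_R < eps:
        fate = SpecificFate.S_fixed
    elif freq_R > 1.0 - eps:
        fate = SpecificFate.R_fixed
    else:
        fate = SpecificFate.polymorphism

    def _q(background: str, freq: float):
        if freq < eps:
            return None, None
        return (
            float(trace.q_mode(background)[-1]),
            float(trace.q_mean(background)[-1]),
        )

    q_S_mode, q_S_mean = _q("S", 1.0 - freq_R)
    q_R_mode, q_R_mean = _q("R", freq_R)

    return OutcomeRecord(
        specific_fate=fate,
        q_S_mode=q_S_mode,
        q_S_mean=q_S_mean,
        q_R_mode=q_R_mode,
        q_R_mean=q_R_mean,
        endemic_persists=float(trace.I_e[-1]) > 0.0,
        foreign_persists=float(trace.I_f[-1]) > 0.0,
        stability=stability,
    )
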