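"""Core compartmental model of host-pathogen dynamics with two forms of resistance.

Uninfected hosts carry a continuous general-resistance trait ``q`` (discretised
on a grid) and one of two alleles at a specific-resistance locus: ``S``
(susceptible) or ``R`` (resistant, reducing endemic transmission by a factor
``r``).  Two sterilizing pathogens circulate: an endemic one (transmission
``beta_e``, affected by both forms of resistance) and a foreign one
(``beta_f``, affected by general resistance only).  Transmission is
frequency-dependent by default; a density-dependent (mass-action) variant is
obtained by dropping the ``1/N`` factor in every transmission term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "TransmissionMode",
    "QGrid",
    "ModelParams",
    "SystemState",
    "StateDerivative",
    "NonViableHostError",
    "cost_of_general_resistance",
    "total_population",
    "derivatives",
    "disease_free_equilibrium",
]


class NonViableHostError(ValueError):
    """Raised when a host genotype cannot maintain a positive population."""


class TransmissionMode(str, Enum):
    """How infection pressure scales with population size."""

    frequency = "frequency"  # hazard ~ I/N (pollinator/STD-like)
    density = "density"      # hazard ~ I (mass action)


def cost_of_general_resistance(q, theta):
    """Fecundity cost of general resistance, ``1 - (1 - q)**theta``.

    ``theta < 1`` gives accelerating costs, ``theta > 1`` decelerating.
    Accepts scalars or arrays; returns the same shape.

    Raises
    ------
    ValueError
        If ``q`` lies outside ``[0, 1]`` or ``theta <= 0``.
    """
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr < 0) or np.any(q_arr > 1):
        raise ValueError(f"q must lie in [0, 1], got {q}")
    out = 1.0 - (1.0 - q_arr) ** theta
    return float(out) if np.isscalar(q) or q_arr.ndim == 0 else out


@dataclass(frozen=True)
class QGrid:
    """Uniform grid of general-resistance strengths spanning [0, 1]."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("QGrid requires a 1-D array of at least 2 values")
        if np.any(np.diff(v) <= 0):
            raise ValueError("QGrid values must be strictly increasing")
        if abs(v[0]) > 1e-12 or abs(v[-1] - 1.0) > 1e-12:
            raise ValueError("QGrid must span [0, 1] exactly")
        steps = np.diff(v)
        if np.any(np.abs(steps - steps[0]) > 1e-9):
            raise ValueError("QGrid must be uniformly spaced")

    @classmethod
    def default(cls, step: float = 0.01) -> "QGrid":
        n = int(round(1.0 / step)) + 1
        return cls(np.linspace(0.0, 1.0, n))

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    def index_of(self, q: float) -> int:
        """Index of the grid point nearest to ``q`` (must be within [0, 1])."""
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"q must lie in [0, 1], got {q}")
        return int(round(q / self.step))


@dataclass(frozen=True)
class ModelParams:
    """Demographic, transmission and resistance parameters.

    Attributes
    ----------
    b : float
        Per-capita birth rate of uninfected hosts.
    mu : float
        Mortality rate, identical for all hosts (no disease-induced death).
    gamma : float
        Coefficient of density-dependent population regulation.
    beta_e, beta_f : float
        Baseline transmission rates of the endemic and foreign pathogens.
    r : float
        Strength of specific resistance (reduction of endemic transmission
        in R hosts), in [0, 1].
    c_r : float
        Fecundity cost of carrying the R allele, in [0, 1].
    theta : float
        Curvature of the general-resistance cost function.
    transmission_mode : TransmissionMode
        Frequency-dependent (default) or density-dependent transmission.
    """

    b: float = 1.5
    mu: float = 0.2
    gamma: float = 0.01
    beta_e: float = 1.0
    beta_f: float = 0.0
    r: float = 0.0
    c_r: float = 0.0
    theta: float = 0.5
    transmission_mode: TransmissionMode = TransmissionMode.frequency

    def __post_init__(self):
        for name in ("b", "mu", "gamma", "beta_e", "beta_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("r", "c_r"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {getattr(self, name)}")
        if self.theta <= 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")
        mode = TransmissionMode(self.transmission_mode)
        object.__setattr__(self, "transmission_mode", mode)
        if self.beta_f > self.beta_e:
            # Standing assumption of the biology, but sweeps may cross it.
            warnings.warn(
                f"beta_f ({self.beta_f}) exceeds beta_e ({self.beta_e}); "
                "foreign pathogens are normally less transmissible",
                stacklevel=2,
            )


@dataclass
class SystemState:
    """Densities of every compartment.

    ``S[i]`` and ``R[i]`` are uninfected hosts at general resistance
    ``grid.values[i]`` without / with the specific-resistance allele;
    ``I_e`` and ``I_f`` are the (sterile) hosts infected by the endemic and
    foreign pathogens.
    """

    S: np.ndarray
    R: np.ndarray
    I_e: float = 0.0
    I_f: float = 0.0

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.S.shape != self.R.shape:
            raise ValueError("S and R vectors must have the same shape")

    @classmethod
    def zeros(cls, grid: QGrid) -> "SystemState":
        return cls(np.zeros(grid.n), np.zeros(grid.n), 0.0, 0.0)

    def copy(self) -> "SystemState":
        return SystemState(self.S.copy(), self.R.copy(), self.I_e, self.I_f)

    @property
    def total_uninfected(self) -> float:
        return float(self.S.sum() + self.R.sum())

    @property
    def total(self) -> float:
        return self.total_uninfected + self.I_e + self.I_f


# Derivatives share the state layout; alias makes signatures self-describing.
StateDerivative = SystemState


def total_population(state: SystemState) -> float:
    """Total density N, counting uninfected and infected hosts alike."""
    return state.total


def derivatives(state: SystemState, params: ModelParams, grid: QGrid) -> StateDerivative:
    """Right-hand side of the compartment ODEs.

    Per-capita rates (frequency-dependent mode)::

        dS_i/dt = S_i (b - c(q_i) - mu - gamma N - (1-q_i)(be Ie + bf If)/N)
        dR_i/dt = R_i (b - c(q_i) - c_r - mu - gamma N
                       - (1-q_i)((1-r) be Ie + bf If)/N)
        dIe/dt  = Ie (sum_i be (1-q_i)(S_i + (1-r) R_i)/N - mu)
        dIf/dt  = If (sum_i bf (1-q_i)(S_i + R_i)/N - mu)

    Density-dependent mode drops the ``1/N`` inside each transmission term.
    Infected hosts are sterile (no birth term) and every compartment with
    zero density has exactly zero derivative.
    """
    if state.S.shape != (grid.n,):
        raise ValueError(
            f"state dimension {state.S.shape} does not match grid size {grid.n}"
        )
    N = total_population(state)
    if N <= 0.0:
        if (
            np.all(state.S == 0.0)
            and np.all(state.R == 0.0)
            and state.I_e == 0.0
            and state.I_f == 0.0
        ):
            return StateDerivative(np.zeros(grid.n), np.zeros(grid.n), 0.0, 0.0)
        raise ValueError("total population N <= 0 for a nonzero state")

    p = params
    inv = 1.0 / N if p.transmission_mode is TransmissionMode.frequency else 1.0
    one_q = 1.0 - grid.values
    cost = 1.0 - (1.0 - grid.values) ** p.theta
    force_e = p.beta_e * state.I_e * inv
    force_f = p.beta_f * state.I_f * inv
    growth = p.b - cost - p.mu - p.gamma * N

    dS = state.S * (growth - one_q * (force_e + force_f))
    dR = state.R * (growth - p.c_r - one_q * ((1.0 - p.r) * force_e + force_f))
    dIe = state.I_e * (
        p.beta_e * inv * float(np.sum(one_q * (state.S + (1.0 - p.r) * state.R))) - p.mu
    )
    dIf = state.I_f * (
        p.beta_f * inv * float(np.sum(one_q * (state.S + state.R))) - p.mu
    )
    return StateDerivative(dS, dR, dIe, dIf)


def disease_free_equilibrium(params: ModelParams, q: float) -> float:
    """Monomorphic uninfected equilibrium density ``(b - c(q) - mu)/gamma``.

    Raises
    ------
    NonViableHostError
        If the net growth rate ``b - c(q) - mu`` is not positive.
    """
    net = params.b - cost_of_general_resistance(q, params.theta) - params.mu
    if net <= 0.0:
        raise NonViableHostError(
            f"host at q={q} is non-viable: b - c(q) - mu = {net:.6g} <= 0"
        )
    if params.gamma <= 0.0:
        raise ValueError("disease-free equilibrium requires gamma > 0")
    return net / params.gamma
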