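"""Explicit two-locus, four-genotype model with recombination.

General resistance is collapsed to two alleles, Q+ (strength ``q_plus``) and
Q- (strength ``q_minus``, usually 0), combined with the S/R specific
resistance locus into four haploid genotypes: Q+S, Q+R, Q-S, Q-R.  Matings
between uninfected plants produce, with probability ``1 - p``, an offspring of
the maternal genotype, and with probability ``p`` a recombinant carrying one
parent's allele at each locus (the two recombinant phases each with
probability ``p/2``).  Resistance costs are additive and act as fecundity
modifiers applied to the offspring genotype after the raw birth counts are
computed.  At ``p = 0`` the model reduces exactly to the clonal grid model
restricted to the same four genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import recomb_run
from .integrate import IntegratorConfig, IntegrationError
from .model import ModelParams, TransmissionMode, cost_of_general_resistance

__all__ = [
    "GENOTYPES",
    "RecombParams",
    "FourGenotypeState",
    "RecombTrajectory",
    "build_mating_matrix",
    "offspring_counts",
    "recomb_derivatives",
    "run_recombination",
]

# Genotype order used everywhere in this module.
GENOTYPES = ("Q+S", "Q+R", "Q-S", "Q-R")
_Q_PLUS = np.array([1, 1, 0, 0])  # carries the Q+ allele
_HAS_R = np.array([0, 1, 0, 1])   # carries the R allele


def _genotype_index(q_plus: bool, has_r: bool) -> int:
    return (0 if q_plus else 2) + (1 if has_r else 0)


@dataclass(frozen=True)
class RecombParams:
    """Four-genotype model parameters: base ecology plus loci definitions."""

    base: ModelParams
    p: float
    q_plus: float
    q_minus: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"recombination rate p must lie in [0, 1], got {self.p}")
        if not 0.0 <= self.q_minus <= self.q_plus <= 1.0:
            raise ValueError(
                f"require 0 <= q_minus <= q_plus <= 1, got {self.q_minus}, {self.q_plus}"
            )

    @property
    def q_values(self) -> np.ndarray:
        """General-resistance strength of each genotype, in GENOTYPES order."""
        return np.where(_Q_PLUS == 1, self.q_plus, self.q_minus)

    @property
    def costs(self) -> np.ndarray:
        """Total fecundity cost per genotype (general + specific, additive)."""
        cq = cost_of_general_resistance(self.q_values, self.base.theta)
        return cq + self.base.c_r * _HAS_R


@dataclass
class FourGenotypeState:
    """Densities of the four uninfected genotypes plus the two infected pools."""

    D: np.ndarray  # shape (4,), GENOTYPES order
    I_e: float = 0.0
    I_f: float = 0.0

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != (4,):
            raise ValueError("D must have shape (4,)")

    def copy(self) -> "FourGenotypeState":
        return FourGenotypeState(self.D.copy(), self.I_e, self.I_f)

    @property
    def total_uninfected(self) -> float:
        return float(self.D.sum())

    @property
    def total(self) -> float:
        return self.total_uninfected + self.I_e + self.I_f


def build_mating_matrix(p: float) -> np.ndarray:
    """Offspring-genotype distribution ``M[mother, father, offspring]``.

    With probability ``1 - p`` the offspring is the maternal genotype; with
    probability ``p/2`` each, it carries (mother's Q, father's S/R) or
    (father's Q, mother's S/R).  Every row sums to 1, and identical parents
    always breed true (recombination between identical haplotypes is silent).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    M = np.zeros((4, 4, 4))
    for m in range(4):
        for f in range(4):
            M[m, f, m] += 1.0 - p
            M[m, f, _genotype_index(bool(_Q_PLUS[m]), bool(_HAS_R[f]))] += p / 2.0
            M[m, f, _genotype_index(bool(_Q_PLUS[f]), bool(_HAS_R[m]))] += p / 2.0
    return M


def _profiles(rp: RecombParams):
    """Fecundity-modifier and susceptibility vectors for the kernel."""
    q = rp.q_values
    fec = rp.base.b - rp.costs
    sus_e = (1.0 - q) * (1.0 - rp.base.r * _HAS_R)
    sus_f = 1.0 - q
    return fec, sus_e, sus_f


def offspring_counts(D: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Raw offspring counts per genotype (before fecundity modifiers).

    Mothers contribute their own density; fathers are drawn from the
    uninfected pollen pool (infected plants are sterile on both sides).
    Summed over offspring genotypes this equals the total maternal density.
    """
    U = float(D.sum())
    if U <= 0.0:
        return np.zeros(len(D))
    return np.einsum("m,f,mfg->g", D / U, D, M)


def recomb_derivatives(state: FourGenotypeState, rp: RecombParams) -> FourGenotypeState:
    """Right-hand side of the four-genotype system.

    Raw births of genotype g pool over all ordered parent pairs via the
    mating matrix, then the offspring genotype's additive resistance costs
    are applied as fecundity modifiers (``b - cost(g)`` per raw birth).
    Losses (mortality, crowding, infection) mirror the clonal model per
    genotype.
    """
    D, I_e, I_f = state.D, state.I_e, state.I_f
    if np.any(D < 0) or I_e < 0 or I_f < 0:
        raise ValueError("state must be non-negative")
    U = float(D.sum())
    N = U + I_e + I_f
    if N <= 0.0:
        if U == 0.0 and I_e == 0.0 and I_f == 0.0:
            return FourGenotypeState(np.zeros(4), 0.0, 0.0)
        raise ValueError("total population N <= 0 for a nonzero state")
    fec, _, _ = _profiles(rp)
    births = offspring_counts(D, build_mating_matrix(rp.p)) * fec

    p = rp.base
    inv = 1.0 / N if p.transmission_mode is TransmissionMode.frequency else 1.0
    _, sus_e, sus_f = _profiles(rp)
    loss = p.mu + p.gamma * N + sus_e * (p.beta_e * I_e * inv) + sus_f * (p.beta_f * I_f * inv)
    dD = births - D * loss
    dIe = I_e * (p.beta_e * inv * float(np.sum(sus_e * D)) - p.mu)
    dIf = I_f * (p.beta_f * inv * float(np.sum(sus_f * D)) - p.mu)
    return FourGenotypeState(dD, dIe, dIf)


@dataclass
class RecombTrajectory:
    """Recorded time course of the four-genotype system."""

    times: np.ndarray
    D: np.ndarray    # (T, 4) in GENOTYPES order
    I_e: np.ndarray
    I_f: np.ndarray

    def linkage_disequilibrium(self) -> np.ndarray:
        """D_LD = x(Q+S) x(Q-R) - x(Q+R) x(Q-S) over uninfected frequencies."""
        U = self.D.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(U[:, None] > 0, self.D / U[:, None], np.nan)
        return x[:, 0] * x[:, 3] - x[:, 1] * x[:, 2]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.D, columns=list(GENOTYPES))
        frame.insert(0, "time", self.times)
        frame["I_e"] = self.I_e
        frame["I_f"] = self.I_f
        frame["linkage_D"] = self.linkage_disequilibrium()
        return frame

    def persisting(self, threshold: float, tail_fraction: float = 0.25) -> set[str]:
        """Genotypes whose density exceeds ``threshold`` somewhere in the last
        ``tail_fraction`` of the trajectory (robust to cyclic attractors)."""
        start = int(len(self.times) * (1.0 - tail_fraction))
        out = {
            name
            for i, name in enumerate(GENOTYPES)
            if self.D[start:, i].max() > threshold
        }
        if self.I_e[start:].max() > threshold:
            out.add("I_e")
        if self.I_f[start:].max() > threshold:
            out.add("I_f")
        return out


def run_recombination(state0: FourGenotypeState, rp: RecombParams,
                      config: IntegratorConfig | None = None,
                      t_end: float | None = None,
                      record_every: float = 1.0,
                      persist_threshold: float = 1e-3) -> tuple[RecombTrajectory, set[str]]:
    """Integrate the four-genotype system and classify persisting genotypes.

    Returns the sampled trajectory and the set of genotype/pathogen labels
    still present (above ``persist_threshold``) near the end of the run.
    """
    config = config or IntegratorConfig()
    horizon = t_end if t_end is not None else config.t_end
    n_steps = int(round(horizon / config.dt))
    stride = max(int(round(record_every / config.dt)), 1)

    M = build_mating_matrix(rp.p)
    fec, sus_e, sus_f = _profiles(rp)
    base = rp.base
    freq = base.transmission_mode is TransmissionMode.frequency

    D = state0.D.copy()
    I_e, I_f = state0.I_e, state0.I_f
    times = [0.0]
    D_hist = [D.copy()]
    Ie_hist = [I_e]
    If_hist = [I_f]
    done = 0
    while done < n_steps:
        chunk = min(stride, n_steps - done)
        I_e, I_f = recomb_run(
            D, I_e, I_f, fec, sus_e, sus_f, M,
            base.mu, base.gamma, base.beta_e, base.beta_f, freq, config.dt, chunk,
        )
        done += chunk
        times.append(done * config.dt)
        D_hist.append(D.copy())
        Ie_hist.append(I_e)
        If_hist.append(I_f)
    if not (np.all(np.isfinite(D)) and np.isfinite(I_e) and np.isfinite(I_f)):
        raise IntegrationError("non-finite density in four-genotype model; reduce dt")

    traj = RecombTrajectory(
        np.array(times), np.array(D_hist), np.array(Ie_hist), np.array(If_hist)
    )
    return traj, traj.persisting(persist_threshold)
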