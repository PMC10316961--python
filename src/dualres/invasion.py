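"""Closed-form invasion and persistence thresholds.

For a sterilizing pathogen with no recovery and frequency-dependent
transmission, R0 = beta/mu, so a foreign pathogen facing general resistance q
spreads iff beta_f (1 - q) > mu, and can persist against a more transmissible
endemic competitor only if beta_f > (1 - r) beta_e.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import ModelParams

__all__ = [
    "InvasionReport",
    "basic_reproduction_number",
    "foreign_invasion_threshold",
    "foreign_persistence_min_r",
    "invasion_report",
]


@dataclass(frozen=True)
class InvasionReport:
    """Invasion analytics for one parameter set at a given resistance level."""

    R0_endemic: float
    R0_foreign: float
    beta_f_threshold: float
    r_min: float


def basic_reproduction_number(beta: float, mu: float) -> float:
    """R0 = beta / mu; the pathogen spreads iff R0 > 1."""
    if mu <= 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    return beta / mu


def foreign_invasion_threshold(q: float, mu: float) -> float:
    """Minimum beta_f for a foreign pathogen to invade hosts at resistance q.

    Solves beta_f (1 - q) = mu for beta_f.  At q = 1 transmission is fully
    blocked and no finite threshold exists.
    """
    if mu <= 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    if q == 1.0:
        raise ValueError("q = 1 blocks transmission entirely; no finite threshold")
    return mu / (1.0 - q)


def foreign_persistence_min_r(beta_e: float, beta_f: float) -> float:
    """Minimum specific-resistance strength r allowing foreign persistence.

    From the necessary condition beta_f > (1 - r) beta_e.  If the foreign
    pathogen already out-transmits the endemic one the condition holds for
    every r and the threshold is 0.
    """
    if beta_e <= 0 or beta_f <= 0:
        raise ValueError("beta_e and beta_f must be > 0")
    if beta_f > beta_e:
        return 0.0
    return 1.0 - beta_f / beta_e


def invasion_report(params: ModelParams, q: float = 0.0) -> InvasionReport:
    """Bundle the three analytics for one parameter set."""
    r_min = (
        foreign_persistence_min_r(params.beta_e, params.beta_f)
        if params.beta_e > 0 and params.beta_f > 0
        else 0.0
    )
    return InvasionReport(
        R0_endemic=basic_reproduction_number(params.beta_e * (1.0 - q), params.mu),
        R0_foreign=basic_reproduction_number(params.beta_f * (1.0 - q), params.mu),
        beta_f_threshold=foreign_invasion_threshold(q, params.mu),
        r_min=r_min,
    )
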