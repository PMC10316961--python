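"""Independent brute-force oracles, written directly from the model equations.

Nothing here imports the package's integrator or evolutionary loop: the
resident system is a hand-coded two-compartment Euler loop and the singular
strategy is located by bisection on the rare-mutant growth gradient.  These
stay deliberately separate from the code paths they check.
"""

from __future__ import annotations

import numpy as np


def resident_equilibrium(q, b, mu, gamma, beta, dt=0.02, t_end=4000.0):
    """Equilibrate a monomorphic host at resistance q with one pathogen.

    Two-ODE system (uninfected density U, infected density I), transmission
    frequency-dependent, infection sterilizing.  Returns (U*, I*).
    """
    cost = 1.0 - (1.0 - q) ** 0.5  # theta = 0.5 throughout the experiments
    U, I = 1.0, 1.0
    for _ in range(int(t_end / dt)):
        N = U + I
        dU = U * (b - cost - mu - gamma * N - (1.0 - q) * beta * I / N)
        dI = I * (beta * (1.0 - q) * U / N - mu)
        U = max(U + dt * dU, 0.0)
        I = max(I + dt * dI, 0.0)
    return U, I


def mutant_growth(q_mut, q_res, b, mu, gamma, beta):
    """Per-capita growth rate of a rare mutant in the resident environment."""
    U, I = resident_equilibrium(q_res, b, mu, gamma, beta)
    N = U + I
    cost = 1.0 - (1.0 - q_mut) ** 0.5
    return b - cost - mu - gamma * N - (1.0 - q_mut) * beta * I / N


def singular_strategy_bisection(b, mu, gamma, beta, lo=0.05, hi=0.95,
                                delta=1e-3, tol=1e-4):
    """Root of the invasion-fitness gradient by pairwise-invasibility bisection.

    The gradient sign at resident q is estimated from the growth of rare
    mutants at q +/- delta; bisection narrows the sign change.
    """

    def gradient(q):
        up = mutant_growth(q + delta, q, b, mu, gamma, beta)
        down = mutant_growth(q - delta, q, b, mu, gamma, beta)
        return up - down

    g_lo, g_hi = gradient(lo), gradient(hi)
    if not (g_lo > 0 > g_hi):
        raise RuntimeError("bisection bracket does not straddle the singular point")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if gradient(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
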