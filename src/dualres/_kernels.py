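"""Inner Euler loops, JIT-compiled with numba when available.

The pure-Python definitions below are the reference implementations; numba
compiles exactly the same source, so the compiled and interpreted paths agree
to the last bit.  Set the environment variable ``DUALRES_NO_NUMBA=1`` to force
the interpreted fallback (used to test the equivalence).
"""

from __future__ import annotations

import os

import numpy as np


def _clonal_run(S, R, Ie, If, q, cost, b, mu, gamma, beta_e, beta_f,
                r, c_r, freq, dt, n_steps):
    """Advance the grid model ``n_steps`` forward-Euler steps in place.

    Mutates ``S`` and ``R``; returns the updated ``(Ie, If)`` scalars.
    Each step projects negative densities back to zero.
    """
    one_q = 1.0 - q
    for _ in range(n_steps):
        N = S.sum() + R.sum() + Ie + If
        if N <= 0.0:
            break
        inv = 1.0 / N if freq else 1.0
        force_e = beta_e * Ie * inv
        force_f = beta_f * If * inv
        gain_e = beta_e * inv * np.sum(one_q * (S + (1.0 - r) * R))
        gain_f = beta_f * inv * np.sum(one_q * (S + R))
        dIe = Ie * (gain_e - mu)
        dIf = If * (gain_f - mu)
        growth = b - cost - mu - gamma * N
        S += dt * S * (growth - one_q * (force_e + force_f))
        R += dt * R * (growth - c_r - one_q * ((1.0 - r) * force_e + force_f))
        S[:] = np.maximum(S, 0.0)
        R[:] = np.maximum(R, 0.0)
        Ie = max(Ie + dt * dIe, 0.0)
        If = max(If + dt * dIf, 0.0)
    return Ie, If


def _recomb_run(D, Ie, If, fec, sus_e, sus_f, M, mu, gamma, beta_e, beta_f,
                freq, dt, n_steps):
    """Advance the four-genotype recombination model in place.

    ``M[m, f, g]`` is the offspring-genotype distribution of mother ``m``
    crossed with father ``f``; raw birth counts pool over ordered parent
    pairs and are then modified by the offspring genotype's cost-adjusted
    fecundity ``fec[g] = b - cost(g)``.  ``sus_e[g] = (1-q_g)(1-r*[g has R])``
    and ``sus_f[g] = 1-q_g`` are the susceptibility profiles.
    """
    n_g = D.shape[0]
    births = np.zeros(n_g)
    for _ in range(n_steps):
        U = D.sum()
        N = U + Ie + If
        if N <= 0.0:
            break
        inv = 1.0 / N if freq else 1.0
        births[:] = 0.0
        if U > 0.0:
            for m in range(n_g):
                w_m = D[m] / U
                for f in range(n_g):
                    w = w_m * D[f]
                    for g in range(n_g):
                        births[g] += w * M[m, f, g]
            births *= fec
        gain_e = beta_e * inv * np.sum(sus_e * D)
        gain_f = beta_f * inv * np.sum(sus_f * D)
        dIe = Ie * (gain_e - mu)
        dIf = If * (gain_f - mu)
        loss = mu + gamma * N + sus_e * (beta_e * Ie * inv) + sus_f * (beta_f * If * inv)
        D += dt * (births - D * loss)
        D[:] = np.maximum(D, 0.0)
        Ie = max(Ie + dt * dIe, 0.0)
        If = max(If + dt * dIf, 0.0)
    return Ie, If


def _compile():
    if os.environ.get("DUALRES_NO_NUMBA"):
        return _clonal_run, _recomb_run, False
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is a hard dependency
        return _clonal_run, _recomb_run, False
    return (
        njit(cache=True)(_clonal_run),
        njit(cache=True)(_recomb_run),
        True,
    )


clonal_run, recomb_run, USING_NUMBA = _compile()
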