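"""Truncated chemical master equation, used as an exact oracle.

On a finite truncation of the state space the master equation

    dp(t, y)/dt = sum_l lambda_l(t, y - xi_l) p(t, y - xi_l)
                  - sum_l lambda_l(t, y) p(t, y)

is a linear ODE system.  With time-homogeneous rates it is solved by the
action of the matrix exponential; otherwise by stiff ODE integration.
Probability flowing to states outside the truncation is tracked as leaked
mass and must stay below a tolerance.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.integrate
import scipy.sparse
import scipy.sparse.linalg

from .network import ReactionNetwork

__all__ = ["cme_transition", "TruncationError", "box_states", "reachable_states"]


class TruncationError(RuntimeError):
    """Leaked probability mass above tolerance: the truncation is too small."""


def box_states(lower, upper) -> list[tuple[int, ...]]:
    """All lattice states in the box ``[lower, upper]`` (inclusive)."""
    ranges = [range(int(lo), int(hi) + 1) for lo, hi in zip(lower, upper)]
    return [tuple(s) for s in itertools.product(*ranges)]


def reachable_states(
    net: ReactionNetwork, x0, max_states: int = 200_000, t: float = 0.0
) -> list[tuple[int, ...]]:
    """States reachable from ``x0`` via reactions with positive rate.

    Only meaningful for networks whose reachable set is finite (conservation
    laws); raises if ``max_states`` is exceeded.
    """
    x0 = tuple(int(v) for v in np.asarray(x0))
    seen = {x0}
    frontier = [x0]
    while frontier:
        nxt = []
        for s in frontier:
            lam = net.rates(t, np.asarray(s))
            for i in range(net.n_reactions):
                if lam[i] > 0:
                    y = tuple(int(v) for v in np.asarray(s) + net.xi[i])
                    if y not in seen:
                        seen.add(y)
                        nxt.append(y)
                        if len(seen) > max_states:
                            raise TruncationError("reachable set too large")
        frontier = nxt
    return sorted(seen)


def _generator_matrix(
    net: ReactionNetwork, states: list[tuple[int, ...]], t: float
) -> scipy.sparse.csr_matrix:
    """Sparse generator ``Q`` with ``Q[j, i] = rate from state i to state j``.

    The diagonal carries the full exit rate (including transitions leaving
    the truncation), so the system is sub-stochastic and mass leaks out.
    """
    index = {s: i for i, s in enumerate(states)}
    rows, cols, vals = [], [], []
    for i, s in enumerate(states):
        lam = net.rates(t, np.asarray(s))
        total = float(lam.sum())
        if total > 0:
            rows.append(i)
            cols.append(i)
            vals.append(-total)
        for l in range(net.n_reactions):
            if lam[l] > 0:
                y = tuple(int(v) for v in np.asarray(s) + net.xi[l])
                j = index.get(y)
                if j is not None:
                    rows.append(j)
                    cols.append(i)
                    vals.append(float(lam[l]))
    n = len(states)
    return scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def cme_transition(
    net: ReactionNetwork,
    truncation,
    x0,
    t: float,
    leak_tol: float = 1e-8,
    t0: float = 0.0,
) -> dict:
    """Transition probabilities ``p(t0, x0; t0 + t, .)`` on a truncation.

    Returns a dict with ``states`` (the truncation, ordered), ``p`` (the
    probability vector over it) and ``leaked`` (mass lost to the outside).
    Raises :class:`TruncationError` if the leak exceeds ``leak_tol``.
    """
    states = [tuple(int(v) for v in np.asarray(s)) for s in truncation]
    index = {s: i for i, s in enumerate(states)}
    key0 = tuple(int(v) for v in np.asarray(x0))
    if key0 not in index:
        raise ValueError("truncation must contain the initial state")
    p0 = np.zeros(len(states))
    p0[index[key0]] = 1.0
    if t == 0:
        return {"states": states, "p": p0, "leaked": 0.0, "index": index}

    if net._time_dependent:
        sol = scipy.integrate.solve_ivp(
            lambda s, p: _generator_matrix(net, states, t0 + s) @ p,
            (0.0, t),
            p0,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"CME integration failed: {sol.message}")
        p = sol.y[:, -1]
    else:
        Q = _generator_matrix(net, states, t0)
        p = scipy.sparse.linalg.expm_multiply(Q * t, p0)
    p = np.clip(p, 0.0, None)
    leaked = float(1.0 - p.sum())
    if leaked > leak_tol:
        raise TruncationError(
            f"leaked mass {leaked:.3g} exceeds tolerance {leak_tol:.3g}"
        )
    return {"states": states, "p": p, "leaked": max(leaked, 0.0), "index": index}
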