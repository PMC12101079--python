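"""Forward (unconditioned) simulation of chemical reaction processes.

For time-homogeneous intensities the next-reaction construction applies
directly: in state ``x`` the holding time is exponential with the total rate
and the firing reaction is categorical with probabilities proportional to the
individual rates (distributionally identical to racing per-reaction
exponential clocks).  Time-inhomogeneous intensities are handled by Poisson
thinning against user-supplied dominating rates.
"""

from __future__ import annotations

import math

import numpy as np

from .network import ReactionNetwork
from .path import Path

__all__ = ["forward_simulate", "simulate_thinning", "BoundViolationError"]


class BoundViolationError(RuntimeError):
    """A dominating rate was exceeded by the true intensity."""


def forward_simulate(
    net: ReactionNetwork,
    x0,
    t0: float,
    t_end: float,
    rng: np.random.Generator,
) -> Path:
    """Sample a trajectory of the jump process on ``[t0, t_end]``.

    Requires time-homogeneous rates (rates are evaluated at the current jump
    time; genuinely time-dependent intensities must go through
    :func:`simulate_thinning`).  Absorbing states produce no further jumps.
    """
    x = np.asarray(net.validate_state(np.asarray(x0)), dtype=np.int64).copy()
    t = float(t0)
    times: list[float] = []
    states = [x.copy()]
    while True:
        lam = net.rates(t, x)
        total = float(lam.sum())
        if total <= 0.0:
            break
        t = t + rng.exponential(1.0 / total)
        if t > t_end:
            break
        i = int(rng.choice(net.n_reactions, p=lam / total))
        x = x + net.xi[i]
        times.append(t)
        states.append(x.copy())
    return Path(t0=t0, t_end=t_end, times=np.array(times), states=np.array(states))


def simulate_thinning(
    net: ReactionNetwork,
    x0,
    t0: float,
    t_end: float,
    rng: np.random.Generator,
    bounds,
    max_events: int = 10_000_000,
) -> Path:
    """Exact simulation with time-dependent rates by Poisson thinning.

    ``bounds(x)`` must return per-reaction dominating rates valid for the
    whole horizon while the state is ``x``:
    ``bounds(x)[l] >= sup_t lambda_l(t, x)``.  Candidate times are proposed
    from the dominating (homogeneous) superposition; a candidate for reaction
    ``l`` at time ``s`` is accepted with probability
    ``lambda_l(s, x) / bounds(x)[l]``; rejected candidates advance the clock
    without a jump.  A true rate exceeding its bound raises
    :class:`BoundViolationError` (the law would otherwise be silently wrong).
    """
    x = np.asarray(net.validate_state(np.asarray(x0)), dtype=np.int64).copy()
    t = float(t0)
    times: list[float] = []
    states = [x.copy()]
    bar = np.asarray(bounds(x), dtype=float)
    events = 0
    while True:
        total_bar = float(bar.sum())
        if total_bar <= 0.0:
            break
        t = t + rng.exponential(1.0 / total_bar)
        if t > t_end:
            break
        events += 1
        if events > max_events:
            raise RuntimeError("thinning event budget exceeded")
        i = int(rng.choice(net.n_reactions, p=bar / total_bar))
        lam_i = float(net.rates(t, x)[i])
        if lam_i > bar[i] * (1.0 + 1e-12):
            raise BoundViolationError(
                f"rate {lam_i} exceeds bound {bar[i]} for reaction {i} at t={t}"
            )
        if rng.random() * bar[i] < lam_i:
            x = x + net.xi[i]
            times.append(t)
            states.append(x.copy())
            bar = np.asarray(bounds(x), dtype=float)
        # rejected candidates advance time without a jump; by memorylessness
        # of the dominating clocks all reactions are redrawn from t onward
    return Path(t0=t0, t_end=t_end, times=np.array(times), states=np.array(states))


def sample_terminal_states(
    net: ReactionNetwork,
    x0,
    t0: float,
    t_end: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Terminal states ``X(t_end)`` of ``n`` independent forward paths.

    Lean loop used by oracle comparisons; avoids storing full paths.
    """
    x0 = np.asarray(net.validate_state(np.asarray(x0)), dtype=np.int64)
    out = np.empty((n, net.d), dtype=np.int64)
    xi = net.xi
    for r in range(n):
        x = x0.copy()
        t = float(t0)
        while True:
            lam = net.rates(t, x)
            total = float(lam.sum())
            if total <= 0.0:
                break
            t += rng.exponential(1.0 / total)
            if t > t_end:
                break
            u = rng.random() * total
            acc = 0.0
            i = 0
            for i in range(len(lam)):
                acc += lam[i]
                if u <= acc:
                    break
            x = x + xi[i]
        out[r] = x
    return out
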