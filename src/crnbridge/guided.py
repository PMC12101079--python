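"""Simulation of the guided process by Poisson thinning.

Within each inter-observation interval the guided process is a jump process
with time-dependent intensities ``lambda^g_l(t, x) = lambda_l(x) alpha_l(t, x)``
that may grow without bound as an observation time approaches.  Candidate
reaction times are proposed from dominating rates valid on a lookahead
window ``[t, t + delta]``:

* for guidings with analytically monotone ratios (the eps-scaled metric
  form, Poisson guidings) the window comes from the target-acceptance rule
  and the bound is the ratio at the worse end of the window — exact;
* otherwise the fallback window is half the remaining interval and bounds
  are sampled over the window with a safety factor; a true intensity
  exceeding its bound raises rather than silently biasing the law.

A path is rejected when an observation is still unmet within ``eps`` of its
time (the guided intensity would have to blow up to fix it), when the
guiding is undefined at a missed noiseless observation, or when the event
budget is exhausted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forward import BoundViolationError
from .guiding import GuidingTerm, _clip_exp
from .network import ReactionNetwork
from .observations import ObservationSet
from .path import Path

__all__ = [
    "ThinningConfig",
    "WeightedPath",
    "simulate_guided",
    "delta_window",
    "DeltaNotApplicableError",
]


class DeltaNotApplicableError(ValueError):
    """The acceptance-rate window rule needs a distance-decreasing move."""


def delta_window(t: float, T: float, eps: float, eta: float,
                 d2_move: float, d2_stay: float) -> float:
    """Lookahead length guaranteeing thinning acceptance at least ``eta``.

    For the eps-scaled guiding the ratio ``alpha(s) = exp(-K / (2(T+eps-s)))``
    with ``K = d(v, L(x+xi))^2 - d(v, Lx)^2 < 0`` increases in ``s``; bounding
    it by its value at ``t + delta`` with

        delta = T + eps - t - (2 ln(eta) / K + 1 / (T + eps - t))^{-1}

    keeps the candidate acceptance probability above ``eta``.  Floored at 0
    and capped so that ``t + delta <= T``.
    """
    K = d2_move - d2_stay
    if K >= 0:
        raise DeltaNotApplicableError(
            "window rule applies to distance-decreasing moves only"
        )
    rem = T + eps - t
    if rem <= 0:
        return 0.0
    delta = rem - 1.0 / (2.0 * math.log(eta) / K + 1.0 / rem)
    return float(max(0.0, min(delta, T - t)))


@dataclass
class ThinningConfig:
    """Tuning of the guided thinning simulator.

    ``eta`` is the target per-candidate acceptance rate used by the window
    rule; ``eps_reject`` the near-miss rejection horizon (defaults to the
    guiding's own eps); ``delta_fraction`` the fallback window as a fraction
    of the remaining interval; ``max_events`` the per-path jump budget.
    """

    eta: float = 0.9
    eps_reject: float | None = None
    delta_fraction: float = 0.5
    min_fraction: float = 1e-3
    max_events: int = 1_000_000
    max_candidates: int = 10_000_000
    max_windows: int = 500_000
    safety: float = 1.05
    max_up: float = 3.0
    max_overshoot: float = 0.25
    max_shrinks: int = 45
    snap_tol: float = 1e-12
    stall_tol: float = 1e-14
    hit_atol: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.eta < 1.0:
            raise ValueError("eta must lie in (0, 1)")
        if self.eps_reject is not None and self.eps_reject < 0:
            raise ValueError("eps_reject must be nonnegative")
        if self.max_events <= 0:
            raise ValueError("max_events must be positive")


@dataclass
class WeightedPath:
    """A guided path with its conditioning diagnostics and weight parts."""

    path: Path
    hits: list = field(default_factory=list)
    rejected: bool = False
    reason: str | None = None
    log_weight: float | None = None
    log_psi: float | None = None
    log_g0: float | None = None
    log_gT: float | None = None
    n_candidates: int = 0

    @property
    def hit(self) -> bool:
        return (not self.rejected) and all(self.hits)


def simulate_guided(
    net: ReactionNetwork,
    guiding: GuidingTerm,
    obs: ObservationSet | None,
    x0,
    rng: np.random.Generator,
    config: ThinningConfig | None = None,
) -> WeightedPath:
    """Sample one path of the guided process on ``[t0, t_n]``.

    The underlying intensities must be time homogeneous (all time dependence
    enters through the guiding ratios).  The returned path carries per-
    observation hit indicators (the state just before each observation time
    is compared); weights are attached separately by the weight module.
    """
    cfg = config or ThinningConfig()
    if obs is not None and len(obs) > 0:
        boundaries = list(obs.times)
        obs_list = list(obs)
        t = float(obs.t0)
    else:
        boundaries = [guiding.t_end]
        obs_list = [None]
        t = 0.0
    x = np.asarray(net.validate_state(np.asarray(x0)), dtype=np.int64).copy()
    eps_rej = cfg.eps_reject
    if eps_rej is None:
        # default to the guiding's own softening; a tiny positive floor cuts
        # off states that linger unresolved within float precision of t_k
        eps_rej = guiding.eps if guiding.eps else 1e-9

    times: list[float] = []
    states = [x.copy()]
    hits: list[bool] = []
    n_cand = 0
    n_events = 0
    rejected = False
    reason = None
    xi = net.xi

    for k, t_k in enumerate(boundaries):
        o_k = obs_list[k] if k < len(obs_list) else None
        frac = cfg.delta_fraction  # adaptive window fraction (step control)
        n_windows = 0
        while t < t_k and not rejected:
            n_windows += 1
            if n_windows > cfg.max_windows:
                rejected, reason = True, "window-budget"
                break
            lam = net.rates(t, x)
            active = lam > 0
            hit_now = o_k is None or o_k.is_hit(x, cfg.hit_atol)
            rem = t_k - t
            if not active.any():
                # frozen state: nothing can fire before t_k
                t = t_k
                break
            delta = guiding.propose_delta(t, x, lam, k, cfg.eta)
            if delta is None or delta <= 0:
                delta = frac * rem
            t1 = min(t + delta, t_k)
            # near-miss rejection: an unmet observation within eps of t_k
            if (not hit_now) and eps_rej > 0 and (t_k - t1) <= eps_rej:
                rejected, reason = True, "near-miss"
                break
            # window bounds; shrink until the guided rate's upward variation
            # over the window is moderate (thinning acceptance) and sampled
            # bounds are trustworthy (no interior overshoot), or blow-up ends
            shrinks = 0
            while True:
                bounds, exact, info = guiding.ratio_bounds(t, t1, x, k, cfg.safety)
                bad = bool(np.any(~np.isfinite(bounds[active])))
                if not exact and not bad:
                    bad = (
                        info["up"] > cfg.max_up
                        or info["overshoot"] > cfg.max_overshoot
                    )
                if not bad or shrinks >= cfg.max_shrinks or (t1 - t) <= cfg.stall_tol:
                    break
                t1 = t + 0.5 * (t1 - t)
                shrinks += 1
            if np.any(~np.isfinite(bounds[active])):
                rejected, reason = True, "boundary-stall"
                break
            # step-size control: remember how much the window had to shrink
            if shrinks == 0:
                frac = min(frac * 1.9, cfg.delta_fraction)
            else:
                frac = max(frac * 0.5**shrinks, cfg.min_fraction)
            bar = np.where(active, lam * bounds, 0.0)
            total = float(bar.sum())
            if total <= 0.0 or not np.isfinite(total):
                if not np.isfinite(total):
                    raise BoundViolationError("dominating rate overflowed")
                t = t1
                if rem < cfg.snap_tol * max(1.0, t_k):
                    t = t_k
                continue
            cum = np.cumsum(bar)
            # candidates within the frozen window [t, t1]
            while t < t1:
                tau = rng.exponential(1.0 / total)
                if t + tau > t1:
                    t = t1
                    break
                n_cand += 1
                if n_cand > cfg.max_candidates:
                    rejected, reason = True, "event-budget"
                    break
                l = int(np.searchsorted(cum, rng.random() * total))
                s = t + tau
                logr = guiding.log_ratio(s, x, l, k)
                rate = lam[l] * _clip_exp(logr)
                if rate > bar[l] * (1.0 + 1e-9):
                    raise BoundViolationError(
                        f"guided rate {rate} exceeds bound {bar[l]} "
                        f"(reaction {l}, t={s})"
                    )
                t = s
                if rng.random() * bar[l] < rate:
                    x = x + xi[l]
                    # forced cascades just below t_k can collide in float
                    # resolution; keep recorded jump times strictly increasing
                    if times and s <= times[-1]:
                        s = np.nextafter(times[-1], np.inf)
                    times.append(s)
                    states.append(x.copy())
                    n_events += 1
                    if n_events > cfg.max_events:
                        rejected, reason = True, "event-budget"
                    break
            if t >= t_k - cfg.snap_tol * max(1.0, t_k) and t < t_k:
                # numerically at the boundary; settle it if nothing blows up
                bnd, _, _ = guiding.ratio_bounds(t, t_k, x, k, cfg.safety)
                if np.all(np.isfinite(bnd[active])):
                    t = t_k
        # boundary of interval k: compare the state just before t_k
        if o_k is not None:
            hits.append(bool(o_k.is_hit(x, cfg.hit_atol)))
            if rejected:
                break
            if guiding.requires_hit and not hits[-1]:
                rejected, reason = True, "undefined-guiding"
                break
        elif rejected:
            break

    path = Path(
        t0=(obs.t0 if obs is not None and len(obs) else 0.0),
        t_end=boundaries[-1],
        times=np.array(times),
        states=np.array(states),
    )
    if obs is not None and len(obs) > 0:
        while len(hits) < len(obs):  # intervals never reached
            hits.append(False)
    return WeightedPath(
        path=path, hits=hits, rejected=rejected, reason=reason, n_candidates=n_cand
    )
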