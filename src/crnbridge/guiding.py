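"""Guiding functions g and their jump ratios.

Conditioning a chemical reaction process on future linear observations is a
Doob h-transform: the conditioned process has intensities
``lambda_l^h = lambda_l * h(t, x + xi_l) / h(t, x)`` with
``h(t, x) = P(conditioning | X(t) = x)``.  Since h is intractable, a
tractable surrogate g replaces it, and path-space importance weights correct
the substitution exactly.  Every surrogate here exposes one interface:

* ``log_g(t, x)``           — the guiding value in log space;
* ``log_ratio(t, x, l)``    — ``log(g(t, x + xi_l) / g(t, x))``, the log of
  the intensity tilt ``alpha_l``;
* ``dt_log_g(t, x)``        — time derivative (analytic where closed form
  exists, otherwise central differences);
* bound/window helpers used by the thinning simulator.

Implemented surrogates: the Euler/CLE Gaussian (Fearnhead), the linear-noise
approximation with restart, the scaled-Brownian backward filter (with the
eps-scaled metric special case), the zero-noise bridge, reversed-Poisson and
mixed diffusion–Poisson guidings for monotone components.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.linalg
from scipy.special import gammaln

from .filtering import BackwardFilter, ZeroNoiseFilter, _pinvh
from .network import ReactionNetwork
from .observations import Observation, ObservationSet

__all__ = [
    "GuidingTerm",
    "UnitGuiding",
    "FunctionGuiding",
    "GaussianFilterGuiding",
    "MetricEpsGuiding",
    "ZeroNoiseGuiding",
    "FearnheadGuiding",
    "LNARGuiding",
    "AffineLNARGuiding",
    "ReversedPoissonGuiding",
    "PoissonMixedGuiding",
    "TimeScaledGuiding",
    "DeadStateError",
    "DegenerateCovarianceError",
    "lnar_guiding",
    "guided_intensities",
    "A_over_g",
    "alpha_eps",
    "g_bm_log",
    "g_fearnhead_log",
    "g_lnar_log",
    "g_poisson_mixed_log",
    "zero_noise_filter",
    "check_greedy",
]

_LOG_CLIP = 700.0  # exp() overflow guard for ratios


class DeadStateError(RuntimeError):
    """g vanishes at the current state: unreachable under the conditioning."""


class DegenerateCovarianceError(RuntimeError):
    """A Gaussian guiding covariance is not positive definite."""


def _clip_exp(logr: float) -> float:
    if logr == -np.inf:
        return 0.0
    return math.exp(min(max(logr, -_LOG_CLIP), _LOG_CLIP))


def _gauss_logpdf(v: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    cov = np.atleast_2d(cov)
    try:
        cho = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise DegenerateCovarianceError(
            "guiding covariance is not positive definite"
        ) from exc
    r = np.atleast_1d(v - mean)
    y = np.linalg.solve(cho, r)
    return float(
        -0.5 * y @ y - np.sum(np.log(np.diag(cho))) - 0.5 * len(r) * math.log(2 * math.pi)
    )


class GuidingTerm:
    """Base class: generic fallbacks built on ``log_g``.

    ``boundaries`` are the observation times covered by the guiding (one
    entry for single-conditioning guidings); ``t_end`` is the final one.
    ``requires_hit`` marks guidings undefined at an unmet observation time
    (the zero-noise family), which forces path rejection on a miss.
    """

    requires_hit = False
    eps: float | None = None

    def __init__(self, xi: np.ndarray, t_end: float, boundaries=None):
        self.xi = np.atleast_2d(np.asarray(xi, dtype=np.int64))
        self.n_reactions = self.xi.shape[0]
        self.t_end = float(t_end)
        self.boundaries = (
            np.asarray(boundaries, dtype=float)
            if boundaries is not None
            else np.array([t_end])
        )
        self.n_intervals = len(self.boundaries)

    # -- required ----------------------------------------------------------

    def log_g(self, t: float, x, k: int | None = None) -> float:
        raise NotImplementedError

    # -- defaults ----------------------------------------------------------

    def log_ratio(self, t: float, x, l: int, k: int | None = None) -> float:
        ga = self.log_g(t, np.asarray(x) + self.xi[l], k)
        gb = self.log_g(t, x, k)
        if gb == -np.inf:
            raise DeadStateError(f"g(t={t}, x={x}) = 0")
        return ga - gb

    def log_ratio_many(self, ts, x, l: int, k: int | None = None) -> np.ndarray:
        return np.array([self.log_ratio(float(s), x, l, k) for s in np.asarray(ts)])

    def ratio(self, t: float, x, l: int, k: int | None = None) -> float:
        return _clip_exp(self.log_ratio(t, x, l, k))

    def log_ratio_block(self, ts, x, k: int | None = None) -> np.ndarray:
        """All reactions' log-ratios at several times: ``(n_reactions, nt)``."""
        return np.stack(
            [self.log_ratio_many(ts, x, l, k) for l in range(self.n_reactions)]
        )

    fd_step: float = 1e-6

    def dt_log_g(self, t: float, x, k: int | None = None) -> float:
        h = self.fd_step * max(1.0, self.t_end)
        lo = max(t - h, 0.0)
        hi = min(t + h, np.nextafter(self.boundaries[k if k is not None else -1], 0.0))
        if hi <= lo:
            hi = t
        return (self.log_g(hi, x, k) - self.log_g(lo, x, k)) / (hi - lo)

    def log_jump(self, k: int, x) -> float:
        """``log g(t_k, x) - log g(t_k-, x)`` at interior boundary ``k``."""
        return 0.0

    def singular_time(self, k: int) -> float | None:
        """Pole location of ``t -> log alpha`` in interval ``k`` (or None)."""
        return None

    def segment_integral_closed(self, a, b, x, k, lam):
        """Closed form for ``int_a^b sum_l lam_l (alpha_l - 1) ds`` or None."""
        return None

    def propose_delta(self, t: float, x, lam, k: int, eta: float) -> float | None:
        """Window length guaranteeing thinning acceptance ``eta`` (or None)."""
        return None

    def ratio_bounds(self, t0: float, t1: float, x, k: int, safety: float = 1.05):
        """Upper bounds for ``alpha_l`` on ``[t0, t1]`` for every reaction.

        The generic fallback samples seven points and inflates the maximum
        by ``safety``; subclasses with known monotonicity return exact
        bounds.  Returns ``(bounds, exact, info)`` where ``info`` carries
        two diagnostics the simulator uses to size windows: ``up``, the
        largest upward log-variation from the window start (large values
        mean poor thinning acceptance), and ``overshoot``, by how much an
        interior sample exceeds both endpoints (a non-monotone ratio, where
        sampled bounds are least trustworthy; the bound is inflated by the
        observed overshoot already).
        """
        ts = np.linspace(t0, t1, 7)
        bounds = np.empty(self.n_reactions)
        up = 0.0
        overshoot = 0.0
        for l in range(self.n_reactions):
            logr = self.log_ratio_many(ts, x, l, k)
            m = float(np.max(logr))
            if np.isfinite(m):
                end = max(logr[0], logr[-1])
                if np.isfinite(logr[0]):
                    up = max(up, m - float(logr[0]))
                ov = m - float(end) if np.isfinite(end) else 0.0
                overshoot = max(overshoot, ov)
                m += min(ov, 2.0)  # margin against unsampled interior maxima
            bounds[l] = _clip_exp(m) * safety
        return bounds, False, {"up": up, "overshoot": overshoot}


class UnitGuiding(GuidingTerm):
    """g = 1: the guided process is the unconditioned forward process."""

    def __init__(self, xi, t_end: float):
        super().__init__(xi, t_end)

    def log_g(self, t, x, k=None):
        return 0.0

    def log_ratio(self, t, x, l, k=None):
        return 0.0

    def log_ratio_many(self, ts, x, l, k=None):
        return np.zeros(len(np.asarray(ts)))

    def dt_log_g(self, t, x, k=None):
        return 0.0

    def ratio_bounds(self, t0, t1, x, k, safety=1.05):
        return np.ones(self.n_reactions), True, None


class FunctionGuiding(GuidingTerm):
    """Wrap an arbitrary ``log g(t, x)`` callable (e.g. the exact h).

    ``singular`` optionally marks a time where the jump ratios blow up
    (typically the conditioning time), so that weight quadrature refines
    toward it.
    """

    def __init__(self, fn, xi, t_end: float, boundaries=None, singular=None):
        super().__init__(xi, t_end, boundaries)
        self.fn = fn
        self.singular = singular

    def log_g(self, t, x, k=None):
        return float(self.fn(t, np.asarray(x)))

    def singular_time(self, k):
        return self.singular


class TimeScaledGuiding(GuidingTerm):
    """``g -> c(t) g`` for a positive differentiable time function ``c``.

    The guided intensities and the full path weight are invariant under this
    rescaling; the wrapper exists to exercise that invariance.
    """

    def __init__(self, base: GuidingTerm, c, dc):
        super().__init__(base.xi, base.t_end, base.boundaries)
        self.base = base
        self.c = c
        self.dc = dc
        self.requires_hit = base.requires_hit
        self.eps = base.eps

    def log_g(self, t, x, k=None):
        return self.base.log_g(t, x, k) + math.log(self.c(t))

    def log_ratio(self, t, x, l, k=None):
        return self.base.log_ratio(t, x, l, k)

    def log_ratio_many(self, ts, x, l, k=None):
        return self.base.log_ratio_many(ts, x, l, k)

    def dt_log_g(self, t, x, k=None):
        return self.base.dt_log_g(t, x, k) + self.dc(t) / self.c(t)

    def log_jump(self, k, x):
        return self.base.log_jump(k, x)

    def singular_time(self, k):
        return self.base.singular_time(k)

    def segment_integral_closed(self, a, b, x, k, lam):
        return self.base.segment_integral_closed(a, b, x, k, lam)

    def propose_delta(self, t, x, lam, k, eta):
        return self.base.propose_delta(t, x, lam, k, eta)

    def ratio_bounds(self, t0, t1, x, k, safety=1.05):
        return self.base.ratio_bounds(t0, t1, x, k, safety)


# ---------------------------------------------------------------------------
# Scaled-Brownian guidings
# ---------------------------------------------------------------------------


class GaussianFilterGuiding(GuidingTerm):
    """Multi-observation scaled-Brownian guiding from the backward filter.

    ``log g(t, x) = -x' H(t) x / 2 + F(t)' x`` with right-continuous
    ``H, F``; interval index ``k`` selects the left limit at boundary times.
    """

    def __init__(self, filt: BackwardFilter, xi):
        super().__init__(xi, filt.times[-1], filt.times)
        self.filter = filt

    def interval_of(self, t: float) -> int:
        return self.filter.interval_of(t)

    def log_g(self, t, x, k=None):
        H, F = self.filter.HF(t, k)
        x = np.asarray(x, dtype=float)
        return float(-0.5 * x @ H @ x + F @ x)

    def log_ratio(self, t, x, l, k=None):
        H, F = self.filter.HF(t, k)
        x = np.asarray(x, dtype=float)
        xi = self.xi[l].astype(float)
        return float(-xi @ H @ (x + 0.5 * xi) + F @ xi)

    def log_ratio_many(self, ts, x, l, k=None):
        x = np.asarray(x, dtype=float)
        xi = self.xi[l].astype(float)
        out = np.empty(len(np.asarray(ts)))
        for i, s in enumerate(np.asarray(ts)):
            H, F = self.filter.HF(float(s), k)
            out[i] = -xi @ H @ (x + 0.5 * xi) + F @ xi
        return out

    def dt_log_g(self, t, x, k=None):
        H, F = self.filter.HF(t, k)
        if k is None:
            k = self.filter.interval_of(t)
        a = self.filter.a[k]
        x = np.asarray(x, dtype=float)
        Ha = H @ a
        return float(-0.5 * x @ Ha @ H @ x + x @ Ha @ F)

    def log_jump(self, k, x):
        # right-minus-left value at the interior boundary t_k, on the hit set
        return self.filter.jump_const[k]

    def singular_time(self, k):
        e = self.filter.obs[k].eps
        return self.filter.times[k] + e if e is not None else None

    def _exponents(self, ts, x, k):
        """Log-ratios for all reactions at several times: (n_reactions, nt)."""
        if k is None:
            k = self.filter.interval_of(float(np.min(ts)))
        Hs = []
        Fs = []
        for s in np.asarray(ts, dtype=float):
            H, F = self.filter.HF(float(s), k)
            Hs.append(H)
            Fs.append(F)
        Hs = np.stack(Hs)  # (nt, d, d)
        Fs = np.stack(Fs)
        x = np.asarray(x, dtype=float)
        xi = self.xi.astype(float)  # (R, d)
        mid = x[None, :] + 0.5 * xi  # (R, d)
        quad = np.einsum("rd,tde,re->rt", xi, Hs, mid)
        lin = xi @ Fs.T  # (R, nt)
        return lin - quad

    def log_ratio_block(self, ts, x, k=None):
        return self._exponents(ts, x, k)

    def ratio_bounds(self, t0, t1, x, k, safety=1.05):
        ts = np.linspace(t0, t1, 7)
        logr = self._exponents(ts, x, k)  # (R, nt)
        m = logr.max(axis=1)
        end = np.maximum(logr[:, 0], logr[:, -1])
        over = m - end
        up = float(np.max(m - logr[:, 0], initial=0.0))
        bounds = np.array(
            [_clip_exp(mm + min(ov, 2.0)) * safety for mm, ov in zip(m, over)]
        )
        return bounds, False, {"up": up, "overshoot": float(over.max(initial=0.0))}


class MetricEpsGuiding(GuidingTerm):
    """Single-conditioning eps-scaled guiding in metric form.

    With ``C = eps L a L'`` the scaled-Brownian guiding reduces to

        log alpha_l(t, x) = -[d(v, L(x+xi_l))^2 - d(v, Lx)^2]
                             / (2 (eps + T - t))

    with the metric ``d(x, y)^2 = (y-x)' (L a L')^+ (y-x)``; only one
    (pseudo-)inverse is ever formed.  ``eps = 0`` gives the zero-noise
    bridge, which conditions exactly at T and is undefined off the hit set
    there.  The pseudo-inverse extends the construction to degenerate
    auxiliary diffusion matrices (constant species, rank-deficient
    stoichiometry); all reachable discrepancies lie in the range of
    ``L a L'``, where the pseudo-metric coincides with the metric.
    """

    def __init__(self, L, v, T: float, a, eps: float, xi, t0: float = 0.0):
        xi = np.atleast_2d(np.asarray(xi, dtype=np.int64))
        super().__init__(xi, T)
        self.L = np.atleast_2d(np.asarray(L, dtype=float))
        self.v = np.atleast_1d(np.asarray(v, dtype=float))
        self.a = np.atleast_2d(np.asarray(a, dtype=float))
        self.eps = float(eps)
        self.T = float(T)
        self.requires_hit = self.eps == 0.0
        self.W = _pinvh(self.L @ self.a @ self.L.T)
        # per-reaction constants: K_l(x) = q_l - 2 u_l . (v - L x)
        self.Lxi = self.xi @ self.L.T  # (n_reactions, m)
        self.u = self.Lxi @ self.W  # (n_reactions, m)
        self.q = np.einsum("lm,lm->l", self.u, self.Lxi)

    def _resid(self, x) -> np.ndarray:
        return self.v - self.L @ np.asarray(x, dtype=float)

    def sq_dist(self, x) -> float:
        r = self._resid(x)
        return float(r @ self.W @ r)

    def K(self, x) -> np.ndarray:
        """``d(v, L(x+xi_l))^2 - d(v, Lx)^2`` for every reaction."""
        return self.q - 2.0 * (self.u @ self._resid(x))

    def log_g(self, t, x, k=None):
        denom = self.eps + self.T - t
        d2 = self.sq_dist(x)
        if denom <= 0.0:
            return 0.0 if d2 <= 1e-16 else -np.inf
        return -d2 / (2.0 * denom)

    def log_ratio(self, t, x, l, k=None):
        denom = self.eps + self.T - t
        Kl = float(self.q[l] - 2.0 * (self.u[l] @ self._resid(x)))
        if denom <= 0.0:
            return -np.inf if Kl > 0 else (np.inf if Kl < 0 else 0.0)
        return -Kl / (2.0 * denom)

    def log_ratio_many(self, ts, x, l, k=None):
        denom = self.eps + self.T - np.asarray(ts, dtype=float)
        Kl = float(self.q[l] - 2.0 * (self.u[l] @ self._resid(x)))
        with np.errstate(divide="ignore"):
            return -Kl / (2.0 * denom)

    def dt_log_g(self, t, x, k=None):
        denom = self.eps + self.T - t
        return -self.sq_dist(x) / (2.0 * denom * denom)

    def singular_time(self, k):
        return self.T + self.eps

    def segment_integral_closed(self, a, b, x, k, lam):
        """Exact ``int_a^b sum_l lam_l (alpha_l(s) - 1) ds``.

        With ``alpha_l(s) = exp(beta_l / y(s))``, ``y(s) = eps + T - s`` and
        ``beta_l = -K_l/2``, ``d/dy [y exp(beta/y) - beta Ei(beta/y)] =
        exp(beta/y)``; the exponential-integral closed form avoids
        quadrature through the near-conditioning layer where the ratio
        varies over many orders of magnitude.
        """
        from scipy.special import expi

        ya = self.eps + self.T - a
        yb = self.eps + self.T - b
        total = 0.0
        for l in range(self.n_reactions):
            if lam[l] <= 0:
                continue
            beta = -0.5 * float(self.q[l] - 2.0 * (self.u[l] @ self._resid(x)))
            if beta == 0.0:
                continue
            ra, rb = beta / ya, beta / yb
            if rb > _LOG_CLIP or ra > _LOG_CLIP:
                return None  # astronomical forcing; caller's problem
            Fa = ya * math.exp(ra) - beta * expi(ra)
            Fb = yb * math.exp(rb) - beta * expi(rb)
            total += lam[l] * ((Fa - Fb) - (ya - yb))
        return total

    def propose_delta(self, t, x, lam, k, eta):
        """Window length from the target-acceptance rule (Eq.-6.3 style)."""
        rem = self.T + self.eps - t
        K = self.K(x)
        best = None
        for l in range(self.n_reactions):
            if lam[l] > 0 and K[l] < 0:
                d = rem - 1.0 / (2.0 * math.log(eta) / K[l] + 1.0 / rem)
                best = d if best is None else min(best, d)
        if best is None:
            return None
        return max(min(best, self.T - t), 0.0)

    def ratio_bounds(self, t0, t1, x, k, safety=1.05):
        K = self.K(x)
        bounds = np.empty(self.n_reactions)
        for l in range(self.n_reactions):
            s = t1 if K[l] < 0 else t0  # alpha increases in t iff K < 0
            denom = self.eps + self.T - s
            if denom <= 0.0:
                bounds[l] = 0.0 if K[l] > 0 else (np.inf if K[l] < 0 else 1.0)
            else:
                bounds[l] = _clip_exp(-K[l] / (2.0 * denom))
        return bounds, True, None


class ZeroNoiseGuiding(GuidingTerm):
    """Zero-noise multi-observation guiding via the block-matrix form."""

    requires_hit = True
    eps = 0.0

    def __init__(self, zfilter: ZeroNoiseFilter, xi):
        super().__init__(xi, zfilter.times[-1], zfilter.times)
        self.zf = zfilter

    def log_g(self, t, x, k=None):
        q = self.zf.quad_form(t, x, k)
        return -np.inf if np.isinf(q) else -0.5 * q

    def singular_time(self, k):
        return self.zf.times[k]


def zero_noise_filter(obs: ObservationSet, a_schedule, xi) -> GuidingTerm:
    """Guiding for noiseless conditionings (all ``C_k = 0``).

    A single conditioning returns the fast metric form (eps = 0); several
    return the block-matrix guiding.
    """
    if len(obs) == 1:
        o = obs[0]
        a = np.asarray(a_schedule, dtype=float)
        if a.ndim == 3:
            a = a[0]
        return MetricEpsGuiding(o.L, o.v, o.t, a, 0.0, xi, t0=obs.t0)
    return ZeroNoiseGuiding(ZeroNoiseFilter(obs, a_schedule), xi)


# ---------------------------------------------------------------------------
# CLE-based guidings
# ---------------------------------------------------------------------------


class FearnheadGuiding(GuidingTerm):
    """One-step Euler/CLE Gaussian guiding for a single observation.

    ``g(t, x) = N(v; L(x + b(t,x)(T-t)), L a(t,x) L' (T-t) + C)`` with
    ``b, a`` the CLE drift and diffusion at the current state.
    """

    def __init__(self, net: ReactionNetwork, L, v, T: float, C):
        super().__init__(net.xi, T)
        self.net = net
        self.L = np.atleast_2d(np.asarray(L, dtype=float))
        self.v = np.atleast_1d(np.asarray(v, dtype=float))
        self.C = np.atleast_2d(np.asarray(C, dtype=float))
        self.T = float(T)

    def log_g(self, t, x, k=None):
        x = np.asarray(x, dtype=float)
        rem = self.T - t
        lam = self.net.rates_continuous(t, x)
        b = lam @ self.net.xi
        a = (self.net.xi.T * lam) @ self.net.xi
        mean = self.L @ (x + b * rem)
        cov = self.L @ a @ self.L.T * rem + self.C
        return _gauss_logpdf(self.v, mean, cov)

    def singular_time(self, k):
        # ratios vary on the noise-floor scale C/(L a L') just beyond T
        return self.T

    def _log_g_many(self, ts: np.ndarray, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        rem = self.T - np.asarray(ts, dtype=float)
        lam = self.net.rates_continuous(0.0, x)
        b = lam @ self.net.xi
        a = (self.net.xi.T * lam) @ self.net.xi
        if self.L.shape[0] == 1:
            mu = float((self.L @ x)[0]) + float((self.L @ b)[0]) * rem
            var = float((self.L @ a @ self.L.T)[0, 0]) * rem + float(self.C[0, 0])
            if np.any(var <= 0):
                raise DegenerateCovarianceError("nonpositive variance")
            return -0.5 * np.log(2 * np.pi * var) - (self.v[0] - mu) ** 2 / (2 * var)
        return np.array([self.log_g(float(s), x) for s in ts])

    def log_ratio_many(self, ts, x, l, k=None):
        if self.net._time_dependent:
            return super().log_ratio_many(ts, x, l, k)
        ts = np.asarray(ts, dtype=float)
        return self._log_g_many(ts, np.asarray(x) + self.xi[l]) - self._log_g_many(
            ts, x
        )


class LNARGuiding(GuidingTerm):
    """Linear-noise approximation with restart, single observation.

    From the current ``(t, x)`` the mean ODE ``dz = b(s, z) ds`` and the
    covariance ODE ``dV = (V J' + J V + a) ds`` are integrated to T with
    ``z(t) = x``, ``V(t) = 0``, and
    ``g(t, x) = N(v; L z_T, L V_T L' + C)``.  Integration uses fixed-step
    RK4, vectorised across batches of (time, state) pairs in lockstep; the
    number of steps scales with the remaining span as
    ``ceil(steps_per_unit * (T - t))`` so that restarts late in the horizon
    stay cheap.  ``steps_per_unit`` must resolve the fastest relaxation of
    the covariance ODE (roughly twice the drift Jacobian's spectral range);
    accuracy is checked against adaptive stiff integration in the tests.
    The mean ODE is evaluated with the state clamped to the nonnegative
    orthant, matching the rate clamping of the continuous-state extension.
    """

    def __init__(
        self, net: ReactionNetwork, L, v, T: float, C, steps_per_unit: int = 32
    ):
        super().__init__(net.xi, T)
        self.net = net
        self.L = np.atleast_2d(np.asarray(L, dtype=float))
        self.v = np.atleast_1d(np.asarray(v, dtype=float))
        self.C = np.atleast_2d(np.asarray(C, dtype=float))
        self.T = float(T)
        self.steps_per_unit = int(steps_per_unit)
        from ._lna_kernel import HAVE_KERNEL, mass_action_tables

        self._tables = mass_action_tables(net) if HAVE_KERNEL else None

    def _rhs_batch(self, s, Z, V):
        # Z: (B, d); V: (B, d, d)
        Zc = np.maximum(Z, 0.0)
        lam = self.net.rates_continuous_batch(s, Zc)  # (B, R)
        b = lam @ self.net.xi  # (B, d)
        a = np.einsum("br,ri,rj->bij", lam, self.net.xi, self.net.xi)
        grads = self.net.rate_gradients_batch(s, Zc)  # (B, R, d)
        J = np.einsum("ri,brj->bij", self.net.xi.astype(float), grads)
        dV = np.einsum("bik,bjk->bij", V, J) + np.einsum("bik,bkj->bij", J, V) + a
        return b, dV

    def _mean_cov_batch(self, ts, states) -> tuple[np.ndarray, np.ndarray]:
        """Integrate the restart ODEs for a batch of (t, x) pairs."""
        ts = np.asarray(ts, dtype=float)
        d = self.net.d
        Z = np.atleast_2d(np.asarray(states, dtype=float)).copy()
        B = Z.shape[0]
        V = np.zeros((B, d, d))
        span = self.T - ts
        n = max(4, int(np.ceil(self.steps_per_unit * float(span.max(initial=0.0)))))
        if self._tables is not None:
            from ._lna_kernel import lna_rk4

            out = lna_rk4(self._tables, ts, Z, self.T, n)
            if out is not None:
                return out
        h = (span / n)[:, None]  # per-item step, lockstep count
        hV = h[:, :, None]
        s = ts.copy()
        for _ in range(n):
            k1z, k1V = self._rhs_batch(s, Z, V)
            k2z, k2V = self._rhs_batch(s, Z + 0.5 * h * k1z, V + 0.5 * hV * k1V)
            k3z, k3V = self._rhs_batch(s, Z + 0.5 * h * k2z, V + 0.5 * hV * k2V)
            k4z, k4V = self._rhs_batch(s, Z + h * k3z, V + hV * k3V)
            Z = Z + h / 6 * (k1z + 2 * k2z + 2 * k3z + k4z)
            V = V + hV / 6 * (k1V + 2 * k2V + 2 * k3V + k4V)
            s = s + h[:, 0]
        return Z, 0.5 * (V + np.transpose(V, (0, 2, 1)))

    def mean_cov(self, t: float, x) -> tuple[np.ndarray, np.ndarray]:
        Z, V = self._mean_cov_batch([t], [np.asarray(x, dtype=float)])
        return Z[0], V[0]

    def log_g(self, t, x, k=None):
        z, V = self.mean_cov(t, x)
        return _gauss_logpdf(self.v, self.L @ z, self.L @ V @ self.L.T + self.C)

    def _log_g_from(self, Z, V) -> float:
        return _gauss_logpdf(self.v, self.L @ Z, self.L @ V @ self.L.T + self.C)

    def log_ratio(self, t, x, l, k=None):
        x = np.asarray(x, dtype=float)
        Z, V = self._mean_cov_batch([t, t], [x + self.xi[l], x])
        return self._log_g_from(Z[0], V[0]) - self._log_g_from(Z[1], V[1])

    def log_ratio_block(self, ts, x, k=None):
        ts = np.asarray(ts, dtype=float)
        x = np.asarray(x, dtype=float)
        nt = len(ts)
        R = self.n_reactions
        states = np.vstack([np.tile(x, (nt, 1))] + [
            np.tile(x + self.xi[l], (nt, 1)) for l in range(R)
        ])
        tall = np.tile(ts, R + 1)
        Z, V = self._mean_cov_batch(tall, states)
        logg = np.array([self._log_g_from(Z[b], V[b]) for b in range(len(tall))])
        logg = logg.reshape(R + 1, nt)
        return logg[1:] - logg[0][None, :]

    def log_ratio_many(self, ts, x, l, k=None):
        return self.log_ratio_block(ts, x, k)[l]

    def ratio_bounds(self, t0, t1, x, k, safety=1.05):
        ts = np.linspace(t0, t1, 5)
        logr = self.log_ratio_block(ts, x, k)
        m = logr.max(axis=1)
        end = np.maximum(logr[:, 0], logr[:, -1])
        over = np.where(np.isfinite(m), m - end, 0.0)
        up = float(np.max(np.where(np.isfinite(m), m - logr[:, 0], 0.0), initial=0.0))
        bounds = np.array(
            [_clip_exp(mm + min(ov, 2.0)) * safety for mm, ov in zip(m, over)]
        )
        return bounds, False, {"up": up, "overshoot": float(over.max(initial=0.0))}

    def singular_time(self, k):
        return self.T


class AffineLNARGuiding(GuidingTerm):
    """LNA with restart for networks with affine intensities.

    When every rate is affine in the state (at most unimolecular
    mass-action), the joint system for ``(z, vec(V), 1)`` is linear with
    constant coefficients, so the restart ODEs are solved by one matrix
    exponential ``exp(M (T - t))`` applied to the initial condition; the
    exponential is evaluated through a precomputed eigendecomposition.
    """

    def __init__(self, net: ReactionNetwork, L, v, T: float, C):
        super().__init__(net.xi, T)
        self.net = net
        self.L = np.atleast_2d(np.asarray(L, dtype=float))
        self.v = np.atleast_1d(np.asarray(v, dtype=float))
        self.C = np.atleast_2d(np.asarray(C, dtype=float))
        self.T = float(T)
        d = net.d
        self.dim = d
        # rate_l(z) = w_l . z + c_l
        Wm = np.zeros((net.n_reactions, d))
        cm = np.zeros(net.n_reactions)
        for i, r in enumerate(net.reactions):
            if not r.is_mass_action or sum(r.rate.nu.values()) > 1:
                raise ValueError("network intensities are not affine")
            if r.rate.nu:
                ((kk, _),) = r.rate.nu.items()
                Wm[i, kk] = r.rate.kappa
            else:
                cm[i] = r.rate.kappa
        B = net.xi.T @ Wm  # drift Jacobian (constant)
        b0 = cm @ net.xi
        # a(z) = A0 + sum_k A1[k] z_k
        A0 = (net.xi.T * cm) @ net.xi
        A1 = np.array([(net.xi.T * Wm[:, kk]) @ net.xi for kk in range(d)])
        D = d + d * d + 1
        M = np.zeros((D, D))
        M[:d, :d] = B
        M[:d, -1] = b0
        for i in range(d):
            for j in range(d):
                row = d + i * d + j
                # d V_ij = sum_m (V_im B_jm + B_im V_mj) + a_ij(z)
                for m in range(d):
                    M[row, d + i * d + m] += B[j, m]
                    M[row, d + m * d + j] += B[i, m]
                M[row, :d] += A1[:, i, j]
                M[row, -1] += A0[i, j]
        self._M = M
        w, S = np.linalg.eig(M)
        try:
            Sinv = np.linalg.inv(S)
            if np.linalg.cond(S) < 1e10:
                self._eig = (w, S, Sinv)
            else:
                self._eig = None
        except np.linalg.LinAlgError:
            self._eig = None

    def _propagate(self, dt: float, u0: np.ndarray) -> np.ndarray:
        if self._eig is not None:
            w, S, Sinv = self._eig
            return np.real(S @ (np.exp(w * dt) * (Sinv @ u0)))
        return scipy.linalg.expm(self._M * dt) @ u0

    def mean_cov(self, t: float, x) -> tuple[np.ndarray, np.ndarray]:
        d = self.dim
        u0 = np.zeros(d + d * d + 1)
        u0[:d] = np.asarray(x, dtype=float)
        u0[-1] = 1.0
        u = self._propagate(self.T - t, u0)
        V = u[d:-1].reshape(d, d)
        return u[:d], 0.5 * (V + V.T)

    def log_g(self, t, x, k=None):
        z, V = self.mean_cov(t, x)
        return _gauss_logpdf(self.v, self.L @ z, self.L @ V @ self.L.T + self.C)

    def singular_time(self, k):
        return self.T

    def _log_g_many(self, ts: np.ndarray, x) -> np.ndarray:
        if self._eig is None:
            return np.array([self.log_g(float(s), x) for s in ts])
        d = self.dim
        w, S, Sinv = self._eig
        u0 = np.zeros(d + d * d + 1, dtype=complex)
        u0[:d] = np.asarray(x, dtype=float)
        u0[-1] = 1.0
        dts = self.T - np.asarray(ts, dtype=float)
        E = np.exp(np.multiply.outer(w, dts))  # (D, B)
        U = np.real(S @ (E * (Sinv @ u0)[:, None]))
        Z = U[:d]  # (d, B)
        Vv = U[d:-1].reshape(d, d, -1)
        if self.L.shape[0] == 1:
            mu = (self.L @ Z)[0]
            var = np.einsum("i,ijb,j->b", self.L[0], Vv, self.L[0]) + float(
                self.C[0, 0]
            )
            if np.any(var <= 0):
                raise DegenerateCovarianceError("nonpositive variance")
            return -0.5 * np.log(2 * np.pi * var) - (self.v[0] - mu) ** 2 / (2 * var)
        out = np.empty(len(dts))
        for b in range(len(dts)):
            V = 0.5 * (Vv[:, :, b] + Vv[:, :, b].T)
            out[b] = _gauss_logpdf(self.v, self.L @ Z[:, b], self.L @ V @ self.L.T + self.C)
        return out

    def log_ratio_many(self, ts, x, l, k=None):
        ts = np.asarray(ts, dtype=float)
        return self._log_g_many(ts, np.asarray(x) + self.xi[l]) - self._log_g_many(
            ts, x
        )


def lnar_guiding(net: ReactionNetwork, L, v, T: float, C, **kw) -> GuidingTerm:
    """LNA-with-restart guiding; closed-form propagator for affine networks."""
    try:
        return AffineLNARGuiding(net, L, v, T, C)
    except ValueError:
        return LNARGuiding(net, L, v, T, C, **kw)


# ---------------------------------------------------------------------------
# Poisson-based guidings for monotone components
# ---------------------------------------------------------------------------


class ReversedPoissonGuiding(GuidingTerm):
    """Guiding from a reversed constant-rate Poisson process (1-d, decreasing).

    For a monotonically decreasing count conditioned on ``X(T) = v``, the
    remaining number of jumps ``x - v`` is modelled as Poisson with mean
    ``theta (T - t)``:

        g(t, x) = (theta (T-t))^{x-v} exp(-theta (T-t)) / (x-v)!

    for ``x >= v`` and 0 otherwise.  Once the target is reached the guiding
    blocks further jumps (alpha = 0), so every non-frozen path is pushed to
    hit exactly.
    """

    def __init__(self, v: float, T: float, theta: float, xi):
        super().__init__(xi, T)
        if np.atleast_2d(np.asarray(xi)).shape[1] != 1:
            raise ValueError("reversed-Poisson guiding is one-dimensional")
        self.v = float(v)
        self.T = float(T)
        self.theta = float(theta)

    def _k(self, x) -> float:
        return float(np.asarray(x).reshape(-1)[0] - self.v)

    def log_g(self, t, x, kk=None):
        k = self._k(x)
        if k < 0:
            return -np.inf
        mu = self.theta * (self.T - t)
        if mu <= 0.0:
            return 0.0 if k == 0 else -np.inf
        return k * math.log(mu) - float(gammaln(k + 1)) - mu

    def log_ratio(self, t, x, l, kk=None):
        step = int(self.xi[l, 0])
        k = self._k(x)
        mu = self.theta * (self.T - t)
        if step == -1:
            if k <= 0:
                return -np.inf
            return math.log(k) - (math.log(mu) if mu > 0 else -np.inf)
        return self.log_g(t, np.asarray(x) + self.xi[l], kk) - self.log_g(t, x, kk)

    def log_ratio_many(self, ts, x, l, kk=None):
        step = int(self.xi[l, 0])
        k = self._k(x)
        mu = self.theta * (self.T - np.asarray(ts, dtype=float))
        if step == -1:
            if k <= 0:
                return np.full(len(mu), -np.inf)
            with np.errstate(divide="ignore"):
                return math.log(k) - np.log(mu)
        return super().log_ratio_many(ts, x, l, kk)

    def dt_log_g(self, t, x, kk=None):
        k = self._k(x)
        return self.theta - k / (self.T - t)

    def singular_time(self, k):
        return self.T

    def propose_delta(self, t, x, lam, k, eta):
        # alpha(s) = (x - v) / (theta (T - s)); acceptance over [t, t+delta]
        # is at least (T - t - delta) / (T - t), so delta = (1 - eta)(T - t)
        if self._k(x) <= 0:
            return None
        return (1.0 - eta) * (self.T - t)

    def ratio_bounds(self, t0, t1, x, k, safety=1.05):
        bounds = np.empty(self.n_reactions)
        for l in range(self.n_reactions):
            s = t1 if int(self.xi[l, 0]) == -1 else t0  # decreasing jump: alpha grows
            bounds[l] = _clip_exp(self.log_ratio(s, x, l))
        return bounds, True, None


class PoissonMixedGuiding(GuidingTerm):
    """Scaled diffusion on the free components, Poisson on a monotone one.

    State ``x = (z, y)``: ``z`` follows the eps-scaled metric guiding toward
    ``z_T``; the monotonically increasing component ``y`` is guided by a
    homogeneous Poisson process with intensity ``theta`` toward ``y_T``:

        log g = -d(z_T, z)^2 / (2 (T + eps - t))
                + (y_T - y) log(theta (T-t)) - log((y_T - y)!)
                - theta (T - t)

    and ``g = 0`` once ``y > y_T``: the reaction producing ``y`` is blocked
    exactly when the target count is reached.
    """

    def __init__(self, v, T: float, a_z, theta: float, eps: float, xi, y_index: int):
        xi = np.atleast_2d(np.asarray(xi, dtype=np.int64))
        super().__init__(xi, T)
        d = xi.shape[1]
        self.y_index = int(y_index)
        self.z_idx = np.array([i for i in range(d) if i != self.y_index])
        v = np.atleast_1d(np.asarray(v, dtype=float))
        self.z_T = v[self.z_idx]
        self.y_T = float(v[self.y_index])
        self.T = float(T)
        self.theta = float(theta)
        self.eps = float(eps)
        self.W = _pinvh(np.asarray(a_z, dtype=float))
        self.zxi = xi[:, self.z_idx].astype(float)
        self.yxi = xi[:, self.y_index]
        self.u = self.zxi @ self.W
        self.q = np.einsum("lm,lm->l", self.u, self.zxi)

    def _parts(self, x):
        x = np.asarray(x, dtype=float)
        return x[self.z_idx], float(x[self.y_index])

    def _K(self, z) -> np.ndarray:
        r = self.z_T - z
        return self.q - 2.0 * (self.u @ r)

    def log_g(self, t, x, kk=None):
        z, y = self._parts(x)
        k = self.y_T - y
        if k < 0:
            return -np.inf
        r = self.z_T - z
        out = -float(r @ self.W @ r) / (2.0 * (self.T + self.eps - t))
        mu = self.theta * (self.T - t)
        if mu <= 0.0:
            return out if k == 0 else -np.inf
        return out + k * math.log(mu) - float(gammaln(k + 1)) - mu

    def _log_ratio_parts(self, t, x, l):
        z, y = self._parts(x)
        K = float(self.q[l] - 2.0 * (self.u[l] @ (self.z_T - z)))
        metric = -K / (2.0 * (self.T + self.eps - t))
        step = int(self.yxi[l])
        if step == 0:
            return metric, 0.0
        k = self.y_T - y
        mu = self.theta * (self.T - t)
        if step > 0:
            if k < step:
                return metric, -np.inf
            pois = sum(math.log(k - j) for j in range(step)) - step * (
                math.log(mu) if mu > 0 else -np.inf
            )
        else:
            m = -step
            pois = m * (math.log(mu) if mu > 0 else -np.inf) - sum(
                math.log(k + j) for j in range(1, m + 1)
            )
        return metric, pois

    def log_ratio(self, t, x, l, kk=None):
        metric, pois = self._log_ratio_parts(t, x, l)
        return metric + pois

    def log_ratio_many(self, ts, x, l, kk=None):
        return np.array([self.log_ratio(float(s), x, l) for s in np.asarray(ts)])

    def dt_log_g(self, t, x, kk=None):
        z, y = self._parts(x)
        r = self.z_T - z
        d2 = float(r @ self.W @ r)
        k = self.y_T - y
        return -d2 / (2.0 * (self.T + self.eps - t) ** 2) + self.theta - k / (
            self.T - t
        )

    def singular_time(self, k):
        return self.T

    def propose_delta(self, t, x, lam, k, eta):
        z, y = self._parts(x)
        K = self._K(z)
        rem = self.T + self.eps - t
        root_eta = math.sqrt(eta)
        best = None
        for l in range(self.n_reactions):
            if lam[l] <= 0:
                continue
            cands = []
            if K[l] < 0:
                cands.append(rem - 1.0 / (2.0 * math.log(root_eta) / K[l] + 1.0 / rem))
            if int(self.yxi[l]) > 0 and self.y_T - y >= 1:
                cands.append((1.0 - root_eta) * (self.T - t))
            for dlt in cands:
                best = dlt if best is None else min(best, dlt)
        if best is None:
            return None
        return max(min(best, self.T - t), 0.0)

    def ratio_bounds(self, t0, t1, x, k, safety=1.05):
        # each factor of alpha is monotone in t: bound each at its worst end
        bounds = np.empty(self.n_reactions)
        for l in range(self.n_reactions):
            z, _y = self._parts(x)
            K = float(self._K(z)[l])
            s_metric = t1 if K < 0 else t0
            metric, _ = self._log_ratio_parts(s_metric, x, l)
            step = int(self.yxi[l])
            s_pois = t1 if step > 0 else t0  # production ratio grows toward T
            _, pois = self._log_ratio_parts(s_pois, x, l)
            bounds[l] = _clip_exp(metric + pois)
        return bounds, True, None


# ---------------------------------------------------------------------------
# Operations on guidings
# ---------------------------------------------------------------------------


def guided_intensities(net: ReactionNetwork, g: GuidingTerm, t: float, x,
                       k: int | None = None) -> np.ndarray:
    """``lambda^g_l(t, x) = lambda_l(t, x) * alpha_l(t, x)``."""
    if g.log_g(t, x, k) == -np.inf:
        raise DeadStateError(f"g(t={t}, x={x}) = 0")
    lam = net.rates(t, x)
    out = np.empty_like(lam)
    for l in range(net.n_reactions):
        out[l] = lam[l] * _clip_exp(g.log_ratio(t, x, l, k)) if lam[l] > 0 else 0.0
    return out


def A_over_g(net: ReactionNetwork, g: GuidingTerm, t: float, x,
             k: int | None = None) -> float:
    """``(A g / g)(t, x) = d/dt log g + sum_l (lambda^g_l - lambda_l)``."""
    lam = net.rates(t, x)
    lam_g = guided_intensities(net, g, t, x, k)
    return float(g.dt_log_g(t, x, k) + np.sum(lam_g - lam))


def alpha_eps(guiding: MetricEpsGuiding, l: int, t: float, x) -> float:
    """Jump ratio ``alpha_l`` of the eps-scaled metric guiding."""
    return _clip_exp(guiding.log_ratio(t, x, l))


def g_bm_log(filt: BackwardFilter, t: float, x, k: int | None = None) -> float:
    """``log g`` of the scaled-Brownian guiding: ``-x'H(t)x/2 + F(t)'x``."""
    H, F = filt.HF(t, k)
    x = np.asarray(x, dtype=float)
    return float(-0.5 * x @ H @ x + F @ x)


def g_fearnhead_log(net: ReactionNetwork, obs: Observation, C, t: float, x) -> float:
    return FearnheadGuiding(net, obs.L, obs.v, obs.t, C).log_g(t, x)


def g_lnar_log(net: ReactionNetwork, obs: Observation, C, t: float, x) -> float:
    return lnar_guiding(net, obs.L, obs.v, obs.t, C).log_g(t, x)


def g_poisson_mixed_log(v, T: float, a_z, theta: float, eps: float, xi,
                        y_index: int, t: float, x) -> float:
    return PoissonMixedGuiding(v, T, a_z, theta, eps, xi, y_index).log_g(t, x)


def check_greedy(net: ReactionNetwork, obs: ObservationSet, a_schedule,
                 probe_states, t: float = 0.0) -> dict:
    """Per-(observation, state) report of the greedy reachability property.

    For every probed state off the hit set of observation ``k``, reports
    whether some reaction with positive rate strictly decreases the distance
    ``d_k(v_k, L_k x)`` in the metric induced by ``(L_k a_k L_k')^+``.
    """
    a_schedule = np.asarray(a_schedule, dtype=float)
    if a_schedule.ndim == 2:
        a_schedule = np.broadcast_to(a_schedule, (len(obs),) + a_schedule.shape)
    report: dict = {}
    for k, o in enumerate(obs):
        W = _pinvh(o.L @ a_schedule[k] @ o.L.T)
        for s in probe_states:
            x = np.asarray(s)
            r = o.v - o.L @ x.astype(float)
            if np.allclose(r, 0.0, atol=1e-10):
                continue
            d0 = float(r @ W @ r)
            lam = net.rates(t, x)
            ok = False
            for l in range(net.n_reactions):
                if lam[l] > 0:
                    r2 = o.v - o.L @ (x + net.xi[l]).astype(float)
                    if float(r2 @ W @ r2) < d0 - 1e-12:
                        ok = True
                        break
            report[(k, tuple(int(v) for v in x))] = ok
    report["all"] = all(v for kk, v in report.items() if kk != "all")
    return report
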