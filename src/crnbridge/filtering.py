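"""Backward Gaussian information filter for the scaled-Brownian guiding.

The guiding surrogate is derived from an auxiliary process
``dX~ = sigma_k dW`` on each inter-observation interval, observed as
``v_k = L_k X~(t_k) + N(0, C_k)``.  Conditioning X~ on all future
observations gives ``g(t, x) = exp(-x' H(t) x / 2 + F(t)' x)`` where
``H, F`` solve backward Riccati-type ODEs

    dH = H a_k H dt,   dF = H a_k F dt        (t in (t_{k-1}, t_k))

with jump updates at observation times

    H(t_k-) = L_k' C_k^{-1} L_k + H(t_k+),
    F(t_k-) = L_k' C_k^{-1} v_k + F(t_k+),

terminal conditions at t_n, and right-continuous convention at interior
observation times.  Within an interval the solution is closed form:
``H(t) = z_k(t) H_k`` and ``F(t) = z_k(t) F_k`` with
``z_k(t) = (I + H_k a_k (t_k - t))^{-1}``.
"""

from __future__ import annotations

import numpy as np

from .observations import ObservationSet

__all__ = ["BackwardFilter", "backward_filter", "ZeroNoiseFilter"]


class BackwardFilter:
    """Closed-form ``H(t), F(t)`` over ``[t0, t_n]``.

    ``a_schedule`` supplies the auxiliary diffusion matrix ``a_k`` for each
    interval ``[t_{k-1}, t_k)``; a single matrix is broadcast to all
    intervals.
    """

    def __init__(self, obs: ObservationSet, a_schedule):
        if len(obs) == 0:
            raise ValueError("need at least one observation")
        n = len(obs)
        d = obs[0].L.shape[1]
        a_schedule = np.asarray(a_schedule, dtype=float)
        if a_schedule.ndim == 2:
            a_schedule = np.broadcast_to(a_schedule, (n, d, d)).copy()
        if a_schedule.shape != (n, d, d):
            raise ValueError("a_schedule must be one d x d matrix per interval")
        self.obs = obs
        self.d = d
        self.n = n
        self.a = a_schedule
        self.times = obs.times
        self.t0 = obs.t0

        # backward recursion for the interval boundary values H_k, F_k
        H_bound = [None] * n  # H(t_k-) for interval k (0-based k-1)
        F_bound = [None] * n
        jump_const = [0.0] * n  # -(1/2) v_k' C_k^{-1} v_k
        H_right = np.zeros((d, d))
        F_right = np.zeros(d)
        for k in range(n - 1, -1, -1):
            o = obs[k]
            if o.C is None:
                raise ValueError(
                    "zero-noise observations require the zero-noise filter"
                )
            Cinv = np.linalg.inv(o.C)
            Hk = o.L.T @ Cinv @ o.L + H_right
            Fk = o.L.T @ Cinv @ o.v + F_right
            H_bound[k] = 0.5 * (Hk + Hk.T)
            F_bound[k] = Fk
            jump_const[k] = -0.5 * float(o.v @ Cinv @ o.v)
            if k > 0:
                dt = o.t - obs[k - 1].t
                z = np.linalg.inv(np.eye(d) + H_bound[k] @ self.a[k] * dt)
                H_right = z @ H_bound[k]
                H_right = 0.5 * (H_right + H_right.T)
                F_right = z @ F_bound[k]
        self.H_bound = H_bound
        self.F_bound = F_bound
        self.jump_const = jump_const

    # -- interval lookup ---------------------------------------------------

    def interval_of(self, t: float) -> int:
        """0-based interval index such that ``t in [t_{k-1}, t_k)``.

        ``t == t_k`` for an interior observation maps to the next interval
        (right continuity); ``t == t_n`` maps to the last interval, whose
        left-limit values apply there.
        """
        k = int(np.searchsorted(self.times, t, side="right"))
        return min(k, self.n - 1)

    def HF(self, t: float, k: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """``H(t), F(t)`` (within interval ``k``, left limit at ``t_k``)."""
        if k is None:
            k = self.interval_of(t)
        dt = self.times[k] - t
        if dt < 0:
            raise ValueError("time beyond the final observation")
        if dt == 0.0:
            return self.H_bound[k], self.F_bound[k]
        z = np.linalg.inv(np.eye(self.d) + self.H_bound[k] @ self.a[k] * dt)
        H = z @ self.H_bound[k]
        return 0.5 * (H + H.T), z @ self.F_bound[k]


def backward_filter(obs: ObservationSet, a_schedule) -> BackwardFilter:
    """Build the closed-form backward filter (all ``C_k`` invertible)."""
    return BackwardFilter(obs, a_schedule)


def _pinvh(A: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Moore–Penrose pseudo-inverse of a symmetric PSD matrix."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    w, V = np.linalg.eigh(0.5 * (A + A.T))
    cut = rtol * max(w.max(initial=0.0), 1.0)
    winv = np.where(w > cut, 1.0 / np.where(w > cut, w, 1.0), 0.0)
    return (V * winv) @ V.T


class ZeroNoiseFilter:
    """Block-matrix form of the guiding for noiseless conditionings.

    With all ``C_k = 0`` the information-filter boundary conditions are not
    defined, but the smoothing covariance of the auxiliary Brownian bridge
    still is: for ``t in [t_{k-1}, t_k)``,

        g(t, x) = exp(-(v(t) - L(t)x)' M(t) (v(t) - L(t)x) / 2)

    where ``L(t), v(t)`` stack observations ``k..n`` and ``M(t)`` is the
    inverse of the block matrix

        M+(t)[i, j] = sum_{l=k}^{min(i,j)-1} L_i a_{l+1} L_j' (t_{l+1}-t_l)
                      + L_i a_k L_j' (t_k - t).

    Singular blocks (degenerate auxiliary diffusion) are inverted in the
    pseudo-inverse sense; discrepancies outside the range make g vanish.
    At ``t = t_k`` the guiding is defined only on ``{L_k x = v_k}``.
    """

    def __init__(self, obs: ObservationSet, a_schedule):
        if len(obs) == 0:
            raise ValueError("need at least one observation")
        n = len(obs)
        d = obs[0].L.shape[1]
        a_schedule = np.asarray(a_schedule, dtype=float)
        if a_schedule.ndim == 2:
            a_schedule = np.broadcast_to(a_schedule, (n, d, d)).copy()
        self.obs = obs
        self.d = d
        self.n = n
        self.a = a_schedule
        self.times = obs.times
        self.t0 = obs.t0

    def interval_of(self, t: float) -> int:
        k = int(np.searchsorted(self.times, t, side="right"))
        return min(k, self.n - 1)

    def stacked(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Stacked ``L, v`` over observations ``k..n-1`` (0-based)."""
        L = np.vstack([self.obs[i].L for i in range(k, self.n)])
        v = np.concatenate([self.obs[i].v for i in range(k, self.n)])
        return L, v

    def M_dagger(self, t: float, k: int) -> np.ndarray:
        obs, a, times = self.obs, self.a, self.times
        ms = [obs[i].m for i in range(k, self.n)]
        offs = np.concatenate(([0], np.cumsum(ms)))
        M = np.zeros((offs[-1], offs[-1]))
        for ii in range(k, self.n):
            for jj in range(ii, self.n):
                # Cov(L_i X~(t_i), L_j X~(t_j)) for the piecewise diffusion
                cov = obs[ii].L @ a[k] @ obs[jj].L.T * (times[k] - t)
                for l in range(k, ii):
                    cov = cov + obs[ii].L @ a[l + 1] @ obs[jj].L.T * (
                        times[l + 1] - times[l]
                    )
                bi, bj = ii - k, jj - k
                M[offs[bi]:offs[bi + 1], offs[bj]:offs[bj + 1]] = cov
                if jj != ii:
                    M[offs[bj]:offs[bj + 1], offs[bi]:offs[bi + 1]] = cov.T
        return M

    def quad_form(self, t: float, x, k: int | None = None) -> float:
        """``(v(t) - L(t)x)' M(t) (v(t) - L(t)x)`` (pseudo-inverse sense).

        Returns ``inf`` for residuals outside the range of ``M+(t)``
        (unreachable under the auxiliary bridge).
        """
        if k is None:
            k = self.interval_of(t)
        L, v = self.stacked(k)
        r = v - L @ np.asarray(x, dtype=float)
        if t == self.times[k]:
            # defined only on the hit set of observation k
            rk = r[: self.obs[k].m]
            if not np.allclose(rk, 0.0, atol=1e-8):
                return np.inf
            if self.n - k == 1:
                return 0.0
        Md = self.M_dagger(t, k)
        Minv = _pinvh(Md)
        val = float(r @ Minv @ r)
        # consistency: residual must lie in the range of M+
        if not np.allclose(Md @ (Minv @ r), r, atol=1e-6 * max(1.0, np.abs(r).max())):
            return np.inf
        return val
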