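"""Compiled inner loop for the LNA-with-restart integrator.

The restart construction evaluates, for every candidate time, the solution
at T of the mean/covariance ODE system started at the current state.  For
mass-action networks the right-hand side is a short polynomial expression,
so the fixed-step RK4 sweep over a batch of (time, state) pairs is compiled
with numba; a pure-numpy fallback keeps the package functional without it.
"""

from __future__ import annotations

import numpy as np

try:
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False


def _lna_rk4_py(xi, kappa, nu, ts, states, T, n):  # pragma: no cover
    raise NotImplementedError  # replaced below when numba is missing


if _HAVE_NUMBA:

    @numba.njit(cache=False, fastmath=False)
    def _rhs(xi, kappa, nu, z, V, bz, bV, d, R):  # pragma: no cover - jitted
        # rates, drift, diffusion and Jacobian at clamped state
        for i in range(d):
            bz[i] = 0.0
            for j in range(d):
                bV[i, j] = 0.0
        J = np.zeros((d, d))
        a = np.zeros((d, d))
        for r in range(R):
            lam = kappa[r]
            for k in range(d):
                m = nu[r, k]
                for jj in range(m):
                    zz = z[k] if z[k] > 0.0 else 0.0
                    lam *= zz - jj
            if lam < 0.0:
                lam = 0.0
            for i in range(d):
                bz[i] += lam * xi[r, i]
                for j in range(d):
                    a[i, j] += lam * xi[r, i] * xi[r, j]
            # gradient of the rate (only where the rate is positive-smooth)
            for k in range(d):
                m = nu[r, k]
                if m == 0:
                    continue
                zk = z[k] if z[k] > 0.0 else 0.0
                dterm = 0.0
                for j in range(m):
                    part = 1.0
                    for jjj in range(m):
                        if jjj != j:
                            part *= zk - jjj
                    dterm += part
                grad = kappa[r] * dterm
                for kk in range(d):
                    if kk != k:
                        mm = nu[r, kk]
                        for j in range(mm):
                            zz = z[kk] if z[kk] > 0.0 else 0.0
                            grad *= zz - j
                for i in range(d):
                    J[i, k] += xi[r, i] * grad
        # dV = V J' + J V + a
        for i in range(d):
            for j in range(d):
                s = a[i, j]
                for m2 in range(d):
                    s += V[i, m2] * J[j, m2] + J[i, m2] * V[m2, j]
                bV[i, j] = s

    @numba.njit(cache=False, fastmath=False)
    def _lna_rk4_nb(xi, kappa, nu, ts, states, T, n):  # pragma: no cover
        B, d = states.shape
        R = xi.shape[0]
        Z = np.empty((B, d))
        Vout = np.empty((B, d, d))
        k1z = np.empty(d)
        k2z = np.empty(d)
        k3z = np.empty(d)
        k4z = np.empty(d)
        k1V = np.empty((d, d))
        k2V = np.empty((d, d))
        k3V = np.empty((d, d))
        k4V = np.empty((d, d))
        for b in range(B):
            z = states[b].copy()
            V = np.zeros((d, d))
            h = (T - ts[b]) / n
            for _ in range(n):
                _rhs(xi, kappa, nu, z, V, k1z, k1V, d, R)
                _rhs(xi, kappa, nu, z + 0.5 * h * k1z, V + 0.5 * h * k1V, k2z, k2V, d, R)
                _rhs(xi, kappa, nu, z + 0.5 * h * k2z, V + 0.5 * h * k2V, k3z, k3V, d, R)
                _rhs(xi, kappa, nu, z + h * k3z, V + h * k3V, k4z, k4V, d, R)
                z = z + h / 6.0 * (k1z + 2.0 * k2z + 2.0 * k3z + k4z)
                V = V + h / 6.0 * (k1V + 2.0 * k2V + 2.0 * k3V + k4V)
            Z[b] = z
            for i in range(d):
                for j in range(d):
                    Vout[b, i, j] = 0.5 * (V[i, j] + V[j, i])
        return Z, Vout


def mass_action_tables(net):
    """``(xi, kappa, nu)`` arrays for a pure mass-action network, or None."""
    R, d = net.n_reactions, net.d
    kappa = np.empty(R)
    nu = np.zeros((R, d), dtype=np.int64)
    for i, r in enumerate(net.reactions):
        if not r.is_mass_action:
            return None
        kappa[i] = r.rate.kappa
        for k, m in r.rate.nu.items():
            nu[i, k] = m
    return net.xi.astype(np.float64), kappa, nu


def lna_rk4(tables, ts, states, T: float, n: int):
    """Batch LNA-restart integration; compiled when numba is available."""
    if not _HAVE_NUMBA:
        return None
    xi, kappa, nu = tables
    return _lna_rk4_nb(
        xi,
        kappa,
        nu,
        np.ascontiguousarray(ts, dtype=np.float64),
        np.ascontiguousarray(states, dtype=np.float64),
        float(T),
        int(n),
    )


HAVE_KERNEL = _HAVE_NUMBA
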