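"""Reaction-network data model and rate evaluation.

A chemical reaction network consists of ``d`` species and a set of reactions,
each characterised by an integer change vector ``xi`` and a nonnegative
intensity ``lambda_l(t, x)``.  Species counts evolve as a continuous-time
Markov jump process on the nonnegative integer lattice: in state ``x`` the
l-th reaction fires at rate ``lambda_l(t, x)`` and moves the state to
``x + xi_l``.

Mass-action kinetics are expressed through a rate constant ``kappa`` and
reactant multiplicities ``nu``; the intensity is ``kappa`` times the product
of falling factorials ``x_k (x_k - 1) ... (x_k - nu_k + 1)``.  For the usual
uni- and bimolecular reactions this reduces to ``kappa * x_i`` and
``kappa * x_i * x_j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml

__all__ = [
    "MassAction",
    "Reaction",
    "ReactionNetwork",
    "CLECoefficients",
    "InvalidStateError",
    "evaluate_rates",
    "cle_coefficients",
    "build_example",
    "load_network",
    "save_network",
]


class InvalidStateError(ValueError):
    """Raised when a state is off the nonnegative integer lattice."""


def _falling_factorial(x: float, nu: int) -> float:
    out = 1.0
    for i in range(nu):
        out *= x - i
    return out


def _d_falling_factorial(x: float, nu: int) -> float:
    # derivative of prod_{i<nu} (x - i) with respect to x
    out = 0.0
    for j in range(nu):
        term = 1.0
        for i in range(nu):
            if i != j:
                term *= x - i
        out += term
    return out


@dataclass(frozen=True)
class MassAction:
    """Mass-action rate: ``kappa * prod_k ff(x_k, nu_k)``.

    ``nu`` maps species index -> reactant multiplicity (entries not listed
    have multiplicity zero).
    """

    kappa: float
    nu: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("rate constant must be nonnegative")
        for k, n in self.nu.items():
            if n < 0 or int(n) != n:
                raise ValueError("multiplicities must be nonnegative integers")

    def __call__(self, t: float, x: np.ndarray) -> float:
        out = self.kappa
        for k, n in self.nu.items():
            out *= _falling_factorial(float(x[k]), n)
        return out

    def gradient(self, x: np.ndarray) -> np.ndarray:
        """Gradient of the rate with respect to the (real-valued) state."""
        g = np.zeros(len(x))
        for k, n in self.nu.items():
            term = self.kappa * _d_falling_factorial(float(x[k]), n)
            for j, m in self.nu.items():
                if j != k:
                    term *= _falling_factorial(float(x[j]), m)
            g[k] = term
        return g


@dataclass(frozen=True)
class Reaction:
    """One reaction: change vector ``xi`` plus a rate law.

    ``rate`` is either a :class:`MassAction` or a callable ``(t, x) -> float``
    (general, possibly time-dependent, nonnegative intensity).
    """

    xi: tuple[int, ...]
    rate: MassAction | Callable[[float, np.ndarray], float]
    name: str = ""

    @property
    def xi_array(self) -> np.ndarray:
        return np.asarray(self.xi, dtype=np.int64)

    @property
    def is_mass_action(self) -> bool:
        return isinstance(self.rate, MassAction)


class ReactionNetwork:
    """Species + reactions on the nonnegative integer lattice."""

    def __init__(self, species: Sequence[str], reactions: Sequence[Reaction]):
        self.species = list(species)
        self.d = len(self.species)
        self.reactions = list(reactions)
        for r in self.reactions:
            if len(r.xi) != self.d:
                raise ValueError(
                    f"change vector {r.xi} has wrong length for {self.d} species"
                )
        self.n_reactions = len(self.reactions)
        # stacked change vectors, one row per reaction
        self.xi = np.array([r.xi for r in self.reactions], dtype=np.int64).reshape(
            self.n_reactions, self.d
        )
        self._time_dependent = any(not r.is_mass_action for r in self.reactions)

    # -- rate evaluation ---------------------------------------------------

    def validate_state(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.shape != (self.d,):
            raise InvalidStateError(f"state must have length {self.d}")
        if np.any(x < 0):
            raise InvalidStateError(f"state {x} has a negative component")
        return x

    def rates(self, t: float, x: np.ndarray) -> np.ndarray:
        """Intensity vector ``(lambda_l(t, x))_l`` at a lattice state.

        Mass-action rates vanish automatically when a reactant is depleted;
        a positive mass-action rate with a destination off the lattice is a
        modelling error and raises.  General callable rates with an off-lattice
        destination are clipped to zero, so that Assumption (2.1b) holds for
        the evaluated vector.
        """
        x = self.validate_state(x)
        lam = np.empty(self.n_reactions)
        for i, r in enumerate(self.reactions):
            li = float(r.rate(t, x))
            if li < 0:
                raise ValueError(f"negative rate {li} for reaction {i} at x={x}")
            if li > 0 and np.any(x + self.xi[i] < 0):
                if r.is_mass_action:
                    raise ValueError(
                        f"mass-action reaction {i} active at x={x} but "
                        f"x+xi={x + self.xi[i]} leaves the lattice"
                    )
                li = 0.0
            lam[i] = li
        return lam

    def rates_continuous(self, t: float, z: np.ndarray) -> np.ndarray:
        """Rates extended to real-valued states (clamped at zero).

        Used by the diffusion (CLE) and linear-noise approximations, whose
        mean trajectories live on the reals.
        """
        z = np.asarray(z, dtype=float)
        lam = np.array([float(r.rate(t, z)) for r in self.reactions])
        return np.maximum(lam, 0.0)

    def total_rate(self, t: float, x: np.ndarray) -> float:
        return float(np.sum(self.rates(t, x)))

    def rates_continuous_batch(self, t: float, Z: np.ndarray) -> np.ndarray:
        """Rates at a batch of real-valued states: ``(B, d) -> (B, R)``."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        out = np.empty((Z.shape[0], self.n_reactions))
        for i, r in enumerate(self.reactions):
            if r.is_mass_action:
                col = np.full(Z.shape[0], r.rate.kappa)
                for k, n in r.rate.nu.items():
                    zk = Z[:, k]
                    for j in range(n):
                        col = col * (zk - j)
                out[:, i] = col
            else:
                out[:, i] = [float(r.rate(t, z)) for z in Z]
        return np.maximum(out, 0.0)

    def rate_gradients_batch(self, t: float, Z: np.ndarray) -> np.ndarray:
        """Gradients of every rate at a batch of states: ``(B, R, d)``."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        B = Z.shape[0]
        out = np.zeros((B, self.n_reactions, self.d))
        for i, r in enumerate(self.reactions):
            if r.is_mass_action:
                for k, n in r.rate.nu.items():
                    term = np.full(B, r.rate.kappa)
                    dterm = np.zeros(B)
                    for j in range(n):  # d/dz prod (z-j) via product rule
                        part = np.ones(B)
                        for jj in range(n):
                            if jj != j:
                                part = part * (Z[:, k] - jj)
                        dterm += part
                    term = term * dterm
                    for kk, nn in r.rate.nu.items():
                        if kk != k:
                            for j in range(nn):
                                term = term * (Z[:, kk] - j)
                    out[:, i, k] = term
            else:
                for b in range(B):
                    out[b, i] = np.array(
                        [
                            (
                                float(r.rate(t, Z[b] + h * e))
                                - float(r.rate(t, Z[b] - h * e))
                            )
                            / (2 * h)
                            for h, e in (
                                (
                                    1e-6 * max(1.0, abs(Z[b, kk])),
                                    np.eye(self.d)[kk],
                                )
                                for kk in range(self.d)
                            )
                        ]
                    )
        return out

    # -- CLE drift/diffusion ----------------------------------------------

    def drift(self, t: float, z: np.ndarray) -> np.ndarray:
        lam = self.rates_continuous(t, z)
        return lam @ self.xi

    def drift_jacobian(self, t: float, z: np.ndarray) -> np.ndarray:
        """Jacobian of the CLE drift; analytic for mass-action rates."""
        z = np.asarray(z, dtype=float)
        J = np.zeros((self.d, self.d))
        for i, r in enumerate(self.reactions):
            if r.is_mass_action:
                grad = r.rate.gradient(z)
            else:  # central differences for general rate laws
                grad = np.zeros(self.d)
                for k in range(self.d):
                    h = 1e-6 * max(1.0, abs(z[k]))
                    zp, zm = z.copy(), z.copy()
                    zp[k] += h
                    zm[k] -= h
                    grad[k] = (float(r.rate(t, zp)) - float(r.rate(t, zm))) / (2 * h)
            J += np.outer(self.xi[i], grad)
        return J

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ReactionNetwork(species={self.species}, "
            f"n_reactions={self.n_reactions})"
        )


@dataclass(frozen=True)
class CLECoefficients:
    """Drift ``b`` and diffusion matrix ``a = sigma sigma'`` of the CLE."""

    b: np.ndarray
    a: np.ndarray


def evaluate_rates(net: ReactionNetwork, t: float, x: np.ndarray) -> np.ndarray:
    """Vector of reaction intensities ``lambda_l(t, x)``."""
    return net.rates(t, x)


def cle_coefficients(net: ReactionNetwork, t: float, x) -> CLECoefficients:
    """Chemical-Langevin drift and diffusion at ``(t, x)``.

    ``b = sum_l lambda_l xi_l`` and ``a = sum_l lambda_l xi_l xi_l'``, the
    latter equal to ``sigma sigma'`` with ``sigma = [xi_1 ... xi_B] *
    sqrt(diag(lambda))``.
    """
    lam = net.rates_continuous(t, np.asarray(x, dtype=float))
    b = lam @ net.xi
    a = (net.xi.T * lam) @ net.xi
    return CLECoefficients(b=b.astype(float), a=a.astype(float))


# -- example networks ------------------------------------------------------


def build_example(name: str, **params) -> ReactionNetwork:
    """Construct one of the benchmark networks.

    ``death``: one species, one reaction ``xi = -1`` with rate ``c x``.
    ``gtt``: gene transcription and translation (gene, mRNA, protein) with
    transcription ``kappa1 * G``, translation ``kappa2 * M``, mRNA
    degradation ``dM * M`` and protein degradation ``dP * P``.
    ``enzyme``: Michaelis–Menten enzyme kinetics for (S, E, SE, P) with
    binding ``kappa1 * S * E``, unbinding ``kappa2 * SE`` and catalysis
    ``kappa3 * SE``.
    """
    if name == "death":
        c = float(params.get("c", 0.5))
        if c < 0:
            raise ValueError("c must be nonnegative")
        return ReactionNetwork(
            ["N"],
            [Reaction(xi=(-1,), rate=MassAction(c, {0: 1}), name="death")],
        )
    if name == "gtt":
        k1 = float(params.get("kappa1", 100.0))
        k2 = float(params.get("kappa2", 10.0))
        dM = float(params.get("dM", 25.0))
        dP = float(params.get("dP", 1.0))
        if min(k1, k2, dM, dP) < 0:
            raise ValueError("rate constants must be nonnegative")
        return ReactionNetwork(
            ["G", "M", "P"],
            [
                Reaction(xi=(0, 1, 0), rate=MassAction(k1, {0: 1}), name="transcription"),
                Reaction(xi=(0, 0, 1), rate=MassAction(k2, {1: 1}), name="translation"),
                Reaction(xi=(0, -1, 0), rate=MassAction(dM, {1: 1}), name="mRNA decay"),
                Reaction(xi=(0, 0, -1), rate=MassAction(dP, {2: 1}), name="protein decay"),
            ],
        )
    if name == "enzyme":
        kappa = params.get("kappa", (5.0, 5.0, 3.0))
        k1, k2, k3 = (float(k) for k in kappa)
        if min(k1, k2, k3) < 0:
            raise ValueError("rate constants must be nonnegative")
        return ReactionNetwork(
            ["S", "E", "SE", "P"],
            [
                Reaction(xi=(-1, -1, 1, 0), rate=MassAction(k1, {0: 1, 1: 1}), name="binding"),
                Reaction(xi=(1, 1, -1, 0), rate=MassAction(k2, {2: 1}), name="unbinding"),
                Reaction(xi=(0, 1, -1, 1), rate=MassAction(k3, {2: 1}), name="catalysis"),
            ],
        )
    raise ValueError(f"unknown example network: {name!r}")


# -- file interface --------------------------------------------------------


def network_to_dict(net: ReactionNetwork) -> dict:
    reactions = []
    for r in net.reactions:
        if not r.is_mass_action:
            raise ValueError("only mass-action reactions can be serialised")
        reactions.append(
            {
                "name": r.name,
                "xi": [int(v) for v in r.xi],
                "rate": {
                    "type": "mass_action",
                    "constant": r.rate.kappa,
                    "reactants": {int(k): int(v) for k, v in r.rate.nu.items()},
                },
            }
        )
    return {"species": list(net.species), "reactions": reactions}


def network_from_dict(spec: dict) -> ReactionNetwork:
    species = spec["species"]
    reactions = []
    for entry in spec["reactions"]:
        rate = entry["rate"]
        if rate.get("type") != "mass_action":
            raise ValueError("only mass_action rate type is supported in files")
        nu = {int(k): int(v) for k, v in rate.get("reactants", {}).items()}
        reactions.append(
            Reaction(
                xi=tuple(int(v) for v in entry["xi"]),
                rate=MassAction(float(rate["constant"]), nu),
                name=entry.get("name", ""),
            )
        )
    return ReactionNetwork(species, reactions)


def save_network(net: ReactionNetwork, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(net), fh, sort_keys=False)


def load_network(path) -> ReactionNetwork:
    with open(path) as fh:
        return network_from_dict(yaml.safe_load(fh))
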