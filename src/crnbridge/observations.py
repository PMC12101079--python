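"""Linear observations ``v_k = L_k X(t_k)`` and their container."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["Observation", "ObservationSet", "load_observations", "save_observations"]


@dataclass
class Observation:
    """One conditioning ``L x = v`` at time ``t``.

    ``C`` is the (symmetric positive semidefinite) extrinsic-noise covariance
    on the observed combination; ``C = None`` marks the noiseless case, which
    only the zero-noise guiding construction can consume.  ``eps`` records
    the softening parameter when ``C`` was derived as ``eps * L a L'``.
    """

    t: float
    L: np.ndarray
    v: np.ndarray
    C: np.ndarray | None = None
    eps: float | None = None

    def __post_init__(self) -> None:
        self.L = np.atleast_2d(np.asarray(self.L, dtype=float))
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        m, _d = self.L.shape
        if self.v.shape != (m,):
            raise ValueError("v must have one entry per row of L")
        if np.linalg.matrix_rank(self.L) < m:
            raise ValueError("rows of L must be linearly independent")
        if self.C is not None:
            self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
            if self.C.shape != (m, m):
                raise ValueError("C must be m x m")
            if not np.allclose(self.C, self.C.T):
                raise ValueError("C must be symmetric")

    @property
    def m(self) -> int:
        return self.L.shape[0]

    def is_hit(self, x, atol: float = 1e-8) -> bool:
        r = self.L @ np.asarray(x, dtype=float) - self.v
        return bool(np.max(np.abs(r)) <= atol)


@dataclass
class ObservationSet:
    """Ordered conditionings; houses the joint event ``A_n``."""

    observations: list[Observation] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.observations = sorted(self.observations, key=lambda o: o.t)
        times = self.times
        if len(times) and (times[0] <= self.t0 or np.any(np.diff(times) <= 0)):
            raise ValueError("observation times must be strictly increasing after t0")

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    def __getitem__(self, k: int) -> Observation:
        return self.observations[k]

    @property
    def times(self) -> np.ndarray:
        return np.array([o.t for o in self.observations])

    @property
    def t_end(self) -> float:
        if not self.observations:
            raise ValueError("empty observation set has no final time")
        return self.observations[-1].t

    def all_hit(self, states, atol: float = 1e-8) -> bool:
        """Whether states (one per observation, pre-observation values) hit A_n."""
        return all(o.is_hit(x, atol) for o, x in zip(self.observations, states))


def _obs_to_dict(o: Observation) -> dict:
    entry: dict = {"t": float(o.t), "L": o.L.tolist(), "v": o.v.tolist()}
    if o.eps is not None:
        entry["eps_scaled"] = float(o.eps)
    elif o.C is None:
        entry["C"] = "zero"
    else:
        entry["C"] = o.C.tolist()
    return entry


def save_observations(obs: ObservationSet, path) -> None:
    data = [_obs_to_dict(o) for o in obs]
    text = yaml.safe_dump(data, sort_keys=False)
    with open(path, "w") as fh:
        fh.write(text)


def load_observations(path, d: int | None = None) -> ObservationSet:
    """Read an observation set from YAML or JSON.

    Each entry: ``{t, L (row-major; defaults to identity), v, C}`` where
    ``C`` is a matrix, the string ``"zero"``, or an ``eps_scaled`` scalar to
    be resolved against an auxiliary diffusion matrix later.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        data = yaml.safe_load(text)
    observations = []
    for entry in data:
        v = np.atleast_1d(np.asarray(entry["v"], dtype=float))
        if "L" in entry:
            L = np.atleast_2d(np.asarray(entry["L"], dtype=float))
        else:
            if d is None:
                d = len(v)
            L = np.eye(d)
        C = entry.get("C")
        eps = entry.get("eps_scaled")
        if C == "zero":
            C = None
        elif C is not None:
            C = np.atleast_2d(np.asarray(C, dtype=float))
        observations.append(Observation(t=float(entry["t"]), L=L, v=v, C=C, eps=eps))
    return ObservationSet(observations)
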