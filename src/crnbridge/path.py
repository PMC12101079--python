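"""Right-continuous piecewise-constant trajectories of a jump process."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Path"]


@dataclass
class Path:
    """A trajectory: jump times ``t_1 < ... < t_N`` within ``[t0, t_end]``.

    ``states`` has one more row than ``times``; ``states[0]`` is the state on
    ``[t0, t_1)`` and ``states[j]`` the state on ``[t_j, t_{j+1})`` (right
    continuity: ``X(t_j) = states[j]``).
    """

    t0: float
    t_end: float
    times: np.ndarray  # shape (N,)
    states: np.ndarray  # shape (N + 1, d), integer

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states))
        if self.states.shape[0] != self.times.shape[0] + 1:
            raise ValueError("need one more state than jump times")
        if self.times.size and (
            np.any(np.diff(self.times) <= 0)
            or self.times[0] <= self.t0
            or self.times[-1] > self.t_end
        ):
            raise ValueError("jump times must be strictly increasing in (t0, t_end]")

    @property
    def n_jumps(self) -> int:
        return len(self.times)

    @property
    def terminal_state(self) -> np.ndarray:
        return self.states[-1]

    def state_at(self, t: float) -> np.ndarray:
        """State ``X(t)`` under the right-continuous convention."""
        if t < self.t0 or t > self.t_end:
            raise ValueError("time outside the path's span")
        j = int(np.searchsorted(self.times, t, side="right"))
        return self.states[j]

    def segments(self):
        """Yield ``(s_start, s_end, state)`` covering ``[t0, t_end]``."""
        knots = np.concatenate(([self.t0], self.times, [self.t_end]))
        for j in range(len(knots) - 1):
            if knots[j + 1] > knots[j]:
                yield knots[j], knots[j + 1], self.states[j]

    # -- IO ----------------------------------------------------------------

    def to_frame(self, species: list[str] | None = None) -> pd.DataFrame:
        d = self.states.shape[1]
        cols = species if species is not None else [f"x{i}" for i in range(d)]
        times = np.concatenate(([self.t0], self.times, [self.t_end]))
        states = np.vstack([self.states, self.states[-1]])
        df = pd.DataFrame(states, columns=cols)
        df.insert(0, "time", times)
        return df

    def to_csv(self, path, species: list[str] | None = None) -> None:
        self.to_frame(species).to_csv(path, index=False)

    def to_ndjson(self, path, species: list[str] | None = None) -> None:
        df = self.to_frame(species)
        with open(path, "w") as fh:
            for rec in df.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Path":
        times = df["time"].to_numpy(dtype=float)
        states = df.drop(columns="time").to_numpy()
        return cls(
            t0=times[0],
            t_end=times[-1],
            times=times[1:-1],
            states=states[:-1],  # rows 0..N are x_0..x_N
        )
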