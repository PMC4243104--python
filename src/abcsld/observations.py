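"""Synthetic "experimental" observations on a regular time grid.

The benchmark protocol observes a single exact SSA trajectory of a network
at its true rate constants, recorded every ``dt`` over ``[0, T]``.  The
initial state ``X_0`` is treated as known (it is the network's initial
condition, not a quantity to fit); the observations proper are
``X_1 .. X_n`` at ``t_l = l * dt`` with ``n = T / dt``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gillespie import RandomSource, Trajectory, simulate
from .networks import ReactionNetwork

__all__ = ["ObservationSet", "generate_observations", "rebin"]


@dataclass
class ObservationSet:
    """Copy-number observations on the regular grid ``t_l = l * dt``."""

    initial_state: np.ndarray      # X_0 at t = 0, known
    states: np.ndarray             # (n, n_species): X_1 .. X_n
    dt: float
    species: list[str]

    def __post_init__(self) -> None:
        self.initial_state = np.asarray(self.initial_state, dtype=np.int64)
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 2 or self.states.shape[0] < 1:
            raise ValueError("need at least one observation row")
        if self.states.shape[1] != self.initial_state.shape[0]:
            raise ValueError("observation width must match initial state")
        if (self.states < 0).any() or (self.initial_state < 0).any():
            raise ValueError("copy numbers must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n(self) -> int:
        """Number of observation time points (excluding X_0)."""
        return self.states.shape[0]

    @property
    def T(self) -> float:
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(1, self.n + 1)

    def to_csv(self, path) -> None:
        """Write as a trajectory CSV including the t = 0 row."""
        times = np.concatenate(([0.0], self.times))
        states = np.vstack([self.initial_state, self.states])
        df = pd.DataFrame(states, columns=self.species)
        df.insert(0, "time", times)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ObservationSet":
        traj = Trajectory.from_csv(path)
        if traj.times[0] != 0.0:
            raise ValueError("observation CSV must start at t = 0")
        if traj.times.size < 2:
            raise ValueError("need at least one observation beyond t = 0")
        dts = np.diff(traj.times)
        dt = dts[0]
        if not np.allclose(dts, dt):
            raise ValueError("observation grid must be regular")
        return cls(traj.states[0], traj.states[1:], float(dt), traj.species)


def generate_observations(network: ReactionNetwork, T: float, dt: float,
                          rng: RandomSource, backend: str = "numba") -> ObservationSet:
    """One SSA realization of ``network`` at its exact rates, on the grid ``l*dt``."""
    n = T / dt
    if abs(n - round(n)) > 1e-9 or round(n) < 1:
        raise ValueError(f"T/dt must be a positive integer, got T={T}, dt={dt}")
    n = int(round(n))
    grid = dt * np.arange(1, n + 1)
    traj = simulate(network, grid, rng, backend=backend)
    return ObservationSet(network.initial_state.copy(), traj.states, float(dt),
                          network.species_names)


def rebin(obs: ObservationSet, new_dt: float) -> ObservationSet:
    """Keep only the observations at multiples of ``new_dt`` (no interpolation).

    Allows one underlying trajectory recorded densely (e.g. dt = 1) to be
    analysed at coarser inference step sizes (dt = 2, 5) while sharing the
    same realization.
    """
    ratio = new_dt / obs.dt
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(f"new_dt={new_dt} must be an integer multiple of dt={obs.dt}")
    step = int(round(ratio))
    if step == 1:
        return ObservationSet(obs.initial_state.copy(), obs.states.copy(), obs.dt,
                              list(obs.species))
    kept = obs.states[step - 1 :: step]
    if kept.shape[0] < 1:
        raise ValueError("rebinning leaves no observations")
    return ObservationSet(obs.initial_state.copy(), kept, float(new_dt), list(obs.species))
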