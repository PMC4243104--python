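"""Exact stochastic simulation (Gillespie direct method).

The direct method draws two uniforms per event: an exponential waiting time
from the total propensity and a channel choice proportional to the
per-reaction propensities.  Recording is cadlag: the state reported at a
grid time ``t_l`` is the state after the last event at time <= ``t_l``.

Simulation between consecutive recording times restarts the waiting-time
draw at each boundary.  By memorylessness of the exponential this is
statistically exact, and it is what makes per-interval restarts (the basis
of the transitional-density sampler) and whole-trajectory simulation share
one kernel: :func:`simulate` over a grid is definitionally a chain of
:func:`simulate_interval` calls with a carried state.

Randomness is organised as a tree of named substreams
(:class:`RandomSource`) built on ``numpy.random.SeedSequence`` spawn keys,
so each (particle, proposal, replicate, interval) gets an independent,
reproducible stream regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .networks import ReactionNetwork

__all__ = [
    "RandomSource",
    "Trajectory",
    "SimulationDivergedError",
    "simulate",
    "simulate_interval",
]

DEFAULT_MAX_EVENTS = 10**8


class SimulationDivergedError(RuntimeError):
    """Raised when a single simulation exceeds the event-count guard.

    Protects against runaway propensities from absurd parameter proposals
    (e.g. extreme prior draws) rather than looping for hours.
    """


class RandomSource:
    """A node in a reproducible tree of random substreams.

    ``RandomSource(seed).child(k1, k2, ...)`` derives an independent
    substream keyed by the integer path, via ``SeedSequence`` spawn keys.
    Identical seed and key path give identical streams, independent of the
    order in which siblings are consumed.
    """

    def __init__(self, seed: int, _key: tuple[int, ...] = ()):
        self.seed = int(seed)
        self.key = _key
        self._seq = np.random.SeedSequence(self.seed, spawn_key=_key)
        self._generator: np.random.Generator | None = None

    def child(self, *key: int) -> "RandomSource":
        return RandomSource(self.seed, self.key + tuple(int(k) for k in key))

    def generator(self) -> np.random.Generator:
        """PCG64 generator for this node (cached; repeated calls continue the stream)."""
        if self._generator is None:
            self._generator = np.random.default_rng(self._seq)
        return self._generator

    def kernel_seed(self) -> int:
        """A 32-bit seed for the Mersenne-Twister SSA kernel."""
        return int(self._seq.generate_state(1, dtype=np.uint32)[0])

    def __repr__(self) -> str:
        return f"RandomSource(seed={self.seed}, key={self.key})"


@dataclass
class Trajectory:
    """States of a jump process sampled on a fixed time grid."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_species) integer copy numbers
    species: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 2 or self.states.shape[0] != self.times.shape[0]:
            raise ValueError("states must be (n_times, n_species)")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.states < 0).any():
            raise ValueError("states must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.species)
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        if df.columns[0] != "time":
            raise ValueError("first column must be 'time'")
        species = list(df.columns[1:])
        states = df[species].to_numpy()
        if not np.array_equal(states, states.astype(np.int64)):
            raise ValueError("states must be integers")
        return cls(df["time"].to_numpy(), states.astype(np.int64), species)


def _run_kernel(network: ReactionNetwork, state: np.ndarray, t_from: float,
                t_to: float, seed: int, backend: str, max_events: int) -> None:
    dimer_factor = 0.5 if network.dimer_convention == "half" else 1.0
    if backend == "numba":
        fn = _kernels.ssa_interval_numba
    elif backend == "python":
        fn = _kernels.ssa_interval_python
    else:
        raise ValueError(f"unknown backend {backend!r}")
    status = fn(state, float(t_from), float(t_to), network.reactant_idx,
                network.reactant_ord, network.change_matrix,
                network.rate_constants, dimer_factor, max_events, seed)
    if status == _kernels.STATUS_EVENT_GUARD:
        raise SimulationDivergedError(
            f"simulation exceeded {max_events} events in [{t_from}, {t_to}]; "
            "check rate constants / prior bounds"
        )


def simulate_interval(network: ReactionNetwork, from_state: np.ndarray,
                      t_from: float, t_to: float, rng: RandomSource,
                      backend: str = "numba",
                      max_events: int = DEFAULT_MAX_EVENTS) -> np.ndarray:
    """State at ``t_to`` of one exact realization started at ``from_state``."""
    if not t_to > t_from:
        raise ValueError("t_to must be > t_from")
    state = np.asarray(from_state, dtype=np.int64).copy()
    if (state < 0).any():
        raise ValueError("from_state must be non-negative")
    _run_kernel(network, state, t_from, t_to, rng.kernel_seed(), backend, max_events)
    return state


def simulate(network: ReactionNetwork, record_times: np.ndarray,
             rng: RandomSource, initial_state: np.ndarray | None = None,
             t_start: float = 0.0, backend: str = "numba",
             max_events: int = DEFAULT_MAX_EVENTS) -> Trajectory:
    """One exact realization recorded at the given grid times.

    Interval ``l`` (from ``record_times[l-1]`` or ``t_start`` to
    ``record_times[l]``) uses the substream ``rng.child(l)``, so the result
    is identical to chaining :func:`simulate_interval` with a carried state.
    If the system freezes (zero total propensity) the remaining grid points
    hold the frozen state.
    """
    record_times = np.asarray(record_times, dtype=float)
    if record_times.ndim != 1 or record_times.size == 0:
        raise ValueError("record_times must be a non-empty 1-D array")
    if (np.diff(record_times) <= 0).any():
        raise ValueError("record_times must be strictly increasing")
    if record_times[0] <= t_start:
        raise ValueError("record_times must all be > t_start")
    if initial_state is None:
        initial_state = network.initial_state
    state = np.asarray(initial_state, dtype=np.int64).copy()
    states = np.empty((record_times.size, state.size), dtype=np.int64)
    t_prev = float(t_start)
    for l, t in enumerate(record_times):
        _run_kernel(network, state, t_prev, float(t), rng.child(l).kernel_seed(),
                    backend, max_events)
        states[l] = state
        t_prev = float(t)
    return Trajectory(record_times, states, network.species_names)
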