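"""Canned benchmark configurations for the two built-in test systems.

System 1 (reversible dimerization with decay) is observed over ``T = 30``;
system 2 (prokaryotic auto-regulation) over ``T = 50``.  In both cases the
"experimental" data are a single exact trajectory at the true rate
constants, recorded at ``dt = 1`` and rebinned to the inference step size,
so every step size analyses the same underlying realization.

The tolerance schedules below are stated for a reference population of 100
particles; :meth:`ToleranceSchedule.rescaled` adapts them to smaller
populations (the acceptance region depends only on ``N * epsilon_k`` under
the default error normalization).
"""

from __future__ import annotations

import numpy as np

from .abc_core import KernelSpec, PriorSpec
from .error_models import DiscrepancySpec
from .gillespie import RandomSource
from .networks import ReactionNetwork, build_system1, build_system2
from .observations import ObservationSet, generate_observations, rebin
from .samplers import InferenceResult, ToleranceSchedule, run_abc_smc, run_sld1, run_sld2

__all__ = [
    "REFERENCE_N",
    "TRUE_RATES",
    "PRIOR_UPPER",
    "EPSILON_SCHEDULES",
    "ALPHA_SCHEDULES",
    "build_network",
    "benchmark_prior",
    "benchmark_observations",
    "benchmark_schedule",
    "run_benchmark",
]

REFERENCE_N = 100  # particle count the printed schedules are stated for

TRUE_RATES = {
    1: np.array([0.1, 0.002, 0.5, 0.04]),
    2: np.array([0.1, 0.7, 0.35, 0.01, 0.1, 0.9, 0.2, 0.01]),
}

PRIOR_UPPER = {
    1: np.array([0.5, 0.005, 1.0, 0.1]),
    2: np.array([0.5, 2.0, 1.0, 0.1, 0.5, 5.0, 1.0, 0.1]),
}

_HORIZON = {1: 30.0, 2: 50.0}

# fitness-tolerance schedules, keyed by (system, algorithm, dt)
EPSILON_SCHEDULES = {
    (1, "sld1", 3): (0.07, 0.06, 0.055, 0.05, 0.045),
    (1, "sld1", 5): (0.05, 0.045, 0.04, 0.035, 0.03),
    (1, "sld2", 3): (0.095, 0.08, 0.065, 0.05, 0.04),
    (1, "sld2", 5): (0.059, 0.055, 0.05, 0.045, 0.04),
    (2, "sld1", 2): (0.21, 0.2, 0.19, 0.18, 0.175),
    (2, "sld1", 5): (0.21, 0.2, 0.19, 0.18, 0.175),
    (2, "sld2", 2): (0.24, 0.23, 0.22, 0.21, 0.2),
    (2, "sld2", 5): (0.24, 0.23, 0.22, 0.21, 0.2),
}

# explicit alpha schedules for the "different epsilon" varying-alpha cases
ALPHA_SCHEDULES = {
    (2, "sld1"): (0.15, 0.125, 0.1, 0.075, 0.07),
    (2, "sld2"): (0.095, 0.09, 0.085, 0.08, 0.075),
}


def build_network(system: int, **kwargs) -> ReactionNetwork:
    if system == 1:
        return build_system1(**kwargs)
    if system == 2:
        return build_system2(**kwargs)
    raise ValueError("system must be 1 or 2")


def benchmark_prior(system: int) -> PriorSpec:
    return PriorSpec(PRIOR_UPPER[system])


def benchmark_observations(system: int, dt: float, rng: RandomSource,
                           backend: str = "numba") -> ObservationSet:
    """One shared trajectory at dt = 1, rebinned to the inference step size."""
    network = build_network(system)
    dense = generate_observations(network, _HORIZON[system], 1.0, rng, backend=backend)
    return rebin(dense, dt)


def benchmark_schedule(system: int, algorithm: str, dt: float,
                       alpha_case: str = "fixed", B: int = 10) -> ToleranceSchedule:
    """A printed tolerance schedule with one of the three alpha strategies.

    ``alpha_case``: ``"fixed"`` (alpha = 0.05), ``"same"`` (alpha_k =
    epsilon_k) or ``"diff"`` (system 2 only: an explicit lower alpha
    schedule alongside the same epsilon_k).
    """
    eps = EPSILON_SCHEDULES[(system, algorithm, dt)]
    if alpha_case == "fixed":
        disc = DiscrepancySpec("fixed", alpha=0.05)
    elif alpha_case == "same":
        disc = DiscrepancySpec("match_epsilon")
    elif alpha_case == "diff":
        disc = DiscrepancySpec("schedule", schedule=ALPHA_SCHEDULES[(system, algorithm)])
    else:
        raise ValueError("alpha_case must be fixed | same | diff")
    return ToleranceSchedule(eps, (B,) * len(eps), disc)


_RUNNERS = {"sld1": run_sld1, "sld2": run_sld2, "smc": run_abc_smc}


def run_benchmark(system: int, algorithm: str, dt: float, seed: int, *,
                  alpha_case: str = "fixed", N: int = REFERENCE_N, B: int = 10,
                  obs: ObservationSet | None = None,
                  kernel: KernelSpec = KernelSpec("gaussian"),
                  backend: str = "numba", max_events: int = 10**7,
                  **driver_kwargs) -> InferenceResult:
    """Run one benchmark cell end to end from a single integer seed.

    Generates the synthetic observations (unless ``obs`` is supplied, for
    protocols that share one dataset across sampler seeds), rescales the
    printed schedule to the requested particle count, and runs the chosen
    sampler.  Substream 0 of the seed generates the data; substream 1
    drives the inference.
    """
    root = RandomSource(seed)
    if obs is None:
        obs = benchmark_observations(system, dt, root.child(0), backend=backend)
    schedule = benchmark_schedule(system, algorithm, dt, alpha_case, B=B)
    schedule = schedule.rescaled(N, REFERENCE_N)
    runner = _RUNNERS[algorithm]
    return runner(obs, build_network(system), benchmark_prior(system), schedule,
                  N, root.child(1), kernel=kernel, backend=backend,
                  max_events=max_events, **driver_kwargs)
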