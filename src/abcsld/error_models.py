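"""Discrepancy tests and fitness errors.

Two tolerance levels steer acceptance:

* the **discrepancy tolerance** ``alpha`` — a relative, per-time-point,
  per-species test: simulated state ``Y`` matches observed state ``X`` when
  ``|X_s - Y_s| <= alpha * X_s`` for every species ``s`` (species observed
  at 0 must be within an absolute ``zero_floor``, default exactly 0);
* the **fitness tolerance** ``epsilon_k`` — a per-iteration threshold on the
  aggregated fitness error of a parameter proposal.

For a proposal evaluated with ``B`` simulation replicates against ``n``
observation points, let ``b_l`` be the number of replicates failing the
point test at time ``l``.  The fitness error is the failure mass

    epsilon = (1/N) * sum_l b_l / B          (``per_particle_N``)

normalized by the particle count ``N``, so its range is ``[0, n/N]`` —
with 100 particles and 10 observation points the worst attainable error is
exactly 0.1, and the tolerance schedule lives on that scale.  The
alternative ``mean_failure_fraction`` normalization divides by ``n``
instead and lives on ``[0, 1]``; acceptance behaviour is identical once
thresholds are rescaled by ``N/n``.

The error is small-is-good: 0 means every replicate matched every
observation.  Acceptance uses ``epsilon <= epsilon_k`` so that a threshold
at the supremum ``n/N`` accepts everything.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as _iterproduct

import numpy as np

__all__ = [
    "DiscrepancySpec",
    "point_test",
    "failure_matrix",
    "failure_counts",
    "fitness_error_alg1",
    "fitness_error_alg2",
    "abc_smc_match_count",
    "frequency_distribution",
    "trajectory_distance",
    "max_fitness_error",
]


@dataclass(frozen=True)
class DiscrepancySpec:
    """Strategy for the discrepancy tolerance alpha across iterations.

    ``fixed``: one constant alpha.  ``match_epsilon``: alpha_k = epsilon_k
    (the varying-alpha strategy).  ``schedule``: an explicit per-iteration
    vector, for runs where the alpha schedule differs from epsilon_k.
    """

    strategy: str = "fixed"
    alpha: float = 0.05
    schedule: tuple[float, ...] | None = None
    zero_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.strategy not in ("fixed", "match_epsilon", "schedule"):
            raise ValueError("strategy must be fixed | match_epsilon | schedule")
        if self.strategy == "fixed" and not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if self.strategy == "schedule" and not self.schedule:
            raise ValueError("schedule strategy requires an alpha schedule")
        if self.zero_floor < 0:
            raise ValueError("zero_floor must be >= 0")

    def alpha_for(self, k: int, epsilon_k: float) -> float:
        """Alpha used at iteration k (1-based)."""
        if self.strategy == "fixed":
            return self.alpha
        if self.strategy == "match_epsilon":
            return epsilon_k
        return self.schedule[k - 1]


def point_test(X_l: np.ndarray, Y_ml: np.ndarray, alpha: float,
               zero_floor: float = 0.0) -> bool:
    """Relative match test between one observed and one simulated state."""
    X_l = np.asarray(X_l, dtype=float)
    Y_ml = np.asarray(Y_ml, dtype=float)
    if X_l.shape != Y_ml.shape:
        raise ValueError("observed and simulated states must have equal length")
    pos = X_l > 0
    ok_pos = np.abs(X_l[pos] - Y_ml[pos]) <= alpha * X_l[pos]
    ok_zero = np.abs(Y_ml[~pos]) <= zero_floor
    return bool(ok_pos.all() and ok_zero.all())


def failure_matrix(observed: np.ndarray, simulations: np.ndarray, alpha: float,
                   zero_floor: float = 0.0) -> np.ndarray:
    """Boolean (B, n) matrix: replicate m fails the point test at time l.

    ``observed`` is (n, S); ``simulations`` is (B, n, S).
    """
    observed = np.asarray(observed, dtype=float)
    simulations = np.asarray(simulations, dtype=float)
    if simulations.shape[1:] != observed.shape:
        raise ValueError("simulations must be (B, n, S) matching observed (n, S)")
    pos = observed > 0
    diff = np.abs(simulations - observed)
    tol = np.where(pos, alpha * observed, zero_floor)
    return (diff > tol).any(axis=2)


def failure_counts(observed: np.ndarray, simulations: np.ndarray,
                   alpha: float, zero_floor: float = 0.0) -> np.ndarray:
    """Per-time-point failure counts b_l = number of replicates failing at l."""
    return failure_matrix(observed, simulations, alpha, zero_floor).sum(axis=0)


def _aggregate(b: np.ndarray, B: int, n: int, N: int, norm: str) -> float:
    if norm == "per_particle_N":
        return float(b.sum() / (B * N))
    if norm == "mean_failure_fraction":
        return float(b.sum() / (B * n))
    raise ValueError("norm must be per_particle_N | mean_failure_fraction")


def fitness_error_alg1(b: np.ndarray, B: int, n: int, N: int,
                       norm: str = "per_particle_N") -> float:
    """Aggregate per-interval failure counts into the scalar fitness error."""
    b = np.asarray(b)
    if b.shape != (n,):
        raise ValueError(f"expected {n} failure counts, got shape {b.shape}")
    if ((b < 0) | (b > B)).any():
        raise ValueError("failure counts must lie in [0, B]")
    return _aggregate(b, B, n, N, norm)


def fitness_error_alg2(observed: np.ndarray, trajectories: np.ndarray,
                       alpha: float, N: int, zero_floor: float = 0.0,
                       norm: str = "per_particle_N") -> float:
    """Fitness error from whole-trajectory replicates.

    Identical aggregation to the per-interval form; the replicates are full
    simulated trajectories on the observation grid instead of per-interval
    restarts.
    """
    b = failure_counts(observed, trajectories, alpha, zero_floor)
    B, n = np.asarray(trajectories).shape[:2]
    return _aggregate(b, B, n, N, norm)


def trajectory_distance(observed: np.ndarray, simulated: np.ndarray,
                        kind: str = "rms_relative", alpha: float = 0.05,
                        zero_floor: float = 0.0) -> float:
    """Whole-trajectory scalar distance for the generic population sampler.

    ``rms_relative``: root mean square of (X - Y) / max(X, 1) over all
    (time, species) cells.  ``rms_absolute``: plain RMS.  ``match_fraction``:
    fraction of time points failing the alpha point test.
    """
    observed = np.asarray(observed, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if observed.shape != simulated.shape:
        raise ValueError("trajectories must have equal shape")
    if kind == "rms_relative":
        rel = (observed - simulated) / np.maximum(observed, 1.0)
        return float(np.sqrt(np.mean(rel**2)))
    if kind == "rms_absolute":
        return float(np.sqrt(np.mean((observed - simulated) ** 2)))
    if kind == "match_fraction":
        fails = failure_matrix(observed, simulated[None], alpha, zero_floor)[0]
        return float(fails.mean())
    raise ValueError("kind must be rms_relative | rms_absolute | match_fraction")


def abc_smc_match_count(observed: np.ndarray, trajectories: np.ndarray,
                        epsilon_k: float, kind: str = "rms_relative",
                        alpha: float = 0.05) -> int:
    """Number of replicates whose whole-trajectory distance is <= epsilon_k."""
    trajectories = np.asarray(trajectories)
    if trajectories.ndim != 3 or trajectories.shape[0] < 1:
        raise ValueError("trajectories must be (B, n, S) with B >= 1")
    return int(sum(
        trajectory_distance(observed, traj, kind=kind, alpha=alpha) <= epsilon_k
        for traj in trajectories
    ))


def frequency_distribution(X_l: np.ndarray, simulated_states: np.ndarray,
                           alpha: float, zero_floor: float = 0.0) -> float:
    """Empirical transitional density at X_l: fraction of replicates matching.

    This is the simulated-likelihood estimate of the one-step transitional
    density, evaluated through the alpha point test.
    """
    simulated_states = np.asarray(simulated_states)
    if simulated_states.ndim != 2 or simulated_states.shape[0] < 1:
        raise ValueError("simulated_states must be (B, S) with B >= 1")
    fails = failure_matrix(np.asarray(X_l)[None, :], simulated_states[:, None, :],
                           alpha, zero_floor)
    return float(1.0 - fails.mean())


def max_fitness_error(n: int, B: int, N: int, norm: str = "per_particle_N",
                      exhaustive_limit: int = 200_000) -> float:
    """Supremum of the fitness error over all failure-count outcomes.

    Enumerates candidate failure-count vectors: fully exhaustively over
    ``{0..B}^n`` when that grid is small enough, otherwise coordinatewise
    (the error is additive across time points, so the maximum separates).
    """
    if (B + 1) ** n <= exhaustive_limit:
        best = 0.0
        for b in _iterproduct(range(B + 1), repeat=n):
            best = max(best, _aggregate(np.array(b), B, n, N, norm))
        return best
    # additive across time points: maximize each coordinate's contribution
    b = np.zeros(n, dtype=int)
    for l in range(n):
        contributions = []
        for v in range(B + 1):
            trial = b.copy()
            trial[l] = v
            contributions.append(_aggregate(trial, B, n, N, norm))
        b[l] = int(np.argmax(contributions))
    return _aggregate(b, B, n, N, norm)
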