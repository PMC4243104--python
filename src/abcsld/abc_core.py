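"""Priors, perturbation kernels, particles and importance weights.

The sequential Monte Carlo machinery shared by all samplers: a population
of ``N`` parameter vectors ("particles") is filtered through a decreasing
tolerance schedule.  At iteration 1 particles are drawn from the prior; at
iteration ``k > 1`` a particle is resampled from the previous population by
weight, jittered by a perturbation kernel scaled by the previous
population's componentwise spread ``sigma_{k-1}``, and re-evaluated.

Importance weights for ``k > 1`` follow the standard sequential form

    w_i  ∝  pi(theta_i) / sum_j w_j^{k-1} q(theta_i | theta_j, sigma_{k-1})

normalized to sum to one.  With hard acceptance the survivorship factor of
the generic population sampler is already enforced by the accept/reject
step; ``weight_bk="match_count"`` optionally multiplies the numerator by a
per-particle replicate match count for cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PriorSpec",
    "KernelSpec",
    "Particle",
    "Population",
    "sample_prior",
    "resample_index",
    "perturb",
    "kernel_density",
    "compute_weights",
    "population_sigma",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Independent componentwise uniform prior U(0, A_j)."""

    upper: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if self.upper.ndim != 1 or (self.upper <= 0).any():
            raise ValueError("prior upper bounds must be a 1-D positive vector")

    @property
    def dim(self) -> int:
        return self.upper.size

    @property
    def mean(self) -> np.ndarray:
        return self.upper / 2.0

    def density(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        if ((theta <= 0) | (theta >= self.upper)).any():
            return 0.0
        return float(np.prod(1.0 / self.upper))


@dataclass(frozen=True)
class KernelSpec:
    """Perturbation kernel family, scaled by the previous population spread."""

    family: str = "gaussian"  # "gaussian" | "uniform"

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "uniform"):
            raise ValueError("kernel family must be 'gaussian' or 'uniform'")


@dataclass
class Particle:
    """An accepted parameter vector with its weight and proposal cost."""

    theta: np.ndarray
    weight: float
    count: int  # proposals consumed before acceptance, >= 1
    epsilon: float = math.nan  # fitness error at acceptance


@dataclass
class Population:
    """All accepted particles of one SMC iteration."""

    iteration: int
    particles: list[Particle]
    sigma: np.ndarray = field(default=None)  # componentwise spread, set post-hoc

    @property
    def N(self) -> int:
        return len(self.particles)

    @property
    def thetas(self) -> np.ndarray:
        return np.array([p.theta for p in self.particles])

    @property
    def weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.particles])

    @property
    def counts(self) -> np.ndarray:
        return np.array([p.count for p in self.particles])

    def weighted_mean(self) -> np.ndarray:
        return self.weights @ self.thetas


def sample_prior(prior: PriorSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw theta componentwise uniform, strictly inside (0, A_j)."""
    u = rng.random(prior.dim)
    while True:
        bad = u == 0.0
        if not bad.any():
            break
        u[bad] = rng.random(int(bad.sum()))
    return prior.upper * u


def resample_index(weights: np.ndarray, rng: np.random.Generator) -> int:
    """Draw a particle index with probability proportional to its weight."""
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("cannot resample from all-zero weights")
    return int(rng.choice(weights.size, p=weights / total))


def perturb(theta_star: np.ndarray, kernel: KernelSpec, sigma_prev: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Jitter a resampled particle: N(theta*, sigma^2) or U(theta* +- sigma)."""
    theta_star = np.asarray(theta_star, dtype=float)
    sigma_prev = np.asarray(sigma_prev, dtype=float)
    if (sigma_prev < 0).any():
        raise ValueError("sigma_prev must be non-negative")
    if kernel.family == "gaussian":
        return theta_star + sigma_prev * rng.standard_normal(theta_star.size)
    return theta_star + sigma_prev * (2.0 * rng.random(theta_star.size) - 1.0)


def kernel_density(theta_to: np.ndarray, theta_from: np.ndarray,
                   kernel: KernelSpec, sigma_prev: np.ndarray) -> float:
    """Product of componentwise kernel densities q(theta_to | theta_from).

    Components with sigma = 0 use the point-mass convention: factor 1 if the
    components are equal, else 0.
    """
    delta = np.asarray(theta_to, dtype=float) - np.asarray(theta_from, dtype=float)
    sigma_prev = np.asarray(sigma_prev, dtype=float)
    dens = 1.0
    for d, s in zip(delta, sigma_prev):
        if s == 0.0:
            if d != 0.0:
                return 0.0
            continue
        if kernel.family == "gaussian":
            dens *= math.exp(-0.5 * (d / s) ** 2) / (s * _SQRT2PI)
        else:
            if abs(d) > s:
                return 0.0
            dens *= 1.0 / (2.0 * s)
    return dens


def compute_weights(prev_thetas: np.ndarray | None, prev_weights: np.ndarray | None,
                    new_thetas: np.ndarray, prior: PriorSpec, kernel: KernelSpec,
                    sigma_prev: np.ndarray | None, iteration: int,
                    match_counts: np.ndarray | None = None) -> np.ndarray:
    """Normalized importance weights for a freshly accepted population.

    Iteration 1: uniform 1/N.  Later iterations: the sequential importance
    ratio prior / (weighted kernel mixture over the previous population),
    optionally scaled by per-particle match counts.
    """
    n = new_thetas.shape[0]
    if n == 0:
        raise ValueError("empty population")
    if iteration == 1:
        w = np.full(n, 1.0 / n)
        if match_counts is not None:
            w = w * np.asarray(match_counts, dtype=float)
            return _normalize(w)
        return w
    if prev_thetas is None or prev_weights is None or sigma_prev is None:
        raise ValueError("previous population required for iteration > 1")
    w = np.empty(n)
    for i in range(n):
        denom = 0.0
        for j in range(prev_thetas.shape[0]):
            denom += prev_weights[j] * kernel_density(new_thetas[i], prev_thetas[j],
                                                      kernel, sigma_prev)
        num = prior.density(new_thetas[i])
        if match_counts is not None:
            num *= float(match_counts[i])
        w[i] = num / denom if denom > 0 else 0.0
    return _normalize(w)


def _normalize(w: np.ndarray) -> np.ndarray:
    total = w.sum()
    if not total > 0:
        raise ValueError(
            "all particle weights are zero; the previous population cannot "
            "explain the accepted particles (kernel scale collapsed?)"
        )
    return w / total


def population_sigma(thetas: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Componentwise spread sigma_k of a population of parameter vectors.

    Default: square root of the unweighted sample variance (ddof = 1).  With
    ``weights`` given, the weighted analogue.
    """
    thetas = np.asarray(thetas, dtype=float)
    if thetas.ndim != 2 or thetas.shape[0] < 2:
        raise ValueError("need at least two particles to compute sigma")
    if weights is None:
        return thetas.std(axis=0, ddof=1)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    mean = weights @ thetas
    var = weights @ (thetas - mean) ** 2 / max(1.0 - (weights**2).sum(), 1e-12)
    return np.sqrt(var)
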