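"""Inference drivers: two simulated-likelihood-density samplers and a
generic population-Monte-Carlo baseline.

All three share the SMC skeleton: ``K`` iterations, each collecting ``N``
accepted particles through a decreasing fitness-tolerance schedule
``epsilon_1 .. epsilon_K``, with weighted resampling and kernel
perturbation between iterations.  They differ only in how a parameter
proposal is scored against the observations:

* ``sld1`` — per-interval restarts: for every observation interval
  ``(t_{l-1}, t_l]`` the simulator is restarted ``B_k`` times from the
  *observed* state ``X_{l-1}``, approximating the one-step transitional
  density; the fitness error aggregates per-time-point failure counts.
* ``sld2`` — whole-trajectory replicates from ``X_0``, but still scored
  per time point with the same aggregation.
* ``smc`` — whole-trajectory replicates scored by a single trajectory
  distance; a proposal is accepted when at least one of ``B_k`` replicates
  lands within ``epsilon_k``, and weights carry the replicate match count.

Diagnostics follow the benchmark conventions: the *mean count number* (MN)
is the average number of proposals consumed per accepted particle (an
inverse acceptance rate), and the *averaged error* (AE) is the population
mean of the summed relative errors of the estimated rate constants against
the generating values.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .abc_core import (
    KernelSpec,
    Particle,
    Population,
    PriorSpec,
    compute_weights,
    perturb,
    population_sigma,
    resample_index,
    sample_prior,
)
from .error_models import (
    DiscrepancySpec,
    point_test,
    trajectory_distance,
)
from .gillespie import (
    DEFAULT_MAX_EVENTS,
    RandomSource,
    SimulationDivergedError,
    simulate,
    simulate_interval,
)
from .networks import ReactionNetwork
from .observations import ObservationSet

__all__ = [
    "ToleranceSchedule",
    "InferenceResult",
    "AcceptanceStallError",
    "run_sld1",
    "run_sld2",
    "run_abc_smc",
    "mean_count_number",
    "averaged_error",
    "posterior_histogram",
]

logger = logging.getLogger("abcsld")

# substream roles under each proposal's RandomSource
_DRAW = 0  # prior draw / resample / perturbation
_SIM = 1   # simulation replicates

_EPS_SLACK = 1e-12


@dataclass(frozen=True)
class ToleranceSchedule:
    """Fitness tolerances, simulation counts and the alpha strategy."""

    epsilon: tuple[float, ...]
    B: tuple[int, ...]
    discrepancy: DiscrepancySpec = DiscrepancySpec()

    def __post_init__(self) -> None:
        eps = tuple(float(e) for e in self.epsilon)
        object.__setattr__(self, "epsilon", eps)
        if len(eps) < 1 or any(e <= 0 for e in eps):
            raise ValueError("epsilon schedule must be non-empty and positive")
        if any(b > a for a, b in zip(eps, eps[1:])):
            raise ValueError("epsilon schedule must be non-increasing")
        B = self.B
        if isinstance(B, (int, np.integer)):
            B = (int(B),) * len(eps)
        else:
            B = tuple(int(b) for b in B)
        if len(B) == 1 and len(eps) > 1:
            B = B * len(eps)
        object.__setattr__(self, "B", B)
        if len(B) != len(eps) or any(b < 1 for b in B):
            raise ValueError("need one simulation count B_k >= 1 per iteration")
        if (self.discrepancy.strategy == "schedule"
                and len(self.discrepancy.schedule) != len(eps)):
            raise ValueError("alpha schedule length must equal K")

    @property
    def K(self) -> int:
        return len(self.epsilon)

    def alpha_for(self, k: int) -> float:
        return self.discrepancy.alpha_for(k, self.epsilon[k - 1])

    def rescaled(self, N_run: int, N_ref: int = 100) -> "ToleranceSchedule":
        """Rescale tolerances from a reference particle count to ``N_run``.

        Under the ``per_particle_N`` normalization the acceptance region
        depends on ``N * epsilon_k`` only, so a schedule printed for
        ``N_ref`` particles is equivalent at ``N_run`` after multiplying by
        ``N_ref / N_run``.  Alpha schedules are left unchanged.
        """
        factor = N_ref / N_run
        return replace(self, epsilon=tuple(e * factor for e in self.epsilon))


@dataclass
class InferenceResult:
    """Populations and per-iteration diagnostics of one inference run."""

    algorithm: str
    populations: list[Population]
    diagnostics: list[dict]
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return len(self.populations)

    def population(self, k: int) -> Population:
        """Population of iteration ``k`` (1-based)."""
        return self.populations[k - 1]

    def posterior_mean(self, k: int | None = None) -> np.ndarray:
        pop = self.populations[-1 if k is None else k - 1]
        return pop.weighted_mean()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pop in self.populations:
            for i, p in enumerate(pop.particles):
                row = {"iteration": pop.iteration, "particle": i}
                row.update({f"theta_{j + 1}": t for j, t in enumerate(p.theta)})
                row.update({"weight": p.weight, "count": p.count, "epsilon": p.epsilon})
                rows.append(row)
        return pd.DataFrame(rows)

    def save(self, outdir) -> None:
        """Write per-iteration population CSVs and a diagnostics JSON sidecar."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frame = self.to_frame()
        for k, pop in enumerate(self.populations, start=1):
            frame[frame["iteration"] == k].to_csv(
                outdir / f"population_{k}.csv", index=False)
        sidecar = {
            "algorithm": self.algorithm,
            "seed": self.seed,
            "config": self.config,
            "iterations": [
                {**d, "sigma": [float(s) for s in pop.sigma]}
                for d, pop in zip(self.diagnostics, self.populations)
            ],
        }
        with open(outdir / "diagnostics.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


class AcceptanceStallError(RuntimeError):
    """A particle exhausted its proposal budget; carries partial results."""

    def __init__(self, message: str, partial: InferenceResult):
        super().__init__(message)
        self.partial = partial


# ---------------------------------------------------------------------------
# proposal evaluation
# ---------------------------------------------------------------------------

def _eval_sld1(theta, obs, network, alpha, zero_floor, eps_k, B, N, rng_sim,
               backend, norm, max_events, early_reject):
    """Per-interval-restart score.  Returns (accepted, epsilon, match_count)."""
    net = network.with_rates(theta)
    n = obs.n
    states = np.vstack([obs.initial_state, obs.states])
    times = np.concatenate(([0.0], obs.times))
    denom = N if norm == "per_particle_N" else n
    budget = eps_k * B * denom + _EPS_SLACK * B * denom
    total_fail = 0
    for l in range(1, n + 1):
        for m in range(B):
            try:
                y = simulate_interval(net, states[l - 1], times[l - 1], times[l],
                                      rng_sim.child(l, m), backend=backend,
                                      max_events=max_events)
                fail = not point_test(states[l], y, alpha, zero_floor)
            except SimulationDivergedError:
                fail = True  # runaway propensity: count as a mismatch
            total_fail += fail
            if early_reject and total_fail > budget:
                return False, np.inf, 0
    eps = total_fail / (B * denom)
    return eps <= eps_k + _EPS_SLACK, eps, n * B - total_fail


def _eval_sld2(theta, obs, network, alpha, zero_floor, eps_k, B, N, rng_sim,
               backend, norm, max_events, early_reject):
    """Whole-trajectory replicates scored per time point."""
    net = network.with_rates(theta)
    n = obs.n
    denom = N if norm == "per_particle_N" else n
    budget = eps_k * B * denom + _EPS_SLACK * B * denom
    total_fail = 0
    for m in range(B):
        try:
            traj = simulate(net, obs.times, rng_sim.child(m),
                            initial_state=obs.initial_state, backend=backend,
                            max_events=max_events)
            fails = sum(
                not point_test(obs.states[l], traj.states[l], alpha, zero_floor)
                for l in range(n)
            )
        except SimulationDivergedError:
            fails = n
        total_fail += fails
        if early_reject and total_fail > budget:
            return False, np.inf, 0
    eps = total_fail / (B * denom)
    return eps <= eps_k + _EPS_SLACK, eps, n * B - total_fail


def _eval_smc(theta, obs, network, alpha, zero_floor, eps_k, B, N, rng_sim,
              backend, norm, max_events, distance_kind):
    """Whole-trajectory distance score: accepted iff any replicate matches."""
    net = network.with_rates(theta)
    matches = 0
    for m in range(B):
        try:
            traj = simulate(net, obs.times, rng_sim.child(m),
                            initial_state=obs.initial_state, backend=backend,
                            max_events=max_events)
            d = trajectory_distance(obs.states, traj.states, kind=distance_kind,
                                    alpha=alpha, zero_floor=zero_floor)
        except SimulationDivergedError:
            d = np.inf
        matches += d <= eps_k + _EPS_SLACK
    return matches > 0, float(matches) / B, matches


# ---------------------------------------------------------------------------
# the shared SMC driver
# ---------------------------------------------------------------------------

def _run(algorithm, obs, network, prior, schedule, N, rng, *, kernel,
         backend, norm, weight_bk, stall_cap, max_events, early_reject,
         count_support_rejections, distance_kind):
    if prior.dim != network.n_reactions:
        raise ValueError("prior dimension must equal the number of rate constants")
    config = {
        "algorithm": algorithm, "N": N, "K": schedule.K,
        "epsilon": list(schedule.epsilon), "B": list(schedule.B),
        "alpha_strategy": schedule.discrepancy.strategy,
        "alpha": schedule.discrepancy.alpha,
        "alpha_schedule": (list(schedule.discrepancy.schedule)
                           if schedule.discrepancy.schedule else None),
        "zero_floor": schedule.discrepancy.zero_floor,
        "prior_upper": [float(a) for a in prior.upper],
        "kernel": kernel.family, "norm": norm, "weight_bk": weight_bk,
        "backend": backend, "distance_kind": distance_kind,
    }
    populations: list[Population] = []
    diagnostics: list[dict] = []
    prev: Population | None = None
    for k in range(1, schedule.K + 1):
        t0 = time.perf_counter()
        eps_k = schedule.epsilon[k - 1]
        B_k = schedule.B[k - 1]
        alpha_k = schedule.alpha_for(k)
        zero_floor = schedule.discrepancy.zero_floor
        accepted: list[Particle] = []
        match_counts: list[int] = []
        total_proposals = 0
        for i in range(N):
            count = 0
            attempt = 0
            while True:
                attempt += 1
                count += 1
                if attempt > stall_cap:
                    partial = InferenceResult(algorithm, populations, diagnostics,
                                              rng.seed, config)
                    raise AcceptanceStallError(
                        f"iteration {k}, particle {i}: no acceptance after "
                        f"{stall_cap} proposals (epsilon_k={eps_k}, alpha_k={alpha_k})",
                        partial,
                    )
                rng_p = rng.child(k, i, attempt)
                gen = rng_p.child(_DRAW).generator()
                if k == 1:
                    theta = sample_prior(prior, gen)
                else:
                    idx = resample_index(prev.weights, gen)
                    theta = perturb(prev.thetas[idx], kernel, prev.sigma, gen)
                    if prior.density(theta) == 0.0:
                        if not count_support_rejections:
                            count -= 1
                        continue
                rng_sim = rng_p.child(_SIM)
                if algorithm == "smc":
                    ok, score, mc = _eval_smc(theta, obs, network, alpha_k,
                                              zero_floor, eps_k, B_k, N, rng_sim,
                                              backend, norm, max_events,
                                              distance_kind)
                else:
                    eval_fn = _eval_sld1 if algorithm == "sld1" else _eval_sld2
                    ok, score, mc = eval_fn(theta, obs, network, alpha_k,
                                            zero_floor, eps_k, B_k, N, rng_sim,
                                            backend, norm, max_events,
                                            early_reject)
                if ok:
                    accepted.append(Particle(theta, 0.0, count, score))
                    match_counts.append(mc)
                    total_proposals += attempt
                    break
        thetas = np.array([p.theta for p in accepted])
        mc_arr = np.asarray(match_counts, dtype=float)
        if algorithm == "smc":
            w = compute_weights(None if prev is None else prev.thetas,
                                None if prev is None else prev.weights,
                                thetas, prior, kernel,
                                None if prev is None else prev.sigma,
                                k, match_counts=mc_arr)
        else:
            w = compute_weights(None if prev is None else prev.thetas,
                                None if prev is None else prev.weights,
                                thetas, prior, kernel,
                                None if prev is None else prev.sigma,
                                k,
                                match_counts=mc_arr if weight_bk == "match_count" else None)
        for p, wi in zip(accepted, w):
            p.weight = float(wi)
        pop = Population(k, accepted, sigma=population_sigma(thetas))
        populations.append(pop)
        wall = time.perf_counter() - t0
        mn = float(pop.counts.mean())
        diagnostics.append({
            "iteration": k, "epsilon_k": eps_k, "alpha_k": alpha_k, "B_k": B_k,
            "mean_count": mn, "acceptance_rate": N / total_proposals,
            "wall_time_s": wall,
        })
        logger.info("%s iter %d/%d: eps=%g alpha=%g MN=%.2f accept=%.3g (%.1fs)",
                    algorithm, k, schedule.K, eps_k, alpha_k, mn,
                    N / total_proposals, wall)
        prev = pop
    return InferenceResult(algorithm, populations, diagnostics, rng.seed, config)


def _driver(algorithm):
    def run(obs: ObservationSet, network: ReactionNetwork, prior: PriorSpec,
            schedule: ToleranceSchedule, N: int, rng: RandomSource, *,
            kernel: KernelSpec = KernelSpec("gaussian"), backend: str = "numba",
            norm: str = "per_particle_N", weight_bk: str = "none",
            stall_cap: int = 10**6, max_events: int = DEFAULT_MAX_EVENTS,
            early_reject: bool = True, count_support_rejections: bool = False,
            distance_kind: str = "rms_relative") -> InferenceResult:
        return _run(algorithm, obs, network, prior, schedule, N, rng,
                    kernel=kernel, backend=backend, norm=norm,
                    weight_bk=weight_bk, stall_cap=stall_cap,
                    max_events=max_events, early_reject=early_reject,
                    count_support_rejections=count_support_rejections,
                    distance_kind=distance_kind)

    run.__name__ = f"run_{algorithm}"
    return run


run_sld1 = _driver("sld1")
run_sld1.__doc__ = """Transitional-density sampler (per-interval restarts).

For each proposal, every observation interval is re-simulated ``B_k`` times
from the observed state at the interval start; the proposal is accepted
when its aggregated fitness error is within ``epsilon_k``.
"""

run_sld2 = _driver("sld2")
run_sld2.__doc__ = """Whole-trajectory sampler with per-time-point scoring.

Replicates run from ``X_0`` over the full horizon; the fitness error
aggregates per-time-point failures exactly as in the per-interval sampler.
"""

run_abc_smc = _driver("smc")
run_abc_smc.__doc__ = """Generic population sampler (whole-trajectory distance).

A proposal is accepted when at least one of ``B_k`` replicates has
trajectory distance <= ``epsilon_k``; weights are proportional to the
replicate match count (times the usual importance ratio after iteration 1).
Note ``epsilon_k`` is on the scale of ``distance_kind`` here, not on the
fitness-error scale of the SLD samplers.
"""


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def mean_count_number(result: InferenceResult, k: int) -> float:
    """Average number of proposals per accepted particle at iteration k."""
    return float(result.population(k).counts.mean())


def averaged_error(result: InferenceResult, k: int, true_rates: np.ndarray,
                   method: str = "estimate", weighted: bool = True) -> float:
    """Summed relative error of the estimated rate constants at iteration k.

    ``method="estimate"`` (default): the error of the population point
    estimate, AE_k = sum_j |theta_hat_j - c_j| / c_j with theta_hat the
    (weighted) population mean.  Averaging the particles before taking
    errors lets sampling spread cancel, so this tracks the quality of the
    reported estimate.

    ``method="particle_mean"``: the population average of per-particle
    summed relative errors, mean_i sum_j |theta_ij - c_j| / c_j, which
    additionally charges the population spread.
    """
    true_rates = np.asarray(true_rates, dtype=float)
    if (true_rates <= 0).any():
        raise ValueError("true rates must be strictly positive")
    pop = result.population(k)
    if method == "estimate":
        est = pop.weighted_mean() if weighted else pop.thetas.mean(axis=0)
        return float((np.abs(est - true_rates) / true_rates).sum())
    if method == "particle_mean":
        per_particle = (np.abs(pop.thetas - true_rates) / true_rates).sum(axis=1)
        if weighted:
            return float(pop.weights @ per_particle)
        return float(per_particle.mean())
    raise ValueError("method must be 'estimate' or 'particle_mean'")


def posterior_histogram(result: InferenceResult, k: int, param_index: int,
                        bins: int = 20,
                        support: tuple[float, float] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Weight-weighted marginal histogram; frequencies sum to one.

    Returns ``(frequencies, bin_edges)``.  The range defaults to the prior
    support recorded in the run configuration.
    """
    pop = result.population(k)
    if support is None:
        upper = result.config.get("prior_upper")
        support = (0.0, upper[param_index]) if upper else None
    freq, edges = np.histogram(pop.thetas[:, param_index], bins=bins,
                               range=support, weights=pop.weights)
    total = freq.sum()
    if total > 0:
        freq = freq / total
    return freq, edges
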