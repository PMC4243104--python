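"""Inference drivers: determinism, acceptance mechanics, diagnostics.

Driver-logic properties (count semantics, tolerance monotonicity, shared
acceptance core) are tested with stubbed proposal evaluators so they run in
milliseconds; end-to-end stochastic behaviour on the benchmark systems
lives in the acceptance suite.
"""

import math

import numpy as np
import pytest
from scipy import stats

import abcsld.samplers as samplers_mod
from abcsld import (
    AcceptanceStallError,
    DiscrepancySpec,
    KernelSpec,
    PriorSpec,
    RandomSource,
    ToleranceSchedule,
    averaged_error,
    build_system1,
    generate_observations,
    mean_count_number,
    posterior_histogram,
    run_abc_smc,
    run_sld1,
    run_sld2,
)
from abcsld.abc_core import Particle, Population
from abcsld.observations import rebin
from abcsld.samplers import InferenceResult

SYS1_PRIOR = PriorSpec(np.array([0.5, 0.005, 1.0, 0.1]))
TRUE1 = np.array([0.1, 0.002, 0.5, 0.04])


@pytest.fixture(scope="module")
def small_obs():
    """System-1 data on a coarse grid (n = 6) for cheap end-to-end runs."""
    net = build_system1()
    dense = generate_observations(net, 30, 1, RandomSource(2024))
    return rebin(dense, 5)


def always_accept_schedule(n, N, K=2, B=2):
    # epsilon at the supremum n/N accepts every proposal
    return ToleranceSchedule((n / N,) * K, (B,) * K, DiscrepancySpec("fixed", alpha=0.05))


def make_result(counts, thetas=None, weights=None):
    n = len(counts)
    thetas = np.asarray(thetas if thetas is not None else np.ones((n, 1)))
    weights = np.asarray(weights if weights is not None else np.full(n, 1.0 / n))
    particles = [Particle(t, w, c) for t, w, c in zip(thetas, weights, counts)]
    pop = Population(1, particles, sigma=np.zeros(thetas.shape[1]))
    return InferenceResult("sld1", [pop], [{}], 0, {})


class TestForcedAcceptance:
    @pytest.mark.parametrize("runner", [run_sld1, run_sld2])
    def test_mean_count_one_at_max_tolerance(self, small_obs, runner):
        N = 5
        sched = always_accept_schedule(small_obs.n, N)
        res = runner(small_obs, build_system1(), SYS1_PRIOR, sched, N, RandomSource(3))
        for k in (1, 2):
            assert mean_count_number(res, k) == 1.0

    def test_iteration_one_weights_are_uniform(self, small_obs):
        N = 5
        sched = always_accept_schedule(small_obs.n, N)
        res = run_sld1(small_obs, build_system1(), SYS1_PRIOR, sched, N, RandomSource(3))
        assert np.allclose(res.population(1).weights, 1.0 / N)

    def test_smc_huge_tolerance_uniform_weights(self, small_obs):
        # distance threshold so large every replicate matches: b_k = B always
        sched = ToleranceSchedule((1e6, 1e6), (2, 2), DiscrepancySpec("fixed", alpha=0.05))
        res = run_abc_smc(small_obs, build_system1(), SYS1_PRIOR, sched, 4, RandomSource(5))
        assert np.allclose(res.population(1).weights, 0.25)
        assert mean_count_number(res, 1) == 1.0


class TestDeterminism:
    @pytest.mark.parametrize("runner", [run_sld1, run_sld2, run_abc_smc])
    def test_same_seed_identical_result(self, small_obs, runner):
        sched = (always_accept_schedule(small_obs.n, 4)
                 if runner is not run_abc_smc
                 else ToleranceSchedule((0.5, 0.5), (2, 2)))
        a = runner(small_obs, build_system1(), SYS1_PRIOR, sched, 4, RandomSource(11))
        b = runner(small_obs, build_system1(), SYS1_PRIOR, sched, 4, RandomSource(11))
        for k in (1, 2):
            assert np.array_equal(a.population(k).thetas, b.population(k).thetas)
            assert np.array_equal(a.population(k).weights, b.population(k).weights)
            assert np.array_equal(a.population(k).counts, b.population(k).counts)


class TestStallProtection:
    def test_stall_raises_with_partial_results(self, small_obs):
        # unreachable tolerance: even one failing replicate exceeds it
        sched = ToleranceSchedule((1e-9,), (2,), DiscrepancySpec("fixed", alpha=1e-9))
        with pytest.raises(AcceptanceStallError) as exc:
            run_sld1(small_obs, build_system1(), SYS1_PRIOR, sched, 3, RandomSource(1),
                     stall_cap=25)
        assert isinstance(exc.value.partial, InferenceResult)
        assert exc.value.partial.populations == []


def _stub_eval(accept_prob):
    """Evaluator stub: accept with fixed probability from the proposal stream."""

    def fake(theta, obs, network, alpha, zero_floor, eps_k, B, N, rng_sim,
             backend, norm, max_events, early_reject):
        u = rng_sim.generator().random()
        return u < accept_prob, u, 1

    return fake


class TestCountSemantics:
    def test_geometric_mean_count(self, small_obs, monkeypatch):
        # with acceptance probability p per proposal, counts are geometric
        p = 0.25
        monkeypatch.setattr(samplers_mod, "_eval_sld1", _stub_eval(p))
        N = 500
        sched = ToleranceSchedule((0.5,), (1,))
        res = run_sld1(small_obs, build_system1(), SYS1_PRIOR, sched, N, RandomSource(21))
        mn = mean_count_number(res, 1)
        se = math.sqrt((1 - p) / p**2 / N)
        assert abs(mn - 1 / p) < 4 * se

    def test_counts_pair_arithmetic(self):
        assert mean_count_number(make_result([1, 3]), 1) == 2.0
        assert mean_count_number(make_result([1, 1, 1]), 1) == 1.0


class TestPriorRecoveryUnderAlwaysAccept:
    def test_iteration_one_population_matches_prior(self, small_obs, monkeypatch):
        # with acceptance forced, iteration 1 is exactly prior sampling
        monkeypatch.setattr(samplers_mod, "_eval_sld1", _stub_eval(1.1))
        N = 1000
        sched = ToleranceSchedule((0.5,), (1,))
        res = run_sld1(small_obs, build_system1(), SYS1_PRIOR, sched, N, RandomSource(31))
        thetas = res.population(1).thetas
        for j, upper in enumerate(SYS1_PRIOR.upper):
            p = stats.kstest(thetas[:, j] / upper, "uniform").pvalue
            assert p > 0.01


class TestSharedAcceptanceCore:
    def test_sld1_and_sld2_accept_identical_sets_for_same_scores(self, small_obs, monkeypatch):
        # identical per-proposal match scores injected into both drivers
        def shared(theta, obs, network, alpha, zero_floor, eps_k, B, N, rng_sim,
                   backend, norm, max_events, early_reject):
            score = float(np.sin(1e3 * theta.sum()) ** 2)  # deterministic in theta
            return score <= eps_k, score, 1

        monkeypatch.setattr(samplers_mod, "_eval_sld1", shared)
        monkeypatch.setattr(samplers_mod, "_eval_sld2", shared)
        sched = ToleranceSchedule((0.5, 0.4), (2, 2))
        a = run_sld1(small_obs, build_system1(), SYS1_PRIOR, sched, 10, RandomSource(8))
        b = run_sld2(small_obs, build_system1(), SYS1_PRIOR, sched, 10, RandomSource(8))
        for k in (1, 2):
            assert np.array_equal(a.population(k).thetas, b.population(k).thetas)
            assert np.array_equal(a.population(k).counts, b.population(k).counts)


class TestToleranceMonotonicity:
    def test_lower_tolerance_never_lowers_median_mn(self, small_obs, monkeypatch):
        # acceptance iff a deterministic theta score <= eps: tightening eps
        # can only raise the proposal count
        def scored(theta, obs, network, alpha, zero_floor, eps_k, B, N, rng_sim,
                   backend, norm, max_events, early_reject):
            score = float(theta[0] / 0.5)  # uniform(0,1) under the prior
            return score <= eps_k, score, 1

        monkeypatch.setattr(samplers_mod, "_eval_sld1", scored)
        medians = []
        for eps in (0.6, 0.3, 0.15):
            mns = []
            for seed in range(10):
                sched = ToleranceSchedule((eps,), (1,))
                res = run_sld1(small_obs, build_system1(), SYS1_PRIOR, sched, 20,
                               RandomSource(100 + seed))
                mns.append(mean_count_number(res, 1))
            medians.append(np.median(mns))
        assert medians[0] <= medians[1] <= medians[2]


class TestAveragedError:
    def test_truth_gives_zero(self):
        res = make_result([1, 1], thetas=np.tile(TRUE1, (2, 1)))
        assert averaged_error(res, 1, TRUE1) == 0.0
        assert averaged_error(res, 1, TRUE1, method="particle_mean") == 0.0

    def test_double_truth_gives_dimension(self):
        res = make_result([1], thetas=(2 * TRUE1)[None, :], weights=[1.0])
        assert averaged_error(res, 1, TRUE1) == pytest.approx(4.0)
        assert averaged_error(res, 1, TRUE1, method="particle_mean") == pytest.approx(4.0)

    def test_particle_mean_matches_brute_force(self, np_rng):
        thetas = np_rng.random((30, 4)) * 0.5 + 0.01
        res = make_result([1] * 30, thetas=thetas)
        expected = np.mean([
            sum(abs(thetas[i, j] - TRUE1[j]) / TRUE1[j] for j in range(4))
            for i in range(30)
        ])
        got = averaged_error(res, 1, TRUE1, method="particle_mean", weighted=False)
        assert got == pytest.approx(expected)

    def test_estimate_uses_weighted_mean(self, np_rng):
        thetas = np_rng.random((10, 4)) * 0.5 + 0.01
        w = np_rng.random(10)
        w /= w.sum()
        res = make_result([1] * 10, thetas=thetas, weights=w)
        est = w @ thetas
        expected = (np.abs(est - TRUE1) / TRUE1).sum()
        assert averaged_error(res, 1, TRUE1) == pytest.approx(expected)

    def test_zero_true_rate_rejected(self):
        res = make_result([1], thetas=TRUE1[None, :], weights=[1.0])
        with pytest.raises(ValueError):
            averaged_error(res, 1, np.array([0.1, 0.0, 0.5, 0.04]))


class TestPosteriorHistogram:
    def test_single_particle_single_bin(self):
        res = make_result([1], thetas=np.array([[0.3]]), weights=[1.0])
        res.config["prior_upper"] = [1.0]
        freq, edges = posterior_histogram(res, 1, 0, bins=10)
        assert freq.sum() == pytest.approx(1.0)
        assert (freq > 0).sum() == 1

    def test_uniform_weights_particles_at_bin_centers(self):
        centers = np.array([[0.125], [0.375], [0.625], [0.875]])
        res = make_result([1] * 4, thetas=centers)
        res.config["prior_upper"] = [1.0]
        freq, _ = posterior_histogram(res, 1, 0, bins=4)
        assert np.allclose(freq, 0.25)

    def test_mass_conservation(self, np_rng):
        thetas = np_rng.random((50, 2))
        w = np_rng.random(50)
        res = make_result([1] * 50, thetas=thetas, weights=w / w.sum())
        res.config["prior_upper"] = [1.0, 1.0]
        freq, _ = posterior_histogram(res, 1, 1, bins=7)
        assert freq.sum() == pytest.approx(1.0)


class TestToleranceSchedule:
    def test_increasing_epsilon_rejected(self):
        with pytest.raises(ValueError):
            ToleranceSchedule((0.05, 0.06), (10, 10))

    def test_scalar_B_broadcast(self):
        s = ToleranceSchedule((0.07, 0.06, 0.055), 10)
        assert s.B == (10, 10, 10)

    def test_rescaled_preserves_acceptance_region(self):
        s = ToleranceSchedule((0.07, 0.06), (10, 10))
        r = s.rescaled(20, 100)
        # N * epsilon is invariant
        assert np.allclose(np.array(r.epsilon) * 20, np.array(s.epsilon) * 100)

    def test_alpha_strategies_forwarded(self):
        s = ToleranceSchedule((0.2, 0.1), (5, 5), DiscrepancySpec("match_epsilon"))
        assert s.alpha_for(2) == 0.1


class TestResultIO:
    def test_save_writes_populations_and_diagnostics(self, small_obs, tmp_path):
        sched = always_accept_schedule(small_obs.n, 3)
        res = run_sld1(small_obs, build_system1(), SYS1_PRIOR, sched, 3, RandomSource(6))
        res.save(tmp_path)
        assert (tmp_path / "population_1.csv").exists()
        assert (tmp_path / "population_2.csv").exists()
        import json

        with open(tmp_path / "diagnostics.json") as fh:
            diag = json.load(fh)
        assert len(diag["iterations"]) == 2
        assert diag["iterations"][0]["mean_count"] == 1.0
        assert len(diag["iterations"][0]["sigma"]) == 4
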