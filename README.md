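# abcsld

Likelihood-free Bayesian inference of stochastic rate constants for
discrete-state chemical reaction networks, using **simulated likelihood
density** inside a sequential Monte Carlo ABC sampler.

## The problem

Gene-regulatory and biochemical networks with low molecular copy numbers
are continuous-time Markov jump processes: the chemical master equation
governs the copy-number state `X(t)`, reactions fire at mass-action
propensities with stochastic rate constants `c`, and the likelihood of a
sparse observed time series is intractable. `abcsld` is for modellers who
have a reaction-network structure, copy-number observations `X_1..X_n` on
a regular grid `t_l = l·Δt`, and uniform prior bounds on the rates, and
want posterior distributions over `c` without evaluating likelihoods.

## The method

The likelihood factorizes over one-step transitional densities
`f(t_l, X_l | t_{l−1}, X_{l−1}; θ)` of the Markov process. Each factor is
approximated by the *simulated likelihood density*: the fraction of `B_k`
exact stochastic-simulation (Gillespie) replicates, restarted from the
observed state `X_{l−1}`, that land within a relative discrepancy
tolerance `α` of `X_l` (per species: `|X_ls − Y_s| ≤ α·X_ls`). A particle
(parameter proposal) `θ*` is scored by the fitness error

    ε(θ*) = (1/N) Σ_{l=1..n} b_l(θ*) / B_k ,   b_l = # replicates failing at t_l

which lives on `[0, n/N]` for `N` particles, and is accepted when
`ε ≤ ε_k` for a decreasing tolerance schedule `ε_1..ε_K`. Populations of
`N` accepted particles are propagated by weighted resampling and Gaussian
perturbation `N(θ*, σ²_{k−1})`, with sequential importance weights
`w_i ∝ π(θ_i)/Σ_j w_j^{k−1} q(θ_i|θ_j)`.

Three drivers share this skeleton:

| driver | replicates | score |
|---|---|---|
| `run_sld1` | per-interval restarts from observed states | per-time-point failures |
| `run_sld2` | whole trajectories from `X_0` | per-time-point failures |
| `run_abc_smc` | whole trajectories from `X_0` | single trajectory distance, accept iff any replicate within `ε_k` |

Two benchmark systems are built in: a reversible **dimerization** model
(S1 → ∅, 2S1 ⇌ S2, S2 → S3; `X_0 = (10000, 0, 0)`) and a **prokaryotic
auto-regulatory gene network** (promoter binding by protein dimers,
transcription, translation, decay; 5 species, 8 reactions). The SSA engine
has a numba JIT fast path that is bit-identical to the pure-Python
reference under fixed seeds. See `docs/methods.md` for the full model
description and numerical choices.

## Worked example

Infer the four dimerization rate constants from one synthetic trajectory
observed at Δt = 3 over T = 30 (10 observation points):

```python
import numpy as np
from abcsld import (RandomSource, PriorSpec, ToleranceSchedule, DiscrepancySpec,
                    build_system1, generate_observations, run_sld1,
                    averaged_error, mean_count_number)
from abcsld.observations import rebin

net = build_system1()                    # true rates c = (0.1, 0.002, 0.5, 0.04)
obs = rebin(generate_observations(net, 30, 1, RandomSource(7001)), 3)

prior = PriorSpec(np.array([0.5, 0.005, 1.0, 0.1]))
schedule = ToleranceSchedule(
    (0.07, 0.06, 0.055, 0.05, 0.045),    # stated for N = 100 particles
    B=5, discrepancy=DiscrepancySpec("fixed", alpha=0.05),
).rescaled(N_run=20)                     # keep N*epsilon invariant at N = 20

result = run_sld1(obs, net, prior, schedule, N=20, rng=RandomSource(1),
                  max_events=10**7)
print("posterior mean:", np.round(result.posterior_mean(), 5))
print("MN per iteration:", [round(mean_count_number(result, k), 1) for k in range(1, 6)])
print("AE at iteration 5:", round(averaged_error(result, 5, net.rate_constants), 4))
```

Output (seed 1):

```
posterior mean: [0.11295 0.00296 0.70614 0.03763]
MN per iteration: [132.7, 13.6, 25.1, 17.7, 8.8]
AE at iteration 5: 1.0802
```

The posterior mean recovers the strongly identified decay (`c1 ≈ 0.113` vs
0.1) and conversion (`c4 ≈ 0.038` vs 0.04) rates; the dimerization pair
(`c2`, `c3`) is identified mainly through its ratio and sits high on that
ridge (`0.00296/0.706 ≈ 0.0042` vs the true `0.002/0.5 = 0.004`). The mean count number (proposals per accepted particle, the cost
diagnostic) is large in the selective first iteration and stabilizes
afterwards. The averaged error is the summed relative error of the
estimated rates, `Σ_j |ĉ_j − c_j|/c_j`.

A CLI wraps the same operations:

```bash
abcsld simulate --system system1 --T 30 --dt 3 --seed 1 --out obs.csv
abcsld infer --algorithm sld1 --system system1 --obs obs.csv \
             --config cfg.yaml --seed 1 --out results/
```

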