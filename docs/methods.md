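# Methods

`abcsld` infers stochastic rate constants of discrete-state mass-action
reaction networks from sparse copy-number time series, using likelihood-free
sequential Monte Carlo with an error model built on *simulated likelihood
density* — the empirical transitional density of repeated exact simulations.

## Model class

A network is a continuous-time Markov jump process on copy-number states
`X ∈ ℕ^S`, with reaction channels `j = 1..R` firing at mass-action
propensities

- zeroth order: `a_j = c_j`
- first order `A → …`: `a_j = c_j · #A`
- second order `A + B → …`: `a_j = c_j · #A · #B`
- homodimerization `2A → …`: `a_j = c_j · #A(#A−1)/2`

The homodimerization factor 1/2 is the classical unordered-pair convention;
`dimer_convention="full"` drops it for cross-checks against parameterizations
that fold it into `c_j`. Total reactant molecularity is capped at two.

Simulation is the exact direct method (Gillespie): two uniforms per event —
an exponential waiting time from the total propensity and a cumulative-sum
channel choice. Recording is càdlàg: the state reported at grid time `t_l`
is the state after the last event at time ≤ `t_l`. Simulation between grid
points restarts the waiting-time draw at each boundary; by memorylessness of
the exponential this is statistically exact and lets whole-trajectory
simulation and per-interval restarts share one kernel. A guard (default
10⁸ events per call; benchmark drivers use 10⁷) aborts runaway simulations
caused by extreme prior draws; the drivers score such a replicate as a total
mismatch instead of failing the run.

Two backends implement the same event loop: a numba-JIT fast path and a
plain-Python reference. numba's in-JIT Mersenne-Twister stream is
bit-identical to `numpy.random.RandomState` under equal seeds, and both
paths perform floating-point operations in the same order, so they produce
bit-identical trajectories (tested). Randomness is organised as a tree of
`SeedSequence`-keyed substreams, one per (iteration, particle, proposal,
replicate, interval), so results are reproducible end to end and invariant
to evaluation order.

## Error model

Two tolerances steer acceptance:

- **Discrepancy tolerance α** (relative, per time point): simulated state
  `Y` matches observation `X_l` when `|X_ls − Y_s| ≤ α·X_ls` for *every*
  species `s`. The scalar-looking test is applied per species because the
  observations are vectors; all species must pass. A species observed at 0
  must be simulated within an absolute `zero_floor` (default 0, i.e.
  exactly 0). The comparison is `≤` throughout. Note that for species with
  few copies (e.g. 10 promoter copies at α = 0.05) this demands an exact
  integer match — the test is intentionally strict at low copy number,
  which is where the discrete stochastic description carries the most
  information.
- **Fitness tolerance ε_k** (per iteration): with `b_l` the number of the
  `B_k` replicates failing the point test at time `l`, the fitness error is
  `ε = (1/N)·Σ_l b_l/B_k ∈ [0, n/N]`, small-is-good, zero iff every
  replicate matches everywhere. A proposal is accepted iff `ε ≤ ε_k`, so a
  threshold at the supremum `n/N` accepts everything: with 100 particles
  and n = 10 observation points the critical tolerance is exactly 0.1, and
  0.06 for n = 6. The normalization by the particle count `N` is what
  places published tolerance schedules (stated for `N = 100`) on this
  scale; `ToleranceSchedule.rescaled` converts a schedule to another
  population size by keeping `N·ε_k` invariant. The alternative
  `mean_failure_fraction` normalization (divide by `n` instead of `N`,
  range [0, 1]) is equivalent after rescaling thresholds and is exposed via
  `error_norm`.

The per-time-point match fraction `(1/B_k)·Σ_m [Y_ml matches X_l]` is the
simulated-likelihood (frequency-distribution) estimate of the one-step
transitional density; the fitness error is, up to normalization, the
aggregated complement of this estimate over the observation grid.

## Samplers

All three drivers share the SMC skeleton: at iteration 1 proposals are
drawn from the componentwise uniform prior `U(0, A_j)`; at iteration k > 1
a particle is resampled from the previous population by weight, perturbed
by a Gaussian kernel `N(θ*, σ²_{k−1})` (or uniform `θ* ± σ_{k−1}`) with
`σ_{k−1}` the componentwise unweighted sample standard deviation of the
previous population, and re-evaluated. Perturbations leaving the prior
support are discarded and redrawn. Weights are uniform at iteration 1 and
follow the sequential importance form
`w_i ∝ π(θ_i) / Σ_j w_j^{k−1} q(θ_i | θ_j, σ_{k−1})` afterwards. With hard
acceptance the survivorship factor of the generic population sampler is
already enforced by the accept/reject step, so it is dropped from the SLD
weights by default (`weight_bk="match_count"` restores a match-count
factor). The generic baseline (`smc`) scores a proposal by a
whole-trajectory distance (default: RMS of per-cell differences relative to
`max(X_ls, 1)`), accepts when at least one of `B_k` replicates lands within
`ε_k`, and weights by the replicate match count.

The two SLD drivers differ only in where replicates start: `sld1` restarts
each observation interval from the *observed* previous state (the Markov
transitional-density factorization), `sld2` simulates whole trajectories
from `X_0` but still scores each time point. Both share acceptance,
weighting and bookkeeping code, and reject a proposal early once its
accumulated failure count exceeds the iteration budget `N·B_k·ε_k` (the
error is non-decreasing in further failures, so early rejection changes no
acceptance decision).

## Diagnostics

- **Mean count number (MN)**: average proposals consumed per accepted
  particle — the inverse acceptance rate and the main cost diagnostic. A
  proposal counts when it is evaluated against data; perturbations rejected
  for prior support are redrawn without incrementing the count (with a
  Gaussian kernel some proposals always leave the box, and the identity
  "MN = 1 when ε_k is at the supremum" can only hold under this
  convention; `count_support_rejections=True` restores the stricter
  bookkeeping).
- **Averaged error (AE)**: summed relative error of the estimated rate
  constants, `Σ_j |ĉ_j − c_j|/c_j`. Default (`method="estimate"`): `ĉ` is
  the weighted population mean, so sampling spread cancels and AE tracks
  the quality of the reported estimate; this is the reading whose
  magnitudes match published benchmark tables (≈0.4–0.9 for the 4-parameter
  system). `method="particle_mean"` instead averages per-particle summed
  relative errors, additionally charging the population spread (≈1.2–1.8
  for the same runs); it is the better-behaved measure of population
  contraction across iterations.
- **Posterior histograms**: weight-weighted marginals over the prior
  support, frequencies summing to one.
- Acceptance stalls (a particle exhausting its proposal budget, default
  10⁶) raise an error carrying the completed populations.

## Benchmark systems and synthetic data

- **System 1 — reversible dimerization with decay** (3 species, 4
  reactions): S1 → ∅, 2 S1 → S2, S2 → 2 S1, S2 → S3; `X_0 = (10000, 0, 0)`,
  true rates `c = (0.1, 0.002, 0.5, 0.04)`, priors `U(0, (0.5, 0.005, 1,
  0.1))`, horizon T = 30. The quantity S1 + 2·S2 + 2·S3 is non-increasing
  (only the decay destroys S1 mass) — used as a trajectory-level invariant.
- **System 2 — prokaryotic auto-regulatory gene network** (5 species, 8
  reactions): promoter binding/unbinding by the protein dimer,
  transcription, mRNA decay, protein/dimer interchange, translation,
  protein decay; `X_0 = (DNA, mRNA, P, P2, DNA·P2) = (10, 100, 100, 800,
  100)`, true rates `(0.1, 0.7, 0.35, 0.01, 0.1, 0.9, 0.2, 0.01)`, priors
  `U(0, (0.5, 2, 1, 0.1, 0.5, 5, 1, 0.1))`, horizon T = 50. DNA + DNA·P2
  is conserved (= 110 for this initial condition) — asserted on every
  trajectory. The source reaction list for this model prints the
  translation product as the dimer (`mRNA → mRNA + P2`) while its narrative
  (and the standard form of this model) makes translation produce the
  protein; both are implemented (`r7_product="P2"` matches the printed
  list and is the default; `"P"` is the narrative/standard reading used by
  the system-2 benchmark runs, where it reproduces the published error
  magnitudes far better).

Synthetic "experimental" data are one exact trajectory at the true rates
recorded every Δt — noise-free by design (no measurement-error model). The
benchmark datasets are generated at Δt = 1 and *rebinned* (subsampled
without interpolation) to the inference step size, so all step sizes
analyse the same underlying realization. What passing benchmarks show is
therefore recovery under the model's own idealized conditions: correct
model structure, known initial state, no observation noise. They do not
exercise model misspecification or noisy measurements.

## Problem sizes

Published benchmark tables use N = 100 particles and B_k = 10 replicates.
The package's standard verification runs are scaled down to N = 20,
B_k = 5 for system 1 (tolerance schedules rescaled by `N·ε` invariance;
median over 5 seeds) and N = 10, B_k = 5 for the system-2 spot check —
sizes chosen so a full verification pass completes on a single CPU core in
tens of minutes. At this scale the point-estimate AE carries a noise floor
of roughly 0.2–0.3 for system 1 (spread/√N summed over 4 parameters), and
per-iteration diagnostics are noticeably noisier than at full scale;
iteration-over-iteration AE trends in particular are only reliable in the
population-contraction (`particle_mean`) reading.

## Numerical choices

- Acceptance uses `ε ≤ ε_k` (not strict `<`), with a 10⁻¹² relative slack
  in floating comparisons, so a schedule at the supremum accepts everything.
- Tolerance schedules must be positive and non-increasing; `B_k` may vary
  by iteration (benchmarks keep it constant).
- `σ_k = 0` components (collapsed populations) perturb to the same value
  and use a point-mass kernel-density convention (1 if equal, else 0).
- The waiting-time uniform is floored at 10⁻³⁰⁰ to avoid `log(0)`.
- Weight underflow to an all-zero population raises a diagnostic error
  rather than renormalizing silently.
- `U(0, A)` prior draws exclude the boundary exactly (redraw on a 0 draw).

## Known limitations

- No τ-leaping, hybrid, or parallel simulation: runtime scales with event
  counts, and systems with ~10⁵ events per trajectory bound the practical
  population sizes on one core.
- No measurement-noise model on observations; `zero_floor` is the only
  slack for observed zeros.
- No adaptive tolerance selection; schedules are user-supplied.
- The generic-baseline trajectory distance is a package choice
  (`rms_relative` by default) — published descriptions of such baselines
  leave the distance unspecified.
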