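"""Low-level stochastic simulation kernels.

Two implementations of the same direct-method event loop:

* :func:`ssa_interval_numba` — JIT-compiled fast path.  Uses numba's
  in-jit Mersenne-Twister stream, which is bit-identical to
  ``numpy.random.RandomState`` for the same integer seed.
* :func:`ssa_interval_python` — plain-Python reference path driven by a
  ``RandomState``.

Both consume exactly two uniforms per reaction event (waiting time, channel
choice) in the same order and perform floating-point operations in the same
order, so a fixed seed produces bit-identical states from either path.

Propensities use compact per-reaction reactant lists ``(species index,
order)`` rather than scanning the full stoichiometry matrix; with total
molecularity capped at two, a reaction has at most two reactant slots and
a second distinct reactant always has order one.

Status codes: 0 = reached the end time, 1 = system froze (zero total
propensity), 2 = event guard exceeded.
"""

from __future__ import annotations

import math

import numba
import numpy as np

STATUS_OK = 0
STATUS_FROZEN = 1
STATUS_EVENT_GUARD = 2

_TINY = 1e-300  # floor for the waiting-time uniform; random() can return 0.0


@numba.njit(cache=False)
def ssa_interval_numba(state, t_from, t_to, reactant_idx, reactant_ord,
                       change_mat, rates, dimer_factor, max_events,
                       seed):  # pragma: no cover - exercised via gillespie
    np.random.seed(seed)
    n_reactions, n_species = change_mat.shape
    props = np.empty(n_reactions)
    t = t_from
    events = 0
    while True:
        a0 = 0.0
        for j in range(n_reactions):
            a = rates[j]
            s0 = reactant_idx[j, 0]
            if s0 >= 0:
                if reactant_ord[j, 0] == 1:
                    a *= state[s0]
                else:
                    a *= state[s0] * (state[s0] - 1) * dimer_factor
                s1 = reactant_idx[j, 1]
                if s1 >= 0:
                    a *= state[s1]
            props[j] = a
            a0 += a
        if a0 <= 0.0:
            return STATUS_FROZEN
        u1 = np.random.random()
        if u1 <= 0.0:
            u1 = _TINY
        t += -math.log(u1) / a0
        if t > t_to:
            return STATUS_OK
        threshold = np.random.random() * a0
        acc = 0.0
        fired = n_reactions - 1
        for j in range(n_reactions):
            acc += props[j]
            if acc > threshold:
                fired = j
                break
        for s in range(n_species):
            state[s] += change_mat[fired, s]
        events += 1
        if events >= max_events:
            return STATUS_EVENT_GUARD


def ssa_interval_python(state, t_from, t_to, reactant_idx, reactant_ord,
                        change_mat, rates, dimer_factor, max_events, seed):
    """Reference implementation; mirrors the JIT path line for line."""
    rng = np.random.RandomState(seed)
    n_reactions, n_species = change_mat.shape
    props = np.empty(n_reactions)
    t = t_from
    events = 0
    while True:
        a0 = 0.0
        for j in range(n_reactions):
            a = rates[j]
            s0 = reactant_idx[j, 0]
            if s0 >= 0:
                if reactant_ord[j, 0] == 1:
                    a *= state[s0]
                else:
                    a *= state[s0] * (state[s0] - 1) * dimer_factor
                s1 = reactant_idx[j, 1]
                if s1 >= 0:
                    a *= state[s1]
            props[j] = a
            a0 += a
        if a0 <= 0.0:
            return STATUS_FROZEN
        u1 = rng.random_sample()
        if u1 <= 0.0:
            u1 = _TINY
        t += -math.log(u1) / a0
        if t > t_to:
            return STATUS_OK
        threshold = rng.random_sample() * a0
        acc = 0.0
        fired = n_reactions - 1
        for j in range(n_reactions):
            acc += props[j]
            if acc > threshold:
                fired = j
                break
        for s in range(n_species):
            state[s] += change_mat[fired, s]
        events += 1
        if events >= max_events:
            return STATUS_EVENT_GUARD
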