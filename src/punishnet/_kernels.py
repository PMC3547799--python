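"""JIT-compiled simulation core.

A single fixation run executes up to millions of elementary imitation steps,
so the inner loop is compiled with numba. Payoffs are *accumulated* over all
neighbors (never degree-normalized) and cached incrementally: a node's cached
payoff changes only when its own strategy or a neighbor's strategy changes,
which the flip update below maintains exactly.

RNG contract: one numpy legacy stream per run, seeded once. Draw order:
first (batch entry point only) the Fisher–Yates shuffle of the initial
label template, then per elementary step
  1. focal node x: one uniform integer in [0, n)
  2. model y: one uniform integer over x's neighborhood
  3. only if strategy[x] != strategy[y]: one uniform float for the
     imitation decision.
Two parameterizations with identical effective payoff matrices therefore
produce bit-identical trajectories under the same seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# exponent clip: exp(±700) is finite in float64; the clip is unobservable at
# the payoff/beta scales of interest (|beta * dP| < ~100)
_CLIP = 700.0


@njit(cache=True)
def fermi(payoff_x: float, payoff_y: float, beta: float) -> float:
    """Pairwise-comparison probability that x adopts y's strategy."""
    z = beta * (payoff_x - payoff_y)
    if z > _CLIP:
        z = _CLIP
    elif z < -_CLIP:
        z = -_CLIP
    return 1.0 / (1.0 + np.exp(z))


@njit(cache=True)
def _run_steps(indptr, indices, strategy, payoff_matrix, beta, max_steps):
    """Advance the already-seeded stream until monomorphic or the step cap."""
    n = strategy.size
    n_labels = payoff_matrix.shape[0]

    counts = np.zeros(n_labels, dtype=np.int64)
    for i in range(n):
        counts[strategy[i]] += 1
    for lab in range(n_labels):
        if counts[lab] == n:
            return lab, 0, 1

    payoff = np.zeros(n, dtype=np.float64)
    for x in range(n):
        s = 0.0
        sx = strategy[x]
        for k in range(indptr[x], indptr[x + 1]):
            s += payoff_matrix[sx, strategy[indices[k]]]
        payoff[x] = s

    steps = 0
    while steps < max_steps:
        steps += 1
        x = np.random.randint(0, n)
        kx = indptr[x + 1] - indptr[x]
        y = indices[indptr[x] + np.random.randint(0, kx)]
        sx = strategy[x]
        sy = strategy[y]
        if sx == sy:
            continue
        if np.random.random() < fermi(payoff[x], payoff[y], beta):
            counts[sx] -= 1
            counts[sy] += 1
            newp = 0.0
            for k in range(indptr[x], indptr[x + 1]):
                nb = indices[k]
                snb = strategy[nb]
                payoff[nb] += payoff_matrix[snb, sy] - payoff_matrix[snb, sx]
                newp += payoff_matrix[sy, snb]
            strategy[x] = sy
            payoff[x] = newp
            if counts[sy] == n:
                return sy, steps, 1

    best = 0
    for lab in range(1, n_labels):
        if counts[lab] > counts[best]:
            best = lab
    return best, steps, 0


@njit(cache=True)
def run_fixation(indptr, indices, strategy, payoff_matrix, beta, max_steps, seed):
    """One fixation run from a prepared initial strategy array (mutated in place).

    Returns ``(winner, n_steps, absorbed)``; when the step cap is hit,
    ``winner`` is the current majority label and ``absorbed`` is 0.
    """
    np.random.seed(seed)
    return _run_steps(indptr, indices, strategy, payoff_matrix, beta, max_steps)


@njit(cache=True)
def batch_fixation(indptr, indices, template, payoff_matrix, beta, max_steps, seeds):
    """Many runs on one network, each from a fresh shuffle of ``template``.

    ``template`` is the balanced initial label vector; each run seeds its own
    stream, Fisher–Yates-shuffles a copy (a uniform random placement of the
    initial strategies) and runs to fixation.

    Returns ``(winners, absorbed)`` int64 arrays.
    """
    n = template.size
    n_runs = seeds.size
    winners = np.empty(n_runs, dtype=np.int64)
    absorbed = np.empty(n_runs, dtype=np.int64)
    for r in range(n_runs):
        np.random.seed(seeds[r])
        strat = template.copy()
        for i in range(n - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = strat[i]
            strat[i] = strat[j]
            strat[j] = tmp
        w, _, a = _run_steps(indptr, indices, strat, payoff_matrix, beta, max_steps)
        winners[r] = w
        absorbed[r] = a
    return winners, absorbed
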