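"""Independent analytic and brute-force references for the simulation engine.

Three layers of cross-validation, none of which shares code with the
Monte-Carlo engine:

1. the replicator-dynamics outcome in an infinite well-mixed population
   (closed form; gives the classical Ω = 0.25 benchmark for the studied
   T–S rectangle);
2. the exact fixation probability of the pairwise-comparison process on a
   complete graph, where the cooperator count is a birth–death chain with a
   product-form absorption probability;
3. exhaustive enumeration of the full 2^n-state Markov chain on arbitrary
   tiny graphs, solved as a linear system.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.special import logsumexp

from .engine import GameParams, imitation_probability
from .networks import Network
from .sweep import PhaseGrid

__all__ = [
    "WellMixedOutcome", "wellmixed_winner", "wellmixed_grid",
    "complete_graph_fixation", "enumerate_tiny_graph",
]


@dataclass(frozen=True)
class WellMixedOutcome:
    """Replicator outcome from a 50/50 start in a well-mixed population."""

    winner: str
    interior_equilibrium: float | None


def wellmixed_winner(T: float, S: float) -> WellMixedOutcome:
    """Deterministic replicator-dynamics winner from cooperator fraction 1/2.

    With R = 1, P = 0 and S < 0: for T > 1 (Prisoner's Dilemma) defection
    dominates.  For T < 1 (Stag Hunt) the dynamics is bistable with the
    unstable interior equilibrium x* = −S / (−S + 1 − T); cooperators take
    over from one half iff x* < 1/2, i.e. iff S > T − 1.  The boundary
    S = T − 1 (x* exactly 1/2) is assigned to D, matching the strict
    inequality used in the cooperation index.
    """
    if T >= 1.0:
        return WellMixedOutcome("D", None)
    if S >= 0:
        return WellMixedOutcome("C", None)
    xstar = -S / (-S + 1.0 - T)
    winner = "C" if S > T - 1.0 else "D"
    return WellMixedOutcome(winner, xstar)


def wellmixed_grid(t_values, s_values) -> PhaseGrid:
    """PhaseGrid filled by the analytic classifier (x_ffc 1 where C wins).

    Evaluating at cell centers of the open rectangle 0 < T < 2, −1 < S < 0
    makes the classical cooperation index exactly 1/4: C wins on the
    triangle {T < 1, S > T − 1}, half of the Stag-Hunt quadrant.
    """
    t_values = np.asarray(t_values, dtype=float)
    s_values = np.asarray(s_values, dtype=float)
    x = np.empty((len(t_values), len(s_values)))
    for i, T in enumerate(t_values):
        for j, S in enumerate(s_values):
            x[i, j] = 1.0 if wellmixed_winner(float(T), float(S)).winner == "C" else 0.0
    shape = x.shape
    return PhaseGrid(t_values, s_values, x, np.ones(shape, dtype=np.int64),
                     np.zeros(shape, dtype=np.int64))


def _payoffs_on_complete_graph(n: int, k: int, params: GameParams) -> tuple[float, float]:
    """Accumulated payoffs of one C and one D when k of n players cooperate."""
    a = params.S - params.q  # C against D
    b = params.T - params.p  # D against C
    pi_c = (k - 1) * 1.0 + (n - k) * a
    pi_d = k * b
    return pi_c, pi_d


def complete_graph_fixation(n: int, k_initial: int, params: GameParams) -> float:
    """Exact cooperator fixation probability on the complete graph K_n.

    On K_n the two-strategy imitation process is a birth–death chain over
    the cooperator count k.  A step increases k when a defector imitates a
    cooperator and decreases it in the opposite case; both require picking
    a discordant (focal, model) pair, so the backward/forward transition
    ratio reduces to γ_k = W(C adopts D) / W(D adopts C) = exp(β(π_D − π_C))
    with the accumulated payoffs π_C(k) = (k−1)·R + (n−k)(S−q),
    π_D(k) = k(T−p).  The absorption probability from k is the standard
    product formula φ_k = (1 + Σ_{j<k} Π_{m≤j} γ_m) / (1 + Σ_{j<n} Π γ_m),
    evaluated in log space for numerical stability.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0 <= k_initial <= n:
        raise ValueError("k_initial must be in [0, n]")
    if k_initial == 0:
        return 0.0
    if k_initial == n:
        return 1.0
    log_gamma = np.empty(n - 1)
    for k in range(1, n):
        pi_c, pi_d = _payoffs_on_complete_graph(n, k, params)
        log_gamma[k - 1] = params.beta * (pi_d - pi_c)
    cum = np.concatenate([[0.0], np.cumsum(log_gamma)])  # cum[j] = log prod_{m<=j} gamma_m
    denom = logsumexp(cum)
    numer = logsumexp(cum[:k_initial])
    return float(np.exp(numer - denom))


def enumerate_tiny_graph(network: Network, params: GameParams) -> np.ndarray:
    """Exact cooperator-absorption probability for every initial state.

    Builds the full 2^n-state transition matrix of the elementary-step chain
    (focal node uniform, model uniform in its neighborhood, Fermi adoption)
    and solves the absorbing-chain linear system.  Returns an array indexed
    by the bitmask of defectors (bit i set ⇔ node i plays D); entry =
    probability of absorbing in the all-C state.
    """
    n = network.n_nodes
    if n > 10:
        raise ValueError("state space 2^n too large; need n <= 10")
    m = np.array([[1.0, params.S - params.q], [params.T - params.p, 0.0]])
    n_states = 1 << n
    all_c = 0
    all_d = n_states - 1

    def strat(state: int, node: int) -> int:
        return (state >> node) & 1

    def payoff(state: int, node: int) -> float:
        return sum(m[strat(state, node), strat(state, nb)] for nb in network.neighbors(node))

    # h[s] = P(absorb all-C | s); h[all_c] = 1, h[all_d] = 0
    A = np.zeros((n_states, n_states))
    b = np.zeros(n_states)
    for s in range(n_states):
        if s in (all_c, all_d):
            A[s, s] = 1.0
            b[s] = 1.0 if s == all_c else 0.0
            continue
        A[s, s] = 1.0
        for x in range(n):
            nbrs = network.neighbors(x)
            for y in nbrs:
                pr_pair = (1.0 / n) * (1.0 / nbrs.size)
                sx, sy = strat(s, x), strat(s, int(y))
                if sx == sy:
                    A[s, s] -= pr_pair  # no state change
                    continue
                w = imitation_probability(payoff(s, x), payoff(s, int(y)), params.beta)
                target = s ^ (1 << x)  # x flips to y's strategy
                A[s, target] -= pr_pair * w
                A[s, s] -= pr_pair * (1.0 - w)
    return np.linalg.solve(A, b)


def enumerate_fixation_by_count(network: Network, params: GameParams) -> dict[int, float]:
    """Mean all-C absorption probability grouped by initial cooperator count.

    Averages :func:`enumerate_tiny_graph` uniformly over the placements of
    each cooperator count — the quantity a balanced random initial condition
    samples.
    """
    h = enumerate_tiny_graph(network, params)
    n = network.n_nodes
    sums: dict[int, list[float]] = {k: [] for k in range(n + 1)}
    for s in range(1 << n):
        k = n - bin(s).count("1")
        sums[k].append(h[s])
    return {k: float(np.mean(v)) for k, v in sums.items()}


def complete_graph(n: int) -> Network:
    """K_n, the fully connected population (well-mixed finite analogue)."""
    edges = np.array([(i, j) for i in range(n) for j in range(i + 1, n)], dtype=np.int64)
    return Network(n_nodes=n, edges=edges)
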