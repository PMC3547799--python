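"""Stochastic imitation dynamics with altruistic peer punishment.

The population plays one-shot two-player games along the links of a network.
With reward R = 1 and mutual-defection payoff P = 0 fixed, the game is
parameterized by the temptation T and the sucker's payoff S: T > 1 with
S < 0 is a Prisoner's Dilemma, T < 1 with S < 0 a Stag Hunt.  Punishing
cooperators pay a cost q per defecting partner to inflict a fine p on that
partner, which turns the off-diagonal payoffs into S - q and T - p — i.e.
punishment is exactly a translation of (T, S) by the vector (p, q).

Strategy labels: 0 = C (cooperator), 1 = D (defector), and in the
three-strategy variant 2 = PC (punishing cooperator).  In the two-strategy
mode every cooperator punishes, so "C" there already carries the fine/cost.

Evolution is asynchronous imitation: an elementary step picks a random
player x and a random neighbor y, and x adopts y's strategy with the
pairwise-comparison (Fermi) probability
``W = 1 / (1 + exp(beta * (P_x - P_y)))`` computed from payoffs accumulated
over all interactions.  There is no mutation, so monomorphic states absorb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .networks import Network

__all__ = [
    "C", "D", "PC", "LABELS",
    "GameParams", "PopulationState", "FixationResult",
    "payoff_entry", "payoff_matrix", "accumulated_payoff",
    "imitation_probability", "elementary_step", "initial_state",
    "run_to_fixation", "default_max_steps",
]

C, D, PC = 0, 1, 2
LABELS = {"C": C, "D": D, "PC": PC}
LABEL_NAMES = {C: "C", D: "D", PC: "PC"}


@dataclass(frozen=True)
class GameParams:
    """Game and update-rule parameters (R = 1 and P = 0 are fixed).

    Attributes
    ----------
    T : temptation payoff (defector against cooperator, before the fine).
    S : sucker's payoff (cooperator against defector, before the cost).
    p : fine inflicted on a defecting partner by a punisher (>= 0).
    q : cost the punisher pays per punished partner (>= 0).
    beta : intensity of selection of the pairwise-comparison rule (>= 0).
    """

    T: float
    S: float
    p: float = 0.0
    q: float = 0.0
    beta: float = 0.25
    R: float = field(default=1.0, init=False)
    P: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if self.p < 0 or self.q < 0:
            raise ValueError("punishment fine p and cost q must be nonnegative")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")

    @property
    def is_altruistic(self) -> bool:
        """True in the altruistic-punishment regime p > q."""
        return self.p > self.q

    def translated(self) -> "GameParams":
        """The punishment-free parameter point with the same effective game."""
        return GameParams(T=self.T - self.p, S=self.S - self.q, p=0.0, q=0.0, beta=self.beta)


def payoff_matrix(params: GameParams, n_strategies: int = 2) -> np.ndarray:
    """Effective payoff matrix, entry [a, b] = payoff of label a against label b.

    Two-strategy mode (every cooperator punishes)::

            C        D
        C   1        S - q
        D   T - p    0

    Three-strategy mode adds the non-punishing cooperator: C and PC are
    neutral towards each other (both earn R = 1), a plain C neither pays q
    nor fines a defector, while PC plays S - q / T - p against D.
    """
    T, S, p, q = params.T, params.S, params.p, params.q
    if n_strategies == 2:
        return np.array([[1.0, S - q], [T - p, 0.0]])
    if n_strategies == 3:
        return np.array(
            [
                [1.0, S, 1.0],
                [T, 0.0, T - p],
                [1.0, S - q, 1.0],
            ]
        )
    raise ValueError("n_strategies must be 2 or 3")


def payoff_entry(strategy_a, strategy_b, params: GameParams, n_strategies: int = 2) -> float:
    """Payoff of ``strategy_a`` against ``strategy_b`` (labels or names)."""
    a = LABELS.get(strategy_a, strategy_a)
    b = LABELS.get(strategy_b, strategy_b)
    m = payoff_matrix(params, n_strategies)
    if not (0 <= a < n_strategies and 0 <= b < n_strategies):
        raise ValueError(f"unknown strategy label for {n_strategies}-strategy mode")
    return float(m[a, b])


@dataclass
class PopulationState:
    """Per-node strategy labels plus consistent per-label counts."""

    strategy: np.ndarray
    n_strategies: int = 2

    def __post_init__(self) -> None:
        self.strategy = np.asarray(self.strategy, dtype=np.int8)
        if self.strategy.ndim != 1 or self.strategy.size == 0:
            raise ValueError("strategy must be a nonempty 1-d array")
        if self.strategy.min() < 0 or self.strategy.max() >= self.n_strategies:
            raise ValueError("strategy labels out of range")

    @property
    def n_nodes(self) -> int:
        return self.strategy.size

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.strategy, minlength=self.n_strategies)

    @property
    def absorbed(self) -> bool:
        """True iff the population is monomorphic."""
        return bool(np.max(self.counts) == self.n_nodes)

    def copy(self) -> "PopulationState":
        return PopulationState(self.strategy.copy(), self.n_strategies)


def initial_state(network: Network, mode: int = 2, rng=None) -> PopulationState:
    """Balanced random initial condition.

    Two-strategy mode: exactly ``n // 2`` cooperators (any remainder goes to
    D); three-strategy mode: thirds, with remainders assigned one-per-label
    in the order C, D, PC. Node placement is a uniform random permutation.
    """
    rng = np.random.default_rng(rng)
    n = network.n_nodes
    if mode == 2:
        counts = [n // 2, n - n // 2]
    elif mode == 3:
        base, rem = divmod(n, 3)
        counts = [base + (1 if lab < rem else 0) for lab in range(3)]
    else:
        raise ValueError("mode must be 2 or 3")
    template = np.repeat(np.arange(len(counts), dtype=np.int8), counts)
    return PopulationState(rng.permutation(template), n_strategies=mode)


def accumulated_payoff(network: Network, state: PopulationState, node: int,
                       params: GameParams) -> float:
    """Payoff of ``node`` summed over all its interactions (not normalized)."""
    nbrs = network.neighbors(node)
    if nbrs.size == 0:
        raise ValueError(f"node {node} has no neighbors")
    m = payoff_matrix(params, state.n_strategies)
    return float(m[state.strategy[node], state.strategy[nbrs]].sum())


def imitation_probability(payoff_x: float, payoff_y: float, beta: float) -> float:
    """Fermi pairwise-comparison probability that x adopts y's strategy."""
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    return float(_kernels.fermi(payoff_x, payoff_y, beta))


def elementary_step(network: Network, state: PopulationState, params: GameParams,
                    rng) -> bool:
    """One asynchronous imitation attempt; returns True if a node flipped.

    Pure-Python reference path (the production loop lives in the compiled
    kernel): draws x uniformly, y uniformly among x's neighbors, and lets x
    adopt y's strategy with the Fermi probability of their accumulated
    payoffs.  At most one node changes per step.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = int(rng.integers(network.n_nodes))
    nbrs = network.neighbors(x)
    y = int(nbrs[rng.integers(nbrs.size)])
    if state.strategy[x] == state.strategy[y]:
        return False
    w = imitation_probability(
        accumulated_payoff(network, state, x, params),
        accumulated_payoff(network, state, y, params),
        params.beta,
    )
    if rng.random() < w:
        state.strategy[x] = state.strategy[y]
        return True
    return False


@dataclass(frozen=True)
class FixationResult:
    """Outcome of one run: surviving label, step count, absorption flag."""

    absorbed_label: str
    n_steps: int
    absorbed: bool

    @property
    def cooperative(self) -> bool:
        """True if a cooperative strategy (C or PC) took over."""
        return self.absorbed_label in ("C", "PC")


def default_max_steps(n_nodes: int) -> int:
    """Absorption safeguard: 5000 elementary steps per node."""
    return 5000 * n_nodes


def run_to_fixation(network: Network, initial: PopulationState, params: GameParams,
                    seed: int, max_steps: int | None = None) -> FixationResult:
    """Run elementary steps until the state is monomorphic or the cap is hit.

    The initial state is not mutated.  Runs that hit ``max_steps`` are
    reported with ``absorbed=False`` (the label is then the current
    majority), never silently truncated to an absorbing outcome.
    """
    if max_steps is None:
        max_steps = default_max_steps(network.n_nodes)
    if max_steps <= 0:
        raise ValueError("max_steps must be positive")
    strat = initial.strategy.copy()
    m = payoff_matrix(params, initial.n_strategies)
    winner, steps, absorbed = _kernels.run_fixation(
        network.indptr, network.indices, strat, m, params.beta,
        max_steps, np.uint32(seed & 0x7FFFFFFF),
    )
    return FixationResult(LABEL_NAMES[int(winner)], int(steps), bool(absorbed))
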