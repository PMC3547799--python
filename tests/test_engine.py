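"""Payoffs, the Fermi rule, elementary steps, and fixation runs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from punishnet.engine import (
    GameParams,
    PopulationState,
    accumulated_payoff,
    elementary_step,
    imitation_probability,
    initial_state,
    payoff_entry,
    payoff_matrix,
    run_to_fixation,
)
from punishnet.networks import Network, generate_ba_network
from punishnet.sweep import mix_seed


class TestPayoffs:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("C", "C", 1.0),
            ("C", "D", -0.5 - 0.04),   # sucker's payoff minus the punishing cost
            ("D", "C", 1.5 - 0.1),     # temptation minus the fine
            ("D", "D", 0.0),
        ],
    )
    def test_two_strategy_effective_matrix(self, a, b, expected):
        params = GameParams(T=1.5, S=-0.5, p=0.1, q=0.04)
        assert payoff_entry(a, b, params) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("C", "C", 1.0),
            ("C", "PC", 1.0),   # cooperators and punishers are mutually neutral
            ("PC", "C", 1.0),
            ("PC", "PC", 1.0),
            ("C", "D", -0.5),   # a plain cooperator pays no punishing cost
            ("D", "C", 1.5),    # and inflicts no fine
            ("PC", "D", -0.54),
            ("D", "PC", 1.4),
            ("D", "D", 0.0),
        ],
    )
    def test_three_strategy_matrix(self, a, b, expected):
        params = GameParams(T=1.5, S=-0.5, p=0.1, q=0.04)
        assert payoff_entry(a, b, params, n_strategies=3) == pytest.approx(expected)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            payoff_entry("PC", "C", GameParams(1.5, -0.5), n_strategies=2)

    def test_altruistic_flag(self):
        assert GameParams(1.0, -0.5, p=0.1, q=0.04).is_altruistic
        assert not GameParams(1.0, -0.5, p=0.1, q=0.1).is_altruistic

    def test_accumulated_payoff_star(self):
        """C at the center of a 4-leaf defector star: 4 * (S - q)."""
        star = Network(n_nodes=5, edges=np.array([[0, i] for i in range(1, 5)]))
        state = PopulationState(np.array([0, 1, 1, 1, 1], dtype=np.int8))
        params = GameParams(T=1.5, S=-0.5, p=0.1, q=0.04)
        assert accumulated_payoff(star, state, 0, params) == pytest.approx(-2.16)

    def test_accumulated_payoff_homogeneous(self, ba_small):
        all_c = PopulationState(np.zeros(100, dtype=np.int8))
        all_d = PopulationState(np.ones(100, dtype=np.int8))
        params = GameParams(T=1.5, S=-0.5)
        for node in (0, 17, 99):
            k = ba_small.degree[node]
            assert accumulated_payoff(ba_small, all_c, node, params) == pytest.approx(k)
            assert accumulated_payoff(ba_small, all_d, node, params) == 0.0


class TestFermiRule:
    def test_equal_payoffs_give_half(self):
        assert imitation_probability(3.7, 3.7, 2.0) == pytest.approx(0.5)

    def test_zero_beta_gives_half(self):
        assert imitation_probability(-5.0, 12.0, 0.0) == pytest.approx(0.5)

    def test_closed_form_value(self):
        # 1 / (1 + e^{-1})
        assert imitation_probability(0.0, 4.0, 0.25) == pytest.approx(0.7310585786300049)

    def test_no_overflow_at_extreme_payoffs(self):
        assert imitation_probability(1e6, -1e6, 10.0) == pytest.approx(0.0)
        assert imitation_probability(-1e6, 1e6, 10.0) == pytest.approx(1.0)

    @given(
        px=st.floats(-100, 100),
        py=st.floats(-100, 100),
        beta=st.floats(0, 10),
    )
    @settings(deadline=None, max_examples=200)
    def test_adoption_probabilities_sum_to_one(self, px, py, beta):
        w_xy = imitation_probability(px, py, beta)
        w_yx = imitation_probability(py, px, beta)
        # strictly inside (0, 1) mathematically; the upper end may round to
        # exactly 1.0 at double precision for large beta * payoff gaps
        assert 0.0 < w_xy <= 1.0
        assert w_xy + w_yx == pytest.approx(1.0, abs=1e-12)

    @given(gap=st.floats(0.01, 50))
    @settings(deadline=None)
    def test_monotone_in_payoff_advantage(self, gap):
        base = imitation_probability(0.0, 0.0, 0.5)
        assert imitation_probability(0.0, gap, 0.5) > base > imitation_probability(gap, 0.0, 0.5)


class TestInitialState:
    def test_two_strategy_counts(self, ba_500):
        state = initial_state(ba_500, mode=2, rng=0)
        assert list(state.counts) == [250, 250]

    def test_three_strategy_exact_thirds(self):
        net = generate_ba_network(999, 2, seed=1)
        state = initial_state(net, mode=3, rng=0)
        assert list(state.counts) == [333, 333, 333]

    def test_remainder_rule(self, ba_small):
        # n = 100: 3-strategy remainder 1 goes to C
        state = initial_state(ba_small, mode=3, rng=0)
        assert list(state.counts) == [34, 33, 33]

    def test_determinism(self, ba_small):
        a = initial_state(ba_small, rng=123)
        b = initial_state(ba_small, rng=123)
        assert np.array_equal(a.strategy, b.strategy)


class TestElementaryStep:
    def test_at_most_one_change_and_count_conservation(self, ba_small):
        rng = np.random.default_rng(0)
        state = initial_state(ba_small, rng=rng)
        params = GameParams(T=1.2, S=-0.3, beta=0.25)
        for _ in range(300):
            before = state.strategy.copy()
            elementary_step(ba_small, state, params, rng)
            assert np.sum(before != state.strategy) <= 1
            assert state.counts.sum() == ba_small.n_nodes

    def test_same_strategy_pair_is_noop(self, path2):
        state = PopulationState(np.array([0, 0], dtype=np.int8))
        rng = np.random.default_rng(1)
        params = GameParams(T=1.5, S=-0.5, beta=5.0)
        for _ in range(20):
            assert not elementary_step(path2, state, params, rng)

    def test_strong_selection_adopts_better_strategy(self, path2):
        """With beta large and a huge payoff gap, adoption is near-certain."""
        params = GameParams(T=5.0, S=-0.5, beta=50.0)
        flips = 0
        rng = np.random.default_rng(2)
        for _ in range(200):
            state = PopulationState(np.array([0, 1], dtype=np.int8))
            if elementary_step(path2, state, params, rng):
                # the defector earns T - p = 5 > the cooperator's S - q = -0.5,
                # so virtually every flip is C -> D
                assert state.counts[1] == 2
                flips += 1
        assert flips > 50


class TestFixation:
    def test_monomorphic_start_absorbs_immediately(self, ba_small):
        all_c = PopulationState(np.zeros(100, dtype=np.int8))
        res = run_to_fixation(ba_small, all_c, GameParams(1.5, -0.5), seed=0)
        assert res.absorbed and res.absorbed_label == "C" and res.n_steps == 0

    def test_absorbed_state_is_all_or_nothing(self, ba_small):
        params = GameParams(T=1.2, S=-0.6, beta=0.25)
        for r in range(10):
            init = initial_state(ba_small, rng=r)
            res = run_to_fixation(ba_small, init, params, seed=r)
            assert res.absorbed
            assert res.absorbed_label in ("C", "D")

    def test_translation_equivalence_is_exact(self, ba_small):
        """(T,S,p,q) and (T-p,S-q,0,0) share the effective game, so matched
        seeds must give identical outcomes, step counts included."""
        params = GameParams(T=1.3, S=-0.4, p=0.1, q=0.04, beta=0.25)
        for r in range(25):
            init = initial_state(ba_small, rng=mix_seed(5, r))
            a = run_to_fixation(ba_small, init, params, seed=mix_seed(6, r))
            b = run_to_fixation(ba_small, init, params.translated(), seed=mix_seed(6, r))
            assert a == b

    def test_neutral_drift_fixates_either_way_evenly(self, ba_small):
        """At beta = 0 labels are exchangeable: P(C fixates) = 1/2."""
        params = GameParams(T=1.5, S=-0.5, beta=0.0)
        n_runs = 1200
        wins = 0
        for r in range(n_runs):
            init = initial_state(ba_small, rng=mix_seed(1, r))
            res = run_to_fixation(ba_small, init, params, seed=mix_seed(2, r))
            assert res.absorbed
            wins += res.absorbed_label == "C"
        se = 0.5 / np.sqrt(n_runs)
        assert abs(wins / n_runs - 0.5) < 3 * se

    def test_unabsorbed_run_reported_not_truncated(self, ba_small):
        init = initial_state(ba_small, rng=3)
        res = run_to_fixation(ba_small, init, GameParams(1.0, -0.5), seed=3, max_steps=5)
        assert not res.absorbed
        assert res.n_steps == 5

    def test_three_strategy_runs_end_monomorphic(self, ba_small):
        params = GameParams(T=0.5, S=-0.3, p=0.1, q=0.04, beta=0.25)
        labels = set()
        for r in range(20):
            init = initial_state(ba_small, mode=3, rng=mix_seed(3, r))
            res = run_to_fixation(ba_small, init, params, seed=mix_seed(4, r))
            assert res.absorbed
            labels.add(res.absorbed_label)
        assert labels <= {"C", "D", "PC"}
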