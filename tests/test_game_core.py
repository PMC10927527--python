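"""Unit tests for the repeated-game core: action probabilities, the joint
Markov chain, its stationary distribution, payoffs, and the unilaterally
enforced engagement constraint."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from misinfogame import (
    GameConfig,
    ReceiverStrategy,
    StationaryDistribution,
    TransmitterStrategy,
    engage_prob,
    enforced_constraint_residual,
    exact_stationary,
    payoffs,
    simulate_rounds,
    stationary_distribution,
    transition_matrix,
    transmit_prob,
)
from conftest import random_pair


class TestTransmitProb:
    def test_sigmoid_midpoint_is_half(self):
        s = TransmitterStrategy.sigmoid(lam=100.0, m_t=0.5, m_f=0.25)
        assert transmit_prob(s, "t", 50, 100) == pytest.approx(0.5)
        assert transmit_prob(s, "f", 25, 100) == pytest.approx(0.5)

    def test_polynomial_no_feedback_is_baseline(self):
        s = TransmitterStrategy.linear(alpha=0.8, beta=0.3)
        for k in (0, 1, 7):
            assert transmit_prob(s, "t", k, 10) == pytest.approx(0.8)

    def test_linear_feedback_direct_evaluation(self):
        s = TransmitterStrategy.linear(alpha=0.2, beta=0.5, gamma=0.5)
        assert transmit_prob(s, "t", 1, 2) == pytest.approx(0.45)

    def test_out_of_range_k_rejected(self):
        s = TransmitterStrategy.linear(alpha=0.5, beta=0.5)
        with pytest.raises(ValueError):
            transmit_prob(s, "t", 3, 2)
        with pytest.raises(ValueError):
            transmit_prob(s, "t", -1, 2)

    def test_non_viable_rejected_at_construction(self):
        with pytest.raises(ValueError):
            TransmitterStrategy.linear(alpha=0.5, beta=0.5, gamma=0.9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_sampled_strategies_viable_on_grid(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random(2)
        g = rng.uniform(-a, 1.0 - a)
        t = rng.uniform(-b, 1.0 - b)
        s = TransmitterStrategy.linear(alpha=a, beta=b, gamma=g, theta=t)
        assert s.is_viable(100)
        for k in range(0, 11):
            assert 0.0 <= transmit_prob(s, "t", k, 10) <= 1.0
            assert 0.0 <= transmit_prob(s, "f", k, 10) <= 1.0


class TestEngageProb:
    def test_fully_attentive_follows_veracity(self):
        r = ReceiverStrategy(a0=1.0, p0=0.9)
        assert engage_prob(r, "n", "t", "t") == pytest.approx(1.0)
        assert engage_prob(r, "n", "t", "f") == pytest.approx(0.0)

    def test_memoryless_inattentive_uses_baseline(self):
        r = ReceiverStrategy(a0=0.0, a1=0.0, p0=0.7)
        for i in ("c", "n"):
            for j in ("t", "f"):
                assert engage_prob(r, i, j, "f") == pytest.approx(0.7)

    def test_mixed_attention_direct_evaluation(self):
        r = ReceiverStrategy(a0=0.5, a1=0.5, p0=0.2, p_ct=0.8)
        assert engage_prob(r, "c", "t", "t") == pytest.approx(0.75)


class TestTransitionMatrix:
    def test_always_true_rows(self):
        s = TransmitterStrategy.linear(alpha=1.0, beta=1.0)
        r = ReceiverStrategy(p0=0.7)
        T = transition_matrix(s, r, GameConfig(epsilon=0.0, eta=0.0))
        for row in T:
            assert row == pytest.approx([0.7, 0.0, 0.3, 0.0])

    def test_rows_stochastic_for_random_pairs(self, rng):
        for _ in range(50):
            s, r = random_pair(rng)
            T = transition_matrix(s, r, GameConfig())
            assert T.min() >= 0.0
            np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_single_step_monte_carlo(self, rng):
        """Entries match brute-force single-step frequencies within 3 MC SE."""
        s, r = random_pair(rng)
        cfg = GameConfig(epsilon=1e-3, eta=0.3)
        T = transition_matrix(s, r, cfg)
        n = 200_000
        states = [("c", "t"), ("c", "f"), ("n", "t"), ("n", "f")]
        for si, (i, j) in enumerate(states):
            k = 1 if i == "c" else 0
            flip = rng.random(n) < cfg.eta
            other = "f" if j == "t" else "t"
            p = np.where(
                flip, transmit_prob(s, other, k, 1), transmit_prob(s, j, k, 1)
            )
            true_draw = rng.random(n) < p
            true_draw ^= rng.random(n) < cfg.epsilon
            q_t = engage_prob(r, i, j, "t")
            q_f = engage_prob(r, i, j, "f")
            q = np.where(true_draw, q_t, q_f)
            engaged = rng.random(n) < q
            engaged ^= rng.random(n) < cfg.epsilon
            emp = np.array(
                [
                    (engaged & true_draw).mean(),
                    (engaged & ~true_draw).mean(),
                    (~engaged & true_draw).mean(),
                    (~engaged & ~true_draw).mean(),
                ]
            )
            se = np.sqrt(np.clip(T[si] * (1 - T[si]), 1e-12, None) / n)
            assert np.all(np.abs(emp - T[si]) < 3.5 * se + 1e-9)


class TestStationaryDistribution:
    def test_always_true_engaging_receiver(self):
        s = TransmitterStrategy.linear(alpha=1.0, beta=1.0)
        r = ReceiverStrategy(p0=0.7)
        v = exact_stationary(s, r, GameConfig(epsilon=0.0, eta=0.0))
        assert v.v_tc == pytest.approx(0.7)
        assert v.v_tn == pytest.approx(0.3)
        assert v.v_f == pytest.approx(0.0, abs=1e-12)

    def test_never_engaging_receiver_two_state_closed_form(self, rng):
        """With q = 0 the veracity marginal is (1-alpha)/(1-alpha+beta)."""
        for _ in range(20):
            a, b = rng.random(2)
            s = TransmitterStrategy.linear(alpha=a, beta=b)
            r = ReceiverStrategy()
            v = exact_stationary(s, r, GameConfig(epsilon=0.0, eta=0.0))
            assert v.v_f == pytest.approx((1 - a) / (1 - a + b), abs=1e-10)
            assert v.v_fc == pytest.approx(0.0, abs=1e-12)

    def test_matches_power_iteration_oracle(self, rng):
        for _ in range(100):
            s, r = random_pair(rng)
            T = transition_matrix(s, r, GameConfig(epsilon=1e-3))
            v = stationary_distribution(T)
            mu = np.full(4, 0.25)
            for _ in range(3000):
                mu = mu @ T
            assert np.abs(v.as_array() - mu).max() < 1e-10

    def test_reducible_chain_raises_then_cesaro(self):
        # alpha=1, beta=0: absorbing true and false veracity classes
        s = TransmitterStrategy.linear(alpha=1.0, beta=0.0)
        r = ReceiverStrategy(p0=0.5)
        T = transition_matrix(s, r, GameConfig(epsilon=0.0, eta=0.0))
        with pytest.raises(ValueError, match="recurrent"):
            stationary_distribution(T)
        v = stationary_distribution(T, reducible="cesaro")
        # uniform start splits mass evenly between the two absorbing classes
        assert v.v_t == pytest.approx(0.5, abs=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            stationary_distribution(np.ones((4, 4)))
        with pytest.raises(ValueError):
            StationaryDistribution(0.5, 0.5, 0.2, -0.2)
        with pytest.raises(ValueError):
            StationaryDistribution(0.5, 0.5, 0.5, 0.5)

    def test_per_story_rate_sentinels(self):
        v = StationaryDistribution(v_tc=0.6, v_tn=0.4, v_fc=0.0, v_fn=0.0)
        assert np.isnan(v.engage_per_false)
        assert v.engage_per_true == pytest.approx(0.6)


class TestSimulateRounds:
    def test_empirical_matches_exact_chain(self):
        rng = np.random.default_rng(3)
        s, r = random_pair(rng)
        cfg = GameConfig(epsilon=1e-3, eta=0.3)
        v = exact_stationary(s, r, cfg)
        dists, trace = simulate_rounds(s, [r], cfg, 100_000, seed=5)
        se = np.sqrt(v.as_array() * (1 - v.as_array()) / 100_000)
        # 3.5 sigma plus a small mixing allowance
        assert np.abs(dists[0].as_array() - v.as_array()).max() < 4 * se.max() + 2e-3
        assert trace.shape == (100_000, 3)

    def test_always_true_transmitter_only_true_stories(self):
        s = TransmitterStrategy.linear(alpha=1.0, beta=1.0)
        cfg = GameConfig(epsilon=0.0, eta=0.0)
        dists, trace = simulate_rounds(s, [ReceiverStrategy(p0=0.5)], cfg, 2000, seed=1)
        assert (trace[:, 1] == 1).all()
        assert dists[0].v_f == 0.0

    def test_same_seed_identical_trace(self):
        rng = np.random.default_rng(7)
        s, r = random_pair(rng)
        cfg = GameConfig()
        _, t1 = simulate_rounds(s, [r], cfg, 5000, seed=42)
        _, t2 = simulate_rounds(s, [r], cfg, 5000, seed=42)
        np.testing.assert_array_equal(t1, t2)

    def test_empty_receivers_rejected(self):
        s = TransmitterStrategy.linear(alpha=0.5, beta=0.5)
        with pytest.raises(ValueError):
            simulate_rounds(s, [], GameConfig(N=1), 10, seed=0)

    def test_convergence_to_stationary_in_T(self):
        """Total-variation distance to the exact chain shrinks with T on average."""
        rng = np.random.default_rng(11)
        cfg = GameConfig(epsilon=1e-3, eta=0.3)
        tv = {500: [], 50_000: []}
        for i in range(5):
            s, r = random_pair(rng)
            v = exact_stationary(s, r, cfg).as_array()
            for T in tv:
                d, _ = simulate_rounds(s, [r], cfg, T, seed=100 + i)
                tv[T].append(0.5 * np.abs(d[0].as_array() - v).sum())
        assert np.mean(tv[50_000]) < np.mean(tv[500])


class TestPayoffs:
    def test_worked_examples(self):
        cfg = GameConfig(pi_t=1.0, pi_f=-1.0, b_t=0.0, b_f=1.0)
        v = StationaryDistribution(v_tc=0.7, v_tn=0.3, v_fc=0.0, v_fn=0.0)
        rec, _ = payoffs(v, cfg)
        assert rec == pytest.approx(0.7)
        v0 = StationaryDistribution(v_tc=0.0, v_tn=0.6, v_fc=0.0, v_fn=0.4)
        assert payoffs(v0, cfg) == (pytest.approx(0.0), pytest.approx(0.0))
        v1 = StationaryDistribution(v_tc=0.2, v_tn=0.3, v_fc=0.4, v_fn=0.1)
        _, trans = payoffs(v1, cfg)
        assert trans == pytest.approx(0.4)

    def test_linearity_by_superposition(self, rng):
        cfg = GameConfig(pi_t=2.0, pi_f=-3.0, b_t=1.5, b_f=0.5)
        x = rng.dirichlet(np.ones(4))
        y = rng.dirichlet(np.ones(4))
        lam = 0.3
        mix = lam * x + (1 - lam) * y

        def mk(arr):
            return StationaryDistribution(arr[0], arr[1], arr[2], arr[3])

        for idx in (0, 1):
            assert payoffs(mk(mix), cfg)[idx] == pytest.approx(
                lam * payoffs(mk(x), cfg)[idx] + (1 - lam) * payoffs(mk(y), cfg)[idx]
            )


class TestEnforcedConstraint:
    def test_exact_at_stationarity_without_errors(self, rng, noiseless_config):
        for _ in range(200):
            s, r = random_pair(rng)
            v = exact_stationary(s, r, noiseless_config)
            assert abs(enforced_constraint_residual(s, v)) < 1e-10

    def test_no_feedback_share_independent_of_receiver(self, rng):
        """With gamma = theta = 0 the false-story share is fixed by the
        strategy alone, whatever the receiver does."""
        cfg = GameConfig(epsilon=0.0, eta=0.2)
        s = TransmitterStrategy.linear(alpha=0.7, beta=0.4)
        shares = []
        for _ in range(10):
            _, r = random_pair(rng)
            shares.append(exact_stationary(s, r, cfg).v_f)
        assert np.ptp(shares) < 1e-12

    def test_residual_scales_with_execution_error(self):
        rng = np.random.default_rng(13)
        s, r = random_pair(rng)
        res = []
        for eps in (1e-3, 1e-4):
            v = exact_stationary(s, r, GameConfig(epsilon=eps, eta=0.0))
            res.append(abs(enforced_constraint_residual(s, v)))
        assert res[0] < 0.05
        # roughly linear in epsilon
        assert 2.0 < res[0] / max(res[1], 1e-300) < 50.0

    def test_degenerate_strategy_rejected(self):
        s = TransmitterStrategy.linear(alpha=1.0, beta=0.0)
        v = StationaryDistribution(0.25, 0.25, 0.25, 0.25)
        with pytest.raises(ValueError, match="degenerate"):
            enforced_constraint_residual(s, v)


class TestSerialization:
    def test_transmitter_round_trip(self):
        for s in (
            TransmitterStrategy.linear(alpha=0.8, beta=0.3, gamma=-0.5, theta=0.1),
            TransmitterStrategy.sigmoid(lam=100.0, m_t=0.5, m_f=0.25),
        ):
            back = TransmitterStrategy.from_json(s.to_json())
            assert back == s

    def test_receiver_round_trip(self):
        r = ReceiverStrategy(a0=0.1, a1=0.9, p0=0.3, p_ct=0.8, p_cf=0.2, p_nt=0.6, p_nf=0.4)
        assert ReceiverStrategy.from_json(r.to_json()) == r
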