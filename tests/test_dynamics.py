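"""Tests of the Fermi acceptance rule, proposal kernels, receiver
optimization, co-optimization and the engagement-region scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from misinfogame import (
    GameConfig,
    OptimizationConfig,
    ReceiverStrategy,
    RegionGrid,
    TransmitterStrategy,
    co_optimize,
    fermi_accept,
    optimize_receiver,
    population_dynamics,
    propose_receiver,
    region_scan,
)
from misinfogame import _engine
from misinfogame.dynamics import _scan_cell
from misinfogame.game_core import exact_stationary


class TestFermiRule:
    def test_closed_form_values(self):
        p = _engine.fermi_probability
        assert float(p(1.0, 1.0, 5.0)) == pytest.approx(0.5)
        assert float(p(np.log(3.0), 0.0, 1.0)) == pytest.approx(0.25)
        assert float(p(-4.0, 3.0, 0.0)) == pytest.approx(0.5)

    def test_overflow_saturates(self):
        p = _engine.fermi_probability
        assert float(p(1e6, -1e6, 10.0)) == pytest.approx(0.0, abs=1e-12)
        assert float(p(-1e6, 1e6, 10.0)) == pytest.approx(1.0)

    @given(
        st.floats(-5, 5),
        st.floats(-5, 5),
        st.floats(-5, 5),
        st.floats(0.01, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_candidate_payoff(self, w, w1, w2, sigma):
        lo, hi = sorted((w1, w2))
        assert _engine.fermi_probability(w, lo, sigma) <= _engine.fermi_probability(w, hi, sigma)

    def test_accept_is_bernoulli_with_fermi_probability(self, rng):
        hits = sum(fermi_accept(0.0, np.log(3.0), 1.0, rng) for _ in range(20_000))
        assert hits / 20_000 == pytest.approx(0.75, abs=0.01)

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            fermi_accept(0.0, 1.0, -1.0, rng)


class TestProposals:
    def test_tiny_scale_keeps_strategy(self, rng):
        cfg = OptimizationConfig(proposal_scale=1e-12)
        current = ReceiverStrategy(p0=0.4, p_ct=0.7)
        cand = propose_receiver(current, cfg, rng)
        assert np.allclose(cand.behavior_vector(), current.behavior_vector(), atol=1e-9)

    def test_components_stay_in_unit_interval(self, rng):
        cfg = OptimizationConfig(proposal_scale=0.4)
        current = ReceiverStrategy(p0=0.05, p_ct=0.97)
        for _ in range(500):
            cand = propose_receiver(current, cfg, rng)
            vec = cand.behavior_vector()
            assert (vec >= 0).all() and (vec <= 1).all()

    def test_attention_weights_held_fixed(self, rng):
        cfg = OptimizationConfig()
        current = ReceiverStrategy(a0=0.2, a1=0.7, p0=0.5)
        for _ in range(50):
            cand = propose_receiver(current, cfg, rng)
            assert cand.a0 == current.a0 and cand.a1 == current.a1

    def test_local_kernel_symmetric_at_interior_point(self, rng):
        cfg = OptimizationConfig(proposal_scale=0.1)
        current = ReceiverStrategy(p0=0.5, p_ct=0.5, p_cf=0.5, p_nt=0.5, p_nf=0.5)
        deltas = []
        for _ in range(20_000):
            cand = propose_receiver(current, cfg, rng)
            deltas.append(cand.behavior_vector().sum() - 2.5)
        se = np.std(deltas) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 4 * se + 1e-4

    def test_global_kind_resamples_uniformly(self, rng):
        cfg = OptimizationConfig(proposal_kind="global")
        current = ReceiverStrategy(p0=0.5, p_ct=0.5, p_cf=0.5, p_nt=0.5, p_nf=0.5)
        base = current.behavior_vector()
        new_vals = []
        for _ in range(3000):
            vec = propose_receiver(current, cfg, rng).behavior_vector()
            delta = vec - base
            idx = np.argmax(np.abs(delta))
            new_vals.append(vec[idx])
        assert np.mean(new_vals) == pytest.approx(0.5, abs=0.03)
        assert np.std(new_vals) == pytest.approx(np.sqrt(1 / 12), abs=0.03)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            OptimizationConfig(proposal_scale=0.0)
        with pytest.raises(ValueError):
            OptimizationConfig(measure=0)
        with pytest.raises(ValueError):
            OptimizationConfig(sigma=-1.0)


class TestOptimizeReceiver:
    def test_learns_to_engage_with_truth_teller(self):
        cfg = GameConfig(epsilon=1e-3, eta=0.0)
        opt = OptimizationConfig(sigma=100.0, burn_in=4000, measure=4000, seed=0)
        res = optimize_receiver(TransmitterStrategy.linear(1.0, 1.0), cfg, opt)
        assert res.engage_per_true >= 0.95

    def test_learns_to_avoid_liar(self):
        cfg = GameConfig(epsilon=1e-3, eta=0.0)
        opt = OptimizationConfig(sigma=100.0, burn_in=4000, measure=4000, seed=0)
        res = optimize_receiver(TransmitterStrategy.linear(0.0, 0.0), cfg, opt)
        assert res.engage_per_false <= 0.05

    def test_seeded_reproducibility(self):
        cfg = GameConfig()
        opt = OptimizationConfig(burn_in=500, measure=500, seed=7)
        s = TransmitterStrategy.linear(alpha=0.8, beta=0.3, gamma=-0.4, theta=0.1)
        r1 = optimize_receiver(s, cfg, opt)
        r2 = optimize_receiver(s, cfg, opt)
        np.testing.assert_array_equal(r1.v_mean, r2.v_mean)
        assert r1.receiver_final == r2.receiver_final

    def test_greedy_limit_matches_grid_enumeration(self):
        """At large sigma, measured payoff concentrates on the optimum found
        by exhaustive enumeration of a coarse blind-strategy grid."""
        rng = np.random.default_rng(2)
        s = TransmitterStrategy.linear(alpha=0.9, beta=0.1, gamma=-0.6, theta=0.3)
        cfg = GameConfig(epsilon=1e-3, eta=0.3)
        best = -np.inf
        for p0 in np.linspace(0, 1, 21):
            v = exact_stationary(s, ReceiverStrategy(p0=p0), cfg)
            best = max(best, cfg.pi_t * v.v_tc + cfg.pi_f * v.v_fc)
        opt = OptimizationConfig(sigma=200.0, burn_in=4000, measure=4000, seed=3)
        res = optimize_receiver(s, cfg, opt, a0=0.0, a1=0.0)
        assert res.receiver_payoff == pytest.approx(best, abs=0.05)

    def test_trajectory_recording(self):
        cfg = GameConfig()
        opt = OptimizationConfig(burn_in=100, measure=100, seed=1)
        res = optimize_receiver(
            TransmitterStrategy.linear(0.7, 0.2), cfg, opt, record_trajectory=True
        )
        assert len(res.trajectory) == 200
        assert {"event", "payoff", "engagement", "v_f"} <= set(res.trajectory.columns)


class TestCoOptimize:
    def test_validation(self):
        s = TransmitterStrategy.linear(0.5, 0.5)
        r = ReceiverStrategy.non_engaging()
        cfg = GameConfig()
        opt = OptimizationConfig(burn_in=10, measure=10)
        with pytest.raises(ValueError):
            co_optimize(s, r, cfg, opt, opt, steps=0)

    def test_accurate_transmitter_attentive_receiver_prefers_truth(self):
        """An accurate transmitter facing an attentive truth-seeking receiver
        ends with more engagement per true than per false story."""
        cfg = GameConfig(pi_t=1.0, pi_f=-1.0, b_t=1.0, b_f=0.0)
        opt_T = OptimizationConfig(sigma=100.0, seed=0)
        opt_R = OptimizationConfig(sigma=100.0, burn_in=1, measure=1500, seed=0)
        diffs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ep = rng.random(4)
            t0 = TransmitterStrategy.linear(ep[0], ep[2], ep[1] - ep[0], ep[3] - ep[2])
            res = co_optimize(
                t0, ReceiverStrategy.non_engaging(), cfg,
                opt_T, OptimizationConfig(sigma=100.0, burn_in=1, measure=1500, seed=seed),
                steps=3000,
            )
            diffs.append(res.engagement_difference)
        assert np.nanmean(diffs) < 0

    def test_returns_viable_final_transmitter(self):
        cfg = GameConfig()
        res = co_optimize(
            TransmitterStrategy.linear(0.5, 0.5),
            ReceiverStrategy.non_engaging(),
            cfg,
            OptimizationConfig(sigma=10.0, seed=1),
            OptimizationConfig(sigma=1.0, burn_in=1, measure=200, seed=1),
            steps=400,
        )
        assert res.transmitter_final.is_viable(1)


class TestRegionScan:
    def test_smoke_grid_returns_finite_values(self):
        grid = RegionGrid(pi_f_values=(-1.0, 1.0), sigma_values=(0.1, 10.0), replicates=3, steps=200)
        df = region_scan(grid, "misinformation", GameConfig(), seed=0)
        assert len(df) == 4
        assert np.isfinite(df["mean_diff"]).all()
        assert (df["n_replicates"] == 3).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            RegionGrid(pi_f_values=(), sigma_values=(1.0,))
        grid = RegionGrid.default(n=2, replicates=1, steps=10)
        with pytest.raises(ValueError):
            region_scan(grid, "clickbait", GameConfig())

    @pytest.mark.parametrize("scale", [0.05, 0.2])
    def test_region_signs_robust_to_proposal_scale(self, scale):
        """F1 and F2 probe signs are unchanged at half and double the
        default local proposal step."""
        cfg = GameConfig()
        rng = np.random.default_rng(8)
        f1 = _scan_cell(-1.0, 100.0, "misinformation", cfg, 60, 2500, rng, scale=scale)
        f2 = _scan_cell(-1.0, 0.1, "misinformation", cfg, 60, 2500, rng, scale=scale)
        assert f1 < 0
        assert f2 > 0


class TestPopulationDynamics:
    def test_deterministic_given_seed(self):
        s = TransmitterStrategy.sigmoid(lam=100.0, m_t=0.5, m_f=0.25)
        t1 = population_dynamics(s, n_receivers=50, rounds=300, seed=5)
        t2 = population_dynamics(s, n_receivers=50, rounds=300, seed=5)
        assert t1.equals(t2)

    def test_always_true_drives_engagement_up(self):
        s = TransmitterStrategy.linear(1.0, 1.0)
        trace = population_dynamics(s, n_receivers=100, rounds=3000, seed=0,
                                    config=GameConfig(epsilon=0.0, eta=0.0, N=100))
        assert trace["mean_p0"].iloc[-1] > 0.6
        assert (trace["veracity"] == 1).all()
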