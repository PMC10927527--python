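"""Myopic noisy strategy optimization.

Players revise strategies by comparing the equilibrium payoff of their
current strategy against a randomly proposed alternative and switching with
probability given by a Fermi (logistic) function

    P(switch) = 1 / (1 + exp[sigma (w_current - w_candidate)]),

where ``sigma`` is the attention the player pays to payoffs: sigma = 0 is
pure drift (accept half the time), sigma -> infinity is greedy hill
climbing.  Payoffs during optimization are the exact stationary payoffs of
the current strategy pair (single-receiver chain); for audiences of N > 1
receivers, payoffs can instead be estimated from finite simulated rounds.

The module provides single-receiver optimization against a fixed
transmitter, joint transmitter/receiver co-optimization, the (pi_f, sigma)
region scan that classifies engagement patterns, and a population-scale
process in which many receivers adapt a veracity-blind engagement rate
against one transmitter (used by the sigmoid-feedback demonstration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _engine
from .game_core import (
    GameConfig,
    ReceiverStrategy,
    StationaryDistribution,
    TransmitterStrategy,
    simulate_rounds,
    transmit_prob,
)

__all__ = [
    "OptimizationConfig",
    "RegionGrid",
    "OptimizeResult",
    "fermi_accept",
    "propose_receiver",
    "optimize_receiver",
    "co_optimize",
    "region_scan",
    "population_dynamics",
]

_RECEIVER_COMPONENTS = ("p0", "p_ct", "p_cf", "p_nt", "p_nf")


@dataclass(frozen=True)
class OptimizationConfig:
    """Knobs of the noisy optimization process.

    ``sigma`` is attention to payoffs; ``proposal_scale`` the half-width of
    the symmetric local proposal (reflected into [0, 1]); ``burn_in`` and
    ``measure`` count update events before and during measurement.
    """

    sigma: float = 1.0
    proposal_scale: float = 0.1
    proposal_kind: str = "local"
    burn_in: int = 10_000
    measure: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.proposal_scale <= 0:
            raise ValueError("proposal_scale must be > 0")
        if self.burn_in < 1 or self.measure < 1:
            raise ValueError("burn_in and measure must be >= 1")
        if self.proposal_kind not in ("local", "global"):
            raise ValueError("proposal_kind must be 'local' or 'global'")


@dataclass(frozen=True)
class RegionGrid:
    """Grid specification for the (pi_f, sigma) engagement-region scan."""

    pi_f_values: tuple[float, ...]
    sigma_values: tuple[float, ...]
    replicates: int = 100
    steps: int = 4000

    def __post_init__(self) -> None:
        if len(self.pi_f_values) == 0 or len(self.sigma_values) == 0:
            raise ValueError("grid must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(self, "pi_f_values", tuple(float(x) for x in self.pi_f_values))
        object.__setattr__(self, "sigma_values", tuple(float(x) for x in self.sigma_values))

    @classmethod
    def default(cls, n: int = 10, replicates: int = 100, steps: int = 4000) -> "RegionGrid":
        """Logarithmic sigma in [1e-2, 1e2], pi_f in [-1, 1] (pi_t = -pi_f)."""
        return cls(
            pi_f_values=tuple(np.linspace(-1.0, 1.0, n)),
            sigma_values=tuple(np.logspace(-2, 2, n)),
            replicates=replicates,
            steps=steps,
        )


@dataclass(frozen=True)
class OptimizeResult:
    """Measurement-window summary of an optimization run."""

    v_mean: np.ndarray  # state order [(c,t), (c,f), (n,t), (n,f)]
    receiver_payoff: float
    receiver_final: ReceiverStrategy
    accept_rate: float
    trajectory: pd.DataFrame | None = None
    transmitter_final: TransmitterStrategy | None = None

    @property
    def v_tc(self) -> float:
        return float(self.v_mean[0])

    @property
    def v_fc(self) -> float:
        return float(self.v_mean[1])

    @property
    def v_t(self) -> float:
        return float(self.v_mean[0] + self.v_mean[2])

    @property
    def v_f(self) -> float:
        return float(self.v_mean[1] + self.v_mean[3])

    @property
    def engagement(self) -> float:
        return float(self.v_mean[0] + self.v_mean[1])

    @property
    def engage_per_true(self) -> float:
        return self.v_tc / self.v_t if self.v_t >= 1e-9 else float("nan")

    @property
    def engage_per_false(self) -> float:
        return self.v_fc / self.v_f if self.v_f >= 1e-9 else float("nan")

    @property
    def engagement_difference(self) -> float:
        """Per-story engagement difference v_fc/v_f - v_tc/v_t."""
        return self.engage_per_false - self.engage_per_true


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def fermi_accept(
    w_current: float, w_candidate: float, sigma: float, rng: np.random.Generator
) -> bool:
    """Accept the candidate with probability 1/(1 + exp[sigma (w_i - w_j)])."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    p = _engine.fermi_probability(np.asarray(w_current), np.asarray(w_candidate), sigma)
    return bool(rng.random() < p)


def propose_receiver(
    current: ReceiverStrategy, config: OptimizationConfig, rng: np.random.Generator
) -> ReceiverStrategy:
    """Propose an alternative receiver strategy.

    One uniformly chosen behavioral component among (p0, p_ct, p_cf, p_nt,
    p_nf) is either perturbed by a uniform step of half-width
    ``proposal_scale`` reflected into [0, 1] (local kind) or resampled
    uniformly (global kind).  Attention weights a0, a1 are exogenous and
    held fixed.
    """
    name = _RECEIVER_COMPONENTS[rng.integers(0, len(_RECEIVER_COMPONENTS))]
    value = getattr(current, name)
    if config.proposal_kind == "local":
        step = rng.uniform(-config.proposal_scale, config.proposal_scale)
        new = float(_engine.reflect_unit(np.asarray(value + step)))
    else:
        new = float(rng.random())
    return replace(current, **{name: new})


# ---------------------------------------------------------------------------
# receiver optimization against a fixed transmitter
# ---------------------------------------------------------------------------


def _endpoints_row(transmitter: TransmitterStrategy) -> np.ndarray:
    return np.array([transmitter.endpoints(1)], dtype=float)


def optimize_receiver(
    transmitter: TransmitterStrategy,
    config: GameConfig,
    opt: OptimizationConfig,
    a0: float = 0.0,
    a1: float = 1.0,
    record_trajectory: bool = False,
    payoff_rounds: int = 10_000,
) -> OptimizeResult:
    """Optimize a receiver from the non-engaging strategy q = {0,0,0,0}.

    Payoffs are exact stationary payoffs for N = 1; for N > 1 they are
    estimated from ``payoff_rounds`` simulated rounds with all receivers
    sharing the candidate strategy.  Measured quantities average the current
    pair's stationary outcome over the ``opt.measure`` events that follow
    the ``opt.burn_in`` events.
    """
    rng = np.random.default_rng(opt.seed)
    if config.N == 1:
        res = _engine.optimize_receivers_batch(
            _endpoints_row(transmitter),
            a0,
            a1,
            config.pi_t,
            config.pi_f,
            config.epsilon,
            config.eta,
            opt.sigma,
            opt.proposal_scale,
            opt.proposal_kind,
            opt.burn_in,
            opt.measure,
            rng,
        )
        p = res["p_final"][0]
        receiver = ReceiverStrategy(a0=a0, a1=a1, p0=p[0], p_ct=p[1], p_cf=p[2], p_nt=p[3], p_nf=p[4])
        return OptimizeResult(
            v_mean=res["v_mean"][0],
            receiver_payoff=float(res["receiver_payoff"][0]),
            receiver_final=receiver,
            accept_rate=float(res["accept_rate"]),
            trajectory=_trajectory_rerun(transmitter, config, opt, a0, a1)
            if record_trajectory
            else None,
        )
    return _optimize_receiver_simulated(transmitter, config, opt, a0, a1, payoff_rounds)


def _trajectory_rerun(
    transmitter: TransmitterStrategy,
    config: GameConfig,
    opt: OptimizationConfig,
    a0: float,
    a1: float,
) -> pd.DataFrame:
    """Re-run the event loop recording per-event payoff and engagement."""
    rng = np.random.default_rng(opt.seed)
    ep = _endpoints_row(transmitter)
    free = _engine.free_receiver_components(a0, a1)
    p = np.zeros((1, 5))

    def solve(p_mat):
        q_t, q_f = _engine.receiver_q(p_mat, a0, a1)
        return _engine.stationary_batch(
            _engine.build_transition(
                ep[:, 0], ep[:, 1], ep[:, 2], ep[:, 3], q_t, q_f, config.epsilon, config.eta
            )
        )

    v = solve(p)
    w = _engine.receiver_payoff(v, config.pi_t, config.pi_f)
    rows = []
    for event in range(opt.burn_in + opt.measure):
        comp = np.asarray(free)[rng.integers(0, len(free), size=1)]
        if opt.proposal_kind == "local":
            cand_val = _engine.reflect_unit(
                p[0, comp] + rng.uniform(-opt.proposal_scale, opt.proposal_scale, size=1)
            )
        else:
            cand_val = rng.random(1)
        p_cand = p.copy()
        p_cand[0, comp] = cand_val
        v_cand = solve(p_cand)
        w_cand = _engine.receiver_payoff(v_cand, config.pi_t, config.pi_f)
        if rng.random(1) < _engine.fermi_probability(w, w_cand, opt.sigma):
            p, v, w = p_cand, v_cand, w_cand
        rows.append((event, float(w[0]), float(v[0, 0] + v[0, 1]), float(v[0, 1] + v[0, 3])))
    return pd.DataFrame(rows, columns=["event", "payoff", "engagement", "v_f"])


def _optimize_receiver_simulated(
    transmitter: TransmitterStrategy,
    config: GameConfig,
    opt: OptimizationConfig,
    a0: float,
    a1: float,
    payoff_rounds: int,
) -> OptimizeResult:
    """Finite-round payoff evaluation for audiences of N > 1 receivers."""
    rng = np.random.default_rng(opt.seed)
    current = ReceiverStrategy.non_engaging(a0=a0, a1=a1)

    def evaluate(strategy: ReceiverStrategy, sub_seed: int):
        dists, _ = simulate_rounds(
            transmitter, [strategy] * config.N, config, payoff_rounds, sub_seed
        )
        v = np.mean([d.as_array() for d in dists], axis=0)
        return v, config.pi_t * v[0] + config.pi_f * v[1]

    v_cur, w_cur = evaluate(current, int(rng.integers(2**31)))
    v_sum = np.zeros(4)
    w_sum = 0.0
    accepted = 0
    for event in range(opt.burn_in + opt.measure):
        cand = propose_receiver(current, opt, rng)
        v_cand, w_cand = evaluate(cand, int(rng.integers(2**31)))
        if fermi_accept(w_cur, w_cand, opt.sigma, rng):
            current, v_cur, w_cur = cand, v_cand, w_cand
            accepted += 1
        if event >= opt.burn_in:
            v_sum += v_cur
            w_sum += w_cur
    v_mean = v_sum / opt.measure
    return OptimizeResult(
        v_mean=v_mean,
        receiver_payoff=w_sum / opt.measure,
        receiver_final=current,
        accept_rate=accepted / (opt.burn_in + opt.measure),
    )


# ---------------------------------------------------------------------------
# co-optimization and region scan
# ---------------------------------------------------------------------------


def co_optimize(
    t_init: TransmitterStrategy,
    r_init: ReceiverStrategy,
    config: GameConfig,
    opt_T: OptimizationConfig,
    opt_R: OptimizationConfig,
    steps: int,
) -> OptimizeResult:
    """Jointly optimize a transmitter/receiver pair for ``steps`` time-steps.

    Each time-step holds one receiver update event followed by one
    transmitter update event.  The transmitter explores the viable
    linear-feedback space through its endpoint rules (rt0, rt1, rf0, rf1).
    The measurement window is the final ``opt_R.measure`` steps and must be
    non-empty.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    measure = min(opt_R.measure, steps)
    if measure < 1:
        raise ValueError("zero-length measurement window")
    rng = np.random.default_rng(opt_R.seed)
    res = _engine.co_optimize_batch(
        _endpoints_row(t_init),
        r_init.behavior_vector()[None, :],
        r_init.a0,
        r_init.a1,
        config.pi_t,
        config.pi_f,
        config.b_t,
        config.b_f,
        config.epsilon,
        config.eta,
        opt_R.sigma,
        opt_T.sigma,
        opt_R.proposal_scale,
        opt_T.proposal_scale,
        steps - measure,
        measure,
        rng,
    )
    p = res["p_final"][0]
    ep = res["endpoints_final"][0]
    receiver = ReceiverStrategy(
        a0=r_init.a0, a1=r_init.a1, p0=p[0], p_ct=p[1], p_cf=p[2], p_nt=p[3], p_nf=p[4]
    )
    transmitter = TransmitterStrategy.linear(
        alpha=ep[0], beta=ep[2], gamma=ep[1] - ep[0], theta=ep[3] - ep[2]
    )
    return OptimizeResult(
        v_mean=res["v_mean"][0],
        receiver_payoff=float(res["receiver_payoff"][0]),
        receiver_final=receiver,
        accept_rate=float("nan"),
        transmitter_final=transmitter,
    )


def _scan_cell(
    pi_f: float,
    sigma: float,
    transmitter_type: str,
    config: GameConfig,
    replicates: int,
    steps: int,
    rng: np.random.Generator,
    sigma_T: float = 100.0,
    scale: float = 0.1,
) -> float:
    """Mean per-story engagement difference v_fc/v_f - v_tc/v_t in one cell."""
    b_t, b_f = (0.0, 1.0) if transmitter_type == "misinformation" else (1.0, 0.0)
    endpoints = rng.random((replicates, 4))  # uniform viable linear strategies
    p_init = np.zeros((replicates, 5))
    measure = max(1, steps // 2)
    res = _engine.co_optimize_batch(
        endpoints,
        p_init,
        0.0,
        0.0,
        -pi_f,
        pi_f,
        b_t,
        b_f,
        config.epsilon,
        config.eta,
        sigma,
        sigma_T,
        scale,
        scale,
        steps - measure,
        measure,
        rng,
    )
    diff = res["engage_per_false"] - res["engage_per_true"]
    return float(np.nanmean(diff))


def region_scan(
    grid: RegionGrid,
    transmitter_type: str,
    config: GameConfig,
    seed: int = 0,
    sigma_T: float = 100.0,
) -> pd.DataFrame:
    """Scan the (pi_f, sigma) plane of co-optimizing pairs.

    For each cell, ``grid.replicates`` independent pairs co-optimize
    (receiver exploration local with a0 = a1 = 0, pi_t = -pi_f, transmitter
    attention ``sigma_T``) and the cell records the replicate-mean per-story
    engagement difference v_fc/v_f - v_tc/v_t.  The sign of a cell
    classifies the engagement region: positive means more engagement per
    false story.
    """
    if transmitter_type not in ("misinformation", "accurate"):
        raise ValueError("transmitter_type must be 'misinformation' or 'accurate'")
    rows = []
    for i, pi_f in enumerate(grid.pi_f_values):
        for j, sigma in enumerate(grid.sigma_values):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(i, j))
            )
            diff = _scan_cell(
                pi_f, sigma, transmitter_type, config, grid.replicates, grid.steps, rng, sigma_T
            )
            rows.append((pi_f, sigma, diff, grid.replicates))
    return pd.DataFrame(rows, columns=["pi_f", "sigma", "mean_diff", "n_replicates"])


# ---------------------------------------------------------------------------
# population-scale receiver adaptation (sigmoid demonstration)
# ---------------------------------------------------------------------------


def population_dynamics(
    transmitter: TransmitterStrategy,
    n_receivers: int = 100,
    rounds: int = 10_000,
    config: GameConfig | None = None,
    sigma: float = 1.0,
    proposal_scale: float = 0.1,
    payoff_window: int = 50,
    seed: int = 0,
    p_init: float = 0.0,
) -> pd.DataFrame:
    """Simulate a transmitter against ``n_receivers`` adapting receivers.

    Receivers are veracity-blind (a0 = a1 = 0) and each carries an
    engagement rate p0.  Every round the transmitter draws the story's
    veracity from its rule given the previous engagement count k and the
    eta-perceived previous veracity; receivers engage independently.  Each
    receiver then performs one myopic update event: a local proposal to its
    p0 is accepted by the Fermi rule, scoring strategies by engagement rate
    times the mean per-engagement utility of the stories seen over the last
    ``payoff_window`` rounds.  This windowed score plays the role of the
    equilibrium payoff at population scale, where the joint stationary
    distribution is not available in closed form.

    Returns one row per round: (round, veracity [1 = true], k_engaged,
    mean_p0).
    """
    if config is None:
        config = GameConfig(N=n_receivers)
    rng = np.random.default_rng(seed)
    N = n_receivers
    eps, eta = config.epsilon, config.eta
    p0 = np.full(N, float(p_init))
    veracity = True
    k = 0
    recent = np.zeros(payoff_window)  # +1 true / -1... store utility per engagement
    recent[:] = config.pi_t  # window initialized as if content were true
    out = np.empty((rounds, 4))
    for t in range(rounds):
        perceived = veracity if rng.random() >= eta else not veracity
        p_true = transmit_prob(transmitter, "t" if perceived else "f", k, N)
        story_true = rng.random() < p_true
        if rng.random() < eps:
            story_true = not story_true
        engage_p = p0 * (1.0 - 2.0 * eps) + eps
        engaged = rng.random(N) < engage_p
        k = int(engaged.sum())
        recent[t % payoff_window] = config.pi_t if story_true else config.pi_f
        psi = recent.mean()
        # one update event per receiver: score(p) = p * psi
        cand = _engine.reflect_unit(p0 + rng.uniform(-proposal_scale, proposal_scale, size=N))
        accept = rng.random(N) < _engine.fermi_probability(p0 * psi, cand * psi, sigma)
        p0 = np.where(accept, cand, p0)
        out[t] = (t, float(story_true), k, p0.mean())
        veracity = story_true
    return pd.DataFrame(out, columns=["round", "veracity", "k_engaged", "mean_p0"]).astype(
        {"round": int, "veracity": int, "k_engaged": int}
    )
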