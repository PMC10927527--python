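"""Scripted computational experiments.

Two experiments mirror the model's headline demonstrations:

* :func:`sigmoid_demo` runs a sigmoid-feedback transmitter against a
  population of adapting, veracity-blind receivers and summarizes the
  resulting engagement pattern — average engagement probability per false
  versus per true story, and misinformation output in high- versus
  low-engagement rounds.

* :func:`simulate_story_sequence` / :func:`rank_experiment` generate short
  news-story sequences from previously evaluated (transmitter, receiver)
  pairs, compute the regression coefficient of standardized engagement on
  perceived accuracy for each sequence, and rank-order those coefficients
  across mixed pools of successful accurate and misinformation
  transmitters.  With feedback, low ranks are negative and dominated by
  misinformation transmitters while high ranks are positive and dominated
  by accurate ones; without feedback the composition of every rank is
  exchangeable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import population_dynamics
from .game_core import (
    GameConfig,
    ReceiverStrategy,
    TransmitterStrategy,
    engage_prob,
    transmit_prob,
)

__all__ = [
    "StoryRecord",
    "SigmoidDemoResult",
    "simulate_story_sequence",
    "engagement_accuracy_slope",
    "rank_experiment",
    "sigmoid_demo",
]


@dataclass(frozen=True)
class StoryRecord:
    """One simulated news story."""

    index: int
    veracity: str  # 't' or 'f'
    perceived_accuracy: float
    engagement_rate: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.engagement_rate <= 1.0):
            raise ValueError("engagement_rate must lie in [0, 1]")


def simulate_story_sequence(
    transmitter: TransmitterStrategy,
    receiver: ReceiverStrategy,
    n_stories: int = 20,
    population: int = 100_000,
    eta: float = 0.3,
    rng: np.random.Generator | None = None,
    engagement_kind: str = "realized",
    accuracy_kind: str = "bernoulli",
) -> list[StoryRecord]:
    """Generate a sequence of stories from an evaluated strategy pair.

    The game iterates from the conventional initial state (no engagement,
    previous story true).  Each story's veracity is drawn from the
    transmitter's rule given the realized engagement count of the previous
    story (a binomial draw over ``population`` receivers) and the
    eta-perceived previous veracity.  The expected engagement probability
    mixes the receiver's engaged/non-engaged memory states according to the
    previous story's realized engagement fraction.

    ``engagement_kind`` selects the reported per-story engagement: the
    realized count divided by ``population`` (default) or the expected
    probability.  ``accuracy_kind`` selects the perceived accuracy: a
    per-story Bernoulli eta-flip of the binary veracity (default) or the
    deterministic expectation 1 - eta / eta.
    """
    if n_stories < 2:
        raise ValueError("need at least 2 stories for a regression")
    if engagement_kind not in ("realized", "expected"):
        raise ValueError("engagement_kind must be 'realized' or 'expected'")
    if accuracy_kind not in ("bernoulli", "expected"):
        raise ValueError("accuracy_kind must be 'bernoulli' or 'expected'")
    rng = np.random.default_rng() if rng is None else rng
    j_prev = "t"
    e_prev = 0.0
    k_prev = 0
    records = []
    for idx in range(1, n_stories + 1):
        perceived_prev = j_prev
        if rng.random() < eta:
            perceived_prev = "f" if j_prev == "t" else "t"
        p_true = transmit_prob(transmitter, perceived_prev, k_prev, population)
        m = "t" if rng.random() < p_true else "f"
        expected = e_prev * engage_prob(receiver, "c", j_prev, m) + (1.0 - e_prev) * engage_prob(
            receiver, "n", j_prev, m
        )
        k = int(rng.binomial(population, expected))
        realized = k / population
        if accuracy_kind == "bernoulli":
            acc = 1.0 if m == "t" else 0.0
            if rng.random() < eta:
                acc = 1.0 - acc
        else:
            acc = 1.0 - eta if m == "t" else eta
        records.append(
            StoryRecord(
                index=idx,
                veracity=m,
                perceived_accuracy=acc,
                engagement_rate=realized if engagement_kind == "realized" else expected,
            )
        )
        j_prev, e_prev, k_prev = m, realized, k
    return records


def engagement_accuracy_slope(stories: list[StoryRecord]) -> float:
    """OLS slope of standardized engagement rate on standardized perceived
    accuracy — the sample correlation coefficient.

    Returns 0 (with a warning) when either variable has zero variance, so
    degenerate always-true transmitters do not break rank ensembles.
    """
    if len(stories) < 2:
        raise ValueError("need at least 2 stories")
    x = np.array([s.perceived_accuracy for s in stories], dtype=float)
    y = np.array([s.engagement_rate for s in stories], dtype=float)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        warnings.warn("zero variance in regression variables; slope set to 0", stacklevel=2)
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def rank_experiment(
    accurate_pool: list[tuple[TransmitterStrategy, ReceiverStrategy]],
    misinfo_pool: list[tuple[TransmitterStrategy, ReceiverStrategy]],
    replicates: int,
    rng: np.random.Generator,
    n_per_type: int = 20,
    n_stories: int = 20,
    population: int = 100_000,
    eta: float = 0.3,
) -> pd.DataFrame:
    """Rank-ordering of engagement-accuracy regression coefficients.

    Each replicate draws ``n_per_type`` pairs (with replacement) from each
    pool, simulates a story sequence per pair, computes the regression
    slope, and sorts the 2 * n_per_type slopes ascending.  Returns one row
    per rank with the replicate-mean slope and the fraction of
    misinformation-type transmitters occupying that rank.
    """
    if not accurate_pool or not misinfo_pool:
        raise ValueError("pools must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    n_ranks = 2 * n_per_type
    slope_sum = np.zeros(n_ranks)
    misinfo_sum = np.zeros(n_ranks)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate sequences contribute slope 0
        for _ in range(replicates):
            slopes = np.empty(n_ranks)
            is_mis = np.zeros(n_ranks, dtype=bool)
            for j in range(n_per_type):
                t, r = accurate_pool[rng.integers(0, len(accurate_pool))]
                slopes[j] = engagement_accuracy_slope(
                    simulate_story_sequence(t, r, n_stories, population, eta, rng)
                )
            for j in range(n_per_type):
                t, r = misinfo_pool[rng.integers(0, len(misinfo_pool))]
                slopes[n_per_type + j] = engagement_accuracy_slope(
                    simulate_story_sequence(t, r, n_stories, population, eta, rng)
                )
                is_mis[n_per_type + j] = True
            order = np.argsort(slopes, kind="stable")
            slope_sum += slopes[order]
            misinfo_sum += is_mis[order]
    return pd.DataFrame(
        {
            "rank": np.arange(1, n_ranks + 1),
            "mean_slope": slope_sum / replicates,
            "fraction_misinformation": misinfo_sum / replicates,
        }
    )


@dataclass(frozen=True)
class SigmoidDemoResult:
    """Summary of the sigmoid-feedback population demonstration."""

    trace: pd.DataFrame
    engage_per_false: float
    engage_per_true: float
    v_f_high_engagement: float
    v_f_low_engagement: float


def sigmoid_demo(
    seed: int = 0,
    rounds: int = 10_000,
    n_receivers: int = 100,
    lam: float = 100.0,
    m_t: float = 0.5,
    m_f: float = 0.25,
    sigma: float = 1.0,
    config: GameConfig | None = None,
    burn_fraction: float = 0.1,
) -> SigmoidDemoResult:
    """Run the sigmoid-feedback transmitter against adapting receivers.

    The transmitter uses r_k^t = 1/(1 + exp[lam (k/N - m_t)]) and r_k^f =
    1/(1 + exp[lam (k/N - m_f)]): it shares true stories while engagement
    is low and switches to false stories once engagement crosses the
    midpoints, with hysteresis between the two rules.  Receivers are
    veracity-blind (a0 = a1 = 0) with attention to payoff ``sigma``.

    The summary (computed after discarding the initial ``burn_fraction`` of
    rounds) reports the mean realized engagement fraction in false-story
    and true-story rounds, and the mean misinformation output in rounds of
    above-median versus below-median engagement.
    """
    transmitter = TransmitterStrategy.sigmoid(lam=lam, m_t=m_t, m_f=m_f)
    config = config or GameConfig(N=n_receivers)
    trace = population_dynamics(
        transmitter,
        n_receivers=n_receivers,
        rounds=rounds,
        config=config,
        sigma=sigma,
        seed=seed,
    )
    start = int(burn_fraction * len(trace))
    t = trace.iloc[start:]
    frac = t["k_engaged"].to_numpy() / n_receivers
    is_false = t["veracity"].to_numpy() == 0
    engage_per_false = float(frac[is_false].mean()) if is_false.any() else float("nan")
    engage_per_true = float(frac[~is_false].mean()) if (~is_false).any() else float("nan")
    median = np.median(frac)
    high = frac > median
    low = frac < median
    v_f_high = float(is_false[high].mean()) if high.any() else float("nan")
    v_f_low = float(is_false[low].mean()) if low.any() else float("nan")
    return SigmoidDemoResult(
        trace=trace,
        engage_per_false=engage_per_false,
        engage_per_true=engage_per_true,
        v_f_high_engagement=v_f_high,
        v_f_low_engagement=v_f_low,
    )
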