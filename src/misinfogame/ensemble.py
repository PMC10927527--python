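"""Random search over viable transmitter strategies.

The search samples linear-feedback transmitter strategies uniformly from
the viable region, lets an inattentive receiver (a0 = 0, attention to
payoff sigma = 1) optimize myopically against each one, and measures the
equilibrium share of false stories ``v_f`` and the per-story engagement
rates ``v_fc/v_f`` and ``v_tc/v_t`` over the measurement window.

Successful *misinformation* strategies are those that share false stories
more often than not (v_f > 0.5) while generating per-false-story engagement
in the top decile of the whole ensemble; successful *accurate* strategies
are defined symmetrically.  Each strategy is then classified by the
structure of the affine constraint it enforces between misinformation
output and engagement (see :func:`classify_enforcement`), in particular
whether at the measured equilibrium it maintains the responsive relation
v_f >= v_fc + v_tc (misinformation) or 1 - v_f >= v_fc + v_tc (accurate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _engine
from .dynamics import OptimizationConfig
from .game_core import GameConfig, ReceiverStrategy, TransmitterStrategy

__all__ = [
    "EnsembleRecord",
    "EnforcementClassification",
    "sample_viable_strategy",
    "run_ensemble",
    "evaluate_strategy",
    "classify_enforcement",
    "select_successful",
    "responsive_proportion",
    "extortion_enrichment",
    "records_to_frame",
    "DELTA_EXTORTION",
]

#: Neighborhood radius (max-norm over alpha, beta, gamma, theta) within
#: which a strategy counts as an extortion strategy.
DELTA_EXTORTION = 0.05


@dataclass(frozen=True)
class EnforcementClassification:
    """Structure of the constraint a strategy enforces on its receivers."""

    enforcement_sign: str  # positive / negative / none
    responsive_misinfo: bool
    responsive_accurate: bool
    extortion_neighbor: bool


@dataclass(frozen=True)
class EnsembleRecord:
    """Per-strategy summary of one ensemble evaluation."""

    strategy: TransmitterStrategy
    v_f: float
    v_t: float
    engage_per_false: float
    engage_per_true: float
    engagement: float
    receiver_payoff: float
    receiver_final: ReceiverStrategy
    has_feedback: bool
    enforcement_sign: str
    responsive_misinfo: bool
    responsive_accurate: bool
    extortion_neighbor: bool


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _sample_params(n: int, with_feedback: bool, rng: np.random.Generator) -> np.ndarray:
    """(n, 4) array of (alpha, beta, gamma, theta), uniform on the viable region."""
    alpha = rng.random(n)
    beta = rng.random(n)
    if with_feedback:
        gamma = rng.uniform(-alpha, 1.0 - alpha)
        theta = rng.uniform(-beta, 1.0 - beta)
    else:
        gamma = np.zeros(n)
        theta = np.zeros(n)
    return np.column_stack([alpha, beta, gamma, theta])


def sample_viable_strategy(
    with_feedback: bool, rng: np.random.Generator
) -> TransmitterStrategy:
    """Draw one viable linear-feedback strategy.

    alpha, beta ~ U[0, 1]; with feedback, gamma ~ U[-alpha, 1-alpha] and
    theta ~ U[-beta, 1-beta] — exactly the intervals on which the linear
    rules stay within [0, 1] for every engagement level.
    """
    a, b, g, t = _sample_params(1, with_feedback, rng)[0]
    return TransmitterStrategy.linear(alpha=a, beta=b, gamma=g, theta=t)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _family_distance(params: np.ndarray, family: np.ndarray) -> float:
    """Min over the family grid of the max-norm distance in (alpha, beta, gamma, theta)."""
    return float(np.abs(family - params[None, :]).max(axis=1).min())


_FAMILY_GRID = np.linspace(0.0, 1.0, 2001)
# Equality-enforcing boundary families of the responsive conditions:
# r+* enforces v_f = v_fc + v_tc identically (alpha=1, gamma=theta=-beta);
# r-* enforces 1 - v_f = v_fc + v_tc identically (beta=0, gamma=theta=1-alpha).
_R_PLUS = np.column_stack(
    [np.ones_like(_FAMILY_GRID), _FAMILY_GRID, -_FAMILY_GRID, -_FAMILY_GRID]
)
_R_MINUS = np.column_stack(
    [_FAMILY_GRID, np.zeros_like(_FAMILY_GRID), 1.0 - _FAMILY_GRID, 1.0 - _FAMILY_GRID]
)


def extortion_distance(strategy: TransmitterStrategy) -> float:
    """Max-norm distance to the nearest equality-enforcing strategy.

    The equality-enforcing families are the boundaries of the two responsive
    conditions: r+* pins v_f = v_fc + v_tc and r-* pins 1 - v_f = v_fc +
    v_tc for every receiver strategy; they play the role that
    zero-determinant extortion strategies play in the iterated prisoner's
    dilemma.
    """
    params = np.array([strategy.alpha, strategy.beta, strategy.gamma, strategy.theta])
    return min(_family_distance(params, _R_PLUS), _family_distance(params, _R_MINUS))


def enforcement_vertices(strategy: TransmitterStrategy) -> np.ndarray:
    """Values of v_f - v_fc - v_tc implied by the enforced constraint at the
    outcome-simplex vertices (v_tc, v_fc) in {(0,0), (1,0), (0,1)}."""
    s = 1.0 - strategy.alpha + strategy.beta
    if s == 0.0:
        raise ValueError("degenerate strategy: 1 - alpha + beta = 0")
    A = 1.0 - strategy.alpha
    out = []
    for x, y in ((0.0, 0.0), (1.0, 0.0), (0.0, 1.0)):
        v_f = (A - strategy.gamma * x - strategy.theta * y) / s
        out.append(v_f - x - y)
    return np.array(out)


def classify_enforcement(
    strategy: TransmitterStrategy,
    outcome: tuple[float, float, float] | None = None,
    delta: float = DELTA_EXTORTION,
) -> EnforcementClassification:
    """Classify the constraint a linear-feedback strategy enforces.

    The enforced relation writes v_f as an affine function of engagement,
    v_f = v_f0 + c_t v_tc + c_f v_fc with c_t = -gamma/s, c_f = -theta/s
    and s = 1 - alpha + beta.  ``enforcement_sign`` is the sign pattern of
    (c_t, c_f): positive when misinformation output rises with engagement.

    The responsive flags record whether the strategy maintains
    v_f >= v_fc + v_tc (misinformation) or 1 - v_f >= v_fc + v_tc
    (accurate).  When ``outcome`` — the measured equilibrium
    (v_f, v_tc, v_fc) — is supplied, the flags are evaluated there, i.e.
    at the operating point the strategy actually drives its receiver to.
    Without an outcome the flags fall back to the strict strategy-only
    criterion that the inequality hold across the whole outcome simplex
    (vertex test); only strategies on or at the equality-enforcing boundary
    families satisfy that for the corners of full engagement, so the strict
    flags are essentially the extortion-boundary membership test.
    """
    s = 1.0 - strategy.alpha + strategy.beta
    if s == 0.0:
        raise ValueError("degenerate strategy: 1 - alpha + beta = 0")
    c_t = -strategy.gamma / s
    c_f = -strategy.theta / s
    tol = 1e-12
    if c_t >= -tol and c_f >= -tol and (c_t > tol or c_f > tol):
        sign = "positive"
    elif c_t <= tol and c_f <= tol and (c_t < -tol or c_f < -tol):
        sign = "negative"
    else:
        sign = "none"

    if outcome is not None:
        v_f, v_tc, v_fc = outcome
        responsive_mis = v_f >= v_fc + v_tc
        responsive_acc = (1.0 - v_f) >= v_fc + v_tc
    else:
        h = enforcement_vertices(strategy)
        responsive_mis = bool(np.all(h >= -1e-9))
        responsive_acc = bool(np.all(-h + (1.0 - 2.0 * np.array([0.0, 1.0, 1.0])) >= -1e-9))
        # 1 - v_f - x - y at the vertices equals -(h) + (1 - 2(x+y))
    neighbor = extortion_distance(strategy) <= delta
    return EnforcementClassification(sign, bool(responsive_mis), bool(responsive_acc), neighbor)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _records_from_batch(
    params: np.ndarray, res: dict[str, np.ndarray], a0: float, a1: float
) -> list[EnsembleRecord]:
    records = []
    for i in range(params.shape[0]):
        a, b, g, t = params[i]
        strategy = TransmitterStrategy.linear(alpha=a, beta=b, gamma=g, theta=t)
        p = res["p_final"][i]
        receiver = ReceiverStrategy(
            a0=a0, a1=a1, p0=p[0], p_ct=p[1], p_cf=p[2], p_nt=p[3], p_nf=p[4]
        )
        v = res["v_mean"][i]
        cls = classify_enforcement(
            strategy, outcome=(float(v[1] + v[3]), float(v[0]), float(v[1]))
        )
        records.append(
            EnsembleRecord(
                strategy=strategy,
                v_f=float(res["v_f"][i]),
                v_t=float(res["v_t"][i]),
                engage_per_false=float(res["engage_per_false"][i]),
                engage_per_true=float(res["engage_per_true"][i]),
                engagement=float(res["engagement"][i]),
                receiver_payoff=float(res["receiver_payoff"][i]),
                receiver_final=receiver,
                has_feedback=strategy.has_feedback,
                enforcement_sign=cls.enforcement_sign,
                responsive_misinfo=cls.responsive_misinfo,
                responsive_accurate=cls.responsive_accurate,
                extortion_neighbor=cls.extortion_neighbor,
            )
        )
    return records


def run_ensemble(
    n: int,
    with_feedback: bool = True,
    config: GameConfig | None = None,
    opt: OptimizationConfig | None = None,
    seed: int = 0,
    a0: float = 0.0,
    a1: float = 1.0,
) -> list[EnsembleRecord]:
    """Evaluate ``n`` randomly sampled viable strategies.

    Defaults follow the study conditions: receiver utilities pi_t = 1,
    pi_f = -1; execution error epsilon = 1e-3; transmitter perception error
    eta = 0.3; single targeted receiver; inattentive receiver (a0 = 0,
    sigma = 1) optimizing its memory-conditioned engagement probabilities
    from the non-engaging strategy q = {0,0,0,0} with 1e4 burn-in and 1e4
    measurement update events.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or GameConfig()
    opt = opt or OptimizationConfig(sigma=1.0, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    params = _sample_params(n, with_feedback, rng)
    # endpoints (rt0, rt1, rf0, rf1) of each linear strategy
    endpoints = np.column_stack(
        [
            params[:, 0],
            params[:, 0] + params[:, 2],
            params[:, 1],
            params[:, 1] + params[:, 3],
        ]
    )
    opt_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    res = _engine.optimize_receivers_batch(
        endpoints,
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
        opt_rng,
    )
    return _records_from_batch(params, res, a0, a1)


def evaluate_strategy(
    strategy: TransmitterStrategy,
    config: GameConfig | None = None,
    opt: OptimizationConfig | None = None,
    a0: float = 0.0,
    a1: float = 1.0,
) -> EnsembleRecord:
    """Evaluate a single strategy under the ensemble protocol."""
    config = config or GameConfig()
    opt = opt or OptimizationConfig(sigma=1.0)
    params = np.array(
        [[strategy.alpha, strategy.beta, strategy.gamma, strategy.theta]], dtype=float
    )
    endpoints = np.array([strategy.endpoints(1)], dtype=float)
    rng = np.random.default_rng(opt.seed)
    res = _engine.optimize_receivers_batch(
        endpoints,
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
    return _records_from_batch(params, res, a0, a1)[0]


# ---------------------------------------------------------------------------
# selection and summaries
# ---------------------------------------------------------------------------


def select_successful(
    records: list[EnsembleRecord],
    type: str,
    top_fraction: float = 0.1,
    share_threshold: float = 0.5,
) -> list[EnsembleRecord]:
    """Successful strategies of the requested type.

    Misinformation: v_f > ``share_threshold`` and per-false-story engagement
    at or above the (1 - ``top_fraction``) quantile of per-false-story
    engagement over *all* records; accurate strategies symmetrically.  The
    quantile uses the 'higher' convention so that at most
    ceil(top_fraction * n) records can pass the engagement criterion in the
    presence of ties.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if type == "misinformation":
        share = np.array([r.v_f for r in records])
        engage = np.array([r.engage_per_false for r in records])
    elif type == "accurate":
        share = np.array([r.v_t for r in records])
        engage = np.array([r.engage_per_true for r in records])
    else:
        raise ValueError("type must be 'misinformation' or 'accurate'")
    finite = engage[np.isfinite(engage)]
    if finite.size == 0:
        return []
    cutoff = np.quantile(finite, 1.0 - top_fraction, method="higher")
    keep = (share > share_threshold) & np.isfinite(engage) & (engage >= cutoff)
    return [r for r, k in zip(records, keep) if k]


def responsive_proportion(successful: list[EnsembleRecord], type: str) -> float:
    """Percentage of successful strategies whose equilibrium satisfies the
    responsive relation of the given type."""
    if not successful:
        raise ValueError("successful must be non-empty")
    if type == "misinformation":
        flags = [r.responsive_misinfo for r in successful]
    elif type == "accurate":
        flags = [r.responsive_accurate for r in successful]
    else:
        raise ValueError("type must be 'misinformation' or 'accurate'")
    return 100.0 * float(np.mean(flags))


def extortion_enrichment(
    records: list[EnsembleRecord], successful: list[EnsembleRecord]
) -> tuple[float, float, float]:
    """One-sided binomial test of extortion-neighbor enrichment.

    Compares the prevalence of extortion-neighborhood strategies among the
    successful set against the null prevalence with which such strategies
    are drawn in the full ensemble.  Returns (prevalence_in_successful,
    null_prevalence, p_value).
    """
    if not records or not successful:
        raise ValueError("records and successful must be non-empty")
    null_prev = float(np.mean([r.extortion_neighbor for r in records]))
    k = int(sum(r.extortion_neighbor for r in successful))
    n = len(successful)
    p_null = min(max(null_prev, 1e-12), 1.0 - 1e-12)
    p = sps.binomtest(k, n, p_null, alternative="greater").pvalue
    return k / n, null_prev, float(p)


def records_to_frame(records: list[EnsembleRecord]) -> pd.DataFrame:
    """One row per record, suitable for CSV export."""
    rows = []
    for r in records:
        s = r.strategy
        rows.append(
            {
                "alpha": s.alpha,
                "beta": s.beta,
                "gamma": s.gamma,
                "theta": s.theta,
                "v_f": r.v_f,
                "v_t": r.v_t,
                "engage_per_false": r.engage_per_false,
                "engage_per_true": r.engage_per_true,
                "engagement": r.engagement,
                "receiver_payoff": r.receiver_payoff,
                "has_feedback": r.has_feedback,
                "enforcement_sign": r.enforcement_sign,
                "responsive_misinfo": r.responsive_misinfo,
                "responsive_accurate": r.responsive_accurate,
                "extortion_neighbor": r.extortion_neighbor,
                "receiver_p0": r.receiver_final.p0,
                "receiver_p_ct": r.receiver_final.p_ct,
                "receiver_p_cf": r.receiver_final.p_cf,
                "receiver_p_nt": r.receiver_final.p_nt,
                "receiver_p_nf": r.receiver_final.p_nf,
            }
        )
    return pd.DataFrame(rows)
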