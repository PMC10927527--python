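"""Core objects of the misinformation game.

The misinformation game is an asymmetric, infinitely repeated game between a
news *transmitter*, who each round shares a story that is either true or
false, and one or more *receivers*, who decide whether to engage with each
story.  A transmitter strategy sets the probability that the next story is
true as a function of the previous story's veracity and of the engagement it
received; a receiver strategy sets the probability of engaging as a function
of attention to the current story's veracity and memory of the previous
interaction with the source.

For a single receiver the joint process is a four-state Markov chain over
(previous engagement, previous veracity) pairs, ordered here as
``[(c,t), (c,f), (n,t), (n,f)]`` where ``c``/``n`` mark engagement /
non-engagement and ``t``/``f`` true / false.  Its stationary distribution
``v = (v_tc, v_tn, v_fc, v_fn)`` gives the long-run frequencies of
(veracity, engagement) outcomes, from which all payoffs are computed.

A transmitter strategy with linear (or polynomial) engagement feedback
unilaterally enforces an affine relationship between the share of false
stories ``v_f`` and the receiver's engagement frequencies ``v_tc`` and
``v_fc`` that holds for *any* receiver strategy:

    v_f = (1 - alpha)/(1 - alpha + beta)
          - theta/(1 - alpha + beta) * v_fc
          - gamma/(1 - alpha + beta) * v_tc

This is the analogue, for this asymmetric game, of the linear payoff
constraints enforced by zero-determinant strategies in the iterated
prisoner's dilemma.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "STATES",
    "TransmitterStrategy",
    "ReceiverStrategy",
    "GameConfig",
    "StationaryDistribution",
    "transmit_prob",
    "engage_prob",
    "transition_matrix",
    "stationary_distribution",
    "exact_stationary",
    "simulate_rounds",
    "payoffs",
    "enforced_constraint_residual",
]

#: Ordered state space of the single-receiver chain: (engagement, veracity)
#: of the previous round.
STATES: tuple[tuple[str, str], ...] = (("c", "t"), ("c", "f"), ("n", "t"), ("n", "f"))

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}

# Sentinel below which a marginal is treated as empty when forming per-story
# engagement rates.
_MARGINAL_FLOOR = 1e-9


def _check_unit(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def _sigmoid(x: float) -> float:
    # Logistic function with a saturating exponent to avoid overflow.
    if x >= 0:
        z = math.exp(-min(x, 700.0))
        return 1.0 / (1.0 + z)
    z = math.exp(min(x, 700.0))
    return z / (1.0 + z)


@dataclass(frozen=True)
class TransmitterStrategy:
    """A rule mapping (previous veracity, engagement count) to P(next true).

    Two functional forms are supported.  The *polynomial* form is

        r_k^t = alpha + sum_l gamma_l (k/N)^l
        r_k^f = beta  + sum_l theta_l (k/N)^l

    where ``r_k^t`` (``r_k^f``) is the probability of sharing a true story
    given the previous story was true (false) and ``k`` of ``N`` receivers
    engaged with it.  The *sigmoid* form is

        r_k^t = 1 / (1 + exp[lam (k/N - m_t)]),
        r_k^f = 1 / (1 + exp[lam (k/N - m_f)]).

    A polynomial strategy is *viable* when both rules stay inside [0, 1] for
    every integer k in 0..N; linear strategies are viable for every N as
    soon as the two endpoints k=0 and k=N are, which is enforced at
    construction.
    """

    alpha: float
    beta: float
    gamma_coeffs: tuple[float, ...] = ()
    theta_coeffs: tuple[float, ...] = ()
    form: str = "polynomial"
    sigmoid_params: tuple[float, float, float] | None = None  # (lam, m_t, m_f)
    check_N: int = field(default=100, compare=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma_coeffs", tuple(float(g) for g in self.gamma_coeffs))
        object.__setattr__(self, "theta_coeffs", tuple(float(t) for t in self.theta_coeffs))
        if self.form == "polynomial":
            _check_unit("alpha", self.alpha)
            _check_unit("beta", self.beta)
            if not self.is_viable(self.check_N):
                raise ValueError(
                    "non-viable polynomial strategy: r_k must stay in [0, 1] "
                    f"for all k in 0..{self.check_N}"
                )
        elif self.form == "sigmoid":
            if self.sigmoid_params is None or len(self.sigmoid_params) != 3:
                raise ValueError("sigmoid form requires sigmoid_params=(lam, m_t, m_f)")
        else:
            raise ValueError(f"unknown form {self.form!r}")

    # -- derived quantities -------------------------------------------------

    @property
    def gamma(self) -> float:
        """Total feedback weight on previously-true stories, gamma = sum_l gamma_l."""
        return float(sum(self.gamma_coeffs))

    @property
    def theta(self) -> float:
        """Total feedback weight on previously-false stories, theta = sum_l theta_l."""
        return float(sum(self.theta_coeffs))

    @property
    def has_feedback(self) -> bool:
        return any(g != 0.0 for g in self.gamma_coeffs) or any(
            t != 0.0 for t in self.theta_coeffs
        )

    # -- constructors -------------------------------------------------------

    @classmethod
    def linear(
        cls, alpha: float, beta: float, gamma: float = 0.0, theta: float = 0.0
    ) -> "TransmitterStrategy":
        """Linear-feedback strategy r_k^t = alpha + gamma k/N, r_k^f = beta + theta k/N."""
        return cls(alpha=alpha, beta=beta, gamma_coeffs=(gamma,), theta_coeffs=(theta,), check_N=1)

    @classmethod
    def sigmoid(cls, lam: float, m_t: float, m_f: float) -> "TransmitterStrategy":
        """Sigmoidal feedback with steepness ``lam`` and midpoints ``m_t``, ``m_f``."""
        return cls(alpha=0.0, beta=0.0, form="sigmoid", sigmoid_params=(lam, m_t, m_f))

    # -- evaluation ---------------------------------------------------------

    def rate(self, prev_veracity: str, k: int, N: int) -> float:
        return transmit_prob(self, prev_veracity, k, N)

    def endpoints(self, N: int = 1) -> tuple[float, float, float, float]:
        """(r_0^t, r_N^t, r_0^f, r_N^f): the rules at zero and full engagement."""
        return (
            transmit_prob(self, "t", 0, N),
            transmit_prob(self, "t", N, N),
            transmit_prob(self, "f", 0, N),
            transmit_prob(self, "f", N, N),
        )

    def is_viable(self, N: int) -> bool:
        """Check r_k^t, r_k^f in [0, 1] on the integer grid k = 0..N."""
        if self.form == "sigmoid":
            return True
        x = np.arange(N + 1) / N
        tol = 1e-12
        for base, coeffs in ((self.alpha, self.gamma_coeffs), (self.beta, self.theta_coeffs)):
            r = np.full_like(x, base)
            for l, c in enumerate(coeffs, start=1):
                r = r + c * x**l
            if r.min() < -tol or r.max() > 1.0 + tol:
                return False
        return True

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma_coeffs": list(self.gamma_coeffs),
            "theta_coeffs": list(self.theta_coeffs),
            "form": self.form,
            "sigmoid_params": list(self.sigmoid_params) if self.sigmoid_params else None,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "TransmitterStrategy":
        sp = d.get("sigmoid_params")
        return cls(
            alpha=d["alpha"],
            beta=d["beta"],
            gamma_coeffs=tuple(d.get("gamma_coeffs", ())),
            theta_coeffs=tuple(d.get("theta_coeffs", ())),
            form=d.get("form", "polynomial"),
            sigmoid_params=tuple(sp) if sp else None,
            check_N=d.get("check_N", 100) if d.get("form", "polynomial") == "polynomial" else 100,
        )

    @classmethod
    def from_json(cls, s: str) -> "TransmitterStrategy":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class ReceiverStrategy:
    """Attention weights and behavioral engagement probabilities.

    With probability ``a0`` the receiver assesses the current story's
    veracity directly and engages iff it is true.  Otherwise, with
    probability ``a1`` they fall back on memory of the previous round,
    engaging with probability ``p_ij`` indexed by previous engagement
    (``c``/``n``) and previous veracity (``t``/``f``); with the remaining
    probability they engage at the baseline rate ``p0``.
    """

    a0: float = 0.0
    a1: float = 0.0
    p0: float = 0.0
    p_ct: float = 0.0
    p_cf: float = 0.0
    p_nt: float = 0.0
    p_nf: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a0", "a1", "p0", "p_ct", "p_cf", "p_nt", "p_nf"):
            _check_unit(name, getattr(self, name))

    @classmethod
    def non_engaging(cls, a0: float = 0.0, a1: float = 0.0) -> "ReceiverStrategy":
        """The all-zero behavioral strategy q = {0,0,0,0}: never engage."""
        return cls(a0=a0, a1=a1)

    def p(self, prev_engaged: str, prev_veracity: str) -> float:
        return getattr(self, f"p_{prev_engaged}{prev_veracity}")

    def behavior_vector(self) -> np.ndarray:
        """(p0, p_ct, p_cf, p_nt, p_nf) as an array."""
        return np.array([self.p0, self.p_ct, self.p_cf, self.p_nt, self.p_nf])

    def to_dict(self) -> dict:
        return {
            "a0": self.a0,
            "a1": self.a1,
            "p0": self.p0,
            "p_ct": self.p_ct,
            "p_cf": self.p_cf,
            "p_nt": self.p_nt,
            "p_nf": self.p_nf,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "ReceiverStrategy":
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "ReceiverStrategy":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class GameConfig:
    """Payoffs, noise rates and audience size of the repeated game.

    ``pi_t``/``pi_f`` are the receiver's utilities per engaged true/false
    story; ``b_t``/``b_f`` the transmitter's benefits per engaged true/false
    story.  ``epsilon`` is the execution-error probability (an intended
    action — the veracity choice, or each receiver's engagement decision —
    is flipped independently with this probability); ``eta`` is the
    transmitter's perception error (the memory of the previous story's
    veracity is flipped when choosing between the two rules).  ``N`` is the
    number of targeted receivers; N=1 corresponds to perfect microtargeting.
    """

    pi_t: float = 1.0
    pi_f: float = -1.0
    b_t: float = 0.0
    b_f: float = 1.0
    epsilon: float = 1e-3
    eta: float = 0.3
    N: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon <= 0.5):
            raise ValueError("epsilon must lie in [0, 0.5]")
        if not (0.0 <= self.eta <= 0.5):
            raise ValueError("eta must lie in [0, 0.5]")
        if self.N < 1:
            raise ValueError("N must be >= 1")


@dataclass(frozen=True)
class StationaryDistribution:
    """Long-run outcome frequencies v = (v_tc, v_tn, v_fc, v_fn)."""

    v_tc: float
    v_tn: float
    v_fc: float
    v_fn: float

    def __post_init__(self) -> None:
        vals = (self.v_tc, self.v_tn, self.v_fc, self.v_fn)
        if min(vals) < -1e-9:
            raise ValueError(f"negative outcome frequency in {vals}")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"outcome frequencies must sum to 1, got {sum(vals)!r}")

    @property
    def v_t(self) -> float:
        """Long-run share of true stories."""
        return self.v_tc + self.v_tn

    @property
    def v_f(self) -> float:
        """Long-run share of false stories."""
        return self.v_fc + self.v_fn

    @property
    def engagement(self) -> float:
        """Overall engagement rate v_tc + v_fc."""
        return self.v_tc + self.v_fc

    @property
    def engage_per_true(self) -> float:
        """Engagement probability per true story, v_tc / v_t (NaN if v_t ~ 0)."""
        return self.v_tc / self.v_t if self.v_t >= _MARGINAL_FLOOR else float("nan")

    @property
    def engage_per_false(self) -> float:
        """Engagement probability per false story, v_fc / v_f (NaN if v_f ~ 0)."""
        return self.v_fc / self.v_f if self.v_f >= _MARGINAL_FLOOR else float("nan")

    def as_array(self) -> np.ndarray:
        """Frequencies in chain-state order [(c,t), (c,f), (n,t), (n,f)]."""
        return np.array([self.v_tc, self.v_fc, self.v_tn, self.v_fn])

    @classmethod
    def from_state_probs(cls, pi: np.ndarray) -> "StationaryDistribution":
        """Build from probabilities over STATES order [(c,t),(c,f),(n,t),(n,f)]."""
        pi = np.asarray(pi, dtype=float)
        pi = np.clip(pi, 0.0, None)
        pi = pi / pi.sum()
        return cls(v_tc=float(pi[0]), v_fc=float(pi[1]), v_tn=float(pi[2]), v_fn=float(pi[3]))


# ---------------------------------------------------------------------------
# per-round action probabilities
# ---------------------------------------------------------------------------


def transmit_prob(strategy: TransmitterStrategy, prev_veracity: str, k: int, N: int) -> float:
    """P(next story true | previous veracity, k of N receivers engaged)."""
    if prev_veracity not in ("t", "f"):
        raise ValueError("prev_veracity must be 't' or 'f'")
    if not (0 <= k <= N):
        raise ValueError(f"k must lie in 0..N, got k={k}, N={N}")
    x = k / N
    if strategy.form == "sigmoid":
        lam, m_t, m_f = strategy.sigmoid_params
        m = m_t if prev_veracity == "t" else m_f
        return _sigmoid(-lam * (x - m))
    base = strategy.alpha if prev_veracity == "t" else strategy.beta
    coeffs = strategy.gamma_coeffs if prev_veracity == "t" else strategy.theta_coeffs
    r = base + sum(c * x**l for l, c in enumerate(coeffs, start=1))
    # viable strategies stay in [0,1] on the integer grid; clip rounding dust
    return float(min(1.0, max(0.0, r)))


def engage_prob(
    receiver: ReceiverStrategy, prev_engaged: str, prev_veracity: str, cur_veracity: str
) -> float:
    """Engagement probability q_ij^m = a0 d_mt + (1-a0)(1-a1) p0 + (1-a0) a1 p_ij."""
    if prev_engaged not in ("c", "n"):
        raise ValueError("prev_engaged must be 'c' or 'n'")
    if prev_veracity not in ("t", "f") or cur_veracity not in ("t", "f"):
        raise ValueError("veracity labels must be 't' or 'f'")
    delta = 1.0 if cur_veracity == "t" else 0.0
    return (
        receiver.a0 * delta
        + (1.0 - receiver.a0) * (1.0 - receiver.a1) * receiver.p0
        + (1.0 - receiver.a0) * receiver.a1 * receiver.p(prev_engaged, prev_veracity)
    )


# ---------------------------------------------------------------------------
# single-receiver Markov chain
# ---------------------------------------------------------------------------


def _flip(p: float, eps: float) -> float:
    return p * (1.0 - 2.0 * eps) + eps


def transition_matrix(
    transmitter: TransmitterStrategy, receiver: ReceiverStrategy, config: GameConfig
) -> np.ndarray:
    """Row-stochastic 4x4 transition matrix of the single-receiver chain.

    States are ordered as in :data:`STATES`.  From state (i, j): with
    probability ``eta`` the transmitter's memory of j is flipped before
    selecting the rule; the chosen veracity action is then flipped with
    probability ``epsilon``, as is the receiver's engagement action.
    """
    if config.N != 1:
        raise ValueError("transition_matrix supports N=1 only; use simulate_rounds for N>1")
    eps, eta = config.epsilon, config.eta
    T = np.zeros((4, 4))
    for si, (i, j) in enumerate(STATES):
        k = 1 if i == "c" else 0
        other = "f" if j == "t" else "t"
        p_true = (1.0 - eta) * transmit_prob(transmitter, j, k, 1) + eta * transmit_prob(
            transmitter, other, k, 1
        )
        p_true = _flip(p_true, eps)
        for m, p_m in (("t", p_true), ("f", 1.0 - p_true)):
            q = _flip(engage_prob(receiver, i, j, m), eps)
            T[si, _STATE_INDEX[("c", m)]] += p_m * q
            T[si, _STATE_INDEX[("n", m)]] += p_m * (1.0 - q)
    return T


def stationary_distribution(
    matrix: np.ndarray, reducible: str = "error"
) -> StationaryDistribution:
    """Stationary distribution of a 4x4 row-stochastic matrix.

    For a chain with a unique stationary distribution this solves the
    linear system pi (T - I) = 0 with the normalization sum(pi) = 1.  When
    the chain has several recurrent classes (possible only at epsilon = 0),
    the default is to raise; with ``reducible="cesaro"`` the Cesaro limit
    of the chain started from the uniform distribution is returned instead.
    """
    T = np.asarray(matrix, dtype=float)
    if T.shape != (4, 4):
        raise ValueError("expected a 4x4 matrix")
    if np.abs(T.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValueError("matrix rows must sum to 1")
    eigvals = np.linalg.eigvals(T)
    n_unit = int(np.sum(np.abs(eigvals - 1.0) < 1e-9))
    if n_unit > 1:
        if reducible == "cesaro":
            return _cesaro_limit(T)
        raise ValueError(
            "chain has multiple recurrent classes; set epsilon > 0 or pass "
            "reducible='cesaro' for the uniform-start Cesaro limit"
        )
    A = T.T - np.eye(4)
    A[3, :] = 1.0
    pi = np.linalg.solve(A, np.array([0.0, 0.0, 0.0, 1.0]))
    return StationaryDistribution.from_state_probs(pi)


def _cesaro_limit(T: np.ndarray, tol: float = 1e-12, max_iter: int = 10**6) -> StationaryDistribution:
    mu = np.full(4, 0.25)
    avg = np.zeros(4)
    prev = None
    for n in range(1, max_iter + 1):
        avg += (mu - avg) / n
        if prev is not None and np.abs(avg - prev).max() < tol:
            break
        prev = avg.copy()
        mu = mu @ T
    return StationaryDistribution.from_state_probs(avg)


def exact_stationary(
    transmitter: TransmitterStrategy,
    receiver: ReceiverStrategy,
    config: GameConfig,
    reducible: str = "error",
) -> StationaryDistribution:
    """Stationary outcome frequencies of a fixed strategy pair (N=1)."""
    return stationary_distribution(transition_matrix(transmitter, receiver, config), reducible)


# ---------------------------------------------------------------------------
# finite simulation (any N)
# ---------------------------------------------------------------------------


def simulate_rounds(
    transmitter: TransmitterStrategy,
    receivers: Sequence[ReceiverStrategy],
    config: GameConfig,
    T: int,
    seed: int,
) -> tuple[list[StationaryDistribution], np.ndarray]:
    """Simulate ``T`` rounds of the game against ``len(receivers)`` receivers.

    Each round the transmitter observes the engagement count ``k`` of the
    previous story and its (eta-perceived) veracity, draws the next story's
    veracity, and each receiver independently draws engagement from its own
    (previous engagement, previous veracity) state; both actions carry an
    epsilon execution-error flip.  The first round starts from state (n, t).

    Returns per-receiver empirical outcome frequencies and the trace as an
    integer array with columns (round, veracity[1=true], k_engaged).
    """
    if len(receivers) == 0:
        raise ValueError("need at least one receiver")
    if len(receivers) != config.N:
        raise ValueError(f"len(receivers)={len(receivers)} must equal config.N={config.N}")
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    N = config.N
    eps, eta = config.epsilon, config.eta

    # receiver engagement probabilities per (i, j, m), per receiver
    q = np.empty((N, 2, 2, 2))  # [receiver, i(c=1/n=0), j(t=1/f=0), m(t=1/f=0)]
    for r_idx, rec in enumerate(receivers):
        for i_bit, i in ((1, "c"), (0, "n")):
            for j_bit, j in ((1, "t"), (0, "f")):
                for m_bit, m in ((1, "t"), (0, "f")):
                    q[r_idx, i_bit, j_bit, m_bit] = _flip(engage_prob(rec, i, j, m), eps)

    engaged = np.zeros(N, dtype=bool)  # previous-round engagement, start (n, t)
    veracity = True
    counts = np.zeros((N, 2, 2), dtype=np.int64)  # [receiver, veracity, engaged]
    trace = np.empty((T, 3), dtype=np.int64)
    for t in range(T):
        k = int(engaged.sum())
        perceived = veracity if rng.random() >= eta else not veracity
        p_true = transmit_prob(transmitter, "t" if perceived else "f", k, N)
        next_true = rng.random() < p_true
        if rng.random() < eps:
            next_true = not next_true
        m_bit = 1 if next_true else 0
        probs = q[np.arange(N), engaged.astype(int), int(veracity), m_bit]
        next_engaged = rng.random(N) < probs
        counts[np.arange(N), m_bit, next_engaged.astype(int)] += 1
        trace[t] = (t, m_bit, int(next_engaged.sum()))
        engaged = next_engaged
        veracity = next_true

    out = []
    for r_idx in range(N):
        c = counts[r_idx] / T
        out.append(
            StationaryDistribution(
                v_tc=float(c[1, 1]), v_tn=float(c[1, 0]), v_fc=float(c[0, 1]), v_fn=float(c[0, 0])
            )
        )
    return out, trace


# ---------------------------------------------------------------------------
# payoffs and the enforced constraint
# ---------------------------------------------------------------------------


def payoffs(v: StationaryDistribution, config: GameConfig) -> tuple[float, float]:
    """Per-round expected payoffs (receiver, transmitter); non-engagement pays 0."""
    receiver = config.pi_t * v.v_tc + config.pi_f * v.v_fc
    transmitter = config.b_t * v.v_tc + config.b_f * v.v_fc
    return receiver, transmitter


def enforced_constraint_residual(
    transmitter: TransmitterStrategy, v: StationaryDistribution
) -> float:
    """Residual of the enforced affine constraint at the outcome ``v``.

    Returns ``v_f - [(1-alpha)/(1-alpha+beta) - theta/(1-alpha+beta) v_fc
    - gamma/(1-alpha+beta) v_tc]``.  For any receiver strategy the exact
    stationary distribution at epsilon = eta = 0 gives a zero residual.
    """
    if transmitter.form != "polynomial":
        raise ValueError("the enforced constraint applies to polynomial strategies")
    s = 1.0 - transmitter.alpha + transmitter.beta
    if s == 0.0:
        raise ValueError("degenerate strategy: 1 - alpha + beta = 0")
    predicted = (
        (1.0 - transmitter.alpha) - transmitter.theta * v.v_fc - transmitter.gamma * v.v_tc
    ) / s
    return v.v_f - predicted
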