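"""Vectorized numerics for myopic strategy optimization.

Everything here operates on batches: a batch is either many transmitter
strategies whose receivers optimize in lockstep (the ensemble search), or
many replicates of a co-optimizing pair (region scans).  Each batch element
is an independent single-receiver game; its exact 4-state stationary
distribution is obtained from a batched linear solve, so one "update event"
for the whole batch costs one (B, 4, 4) solve.

The public modules (:mod:`misinfogame.dynamics`, :mod:`misinfogame.ensemble`)
wrap these routines with the domain-level API.
"""

from __future__ import annotations

import numpy as np

# state order matches game_core.STATES: [(c,t), (c,f), (n,t), (n,f)]

_B_IDENTITY = np.eye(4)


def reflect_unit(x: np.ndarray) -> np.ndarray:
    """Reflect values into [0, 1] (billiard boundary)."""
    x = np.abs(x)
    x = np.remainder(x, 2.0)
    return np.where(x > 1.0, 2.0 - x, x)


def fermi_probability(w_current: np.ndarray, w_candidate: np.ndarray, sigma: float) -> np.ndarray:
    """Acceptance probability 1 / (1 + exp[sigma (w_current - w_candidate)])."""
    z = np.clip(sigma * (np.asarray(w_current) - np.asarray(w_candidate)), -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(z))


def receiver_q(p: np.ndarray, a0: float, a1: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-state engagement probabilities (q_true, q_false), each (B, 4).

    ``p`` is (B, 5) = (p0, p_ct, p_cf, p_nt, p_nf); columns 1..4 follow the
    chain state order.
    """
    base = (1.0 - a0) * (1.0 - a1) * p[:, 0:1] + (1.0 - a0) * a1 * p[:, 1:5]
    return a0 + base, base.copy()


def build_transition(
    rt0: np.ndarray,
    rt1: np.ndarray,
    rf0: np.ndarray,
    rf1: np.ndarray,
    q_t: np.ndarray,
    q_f: np.ndarray,
    eps: float,
    eta: float,
) -> np.ndarray:
    """Batched 4x4 transition matrices, shape (B, 4, 4).

    ``rt0..rf1`` are the transmitter rules at k=0 and k=1 (N=1), shape (B,).
    ``q_t``/``q_f`` are the receiver's engagement probabilities per source
    state for a true/false current story, shape (B, 4).
    """
    B = rt0.shape[0]
    # eta flips the transmitter's memory of the previous story's veracity
    pt = np.empty((B, 4))
    pt[:, 0] = (1.0 - eta) * rt1 + eta * rf1  # from (c, t)
    pt[:, 1] = (1.0 - eta) * rf1 + eta * rt1  # from (c, f)
    pt[:, 2] = (1.0 - eta) * rt0 + eta * rf0  # from (n, t)
    pt[:, 3] = (1.0 - eta) * rf0 + eta * rt0  # from (n, f)
    pt = pt * (1.0 - 2.0 * eps) + eps
    qt = q_t * (1.0 - 2.0 * eps) + eps
    qf = q_f * (1.0 - 2.0 * eps) + eps
    T = np.empty((B, 4, 4))
    T[:, :, 0] = pt * qt
    T[:, :, 1] = (1.0 - pt) * qf
    T[:, :, 2] = pt * (1.0 - qt)
    T[:, :, 3] = (1.0 - pt) * (1.0 - qf)
    return T


def stationary_batch(T: np.ndarray) -> np.ndarray:
    """Stationary distributions of batched 4x4 row-stochastic matrices, (B, 4)."""
    A = np.swapaxes(T, 1, 2) - _B_IDENTITY
    A[:, 3, :] = 1.0
    b = np.zeros((T.shape[0], 4, 1))
    b[:, 3, 0] = 1.0
    pi = np.linalg.solve(A, b)[:, :, 0]
    np.clip(pi, 0.0, None, out=pi)
    pi /= pi.sum(axis=1, keepdims=True)
    return pi


def receiver_payoff(v: np.ndarray, pi_t: float, pi_f: float) -> np.ndarray:
    return pi_t * v[:, 0] + pi_f * v[:, 1]


def transmitter_payoff(v: np.ndarray, b_t: float, b_f: float) -> np.ndarray:
    return b_t * v[:, 0] + b_f * v[:, 1]


def free_receiver_components(a0: float, a1: float) -> list[int]:
    """Indices into (p0, p_ct, p_cf, p_nt, p_nf) that affect behavior.

    Attention weights gate which behavioral probabilities can ever be
    expressed: with a1 = 1 the baseline p0 is never used, with a1 = 0 the
    memory-conditioned entries are never used.  Proposals are restricted to
    expressed components so that every update event explores the strategy
    space actually available to the receiver.
    """
    w0 = (1.0 - a0) * (1.0 - a1)
    wm = (1.0 - a0) * a1
    free = []
    if w0 > 0.0:
        free.append(0)
    if wm > 0.0:
        free.extend([1, 2, 3, 4])
    return free or [0]


class _MeasureAccumulator:
    def __init__(self, B: int):
        self.v_sum = np.zeros((B, 4))
        self.w_sum = np.zeros(B)
        self.n = 0

    def add(self, v: np.ndarray, w: np.ndarray) -> None:
        self.v_sum += v
        self.w_sum += w
        self.n += 1

    def summary(self) -> dict[str, np.ndarray]:
        v = self.v_sum / self.n
        v_t = v[:, 0] + v[:, 2]
        v_f = v[:, 1] + v[:, 3]
        with np.errstate(invalid="ignore", divide="ignore"):
            ept = np.where(v_t >= 1e-9, v[:, 0] / v_t, np.nan)
            epf = np.where(v_f >= 1e-9, v[:, 1] / v_f, np.nan)
        return {
            "v_mean": v,
            "v_t": v_t,
            "v_f": v_f,
            "engagement": v[:, 0] + v[:, 1],
            "engage_per_true": ept,
            "engage_per_false": epf,
            "receiver_payoff": self.w_sum / self.n,
        }


def optimize_receivers_batch(
    endpoints: np.ndarray,
    a0: float,
    a1: float,
    pi_t: float,
    pi_f: float,
    eps: float,
    eta: float,
    sigma: float,
    proposal_scale: float,
    proposal_kind: str,
    burn_in: int,
    measure: int,
    rng: np.random.Generator,
    p_init: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Myopic noisy receiver optimization against fixed transmitters.

    ``endpoints`` is (B, 4) = (rt0, rt1, rf0, rf1) per transmitter.  Each
    update event proposes a change to one expressed behavioral component,
    evaluates the exact stationary payoff of current and candidate
    strategies, and accepts via the Fermi rule.  Measured quantities are
    averages of the *current* pair's stationary outcome over the
    measurement window, so slow receiver drift contributes covariance
    between engagement and veracity exactly as in the underlying process.
    """
    endpoints = np.asarray(endpoints, dtype=float)
    B = endpoints.shape[0]
    rt0, rt1, rf0, rf1 = endpoints.T
    free = free_receiver_components(a0, a1)
    p = np.zeros((B, 5)) if p_init is None else np.array(p_init, dtype=float)

    def solve(p_mat: np.ndarray) -> np.ndarray:
        q_t, q_f = receiver_q(p_mat, a0, a1)
        return stationary_batch(build_transition(rt0, rt1, rf0, rf1, q_t, q_f, eps, eta))

    v_cur = solve(p)
    w_cur = receiver_payoff(v_cur, pi_t, pi_f)
    acc = _MeasureAccumulator(B)
    rows = np.arange(B)
    n_accepted = 0
    for event in range(burn_in + measure):
        comp = np.asarray(free)[rng.integers(0, len(free), size=B)]
        if proposal_kind == "local":
            delta = rng.uniform(-proposal_scale, proposal_scale, size=B)
            cand_val = reflect_unit(p[rows, comp] + delta)
        else:
            cand_val = rng.random(B)
        p_cand = p.copy()
        p_cand[rows, comp] = cand_val
        v_cand = solve(p_cand)
        w_cand = receiver_payoff(v_cand, pi_t, pi_f)
        accept = rng.random(B) < fermi_probability(w_cur, w_cand, sigma)
        p[accept] = p_cand[accept]
        v_cur[accept] = v_cand[accept]
        w_cur[accept] = w_cand[accept]
        n_accepted += int(accept.sum())
        if event >= burn_in:
            acc.add(v_cur, w_cur)
    out = acc.summary()
    out["p_final"] = p
    out["accept_rate"] = n_accepted / ((burn_in + measure) * B)
    return out


def co_optimize_batch(
    endpoints_init: np.ndarray,
    p_init: np.ndarray,
    a0: float,
    a1: float,
    pi_t: float,
    pi_f: float,
    b_t: float,
    b_f: float,
    eps: float,
    eta: float,
    sigma_R: float,
    sigma_T: float,
    scale_R: float,
    scale_T: float,
    burn_in: int,
    measure: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Joint receiver/transmitter optimization, batched over replicates.

    Per time-step the receiver updates first, then the transmitter.  The
    transmitter explores the viable linear-feedback space through its four
    endpoint rules (rt0, rt1, rf0, rf1), each perturbed locally and
    reflected into [0, 1]; any endpoint combination is a viable strategy.
    """
    ep = np.array(endpoints_init, dtype=float)
    p = np.array(p_init, dtype=float)
    B = ep.shape[0]
    free = free_receiver_components(a0, a1)
    rows = np.arange(B)

    def solve(ep_mat: np.ndarray, p_mat: np.ndarray) -> np.ndarray:
        q_t, q_f = receiver_q(p_mat, a0, a1)
        return stationary_batch(
            build_transition(ep_mat[:, 0], ep_mat[:, 1], ep_mat[:, 2], ep_mat[:, 3], q_t, q_f, eps, eta)
        )

    v_cur = solve(ep, p)
    wR = receiver_payoff(v_cur, pi_t, pi_f)
    wT = transmitter_payoff(v_cur, b_t, b_f)
    acc = _MeasureAccumulator(B)
    for step in range(burn_in + measure):
        # receiver update event
        comp = np.asarray(free)[rng.integers(0, len(free), size=B)]
        cand_val = reflect_unit(p[rows, comp] + rng.uniform(-scale_R, scale_R, size=B))
        p_cand = p.copy()
        p_cand[rows, comp] = cand_val
        v_cand = solve(ep, p_cand)
        wR_cand = receiver_payoff(v_cand, pi_t, pi_f)
        accept = rng.random(B) < fermi_probability(wR, wR_cand, sigma_R)
        p[accept] = p_cand[accept]
        v_cur[accept] = v_cand[accept]
        wR[accept] = wR_cand[accept]
        wT[accept] = transmitter_payoff(v_cand, b_t, b_f)[accept]

        # transmitter update event
        comp_t = rng.integers(0, 4, size=B)
        cand_ep = ep.copy()
        cand_ep[rows, comp_t] = reflect_unit(
            ep[rows, comp_t] + rng.uniform(-scale_T, scale_T, size=B)
        )
        v_cand = solve(cand_ep, p)
        wT_cand = transmitter_payoff(v_cand, b_t, b_f)
        accept = rng.random(B) < fermi_probability(wT, wT_cand, sigma_T)
        ep[accept] = cand_ep[accept]
        v_cur[accept] = v_cand[accept]
        wT[accept] = wT_cand[accept]
        wR[accept] = receiver_payoff(v_cand, pi_t, pi_f)[accept]

        if step >= burn_in:
            acc.add(v_cur, wR)
    out = acc.summary()
    out["p_final"] = p
    out["endpoints_final"] = ep
    return out
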