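"""Two-state hidden Markov segmentation of the 5-s ODBA series.

Each chick's ODBA series is modeled, on the log scale y = log(ODBA + ε),
as a two-state Gaussian HMM: a low-mean "nonactive" state (brooding and
other rest) and a high-mean "active" state.  Parameters are fitted per
chick by Baum–Welch (EM with scaled forward–backward recursions) and the
most probable state path is decoded with the Viterbi algorithm.

Initialization is deterministic — state means at the 20th/80th percentiles
of y, shared SD, 0.95 self-persistence — so the unsupervised fit is
reproducible; the seed only enters the fallback re-initialization used when
a fit collapses onto one state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .bouts import Bout, BoutSet

STATE_NONACTIVE = "nonactive"
STATE_ACTIVE = "active"

_LOG2PI = float(np.log(2.0 * np.pi))


class DegenerateFitError(ValueError):
    """The series has no two-state structure (one state absorbs everything)."""


@dataclass
class HmmParams:
    """Fitted two-state HMM; state 0 is always the lower-mean (nonactive) state."""

    init_prob: np.ndarray  # (2,)
    trans: np.ndarray  # (2, 2) row-stochastic
    emis_mean: np.ndarray  # (2,) on log-ODBA scale
    emis_sd: np.ndarray  # (2,) > 0
    eps_g: float  # ε used in y = log(odba + ε)
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0

    def validate(self) -> None:
        if not np.allclose(self.trans.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.init_prob.sum(), 1.0, atol=1e-9):
            raise ValueError("init_prob must sum to 1")
        if np.any(self.emis_sd <= 0):
            raise ValueError("emission SDs must be positive")


@dataclass
class StatePath:
    t5: np.ndarray
    state: np.ndarray  # array of STATE_* strings, same length as input

    @property
    def nonactive(self) -> np.ndarray:
        return self.state == STATE_NONACTIVE


# ---------------------------------------------------------------------------
# numerical core (scaled recursions)


@njit(cache=True)
def _forward_backward(b: np.ndarray, trans: np.ndarray, init: np.ndarray):
    """Scaled forward–backward for 2 states.

    Returns (loglik, gamma, xi_sum) where gamma[t, i] = p(state_t = i | y)
    and xi_sum[i, j] = Σ_t p(state_t = i, state_{t+1} = j | y).
    """
    T = b.shape[0]
    alpha = np.empty((T, 2))
    beta = np.empty((T, 2))
    scale = np.empty(T)

    a0 = init[0] * b[0, 0]
    a1 = init[1] * b[0, 1]
    c = a0 + a1
    if c <= 0.0:
        c = 1e-300
    alpha[0, 0] = a0 / c
    alpha[0, 1] = a1 / c
    scale[0] = c
    for t in range(1, T):
        a0 = (alpha[t - 1, 0] * trans[0, 0] + alpha[t - 1, 1] * trans[1, 0]) * b[t, 0]
        a1 = (alpha[t - 1, 0] * trans[0, 1] + alpha[t - 1, 1] * trans[1, 1]) * b[t, 1]
        c = a0 + a1
        if c <= 0.0:
            c = 1e-300
        alpha[t, 0] = a0 / c
        alpha[t, 1] = a1 / c
        scale[t] = c

    beta[T - 1, 0] = 1.0
    beta[T - 1, 1] = 1.0
    for t in range(T - 2, -1, -1):
        b0 = (trans[0, 0] * b[t + 1, 0] * beta[t + 1, 0]
              + trans[0, 1] * b[t + 1, 1] * beta[t + 1, 1])
        b1 = (trans[1, 0] * b[t + 1, 0] * beta[t + 1, 0]
              + trans[1, 1] * b[t + 1, 1] * beta[t + 1, 1])
        beta[t, 0] = b0 / scale[t + 1]
        beta[t, 1] = b1 / scale[t + 1]

    gamma = alpha * beta
    for t in range(T):
        s = gamma[t, 0] + gamma[t, 1]
        if s > 0.0:
            gamma[t, 0] /= s
            gamma[t, 1] /= s

    xi = np.zeros((2, 2))
    for t in range(T - 1):
        denom = 0.0
        tmp = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                tmp[i, j] = (alpha[t, i] * trans[i, j] * b[t + 1, j]
                             * beta[t + 1, j])
                denom += tmp[i, j]
        if denom > 0.0:
            for i in range(2):
                for j in range(2):
                    xi[i, j] += tmp[i, j] / denom

    loglik = 0.0
    for t in range(T):
        loglik += np.log(scale[t])
    return loglik, gamma, xi


@njit(cache=True)
def _viterbi(logb: np.ndarray, log_trans: np.ndarray, log_init: np.ndarray):
    """Most probable state path; ties broken toward the lower state index."""
    T = logb.shape[0]
    delta = np.empty((T, 2))
    psi = np.zeros((T, 2), dtype=np.int64)
    delta[0, 0] = log_init[0] + logb[0, 0]
    delta[0, 1] = log_init[1] + logb[0, 1]
    for t in range(1, T):
        for j in range(2):
            s0 = delta[t - 1, 0] + log_trans[0, j]
            s1 = delta[t - 1, 1] + log_trans[1, j]
            if s1 > s0:  # strict: ties go to state 0
                psi[t, j] = 1
                delta[t, j] = s1 + logb[t, j]
            else:
                psi[t, j] = 0
                delta[t, j] = s0 + logb[t, j]
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = 1 if delta[T - 1, 1] > delta[T - 1, 0] else 0
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def _emission_probs(y: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    z = (y[:, None] - mean[None, :]) / sd[None, :]
    return np.exp(-0.5 * z**2) / (sd[None, :] * np.sqrt(2.0 * np.pi))


def _log_emission(y: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    z = (y[:, None] - mean[None, :]) / sd[None, :]
    return -0.5 * z**2 - np.log(sd[None, :]) - 0.5 * _LOG2PI


# ---------------------------------------------------------------------------
# fitting


def _run_em(
    y: np.ndarray,
    mean: np.ndarray,
    sd: np.ndarray,
    trans: np.ndarray,
    init: np.ndarray,
    tol: float,
    max_iter: int,
) -> HmmParams:
    min_sd = 1e-4
    loglik_trace: list[float] = []
    prev = -np.inf
    n_iter = 0
    for it in range(max_iter):
        b = _emission_probs(y, mean, sd)
        loglik, gamma, xi = _forward_backward(b, trans, init)
        loglik_trace.append(float(loglik))
        n_iter = it + 1
        if loglik - prev < tol and it > 0:
            break
        prev = loglik
        # M step
        init = gamma[0] / gamma[0].sum()
        occ = gamma.sum(axis=0)
        row = xi.sum(axis=1)
        trans = np.where(row[:, None] > 0, xi / np.maximum(row[:, None], 1e-300),
                         np.array([[0.5, 0.5], [0.5, 0.5]]))
        trans = trans / trans.sum(axis=1, keepdims=True)
        mean = (gamma * y[:, None]).sum(axis=0) / np.maximum(occ, 1e-300)
        var = (gamma * (y[:, None] - mean[None, :]) ** 2).sum(axis=0) / np.maximum(
            occ, 1e-300
        )
        sd = np.maximum(np.sqrt(var), min_sd)
    return HmmParams(
        init_prob=init, trans=trans, emis_mean=mean, emis_sd=sd,
        eps_g=np.nan, loglik_trace=loglik_trace, n_iter=n_iter,
    )


def _order_states(p: HmmParams) -> HmmParams:
    """Reindex so state 0 is the lower-mean (nonactive) state."""
    if p.emis_mean[0] <= p.emis_mean[1]:
        return p
    perm = np.array([1, 0])
    return HmmParams(
        init_prob=p.init_prob[perm],
        trans=p.trans[np.ix_(perm, perm)],
        emis_mean=p.emis_mean[perm],
        emis_sd=p.emis_sd[perm],
        eps_g=p.eps_g,
        loglik_trace=p.loglik_trace,
        n_iter=p.n_iter,
    )


def fit_two_state(
    odba5: np.ndarray,
    seed: int = 0,
    eps_g: float = 1e-4,
    tol: float = 1e-6,
    max_iter: int = 200,
    min_bins: int = 500,
) -> HmmParams:
    """Fit the per-chick two-state HMM on log(ODBA + ε) by Baum–Welch.

    Raises :class:`DegenerateFitError` when the decoded occupancy of either
    state stays below 1% after a seeded re-initialization — the series has
    no usable two-state structure (e.g. a constant trace).
    """
    odba5 = np.asarray(odba5, dtype=float)
    if len(odba5) < min_bins:
        raise ValueError(f"need at least {min_bins} bins, got {len(odba5)}")
    if np.any(odba5 < 0):
        raise ValueError("ODBA must be non-negative")
    y = np.log(odba5 + eps_g)

    lo, hi = np.percentile(y, [20, 80])
    sd0 = float(np.std(y))
    if sd0 < 1e-8 or hi - lo < 1e-8:
        raise DegenerateFitError("no two-state structure: series is constant")
    trans0 = np.array([[0.95, 0.05], [0.05, 0.95]])
    init0 = np.array([0.5, 0.5])

    params = _run_em(
        y, np.array([lo, hi]), np.array([sd0, sd0]), trans0.copy(), init0.copy(),
        tol, max_iter,
    )
    params.eps_g = eps_g
    params = _order_states(params)
    if not _is_degenerate(params, y):
        params.validate()
        return params

    # fallback: randomized re-initialization
    rng = np.random.default_rng(seed)
    qs = np.sort(rng.uniform(5, 95, size=2))
    m = np.percentile(y, qs)
    params = _run_em(
        y, m, np.array([sd0, sd0]), trans0.copy(), init0.copy(), tol, max_iter
    )
    params.eps_g = eps_g
    params = _order_states(params)
    if _is_degenerate(params, y):
        raise DegenerateFitError("no two-state structure in ODBA series")
    params.validate()
    return params


def _is_degenerate(params: HmmParams, y: np.ndarray, min_frac: float = 0.01) -> bool:
    logb = _log_emission(y, params.emis_mean, params.emis_sd)
    path = _viterbi(
        logb,
        np.log(np.maximum(params.trans, 1e-300)),
        np.log(np.maximum(params.init_prob, 1e-300)),
    )
    frac1 = float(np.mean(path))
    return min(frac1, 1.0 - frac1) < min_frac


# ---------------------------------------------------------------------------
# decoding


def viterbi_decode(params: HmmParams, odba5: np.ndarray,
                   t5: np.ndarray | None = None) -> StatePath:
    """Globally most probable active/nonactive path under ``params``."""
    params.validate()
    odba5 = np.asarray(odba5, dtype=float)
    if t5 is None:
        t5 = np.arange(len(odba5), dtype=float) * 5.0
    if len(t5) != len(odba5):
        raise ValueError("t5 and odba5 length mismatch")
    y = np.log(odba5 + params.eps_g)
    logb = _log_emission(y, params.emis_mean, params.emis_sd)
    path = _viterbi(
        logb,
        np.log(np.maximum(params.trans, 1e-300)),
        np.log(np.maximum(params.init_prob, 1e-300)),
    )
    state = np.where(path == 0, STATE_NONACTIVE, STATE_ACTIVE)
    return StatePath(t5=np.asarray(t5, dtype=float), state=state)


def states_to_bouts(path: StatePath, chick_id: str = "", bin_s: float = 5.0
                    ) -> BoutSet:
    """Maximal constant-state runs → candidate bouts.

    Nonactive runs become candidate brooding bouts; active runs keep the
    ``active`` label.  Each bin covers [t, t + bin_s).
    """
    if len(path.state) == 0:
        return BoutSet(chick_id, [])
    t = path.t5
    changes = np.flatnonzero(path.state[1:] != path.state[:-1]) + 1
    starts = np.concatenate([[0], changes])
    ends = np.concatenate([changes, [len(path.state)]])
    bouts = []
    for s, e in zip(starts, ends):
        label = "brooding" if path.state[s] == STATE_NONACTIVE else "active"
        bouts.append(Bout(float(t[s]), float(t[e - 1]) + bin_s, label, "hmm"))
    return BoutSet(chick_id, bouts)
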