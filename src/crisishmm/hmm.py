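"""Exact single-subject HMM computations with Gaussian emissions and missing data.

The model: a latent first-order Markov chain :math:`S_t \\in \\{1..m\\}` emits a
K-vector of conditionally independent Gaussian channels at every occasion.
Missing channels are marginalized out of the emission density (missing at
random), and fully missing occasions contribute transition structure only —
the chain is never split at gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels

_LOG2PI = _kernels.LOG2PI


def row_probs_from_logits(alpha_row: np.ndarray) -> np.ndarray:
    """Map a length m-1 log-odds vector (reference = first category) to a
    probability row of length m via softmax over (0, alpha_row)."""
    alpha_row = np.asarray(alpha_row, dtype=float)
    if not np.all(np.isfinite(alpha_row)):
        raise ValueError("transition logits must be finite")
    logits = np.concatenate(([0.0], alpha_row))
    logits -= logits.max()
    w = np.exp(logits)
    return w / w.sum()


def logits_from_row_probs(row: np.ndarray) -> np.ndarray:
    """Inverse of :func:`row_probs_from_logits` for strictly positive rows."""
    row = np.asarray(row, dtype=float)
    if np.any(row <= 0):
        raise ValueError("logit transform requires strictly positive probabilities")
    return np.log(row[1:] / row[0])


def stationary_distribution(gamma: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (least-squares
    fallback for reducible chains)."""
    gamma = np.asarray(gamma, dtype=float)
    m = gamma.shape[0]
    A = np.vstack([np.eye(m) - gamma.T, np.ones(m)])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


@dataclass
class SubjectParams:
    """One subject's emission and dynamics parameters.

    means, sds : (m, K) state-by-channel Gaussian emission parameters
    gamma      : (m, m) transition probability matrix
    init       : (m,) initial state distribution; defaults to the stationary
                 distribution of gamma
    """

    means: np.ndarray
    sds: np.ndarray
    gamma: np.ndarray
    init: np.ndarray | None = None

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.sds = np.atleast_2d(np.asarray(self.sds, dtype=float))
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        if self.sds.shape != self.means.shape:
            raise ValueError("means and sds must share shape (m, K)")
        m = self.means.shape[0]
        if self.gamma.shape != (m, m):
            raise ValueError("gamma must be (m, m) with m = number of states")
        if np.any(self.sds <= 0):
            raise ValueError("emission sds must be strictly positive")
        if not np.allclose(self.gamma.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows of gamma must sum to 1")
        if self.init is None:
            self.init = stationary_distribution(self.gamma)
        else:
            self.init = np.asarray(self.init, dtype=float)
            if abs(self.init.sum() - 1.0) > 1e-12:
                raise ValueError("init must sum to 1")

    @property
    def m(self) -> int:
        return self.means.shape[0]

    @property
    def K(self) -> int:
        return self.means.shape[1]

    def permuted(self, perm: np.ndarray) -> "SubjectParams":
        """Relabel states: new state s is old state perm[s]."""
        perm = np.asarray(perm)
        return SubjectParams(
            means=self.means[perm],
            sds=self.sds[perm],
            gamma=self.gamma[np.ix_(perm, perm)],
            init=self.init[perm] / self.init[perm].sum(),
        )


@dataclass
class DecodedTrajectory:
    """Viterbi path for one subject, 1-based states aligned to occasions."""

    states: np.ndarray
    log_prob: float
    occupancy: np.ndarray = field(init=False)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=int)
        m = int(self.states.max())
        counts = np.bincount(self.states - 1, minlength=m)
        self.occupancy = counts / counts.sum()


def _as_masked(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(T, K) observations with NaN for missing -> (values, observed mask)."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    mask = np.isfinite(y)
    return np.where(mask, y, 0.0), mask


def emission_log_b(y: np.ndarray, params: SubjectParams) -> np.ndarray:
    """Per-occasion per-state emission log densities, (T, m).

    Channels are conditionally independent given the state; unobserved
    channels are marginalized (contribute 0), so a fully missing occasion has
    log density 0 in every state.
    """
    vals, mask = _as_masked(y)
    # (T, m, K) standardized residuals, masked channels zeroed out
    z = (vals[:, None, :] - params.means[None, :, :]) / params.sds[None, :, :]
    contrib = -0.5 * z**2 - np.log(params.sds)[None, :, :] - 0.5 * _LOG2PI
    return np.where(mask[:, None, :], contrib, 0.0).sum(axis=2)


def emission_logdensity(y: np.ndarray, state: int, params: SubjectParams) -> float:
    """Log emission density of one occasion's K-vector in `state` (1-based)."""
    log_b = emission_log_b(np.atleast_2d(np.asarray(y, dtype=float)), params)
    return float(log_b[0, state - 1])


def _check_sequence(y: np.ndarray) -> np.ndarray:
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] == 0:
        raise ValueError("empty observation sequence")
    return y


def forward_loglik(y: np.ndarray, params: SubjectParams) -> float:
    """Exact marginal log-likelihood of one subject's sequence (scaled
    forward recursion; missing data marginalized)."""
    y = _check_sequence(y)
    log_b = emission_log_b(y, params)
    ll = _kernels.forward_loglik(log_b, params.gamma, params.init)
    if not np.isfinite(ll):
        raise FloatingPointError("forward recursion underflowed")
    return float(ll)


def ffbs_sample(y: np.ndarray, params: SubjectParams, rng: np.random.Generator) -> np.ndarray:
    """One exact draw from P(S_1..T | y, params); returns 1-based states."""
    y = _check_sequence(y)
    log_b = emission_log_b(y, params)
    T = y.shape[0]
    states = np.empty(T, dtype=np.int64)
    u = rng.random(T)
    ll = _kernels.ffbs(log_b, params.gamma, params.init, u, states)
    if not np.isfinite(ll):
        bad = int(np.argmin(np.isfinite(log_b.sum(axis=1))))
        raise FloatingPointError(f"FFBS underflow near occasion {bad + 1}")
    return states + 1


def viterbi_decode(y: np.ndarray, params: SubjectParams) -> DecodedTrajectory:
    """Joint maximum a posteriori state path (1-based).

    Ties are broken toward the lower state index; fully missing occasions are
    decoded from the transition structure alone.
    """
    y = _check_sequence(y)
    log_b = emission_log_b(y, params)
    with np.errstate(divide="ignore"):
        log_gamma = np.log(params.gamma)
        log_init = np.log(params.init)
    path, logp = _kernels.viterbi(log_b, log_gamma, log_init)
    return DecodedTrajectory(states=path + 1, log_prob=float(logp))


def path_log_prob(y: np.ndarray, states: np.ndarray, params: SubjectParams) -> float:
    """Joint log P(S = states, y | params) for a given 1-based path."""
    y = _check_sequence(y)
    s = np.asarray(states, dtype=int) - 1
    log_b = emission_log_b(y, params)
    with np.errstate(divide="ignore"):
        lp = np.log(params.init[s[0]]) + log_b[0, s[0]]
        for t in range(1, len(s)):
            lp += np.log(params.gamma[s[t - 1], s[t]]) + log_b[t, s[t]]
    return float(lp)
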