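"""Compiled inner loops for the HMM recursions and the transition Metropolis sweep.

Everything here operates on plain float64/int64 arrays and is free of Python
objects so numba can compile it; randomness enters only through pre-generated
uniform/normal variates, which keeps the replay contract (one numpy Generator
per chain) outside the compiled code.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG2PI = 1.8378770664093453


@njit(cache=True)
def _sample_categorical(p, u):
    """Index of the category containing quantile u of the discrete cdf of p."""
    acc = 0.0
    m = p.shape[0]
    for s in range(m - 1):
        acc += p[s]
        if u < acc:
            return s
    return m - 1


@njit(cache=True)
def forward_filter(log_b, gamma, init, alpha_out):
    """Scaled forward recursion.

    log_b : (T, m) per-occasion emission log densities (0.0 for fully missing)
    alpha_out : (T, m) filled with filtered state probabilities P(S_t | y_1:t)
    Returns the marginal log-likelihood.
    """
    T, m = log_b.shape
    loglik = 0.0
    for t in range(T):
        c = log_b[t, 0]
        for s in range(1, m):
            if log_b[t, s] > c:
                c = log_b[t, s]
        norm = 0.0
        for s in range(m):
            if t == 0:
                pred = init[s]
            else:
                pred = 0.0
                for r in range(m):
                    pred += alpha_out[t - 1, r] * gamma[r, s]
            w = pred * np.exp(log_b[t, s] - c)
            alpha_out[t, s] = w
            norm += w
        if norm <= 0.0 or not np.isfinite(norm):
            # scaling failed despite the max-shift; report the occasion
            return -np.inf
        for s in range(m):
            alpha_out[t, s] /= norm
        loglik += np.log(norm) + c
    return loglik


@njit(cache=True)
def forward_loglik(log_b, gamma, init):
    T, m = log_b.shape
    alpha = np.empty((T, m))
    return forward_filter(log_b, gamma, init, alpha)


@njit(cache=True)
def ffbs(log_b, gamma, init, u, states_out):
    """Forward-filtering backward-sampling draw of the hidden path.

    u : (T,) iid Uniform(0,1) variates consumed back-to-front.
    states_out : (T,) int64, filled with the sampled path (0-based).
    Returns the marginal log-likelihood from the shared forward pass.
    """
    T, m = log_b.shape
    alpha = np.empty((T, m))
    loglik = forward_filter(log_b, gamma, init, alpha)
    if not np.isfinite(loglik):
        return loglik
    states_out[T - 1] = _sample_categorical(alpha[T - 1], u[T - 1])
    w = np.empty(m)
    for t in range(T - 2, -1, -1):
        nxt = states_out[t + 1]
        norm = 0.0
        for s in range(m):
            w[s] = alpha[t, s] * gamma[s, nxt]
            norm += w[s]
        for s in range(m):
            w[s] /= norm
        states_out[t] = _sample_categorical(w, u[t])
    return loglik


@njit(cache=True)
def viterbi(log_b, log_gamma, log_init):
    """Joint-MAP state path; ties broken toward the lower state index."""
    T, m = log_b.shape
    delta = np.empty((T, m))
    psi = np.zeros((T, m), np.int64)
    for s in range(m):
        delta[0, s] = log_init[s] + log_b[0, s]
    for t in range(1, T):
        for j in range(m):
            best = delta[t - 1, 0] + log_gamma[0, j]
            arg = 0
            for i in range(1, m):
                v = delta[t - 1, i] + log_gamma[i, j]
                if v > best:  # strict: first (lowest) index wins ties
                    best = v
                    arg = i
            delta[t, j] = best + log_b[t, j]
            psi[t, j] = arg
    path = np.empty(T, np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for s in range(1, m):
        if delta[T - 1, s] > best:
            best = delta[T - 1, s]
            arg = s
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best


@njit(cache=True)
def stationary_dist(gamma):
    """Stationary distribution of an ergodic row-stochastic matrix."""
    m = gamma.shape[0]
    A = np.eye(m) - gamma.T
    for j in range(m):
        A[m - 1, j] = 1.0
    b = np.zeros(m)
    b[m - 1] = 1.0
    pi = np.linalg.solve(A, b)
    tot = 0.0
    for s in range(m):
        if pi[s] < 1e-12:
            pi[s] = 1e-12
        tot += pi[s]
    return pi / tot


@njit(cache=True)
def gamma_from_diag_logits(alpha):
    """Map (m, m-1) diagonal-reference logits to an (m, m) stochastic matrix.

    Row r lists log-odds of each off-diagonal destination (in increasing state
    order, skipping r) against staying in r.
    """
    m = alpha.shape[0]
    gamma = np.empty((m, m))
    for r in range(m):
        hi = 0.0
        for c in range(m - 1):
            if alpha[r, c] > hi:
                hi = alpha[r, c]
        norm = np.exp(-hi)
        gamma[r, r] = norm
        c = 0
        for j in range(m):
            if j == r:
                continue
            v = np.exp(alpha[r, c] - hi)
            gamma[r, j] = v
            norm += v
            c += 1
        for j in range(m):
            gamma[r, j] /= norm
    return gamma


@njit(cache=True)
def _row_loglik(counts_row, probs_row):
    ll = 0.0
    for j in range(counts_row.shape[0]):
        if counts_row[j] > 0:
            ll += counts_row[j] * np.log(probs_row[j])
    return ll


@njit(cache=True)
def ffbs_sweep(log_b, gammas, lengths, u, states_out):
    """One FFBS draw per subject; initial distribution = stationary(Gamma_i)."""
    n = log_b.shape[0]
    loglik = np.zeros(n)
    for i in range(n):
        T = lengths[i]
        init = stationary_dist(gammas[i])
        loglik[i] = ffbs(log_b[i, :T], gammas[i], init, u[i, :T], states_out[i, :T])
    return loglik


@njit(cache=True)
def transition_mh_sweep(
    trans_counts, first_state, alpha_i, alpha_bar, omega, steps, z, u, accepts,
    frac_accept
):
    """Cell-wise random-walk Metropolis on every subject's transition logits.

    Target for cell (r, c) of subject i: multinomial transition counts under
    the row, the stationary-initial-state term (recomputed from the full
    matrix, so the rows stay exactly coupled), and the Normal(alpha_bar,
    omega) random-effect prior. alpha_i is updated in place; accepts counts
    accepted cells per (i, r); frac_accept gets the per-row accepted fraction
    of this sweep (for step adaptation).
    """
    n, m, _ = trans_counts.shape
    for i in range(n):
        gamma = gamma_from_diag_logits(alpha_i[i])
        for r in range(m):
            n_acc = 0
            for c in range(m - 1):
                prop_alpha = alpha_i[i].copy()
                prop_alpha[r, c] = alpha_i[i, r, c] + steps[i, r] * z[i, r, c]
                gamma_new = gamma_from_diag_logits(prop_alpha)
                lp_cur = _row_loglik(trans_counts[i, r], gamma[r])
                lp_new = _row_loglik(trans_counts[i, r], gamma_new[r])
                lp_cur += np.log(stationary_dist(gamma)[first_state[i]])
                lp_new += np.log(stationary_dist(gamma_new)[first_state[i]])
                om = omega[r, c]
                if om < 1e-6:
                    om = 1e-6
                d_cur = (alpha_i[i, r, c] - alpha_bar[r, c]) / om
                d_new = (prop_alpha[r, c] - alpha_bar[r, c]) / om
                lp_cur -= 0.5 * d_cur * d_cur
                lp_new -= 0.5 * d_new * d_new
                if np.log(u[i, r, c]) < lp_new - lp_cur:
                    alpha_i[i, r, c] = prop_alpha[r, c]
                    gamma = gamma_new
                    n_acc += 1
            accepts[i, r] += n_acc
            frac_accept[i, r] = n_acc / (m - 1.0)


@njit(cache=True)
def group_shift_mh_sweep(
    trans_counts, first_state, alpha_i, alpha_bar,
    prior_loc, prior_scale, steps_g, z, u, accepts_g
):
    """Interweaved (ASIS) group-level move: for each transition row r, propose
    a common shift of alpha_bar[r] and of every subject's alpha_i[:, r] with
    the subject offsets held fixed. The subject-level multinomial likelihoods
    then inform alpha_bar directly, which breaks the slow centered-hierarchy
    mixing when per-subject transition counts are sparse.
    """
    n, m, _ = trans_counts.shape
    for r in range(m):
        lp_cur = 0.0
        lp_new = 0.0
        for i in range(n):
            gamma = gamma_from_diag_logits(alpha_i[i])
            prop_alpha = alpha_i[i].copy()
            for c in range(m - 1):
                prop_alpha[r, c] = alpha_i[i, r, c] + steps_g[r] * z[r, c]
            gamma_new = gamma_from_diag_logits(prop_alpha)
            lp_cur += _row_loglik(trans_counts[i, r], gamma[r])
            lp_new += _row_loglik(trans_counts[i, r], gamma_new[r])
            lp_cur += np.log(stationary_dist(gamma)[first_state[i]])
            lp_new += np.log(stationary_dist(gamma_new)[first_state[i]])
        for c in range(m - 1):
            d_cur = (alpha_bar[r, c] - prior_loc) / prior_scale
            d_new = (alpha_bar[r, c] + steps_g[r] * z[r, c] - prior_loc) / prior_scale
            lp_cur -= 0.5 * d_cur * d_cur
            lp_new -= 0.5 * d_new * d_new
        if np.log(u[r]) < lp_new - lp_cur:
            for c in range(m - 1):
                alpha_bar[r, c] += steps_g[r] * z[r, c]
                for i in range(n):
                    alpha_i[i, r, c] += steps_g[r] * z[r, c]
            accepts_g[r] += 1


@njit(cache=True)
def omega_scale_mh_sweep(
    trans_counts, first_state, alpha_i, alpha_bar, omega,
    omega_prior_scale, steps_o, z, u, accepts_o
):
    """Interweaved rescaling move for the transition random-effect SDs.

    Row-wise log-normal proposal on the omega cells with the standardized
    subject offsets delta_i = (alpha_i - alpha_bar)/omega held fixed, so the
    proposal rescales every subject's deviation. The target in the
    non-centered parametrization is the subjects' multinomial likelihood,
    the half-Cauchy(0, omega_prior_scale) prior, and the log-scale Jacobian.
    """
    n, m, _ = trans_counts.shape
    for r in range(m):
        lp_cur = 0.0
        lp_new = 0.0
        for i in range(n):
            gamma = gamma_from_diag_logits(alpha_i[i])
            prop_alpha = alpha_i[i].copy()
            for c in range(m - 1):
                f = np.exp(steps_o[r] * z[r, c])
                prop_alpha[r, c] = alpha_bar[r, c] + f * (alpha_i[i, r, c] - alpha_bar[r, c])
            gamma_new = gamma_from_diag_logits(prop_alpha)
            lp_cur += _row_loglik(trans_counts[i, r], gamma[r])
            lp_new += _row_loglik(trans_counts[i, r], gamma_new[r])
            lp_cur += np.log(stationary_dist(gamma)[first_state[i]])
            lp_new += np.log(stationary_dist(gamma_new)[first_state[i]])
        for c in range(m - 1):
            f = np.exp(steps_o[r] * z[r, c])
            om_new = omega[r, c] * f
            lp_cur += -np.log(1.0 + (omega[r, c] / omega_prior_scale) ** 2)
            lp_new += -np.log(1.0 + (om_new / omega_prior_scale) ** 2)
            lp_new += np.log(f)  # Jacobian of the log-scale proposal
        if np.log(u[r]) < lp_new - lp_cur:
            for c in range(m - 1):
                f = np.exp(steps_o[r] * z[r, c])
                for i in range(n):
                    alpha_i[i, r, c] = alpha_bar[r, c] + f * (alpha_i[i, r, c] - alpha_bar[r, c])
                omega[r, c] *= f
            accepts_o[r] += 1
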