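"""Multilevel Bayesian HMM estimator.

Metropolis-within-Gibbs over (a) each patient's hidden state path, drawn
exactly by forward-filtering backward-sampling, (b) patient-level emission
means and transition logits (Gaussian random effects around group-level
parameters), and (c) the group-level hyperparameters. Emission SDs are shared
across patients (state x channel specific). Transition rows are parametrized
as multinomial logits with the row's own staying probability as reference
category, so Gaussian random effects and state relabeling both act cell-wise.

Half-Cauchy priors on all scale parameters are implemented through the
inverse-gamma auxiliary-variable representation (tau^2 ~ IG(1/2, 1/a),
a ~ IG(1/2, 1/A^2)), which makes every variance update conjugate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import _kernels
from .simulate import EsmPanel

logger = logging.getLogger(__name__)

_LOG2PI = _kernels.LOG2PI


class FitError(RuntimeError):
    pass


@dataclass
class Priors:
    """Weakly informative priors, scaled to the 1-100 item range.

    Group emission means ~ Normal(mean_loc, mean_scale^2) per channel;
    within- and between-patient SDs ~ half-Cauchy(0, sigma_scale /
    tau_scale); group transition logits ~ Normal(logit_loc, logit_scale^2);
    transition random-effect SDs ~ half-Cauchy(0, omega_scale).
    """

    mean_loc: float = 50.0
    mean_scale: float = 25.0
    sigma_scale: float = 10.0
    tau_scale: float = 10.0
    logit_loc: float = 0.0
    logit_scale: float = 5.0
    omega_scale: float = 1.0

    def __post_init__(self):
        for name in ("mean_scale", "sigma_scale", "tau_scale", "logit_scale", "omega_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior scale {name} must be > 0")

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


@dataclass
class GroupParams:
    """Sample-level parameters: emission means/SDs per state x channel,
    random-effect SDs, and transition logits (diagonal reference)."""

    mu: np.ndarray          # (m, K) emission means
    tau: np.ndarray         # (m, K) between-patient SDs of emission means
    sigma: np.ndarray       # (m, K) within-patient emission SDs
    alpha_bar: np.ndarray   # (m, m-1) transition logits, diagonal reference
    omega: np.ndarray       # (m, m-1) random-effect SDs of the logits

    @property
    def transition(self) -> np.ndarray:
        if self.mu.shape[0] == 1:
            return np.ones((1, 1))
        return _kernels.gamma_from_diag_logits(np.ascontiguousarray(self.alpha_bar))


def diag_logits_from_gamma(gamma: np.ndarray) -> np.ndarray:
    """(m, m) stochastic matrix -> (m, m-1) diagonal-reference logits.

    Probabilities are floored at 1e-12 so rows with an underflowed cell
    (e.g. a starved state) map to large finite logits.
    """
    gamma = np.maximum(np.asarray(gamma, dtype=float), 1e-12)
    m = gamma.shape[0]
    out = np.empty((m, m - 1))
    for r in range(m):
        off = [j for j in range(m) if j != r]
        out[r] = np.log(gamma[r, off] / gamma[r, r])
    return out


# ---------------------------------------------------------------------------
# conjugate building blocks (exposed for unit testing against closed forms)
# ---------------------------------------------------------------------------

def sample_conjugate_mean(sum_x, n, lik_sd, prior_mean, prior_sd, rng):
    """Posterior draw of a Gaussian mean given iid N(mean, lik_sd) data with
    sufficient statistics (sum_x, n) and a N(prior_mean, prior_sd) prior."""
    lik_sd = np.maximum(lik_sd, 1e-8)
    prec = n / lik_sd**2 + 1.0 / prior_sd**2
    mean = (sum_x / lik_sd**2 + prior_mean / prior_sd**2) / prec
    return rng.normal(mean, 1.0 / np.sqrt(prec))


def sample_halfcauchy_variance(rss, n, aux, scale, rng):
    """Gibbs update of (variance, auxiliary) under a half-Cauchy(0, scale)
    prior on the SD, given residual sum of squares `rss` from `n` terms."""
    rate = 1.0 / aux + 0.5 * rss
    var = 1.0 / rng.gamma((np.asarray(n) + 1.0) / 2.0, 1.0 / rate)
    aux_new = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / scale**2 + 1.0 / var))
    return var, aux_new


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_chain(panel: EsmPanel, m: int, seed: int, ordering_channel: str | None = None,
               jitter_sd: float = 2.0):
    """Chain starting values.

    Emission means start at the k-means centroids of the fully observed
    occasions (jittered per chain) so that channels that decrease with
    severity start decreasing; with too few complete occasions they fall
    back to m equally spaced pooled per-channel quantiles. Rows are sorted
    by the ordering channel; transitions start diagonal-dominant (0.7
    staying). Subject transition logits start at the group values; subject
    emission means start at each patient's nearest-centroid assignment means
    shrunk toward the group centroids.
    """
    from scipy.cluster.vq import kmeans2

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((int(seed), 101))))
    y, _ = panel.to_arrays()
    K = panel.K
    levels = (np.arange(m) + 0.5) / m
    mu0 = np.empty((m, K))
    sd0 = np.empty(K)
    for k in range(K):
        col = y[:, :, k]
        col = col[np.isfinite(col)]
        if col.size == 0:
            raise ValueError(f"channel {panel.channels[k]!r} has no observed values")
        mu0[:, k] = np.quantile(col, levels)
        sd0[k] = max(col.std(ddof=1), 1e-3)
    flat = y.reshape(-1, K)
    complete = flat[np.all(np.isfinite(flat), axis=1)]
    if complete.shape[0] >= 10 * m:
        best_sse = np.inf
        for _ in range(5):  # restarts guard against poor local partitions
            centroids, label = kmeans2(complete, m, minit="++",
                                       seed=int(rng.integers(2**31 - 1)))
            if len(np.unique(label)) < m:  # an empty cluster
                continue
            sse = float(((complete - centroids[label]) ** 2).sum())
            if sse < best_sse:
                best_sse, mu0 = sse, centroids
    mu0 = mu0 + rng.normal(0.0, jitter_sd, size=mu0.shape)
    if ordering_channel is None:
        ordering_channel = "negative_affect" if "negative_affect" in panel.channels else panel.channels[0]
    order = np.argsort(mu0[:, panel.channels.index(ordering_channel)], kind="stable")
    mu0 = mu0[order]
    sigma0 = np.tile(sd0 * 0.7, (m, 1))
    tau0 = np.tile(sd0 * 0.3, (m, 1))
    if m > 1:
        gamma0 = np.full((m, m), 0.3 / (m - 1))
        np.fill_diagonal(gamma0, 0.7)
        alpha_bar0 = diag_logits_from_gamma(gamma0)
    else:
        alpha_bar0 = np.zeros((1, 0))
    omega0 = np.full((m, max(m - 1, 0)), 0.5)
    group = GroupParams(mu=mu0, tau=tau0, sigma=sigma0, alpha_bar=alpha_bar0, omega=omega0)
    n = panel.n_patients
    # subject means: each patient's occasions assigned to the nearest group
    # centroid, state means = within-assignment means shrunk toward the group
    # (weight ~ a-priori 10 pseudo-occasions); keeps every chain's patients
    # near the same data-determined configuration
    mu_i0 = np.tile(mu0, (n, 1, 1)).astype(float)
    shrink = 10.0
    for i in range(n):
        yi = y[i]
        ok = np.all(np.isfinite(yi), axis=1)
        if ok.sum() < m:
            continue
        d = ((yi[ok][:, None, :] - mu0[None, :, :]) ** 2).sum(axis=2)
        lab = np.argmin(d, axis=1)
        for s in range(m):
            sel = lab == s
            if sel.any():
                ns = sel.sum()
                mu_i0[i, s] = (ns * yi[ok][sel].mean(axis=0) + shrink * mu0[s]) / (ns + shrink)
    alpha_i0 = np.tile(alpha_bar0, (n, 1, 1))
    return group, mu_i0, alpha_i0


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Per-chain MCMC output on interpretable scales.

    Transition draws are stored as probability matrices (gamma_bar, gamma_i);
    omega is stored as a full (m, m) matrix with NaN on the diagonal so state
    relabeling permutes its cells exactly.
    """

    channels: tuple
    patient_ids: list
    m: int
    n_iter: int
    burn_in: int
    n_chains: int
    seed: int
    data_hash: str
    mu: np.ndarray        # (C, I, m, K)
    tau: np.ndarray       # (C, I, m, K)
    sigma: np.ndarray     # (C, I, m, K)
    gamma_bar: np.ndarray  # (C, I, m, m)
    omega: np.ndarray     # (C, I, m, m), NaN diagonal
    mu_i: np.ndarray      # (C, I, n, m, K)
    gamma_i: np.ndarray   # (C, I, n, m, m)
    states: np.ndarray    # (C, I, n, T) int8, 0-based, -1 padding
    accept_rate: np.ndarray  # (C, n, m) post-burn-in Metropolis acceptance
    relabeled: bool = False

    @property
    def K(self) -> int:
        return self.mu.shape[3]

    @property
    def n_patients(self) -> int:
        return self.mu_i.shape[2]

    def post_burn(self, arr: np.ndarray) -> np.ndarray:
        return arr[:, self.burn_in:]

    def n_post(self) -> int:
        return self.n_chains * (self.n_iter - self.burn_in)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class MHMMSampler:
    """One chain of the Metropolis-within-Gibbs sampler (internal)."""

    def __init__(self, y, lengths, m, priors, rng, group, mu_i, alpha_i,
                 adapt_target=0.35, init_step=0.3):
        self.y = np.nan_to_num(y)
        self.obs = np.isfinite(y)
        self.lengths = lengths
        self.n, self.T, self.K = y.shape
        self.m = m
        self.priors = priors
        self.rng = rng
        self.mu = group.mu.copy()
        self.tau = group.tau.copy()
        self.sigma = group.sigma.copy()
        self.alpha_bar = group.alpha_bar.copy()
        self.omega = group.omega.copy()
        self.mu_i = mu_i.copy()
        self.alpha_i = np.ascontiguousarray(alpha_i.copy())
        self.a_tau = np.ones_like(self.tau)
        self.a_sigma = np.ones_like(self.sigma)
        self.a_omega = np.ones_like(self.omega)
        self.S = np.zeros((self.n, self.T), dtype=np.int64)
        self.steps = np.full((self.n, m), init_step)
        self.accepts = np.zeros((self.n, m), dtype=np.int64)
        self.steps_g = np.full(m, 0.15)
        self.accepts_g = np.zeros(m, dtype=np.int64)
        self.steps_o = np.full(m, 0.3)
        self.accepts_o = np.zeros(m, dtype=np.int64)
        self.steps_t = np.full((m, self.K), 0.3)
        self.n_sweeps = 0
        self.adapt_target = adapt_target
        self._starve = np.zeros(m, dtype=int)

    # -- state path block --------------------------------------------------
    def log_b(self) -> np.ndarray:
        z = (self.y[:, :, None, :] - self.mu_i[:, None, :, :]) / self.sigma[None, None]
        contrib = -0.5 * z**2 - np.log(self.sigma)[None, None] - 0.5 * _LOG2PI
        return np.where(self.obs[:, :, None, :], contrib, 0.0).sum(axis=3)

    def subject_gammas(self) -> np.ndarray:
        if self.m == 1:
            return np.ones((self.n, 1, 1))
        return np.stack([
            _kernels.gamma_from_diag_logits(self.alpha_i[i]) for i in range(self.n)
        ])

    def update_states(self):
        if self.m == 1:
            return
        u = self.rng.random((self.n, self.T))
        log_b = np.ascontiguousarray(self.log_b())
        gammas = np.ascontiguousarray(self.subject_gammas())
        ll = _kernels.ffbs_sweep(log_b, gammas, self.lengths, u, self.S)
        if not np.all(np.isfinite(ll)):
            bad = int(np.argmin(np.isfinite(ll)))
            raise FloatingPointError(f"non-finite forward pass for patient index {bad} (states block)")

    def update_patient_label_swap(self):
        """Collapsed per-patient label-swap move.

        For each patient, propose exchanging an adjacent pair of states in
        that patient's parameters (emission-mean rows and the corresponding
        permutation of the transition matrix) and accept with the exact
        path-marginalized likelihood plus the random-effect priors. Borderline
        patients can then flip which group-level state interprets their data,
        which de-couples chains from patient-assignment modes. The state path
        is refreshed by FFBS immediately afterwards.
        """
        if self.m == 1:
            return
        sig = self.sigma
        tau = np.maximum(self.tau, 1e-8)
        om = np.maximum(self.omega, 1e-6)
        log_b_all = self.log_b()
        gammas = self.subject_gammas()
        first = self.rng.integers(0, self.m - 1, self.n)
        u = self.rng.random((self.n, 1))
        for i in range(self.n):
            T = self.lengths[i]
            mu_cur = self.mu_i[i]
            gamma_cur = np.ascontiguousarray(gammas[i])
            log_b_cur = np.ascontiguousarray(log_b_all[i, :T])
            alpha_cur = self.alpha_i[i]
            ll_cur = _kernels.forward_loglik(
                log_b_cur, gamma_cur, _kernels.stationary_dist(gamma_cur))
            for j, s1 in enumerate((int(first[i]),)):
                s2 = s1 + 1
                perm = np.arange(self.m)
                perm[s1], perm[s2] = s2, s1
                mu_new = mu_cur[perm]
                gamma_new = np.ascontiguousarray(gamma_cur[np.ix_(perm, perm)])
                log_b_new = log_b_cur.copy()
                for s in (s1, s2):
                    z = (self.y[i, :T] - mu_new[s]) / sig[s]
                    contrib = -0.5 * z**2 - np.log(sig[s]) - 0.5 * _LOG2PI
                    log_b_new[:, s] = np.where(self.obs[i, :T], contrib, 0.0).sum(axis=1)
                ll_new = _kernels.forward_loglik(
                    log_b_new, gamma_new, _kernels.stationary_dist(gamma_new))
                alpha_new = diag_logits_from_gamma(gamma_new)
                lp_new = ll_new - 0.5 * (((mu_new - self.mu) / tau) ** 2).sum() \
                    - 0.5 * (((alpha_new - self.alpha_bar) / om) ** 2).sum()
                lp_cur = ll_cur - 0.5 * (((mu_cur - self.mu) / tau) ** 2).sum() \
                    - 0.5 * (((alpha_cur - self.alpha_bar) / om) ** 2).sum()
                if np.log(u[i, j]) < lp_new - lp_cur:
                    mu_cur, gamma_cur, log_b_cur, alpha_cur, ll_cur = (
                        mu_new, gamma_new, log_b_new, alpha_new, ll_new)
            self.mu_i[i] = mu_cur
            self.alpha_i[i] = alpha_cur

    # -- emission blocks ---------------------------------------------------
    def _emission_sufficients(self):
        idx = (np.arange(self.n)[:, None] * self.m + self.S).ravel()
        w = self.obs.reshape(-1, self.K).astype(float)
        counts = np.zeros((self.n * self.m, self.K))
        sums = np.zeros((self.n * self.m, self.K))
        sumsq = np.zeros((self.n * self.m, self.K))
        np.add.at(counts, idx, w)
        np.add.at(sums, idx, (self.y * self.obs).reshape(-1, self.K))
        np.add.at(sumsq, idx, (self.y**2 * self.obs).reshape(-1, self.K))
        shape = (self.n, self.m, self.K)
        return counts.reshape(shape), sums.reshape(shape), sumsq.reshape(shape)

    def update_subject_means(self):
        counts, sums, self._sumsq = self._emission_sufficients()
        self._counts, self._sums = counts, sums
        tau = np.maximum(self.tau, 1e-8)
        prec = counts / self.sigma[None] ** 2 + 1.0 / tau[None] ** 2
        mean = (sums / self.sigma[None] ** 2 + self.mu[None] / tau[None] ** 2) / prec
        self.mu_i = mean + self.rng.standard_normal(mean.shape) / np.sqrt(prec)
        tiny = self.tau < 1e-8
        if np.any(tiny):
            self.mu_i[:, tiny] = np.broadcast_to(self.mu[None], self.mu_i.shape)[:, tiny]
        return counts

    def update_sigma(self, counts):
        mu_sel = self.mu_i[np.arange(self.n)[:, None], self.S]  # (n, T, K)
        resid2 = np.where(self.obs, (self.y - mu_sel) ** 2, 0.0)
        rss = np.zeros((self.m, self.K))
        np.add.at(rss, self.S.ravel(), resid2.reshape(-1, self.K))
        n_sk = counts.sum(axis=0)
        var, self.a_sigma = sample_halfcauchy_variance(
            rss, n_sk, self.a_sigma, self.priors.sigma_scale, self.rng)
        self.sigma = np.sqrt(np.maximum(var, 1e-6))
        starved = n_sk.sum(axis=1) == 0
        self._starve = np.where(starved, self._starve + 1, 0)
        if np.any(self._starve == 50):
            for s in np.where(self._starve == 50)[0]:
                logger.warning("state %d has had zero occupancy for 50 iterations (starvation)", s + 1)

    # -- transition blocks -------------------------------------------------
    def _transition_counts(self):
        counts = np.zeros((self.n, self.m, self.m))
        for i in range(self.n):
            T = self.lengths[i]
            np.add.at(counts[i], (self.S[i, : T - 1], self.S[i, 1:T]), 1.0)
        return counts

    def update_subject_transitions(self, counts, iteration, burn_in):
        if self.m == 1:
            return
        z = self.rng.standard_normal((self.n, self.m, self.m - 1))
        u = self.rng.random((self.n, self.m, self.m - 1))
        frac = np.zeros((self.n, self.m))
        self.n_sweeps += 1
        _kernels.transition_mh_sweep(
            counts, np.ascontiguousarray(self.S[:, 0]), self.alpha_i,
            np.ascontiguousarray(self.alpha_bar), np.ascontiguousarray(self.omega),
            self.steps, z, u, self.accepts, frac)
        if iteration < burn_in:
            # Robbins-Monro adaptation toward the target acceptance rate,
            # frozen after burn-in to preserve detailed balance
            gain = (iteration + 1.0) ** -0.6
            self.steps = np.exp(np.log(self.steps) + gain * (frac - self.adapt_target))
            self.steps = np.clip(self.steps, 1e-3, 10.0)

    def update_group_transition_shift(self, counts, iteration, burn_in):
        """ASIS interweaving move: shift a group logit row and all subject
        rows jointly, holding the random-effect offsets fixed."""
        if self.m == 1:
            return
        z = self.rng.standard_normal((self.m, self.m - 1))
        u = self.rng.random(self.m)
        before = self.accepts_g.copy()
        _kernels.group_shift_mh_sweep(
            counts, np.ascontiguousarray(self.S[:, 0]), self.alpha_i,
            self.alpha_bar, self.priors.logit_loc, self.priors.logit_scale,
            self.steps_g, z, u, self.accepts_g)
        if iteration < burn_in:
            gain = (iteration + 1.0) ** -0.6
            ind = (self.accepts_g - before).astype(float)
            self.steps_g = np.exp(np.log(self.steps_g) + gain * (ind - 0.25))
            self.steps_g = np.clip(self.steps_g, 1e-3, 5.0)

    def update_omega_scale(self, counts, iteration, burn_in):
        """ASIS rescaling move for omega with standardized offsets fixed."""
        if self.m == 1:
            return
        z = self.rng.standard_normal((self.m, self.m - 1))
        u = self.rng.random(self.m)
        before = self.accepts_o.copy()
        _kernels.omega_scale_mh_sweep(
            counts, np.ascontiguousarray(self.S[:, 0]), self.alpha_i,
            self.alpha_bar, np.ascontiguousarray(self.omega),
            self.priors.omega_scale, self.steps_o, z, u, self.accepts_o)
        if iteration < burn_in:
            gain = (iteration + 1.0) ** -0.6
            ind = (self.accepts_o - before).astype(float)
            self.steps_o = np.exp(np.log(self.steps_o) + gain * (ind - 0.25))
            self.steps_o = np.clip(self.steps_o, 1e-3, 5.0)

    # -- group-level blocks ------------------------------------------------
    def update_group_emissions(self):
        p = self.priors
        sum_mu = self.mu_i.sum(axis=0)
        self.mu = sample_conjugate_mean(sum_mu, self.n, np.maximum(self.tau, 1e-8),
                                        p.mean_loc, p.mean_scale, self.rng)
        rss = ((self.mu_i - self.mu[None]) ** 2).sum(axis=0)
        var, self.a_tau = sample_halfcauchy_variance(rss, self.n, self.a_tau, p.tau_scale, self.rng)
        self.tau = np.sqrt(var)

    def update_emission_interweave(self, iteration, burn_in):
        """Non-centered (interweaved) updates for the emission hierarchy.

        With the subject offsets d_i = mu_i - mu held fixed, the group mean
        conditional given the data is Gaussian and is drawn exactly; tau is
        then rescaled by a log-scale Metropolis move with the standardized
        offsets fixed, using the per-(patient, state, channel) sufficient
        statistics, so both hyperparameters move with the data directly.
        """
        p = self.priors
        counts, sums, sumsq = self._counts, self._sums, self._sumsq
        sig2 = self.sigma**2
        d = self.mu_i - self.mu[None]
        N = counts.sum(axis=0)
        prec = N / sig2 + 1.0 / p.mean_scale**2
        num = (sums.sum(axis=0) - (counts * d).sum(axis=0)) / sig2 \
            + p.mean_loc / p.mean_scale**2
        self.mu = num / prec + self.rng.standard_normal(self.mu.shape) / np.sqrt(prec)
        self.mu_i = self.mu[None] + d

        tau = np.maximum(self.tau, 1e-8)
        delta = d / tau[None]
        f = np.exp(self.steps_t * self.rng.standard_normal(tau.shape))
        mu_i_new = self.mu[None] + (tau * f)[None] * delta

        def cell_ll(mu_i_arr):
            rss = (sumsq - 2.0 * mu_i_arr * sums + counts * mu_i_arr**2).sum(axis=0)
            return -0.5 * rss / sig2

        lp = cell_ll(mu_i_new) - cell_ll(self.mu_i)
        lp += np.log1p((tau / p.tau_scale) ** 2) - np.log1p((tau * f / p.tau_scale) ** 2)
        lp += np.log(f)  # Jacobian of the log-scale proposal
        acc = np.log(self.rng.random(tau.shape)) < lp
        self.tau = np.where(acc, tau * f, self.tau)
        self.mu_i = np.where(acc[None], mu_i_new, self.mu_i)
        if iteration < burn_in:
            gain = (iteration + 1.0) ** -0.6
            self.steps_t = np.exp(np.log(self.steps_t) + gain * (acc - 0.35))
            self.steps_t = np.clip(self.steps_t, 1e-3, 5.0)

    def update_group_transitions(self):
        if self.m == 1:
            return
        p = self.priors
        sum_a = self.alpha_i.sum(axis=0)
        self.alpha_bar = np.ascontiguousarray(sample_conjugate_mean(
            sum_a, self.n, np.maximum(self.omega, 1e-8),
            p.logit_loc, p.logit_scale, self.rng))
        rss = ((self.alpha_i - self.alpha_bar[None]) ** 2).sum(axis=0)
        var, self.a_omega = sample_halfcauchy_variance(rss, self.n, self.a_omega, p.omega_scale, self.rng)
        self.omega = np.sqrt(var)

    def iterate(self, iteration, burn_in):
        self.update_patient_label_swap()
        self.update_states()
        counts = self.update_subject_means()
        self.update_sigma(counts)
        trans_counts = self._transition_counts() if self.m > 1 else None
        # two sweeps of every transition block per scan: the sparse per-patient
        # transition counts make these the slowest-mixing blocks
        for _ in range(2):
            self.update_subject_transitions(trans_counts, iteration, burn_in)
            self.update_group_transitions()
            self.update_group_transition_shift(trans_counts, iteration, burn_in)
            self.update_omega_scale(trans_counts, iteration, burn_in)
        self.update_group_emissions()
        self.update_emission_interweave(iteration, burn_in)


def _omega_full(alpha_like: np.ndarray) -> np.ndarray:
    """(m, m-1) diagonal-reference cell layout -> (m, m) with NaN diagonal."""
    m = alpha_like.shape[0]
    out = np.full((m, m), np.nan)
    for r in range(m):
        off = [j for j in range(m) if j != r]
        out[r, off] = alpha_like[r]
    return out


def fit_mhmm(panel: EsmPanel, m: int, n_iter: int = 10_000, burn_in: int = 5_000,
             chains: int = 1, priors: Priors | None = None, seed: int = 0,
             ordering_channel: str | None = None) -> PosteriorDraws:
    """Fit the multilevel HMM by MCMC and return multi-chain posterior draws.

    Chains run sequentially; chain c uses the derived seed (seed, c), so the
    full run replays bit-exactly. Default run length is 10,000 iterations
    with a 5,000 burn-in.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (n_iter > burn_in >= 0):
        raise ValueError("need n_iter > burn_in >= 0")
    if chains < 1:
        raise ValueError("chains must be >= 1")
    priors = priors or Priors()
    y, lengths = panel.to_arrays()
    n, T, K = y.shape
    C = chains
    draws = PosteriorDraws(
        channels=panel.channels, patient_ids=panel.patient_ids, m=m,
        n_iter=n_iter, burn_in=burn_in, n_chains=C, seed=seed,
        data_hash=panel.content_hash(),
        mu=np.empty((C, n_iter, m, K)), tau=np.empty((C, n_iter, m, K)),
        sigma=np.empty((C, n_iter, m, K)), gamma_bar=np.empty((C, n_iter, m, m)),
        omega=np.empty((C, n_iter, m, m)),
        mu_i=np.empty((C, n_iter, n, m, K), dtype=np.float32),
        gamma_i=np.empty((C, n_iter, n, m, m), dtype=np.float32),
        states=np.full((C, n_iter, n, T), -1, dtype=np.int8),
        accept_rate=np.zeros((C, n, m)),
    )
    for c in range(C):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((int(seed), c))))
        group, mu_i0, alpha_i0 = init_chain(panel, m, seed=int(seed) * 131 + c,
                                            ordering_channel=ordering_channel)
        sampler = MHMMSampler(y, lengths, m, priors, rng, group, mu_i0, alpha_i0)
        accepts_at_burn = 0
        report_every = max(n_iter // 10, 1)
        for it in range(n_iter):
            sampler.iterate(it, burn_in)
            if it + 1 == burn_in:
                accepts_at_burn = sampler.accepts.copy()
                sweeps_at_burn = sampler.n_sweeps
            draws.mu[c, it] = sampler.mu
            draws.tau[c, it] = sampler.tau
            draws.sigma[c, it] = sampler.sigma
            if m > 1:
                draws.gamma_bar[c, it] = _kernels.gamma_from_diag_logits(
                    np.ascontiguousarray(sampler.alpha_bar))
                draws.omega[c, it] = _omega_full(sampler.omega)
                draws.gamma_i[c, it] = sampler.subject_gammas()
            else:
                draws.gamma_bar[c, it] = 1.0
                draws.omega[c, it] = np.nan
                draws.gamma_i[c, it] = 1.0
            draws.mu_i[c, it] = sampler.mu_i
            for i in range(n):
                draws.states[c, it, i, : lengths[i]] = sampler.S[i, : lengths[i]]
            if (it + 1) % report_every == 0:
                logger.info("chain %d: iteration %d/%d", c + 1, it + 1, n_iter)
        if burn_in == 0:
            sweeps_at_burn = 0
        post_sweeps = max((sampler.n_sweeps - sweeps_at_burn) * max(m - 1, 1), 1)
        draws.accept_rate[c] = (sampler.accepts - accepts_at_burn) / post_sweeps
    return draws


# ---------------------------------------------------------------------------
# relabeling and summaries
# ---------------------------------------------------------------------------

def relabel_states(draws: PosteriorDraws, ordering_channel: str = "negative_affect",
                   fallback_channel: str = "self_control") -> PosteriorDraws:
    """Resolve label switching: permute every post-burn-in draw so the group
    means of the ordering channel increase with the state index (severity
    order). Ties broken by the fallback channel descending, then by index.
    Idempotent; the same permutation is applied to all parameters and paths.
    """
    import copy

    if draws.m == 1:
        out = copy.copy(draws)
        out.relabeled = True
        return out
    ch = draws.channels.index(ordering_channel) if ordering_channel in draws.channels else 0
    fb = draws.channels.index(fallback_channel) if fallback_channel in draws.channels else ch
    out = copy.copy(draws)
    for name in ("mu", "tau", "sigma", "gamma_bar", "omega", "mu_i", "gamma_i", "states"):
        setattr(out, name, getattr(draws, name).copy())
    m = draws.m
    for c in range(draws.n_chains):
        for it in range(draws.burn_in, draws.n_iter):
            key = out.mu[c, it]
            perm = np.lexsort((np.arange(m), -key[:, fb], key[:, ch]))
            if np.array_equal(perm, np.arange(m)):
                continue
            inv = np.argsort(perm)
            out.mu[c, it] = out.mu[c, it][perm]
            out.tau[c, it] = out.tau[c, it][perm]
            out.sigma[c, it] = out.sigma[c, it][perm]
            out.gamma_bar[c, it] = out.gamma_bar[c, it][np.ix_(perm, perm)]
            out.omega[c, it] = out.omega[c, it][np.ix_(perm, perm)]
            out.mu_i[c, it] = out.mu_i[c, it][:, perm]
            out.gamma_i[c, it] = out.gamma_i[c, it][:, perm][:, :, perm]
            st = out.states[c, it]
            valid = st >= 0
            st[valid] = inv[st[valid]].astype(np.int8)
    out.relabeled = True
    return out


@dataclass
class PosteriorSummary:
    """Posterior medians and central 95% intervals (tidy tables)."""

    group_emissions: pd.DataFrame
    group_transitions: pd.DataFrame
    subject_emissions: pd.DataFrame
    subject_transitions: pd.DataFrame
    m: int
    channels: tuple
    patient_ids: list
    n_draws: int
    data_hash: str
    relabeled: bool

    def group_point_params(self):
        """(mu, sigma, gamma) posterior-median group parameters; transition
        rows renormalized to sum to one."""
        ge = self.group_emissions
        mu = _pivot(ge[ge.parameter == "mean"], self.m, self.channels)
        sigma = _pivot(ge[ge.parameter == "within_sd"], self.m, self.channels)
        gt = self.group_transitions
        gamma = np.empty((self.m, self.m))
        for _, row in gt.iterrows():
            gamma[int(row.from_state) - 1, int(row.to_state) - 1] = row["median"]
        gamma /= gamma.sum(axis=1, keepdims=True)
        return mu, sigma, gamma

    def subject_point_params(self, patient_id):
        se = self.subject_emissions
        se = se[se.patient_id == patient_id]
        mu = _pivot(se, self.m, self.channels)
        st = self.subject_transitions
        st = st[st.patient_id == patient_id]
        gamma = np.empty((self.m, self.m))
        for _, row in st.iterrows():
            gamma[int(row.from_state) - 1, int(row.to_state) - 1] = row["median"]
        gamma /= gamma.sum(axis=1, keepdims=True)
        return mu, gamma

    def to_dir(self, path):
        import pathlib

        path = pathlib.Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.group_emissions.to_csv(path / "group_emissions.csv", index=False)
        self.group_transitions.to_csv(path / "group_transitions.csv", index=False)
        self.subject_emissions.to_csv(path / "subject_emissions.csv", index=False)
        self.subject_transitions.to_csv(path / "subject_transitions.csv", index=False)
        meta = {
            "m": int(self.m), "channels": list(self.channels),
            "patient_ids": [str(p) for p in self.patient_ids],
            "n_draws": int(self.n_draws), "data_hash": self.data_hash,
            "relabeled": bool(self.relabeled),
        }
        with open(path / "summary_meta.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def from_dir(cls, path):
        import pathlib

        path = pathlib.Path(path)
        with open(path / "summary_meta.yaml", encoding="utf-8") as fh:
            meta = yaml.safe_load(fh)
        return cls(
            group_emissions=pd.read_csv(path / "group_emissions.csv"),
            group_transitions=pd.read_csv(path / "group_transitions.csv"),
            subject_emissions=pd.read_csv(path / "subject_emissions.csv"),
            subject_transitions=pd.read_csv(path / "subject_transitions.csv"),
            m=meta["m"], channels=tuple(meta["channels"]),
            patient_ids=meta["patient_ids"], n_draws=meta["n_draws"],
            data_hash=meta["data_hash"], relabeled=meta["relabeled"],
        )


def _pivot(df: pd.DataFrame, m: int, channels) -> np.ndarray:
    out = np.empty((m, len(channels)))
    for _, row in df.iterrows():
        out[int(row.state) - 1, list(channels).index(row.channel)] = row["median"]
    return out


def _quantiles(x: np.ndarray, axis=0):
    med = np.median(x, axis=axis)
    lo = np.quantile(x, 0.025, axis=axis)
    hi = np.quantile(x, 0.975, axis=axis)
    return med, lo, hi


def posterior_summary(draws: PosteriorDraws) -> PosteriorSummary:
    """Posterior medians and central 95% credible intervals, pooled over
    chains post burn-in. Transition parameters are summarized on the
    probability scale (per-draw transform, then quantiles), so summarized
    rows need not sum exactly to one."""
    n_post = draws.n_post()
    if n_post < 100:
        raise ValueError(f"need >= 100 post-burn-in draws, have {n_post}")
    m, K = draws.m, draws.K
    chs = draws.channels

    def pooled(arr):
        a = draws.post_burn(arr)
        return a.reshape(-1, *a.shape[2:])

    rows = []
    for name, arr in (("mean", pooled(draws.mu)), ("within_sd", pooled(draws.sigma)),
                      ("between_sd", pooled(draws.tau))):
        med, lo, hi = _quantiles(arr)
        for s in range(m):
            for k in range(K):
                rows.append(("sample", name, s + 1, chs[k], med[s, k], lo[s, k], hi[s, k]))
    group_emissions = pd.DataFrame(
        rows, columns=["level", "parameter", "state", "channel", "median", "lo", "hi"])

    med, lo, hi = _quantiles(pooled(draws.gamma_bar))
    rows = [(r + 1, j + 1, med[r, j], lo[r, j], hi[r, j]) for r in range(m) for j in range(m)]
    group_transitions = pd.DataFrame(rows, columns=["from_state", "to_state", "median", "lo", "hi"])

    med, lo, hi = _quantiles(pooled(draws.mu_i).astype(float))
    rows = []
    for i, pid in enumerate(draws.patient_ids):
        for s in range(m):
            for k in range(K):
                rows.append((pid, s + 1, chs[k], med[i, s, k], lo[i, s, k], hi[i, s, k]))
    subject_emissions = pd.DataFrame(
        rows, columns=["patient_id", "state", "channel", "median", "lo", "hi"])

    med, lo, hi = _quantiles(pooled(draws.gamma_i).astype(float))
    rows = []
    for i, pid in enumerate(draws.patient_ids):
        for r in range(m):
            for j in range(m):
                rows.append((pid, r + 1, j + 1, med[i, r, j], lo[i, r, j], hi[i, r, j]))
    subject_transitions = pd.DataFrame(
        rows, columns=["patient_id", "from_state", "to_state", "median", "lo", "hi"])

    return PosteriorSummary(
        group_emissions=group_emissions, group_transitions=group_transitions,
        subject_emissions=subject_emissions, subject_transitions=subject_transitions,
        m=m, channels=chs, patient_ids=draws.patient_ids, n_draws=n_post,
        data_hash=draws.data_hash, relabeled=draws.relabeled)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_draws(draws: PosteriorDraws, path, thin: int = 1,
               include_subject: bool = True, manifest_extra: dict | None = None) -> None:
    """Persist draws as per-chain long-format CSV plus a YAML run manifest."""
    import pathlib

    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    m, K, chs = draws.m, draws.K, draws.channels
    iters = np.arange(0, draws.n_iter, thin)
    for c in range(draws.n_chains):
        frames = []
        for name, arr, cols in (
            ("mean", draws.mu, chs), ("within_sd", draws.sigma, chs),
            ("between_sd", draws.tau, chs),
        ):
            a = arr[c][iters]
            frames.append(pd.DataFrame({
                "iteration": np.repeat(iters, m * K),
                "parameter": name,
                "state": np.tile(np.repeat(np.arange(1, m + 1), K), len(iters)),
                "column": np.tile(list(cols), len(iters) * m),
                "patient_id": "",
                "value": a.reshape(-1),
            }))
        a = draws.gamma_bar[c][iters]
        frames.append(pd.DataFrame({
            "iteration": np.repeat(iters, m * m),
            "parameter": "transition",
            "state": np.tile(np.repeat(np.arange(1, m + 1), m), len(iters)),
            "column": np.tile([f"to_{j + 1}" for j in range(m)], len(iters) * m),
            "patient_id": "",
            "value": a.reshape(-1),
        }))
        if include_subject:
            a = draws.mu_i[c][iters].astype(float)
            n = draws.n_patients
            frames.append(pd.DataFrame({
                "iteration": np.repeat(iters, n * m * K),
                "parameter": "subject_mean",
                "state": np.tile(np.repeat(np.arange(1, m + 1), K), len(iters) * n),
                "column": np.tile(list(chs), len(iters) * n * m),
                "patient_id": np.tile(np.repeat(draws.patient_ids, m * K), len(iters)),
                "value": a.reshape(-1),
            }))
        pd.concat(frames, ignore_index=True).to_csv(path / f"chain_{c}.csv", index=False)
    manifest = {
        "seed": int(draws.seed), "chains": int(draws.n_chains),
        "n_iter": int(draws.n_iter), "burn_in": int(draws.burn_in),
        "thin": int(thin), "m": int(m), "channels": list(chs),
        "data_hash": draws.data_hash, "relabeled": bool(draws.relabeled),
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(path / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
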