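"""Shared fixtures and independent oracles for the test suite.

The brute-force oracles below recompute HMM quantities by explicit path
enumeration with scipy densities; they share no code with the package's
recursions.
"""

from itertools import product

import numpy as np
import pytest
from hypothesis import settings
from scipy import stats

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from crisishmm import SimConfig, SubjectParams, simulate_panel


def brute_force_emission_logdensity(y_row, means, sds):
    """Per-state emission log density of one occasion by direct summation
    over observed channels (NaN = missing); log-space avoids underflow on
    extreme instances."""
    m = means.shape[0]
    out = np.zeros(m)
    for s in range(m):
        for k in range(means.shape[1]):
            if np.isfinite(y_row[k]):
                out[s] += stats.norm.logpdf(y_row[k], means[s, k], sds[s, k])
    return out


def brute_force_path_logprobs(y, params: SubjectParams):
    """Joint log probability of every state path by enumeration."""
    y = np.atleast_2d(y)
    T, m = y.shape[0], params.m
    dens = np.stack([brute_force_emission_logdensity(y[t], params.means, params.sds)
                     for t in range(T)])
    with np.errstate(divide="ignore"):
        log_gamma = np.log(params.gamma)
        log_init = np.log(params.init)
    paths, logps = [], []
    for path in product(range(m), repeat=T):
        lp = log_init[path[0]] + dens[0, path[0]]
        for t in range(1, T):
            lp += log_gamma[path[t - 1], path[t]] + dens[t, path[t]]
        paths.append(path)
        logps.append(lp)
    return np.array(paths), np.array(logps)


def brute_force_path_probs(y, params: SubjectParams):
    """(paths, normalized posterior path probabilities) by enumeration."""
    paths, logps = brute_force_path_logprobs(y, params)
    w = np.exp(logps - logps.max())
    return paths, w / w.sum()


def brute_force_loglik(y, params: SubjectParams) -> float:
    _, logps = brute_force_path_logprobs(y, params)
    from scipy.special import logsumexp

    return float(logsumexp(logps))


def brute_force_viterbi(y, params: SubjectParams) -> np.ndarray:
    """Argmax path by enumeration; first (lexicographically smallest) path
    wins exact ties, matching low-index tie-breaking."""
    paths, logps = brute_force_path_logprobs(y, params)
    return paths[int(np.argmax(logps))] + 1


def random_instance(seed, max_m=3, max_T=6, K=2, with_missing=True):
    """A random small HMM instance (params, data) for oracle comparisons."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(1, max_m + 1))
    T = int(rng.integers(1, max_T + 1))
    means = rng.normal(0, 5, size=(m, K))
    sds = rng.uniform(0.5, 3.0, size=(m, K))
    gamma = rng.dirichlet(np.ones(m) * 2, size=m)
    init = rng.dirichlet(np.ones(m) * 2)
    params = SubjectParams(means=means, sds=sds, gamma=gamma, init=init)
    y = rng.normal(0, 5, size=(T, K))
    if with_missing:
        y[rng.random((T, K)) < 0.25] = np.nan
    return params, y


@pytest.fixture(scope="session")
def toy_params_2state():
    """Well-separated two-state, two-channel toy used across oracle tests."""
    return SubjectParams(
        means=[[0.0, 0.0], [5.0, 5.0]],
        sds=[[1.0, 1.0], [1.0, 1.0]],
        gamma=[[0.8, 0.2], [0.3, 0.7]],
        init=[0.6, 0.4],
    )


@pytest.fixture(scope="session")
def small_config():
    """A small two-state design for fast end-to-end fits."""
    return SimConfig(
        n_patients=8, n_occasions=40, n_states=2, n_channels=5,
        group_means=[[30, 30, 20, 40, 10], [70, 60, 45, 35, 55]],
        between_sd=np.full((2, 5), 5.0), within_sd=np.full((2, 5), 10.0),
        group_transition=[[0.8, 0.2], [0.3, 0.7]], transition_re_sd=0.4,
        missing_rate=0.1, seed=5, clip_to_scale=False,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    panel, states, subjects = simulate_panel(small_config)
    return panel, states, subjects
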