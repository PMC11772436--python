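"""Model selection, convergence and goodness of fit.

AIC convention used throughout this package (recorded in every export): the
log-likelihood is the sum over patients of the exact marginal HMM likelihood
evaluated at the *group-level* posterior-median parameters, and the penalty
counts only the group-level free parameters, p = 2mK + m(m-1) (state-by-channel
means and SDs plus transition logits).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hmm import SubjectParams, forward_loglik, emission_log_b
from .fit import PosteriorDraws, PosteriorSummary, fit_mhmm, posterior_summary, relabel_states
from .simulate import EsmPanel

logger = logging.getLogger(__name__)

AIC_DEFINITION = ("AIC = -2 * sum_i loglik(y_i | group posterior medians)"
                  " + 2 * (2*m*K + m*(m-1))")


def compute_aic(panel: EsmPanel, summary: PosteriorSummary, m: int | None = None) -> float:
    """AIC of a fitted m-state model at group-level point parameters."""
    if summary.data_hash != panel.content_hash():
        raise ValueError("panel does not match the fitted summary (data hash mismatch)")
    m = m or summary.m
    if m != summary.m:
        raise ValueError("m disagrees with the summary")
    mu, sigma, gamma = summary.group_point_params()
    params = SubjectParams(means=mu, sds=sigma, gamma=gamma)
    ll = sum(forward_loglik(_drop_trailing_nan(panel.patient_values(pid)), params)
             for pid in panel.patient_ids)
    K = len(summary.channels)
    p = 2 * m * K + m * (m - 1)
    return float(-2.0 * ll + 2.0 * p)


def _drop_trailing_nan(y: np.ndarray) -> np.ndarray:
    return y


@dataclass
class SelectionResult:
    aic_by_m: dict
    selected_m: int | None
    convergence: dict
    failures: dict
    summaries: dict = field(default_factory=dict)


def select_num_states(panel: EsmPanel, m_range, n_iter=2000, burn_in=1000,
                      chains=1, seed=0, priors=None, keep_summaries=False) -> SelectionResult:
    """Fit each m in m_range, tabulate AIC, select the minimum.

    Ties within 1e-6 resolve to the smaller m; failed fits are recorded and
    excluded from selection.
    """
    m_range = list(m_range)
    if min(m_range) < 2:
        raise ValueError("m_range must start at 2 or above")
    if m_range != list(range(min(m_range), max(m_range) + 1)):
        raise ValueError("m_range must be contiguous")
    aic_by_m, convergence, failures, summaries = {}, {}, {}, {}
    for m in m_range:
        try:
            draws = fit_mhmm(panel, m, n_iter=n_iter, burn_in=burn_in,
                             chains=chains, seed=seed, priors=priors)
            draws = relabel_states(draws)
            summ = posterior_summary(draws)
            aic_by_m[m] = compute_aic(panel, summ)
            if chains >= 2:
                convergence[m] = float(max(gelman_rubin(draws).values()))
            if keep_summaries:
                summaries[m] = summ
        except Exception as exc:  # record, keep selecting over successes
            logger.warning("fit with m=%d failed: %s", m, exc)
            failures[m] = str(exc)
    selected = None
    for m in sorted(aic_by_m):
        if selected is None or aic_by_m[m] < aic_by_m[selected] - 1e-6:
            selected = m
    return SelectionResult(aic_by_m=aic_by_m, selected_m=selected,
                           convergence=convergence, failures=failures,
                           summaries=summaries)


# ---------------------------------------------------------------------------
# convergence
# ---------------------------------------------------------------------------

def psrf(chains: np.ndarray) -> float:
    """Classic (split-free) Gelman-Rubin potential scale reduction factor for
    one scalar parameter; `chains` is (n_chains, n_draws)."""
    chains = np.asarray(chains, dtype=float)
    c, n = chains.shape
    if c < 2:
        raise ValueError("PSRF needs at least 2 chains")
    W = chains.var(axis=1, ddof=1).mean()
    B = n * chains.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    # floored at 1: the pooled-variance estimate understates W by (n-1)/n in
    # finite samples, so identical chains would otherwise fall below 1
    return float(max(np.sqrt(var_hat / W), 1.0))


def gelman_rubin(draws: PosteriorDraws, flag_threshold: float = 1.20) -> dict:
    """PSRF for every scalar group-level parameter, post burn-in.

    Parameters with PSRF at or above `flag_threshold` are logged.
    """
    if draws.n_chains < 2:
        raise ValueError("Gelman-Rubin diagnostics require >= 2 chains")
    if draws.n_iter - draws.burn_in < 100:
        raise ValueError("need >= 100 post-burn-in draws per chain")
    m, K, chs = draws.m, draws.K, draws.channels
    out = {}

    def add(name, arr_cik):
        out[name] = psrf(arr_cik)

    mu = draws.post_burn(draws.mu)
    sigma = draws.post_burn(draws.sigma)
    tau = draws.post_burn(draws.tau)
    for s in range(m):
        for k in range(K):
            add(f"mean[{s + 1},{chs[k]}]", mu[:, :, s, k])
            add(f"within_sd[{s + 1},{chs[k]}]", sigma[:, :, s, k])
            add(f"between_sd[{s + 1},{chs[k]}]", tau[:, :, s, k])
    if m > 1:
        gb = draws.post_burn(draws.gamma_bar)
        om = draws.post_burn(draws.omega)
        for r in range(m):
            for j in range(m):
                add(f"transition[{r + 1},{j + 1}]", gb[:, :, r, j])
                if r != j:
                    add(f"omega[{r + 1},{j + 1}]", om[:, :, r, j])
    for name, value in out.items():
        if value >= flag_threshold:
            logger.warning("PSRF %.3f >= %.2f for %s", value, flag_threshold, name)
    return out


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------

def posterior_predictive_check(draws: PosteriorDraws, panel: EsmPanel,
                               n_rep: int = 200, seed: int = 0) -> pd.DataFrame:
    """Replicate the panel from thinned posterior draws and compare pooled
    per-channel means and SDs with the observed ones.

    Replicates reuse the observed missingness mask and the subject-level
    parameter draws, so the check covers the full two-level model.
    """
    n_post = draws.n_post()
    if n_rep < 1 or n_rep > n_post:
        raise ValueError(f"n_rep must be in [1, {n_post}]")
    rng = np.random.default_rng(seed)
    y, lengths = panel.to_arrays()
    obs = np.isfinite(y)
    n, T, K = y.shape
    post_len = draws.n_iter - draws.burn_in
    flat_idx = np.linspace(0, draws.n_chains * post_len - 1, n_rep).astype(int)
    stats_rep = np.empty((n_rep, K, 2))
    for r, fi in enumerate(flat_idx):
        c, it = divmod(int(fi), post_len)
        it += draws.burn_in
        mu_i = draws.mu_i[c, it].astype(float)        # (n, m, K)
        sigma = draws.sigma[c, it]                    # (m, K)
        gam = draws.gamma_i[c, it].astype(float)      # (n, m, m)
        gam /= gam.sum(axis=2, keepdims=True)
        cum = np.cumsum(gam, axis=2)
        s = np.empty((n, T), dtype=int)
        init = np.stack([_stationary_py(gam[i]) for i in range(n)])
        s[:, 0] = (rng.random((n, 1)) > np.cumsum(init, axis=1)).sum(axis=1)
        for t in range(1, T):
            rows = cum[np.arange(n), s[:, t - 1]]
            s[:, t] = (rng.random((n, 1)) > rows).sum(axis=1)
        y_rep = rng.normal(mu_i[np.arange(n)[:, None], s], sigma[s])
        for k in range(K):
            vals = y_rep[:, :, k][obs[:, :, k]]
            stats_rep[r, k] = (vals.mean(), vals.std(ddof=1))
    rows = []
    for k, ch in enumerate(panel.channels):
        vals = y[:, :, k][obs[:, :, k]]
        for j, stat in enumerate(("mean", "sd")):
            observed = vals.mean() if stat == "mean" else vals.std(ddof=1)
            rep = stats_rep[:, k, j]
            p_lo = (rep <= observed).mean()
            p_hi = (rep >= observed).mean()
            rows.append((ch, stat, observed, *np.quantile(rep, (0.025, 0.5, 0.975)),
                         float(min(1.0, 2 * min(p_lo, p_hi)))))
    return pd.DataFrame(rows, columns=["channel", "statistic", "observed",
                                       "q025", "q50", "q975", "p_value"])


def _stationary_py(gamma):
    from .hmm import stationary_distribution

    return stationary_distribution(gamma)


# ---------------------------------------------------------------------------
# pseudo-residuals
# ---------------------------------------------------------------------------

def pseudo_residuals(panel: EsmPanel, subject_params: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-step-ahead normal pseudo-residuals per observed channel value.

    Each observed value is transformed by its forecast CDF — the state-
    prediction-weighted mixture of the channel's Gaussian emission CDFs —
    and mapped through the standard normal quantile, so a well-specified
    model yields iid standard normal residuals. Missing values are skipped;
    PITs of exactly 0/1 are clamped to the nearest representable value.

    subject_params maps patient_id -> SubjectParams (decoded-model point
    parameters). Returns (residuals, summaries).
    """
    eps = 1e-12
    clamped = 0
    rows = []
    for pid in panel.patient_ids:
        params = subject_params[pid]
        y = panel.patient_values(pid)
        T, K = y.shape
        log_b = emission_log_b(y, params)
        filtered = None
        for t in range(T):
            pred = params.init if t == 0 else filtered @ params.gamma
            for k in range(K):
                if np.isfinite(y[t, k]):
                    z = (y[t, k] - params.means[:, k]) / params.sds[:, k]
                    pit = float(pred @ stats.norm.cdf(z))
                    if pit <= 0.0 or pit >= 1.0:
                        clamped += 1
                        pit = min(max(pit, eps), 1 - eps)
                    rows.append((pid, t + 1, panel.channels[k], stats.norm.ppf(pit)))
            w = pred * np.exp(log_b[t] - log_b[t].max())
            filtered = w / w.sum()
    if clamped:
        logger.warning("%d PIT values clamped away from {0,1}", clamped)
    resid = pd.DataFrame(rows, columns=["patient_id", "occasion", "channel", "residual"])
    summaries = []
    for (pid, ch), grp in resid.groupby(["patient_id", "channel"], sort=False):
        r = grp.sort_values("occasion")
        vals = r["residual"].to_numpy()
        occ = r["occasion"].to_numpy()
        pairs = occ[1:] == occ[:-1] + 1  # consecutive observed occasions only
        if pairs.sum() >= 3 and vals.std() > 0:
            a, b = vals[:-1][pairs], vals[1:][pairs]
            acf1 = float(np.corrcoef(a, b)[0, 1])
        else:
            acf1 = np.nan
        summaries.append((pid, ch, vals.mean(), vals.std(ddof=1), acf1, len(vals)))
    summary_df = pd.DataFrame(
        summaries, columns=["patient_id", "channel", "mean", "sd", "lag1_acf", "n_obs"])
    return resid, summary_df


# ---------------------------------------------------------------------------
# bundled report
# ---------------------------------------------------------------------------

@dataclass
class FitDiagnostics:
    aic_by_m: dict = field(default_factory=dict)
    selected_m: int | None = None
    rhat: dict = field(default_factory=dict)
    ppc_table: pd.DataFrame | None = None
    residual_summaries: pd.DataFrame | None = None
    aic_definition: str = AIC_DEFINITION

    def to_json(self, path) -> None:
        payload = {
            "aic_definition": self.aic_definition,
            "aic_by_m": {str(k): float(v) for k, v in self.aic_by_m.items()},
            "selected_m": self.selected_m,
            "rhat": {k: float(v) for k, v in self.rhat.items()},
            "rhat_max": float(max(self.rhat.values())) if self.rhat else None,
            "ppc": self.ppc_table.to_dict(orient="records") if self.ppc_table is not None else None,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    def write_tables(self, directory) -> None:
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        if self.aic_by_m:
            pd.DataFrame(sorted(self.aic_by_m.items()), columns=["m", "aic"]).to_csv(
                d / "aic_by_m.csv", index=False)
        if self.rhat:
            pd.DataFrame(sorted(self.rhat.items()), columns=["parameter", "rhat"]).to_csv(
                d / "rhat.csv", index=False)
        if self.ppc_table is not None:
            self.ppc_table.to_csv(d / "ppc_table.csv", index=False)
        if self.residual_summaries is not None:
            self.residual_summaries.to_csv(d / "pseudo_residual_summaries.csv", index=False)
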