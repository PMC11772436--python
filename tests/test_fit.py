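"""Sampler blocks against closed forms; relabeling; summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from crisishmm import (
    Priors,
    fit_mhmm,
    init_chain,
    posterior_summary,
    relabel_states,
    save_draws,
    simulate_panel,
)
from crisishmm.fit import (
    diag_logits_from_gamma,
    sample_conjugate_mean,
    sample_halfcauchy_variance,
    _omega_full,
)
from crisishmm._kernels import gamma_from_diag_logits
from crisishmm.simulate import SimConfig


class TestDiagLogits:
    def test_round_trip(self):
        gamma = np.array([[0.84, 0.10, 0.04, 0.02],
                          [0.06, 0.73, 0.14, 0.07],
                          [0.04, 0.20, 0.63, 0.13],
                          [0.02, 0.13, 0.28, 0.57]])
        back = gamma_from_diag_logits(np.ascontiguousarray(diag_logits_from_gamma(gamma)))
        assert np.allclose(back, gamma, atol=1e-12)

    def test_zero_logits_give_uniform(self):
        gamma = gamma_from_diag_logits(np.zeros((3, 2)))
        assert np.allclose(gamma, 1 / 3)


class TestConjugateBlocks:
    """Each Gibbs block run on fixed sufficient statistics matches the
    closed-form (or quadrature) posterior moments within Monte Carlo error."""

    def test_gaussian_mean_block(self):
        rng = np.random.default_rng(0)
        sum_x, n, lik_sd, prior_mean, prior_sd = 170.0, 20, 3.0, 0.0, 10.0
        draws = np.array([
            sample_conjugate_mean(sum_x, n, lik_sd, prior_mean, prior_sd, rng)
            for _ in range(20_000)
        ])
        prec = n / lik_sd**2 + 1 / prior_sd**2
        post_mean = (sum_x / lik_sd**2) / prec
        post_sd = 1 / np.sqrt(prec)
        assert abs(draws.mean() - post_mean) < 2 * post_sd / np.sqrt(len(draws)) * 1.5
        assert abs(draws.std(ddof=1) - post_sd) < 0.02 * post_sd * 3

    def test_halfcauchy_variance_block_matches_quadrature(self):
        """The (variance, auxiliary) Gibbs pair targets the half-Cauchy-prior
        posterior: compare the chain mean of the variance with numerical
        integration of p(v) ∝ v^{-(n+1)/2} e^{-rss/2v} / (1 + v/A^2)."""
        rng = np.random.default_rng(1)
        rss, n, scale = 250.0, 12, 10.0

        peak = rss / (n + 3)  # mode scale for stable quadrature

        def unnorm(v):
            # shifted to the mode in log-space so quad sees an O(1) integrand
            logp = -(n + 1) / 2 * np.log(v) - rss / (2 * v) - np.log1p(v / scale**2)
            logp0 = -(n + 1) / 2 * np.log(peak) - rss / (2 * peak)
            return np.exp(logp - logp0)

        pts = [peak / 4, peak / 2, peak, 2 * peak, 4 * peak, 10 * peak]
        Z, _ = integrate.quad(unnorm, 1e-8, 1e4, limit=800, points=pts)
        EV, _ = integrate.quad(lambda v: v * unnorm(v), 1e-8, 1e4, limit=800, points=pts)
        expected = EV / Z
        var, aux = 1.0, 1.0
        chain = np.empty(20_000)
        for i in range(len(chain)):
            var, aux = sample_halfcauchy_variance(rss, n, aux, scale, rng)
            chain[i] = var
        mcse = chain.std(ddof=1) / np.sqrt(len(chain) / 10)  # generous ESS deflation
        assert abs(chain.mean() - expected) < 3 * mcse


class TestInitChain:
    def test_ordering_channel_monotone(self, small_panel):
        panel, _, _ = small_panel
        group, mu_i0, _ = init_chain(panel, 2, seed=0)
        k = panel.channels.index("negative_affect")
        assert np.all(np.diff(group.mu[:, k]) >= 0)

    def test_different_seeds_differ(self, small_panel):
        panel, _, _ = small_panel
        g1, _, _ = init_chain(panel, 2, seed=0)
        g2, _, _ = init_chain(panel, 2, seed=1)
        assert not np.allclose(g1.mu, g2.mu)

    def test_bimodal_sample_bracket(self):
        """m=2 starting means bracket the modes of a two-point mixture."""
        rng = np.random.default_rng(3)
        comp = rng.random((6, 80)) < 0.5
        vals = np.where(comp, rng.normal(20, 4, (6, 80)), rng.normal(70, 4, (6, 80)))
        from crisishmm import EsmPanel

        panel = EsmPanel.from_values([v[:, None] for v in vals],
                                     channels=("negative_affect",))
        group, _, _ = init_chain(panel, 2, seed=0)
        assert 10 < group.mu[0, 0] < 35
        assert 55 < group.mu[1, 0] < 85

    def test_all_missing_channel_rejected(self, small_panel):
        panel, _, _ = small_panel
        broken = panel.df.copy()
        broken["self_control"] = np.nan
        from crisishmm import EsmPanel

        with pytest.raises(ValueError, match="self_control"):
            init_chain(EsmPanel(df=broken, channels=panel.channels), 2, seed=0)


@pytest.fixture(scope="module")
def small_fit(small_panel):
    panel, states, subjects = small_panel
    draws = fit_mhmm(panel, 2, n_iter=800, burn_in=400, chains=2, seed=11)
    return panel, states, subjects, relabel_states(draws)


class TestFitMhmm:
    def test_argument_validation(self, small_panel):
        panel, _, _ = small_panel
        with pytest.raises(ValueError):
            fit_mhmm(panel, 2, n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            fit_mhmm(panel, 0)

    def test_single_state_reduces_to_hierarchical_gaussian(self):
        """m=1: posterior mean of the group mean lands within ~2 posterior SDs
        of the generating value (conjugate hierarchical-model behaviour)."""
        cfg = SimConfig(n_patients=12, n_occasions=50, n_states=1, n_channels=2,
                        channel_names=("negative_affect", "self_control"),
                        group_means=[[40.0, 60.0]], between_sd=[[5.0, 5.0]],
                        within_sd=[[8.0, 8.0]],
                        group_transition=[[1.0]], transition_re_sd=0.0,
                        missing_rate=0.1, seed=21, clip_to_scale=False)
        panel, _, _ = simulate_panel(cfg)
        draws = fit_mhmm(panel, 1, n_iter=600, burn_in=300, chains=1, seed=2)
        mu = draws.post_burn(draws.mu).reshape(-1, 2)
        for k, truth in enumerate((40.0, 60.0)):
            sd = mu[:, k].std(ddof=1)
            assert abs(mu[:, k].mean() - truth) < 3 * max(sd, 1.0)

    def test_recovers_two_state_structure(self, small_fit):
        panel, _, _, draws = small_fit
        su = posterior_summary(draws)
        ge = su.group_emissions
        means = ge[ge.parameter == "mean"].pivot_table(
            index="state", columns="channel", values="median")
        # generating config: state 1 = (30,30,20,40,10), state 2 = (70,60,45,35,55)
        assert abs(means.loc[1, "self_control"] - 30) < 8
        assert abs(means.loc[2, "self_control"] - 70) < 8
        assert abs(means.loc[1, "suicidal_ideation"] - 10) < 8
        assert abs(means.loc[2, "suicidal_ideation"] - 55) < 8

    def test_metropolis_acceptance_in_healthy_band(self, small_fit):
        _, _, _, draws = small_fit
        assert 0.10 < draws.accept_rate.mean() < 0.60

    def test_deterministic_replay(self, small_panel):
        panel, _, _ = small_panel
        d1 = fit_mhmm(panel, 2, n_iter=120, burn_in=60, chains=1, seed=5)
        d2 = fit_mhmm(panel, 2, n_iter=120, burn_in=60, chains=1, seed=5)
        assert np.array_equal(d1.mu, d2.mu)
        assert np.array_equal(d1.states, d2.states)
        assert np.array_equal(d1.gamma_i, d2.gamma_i)


class TestRelabelStates:
    def test_idempotent(self, small_fit):
        _, _, _, draws = small_fit
        again = relabel_states(draws)
        assert np.array_equal(again.mu, draws.mu)
        assert np.array_equal(again.states, draws.states)

    def test_constructed_swap_is_undone(self, small_fit):
        _, _, _, draws = small_fit
        import copy

        swapped = copy.copy(draws)
        perm = np.array([1, 0])
        for name in ("mu", "tau", "sigma", "gamma_bar", "omega", "mu_i", "gamma_i", "states"):
            setattr(swapped, name, getattr(draws, name).copy())
        it = draws.burn_in + 3
        swapped.mu[0, it] = swapped.mu[0, it][perm]
        swapped.tau[0, it] = swapped.tau[0, it][perm]
        swapped.sigma[0, it] = swapped.sigma[0, it][perm]
        swapped.gamma_bar[0, it] = swapped.gamma_bar[0, it][np.ix_(perm, perm)]
        swapped.omega[0, it] = swapped.omega[0, it][np.ix_(perm, perm)]
        swapped.mu_i[0, it] = swapped.mu_i[0, it][:, perm]
        swapped.gamma_i[0, it] = swapped.gamma_i[0, it][:, perm][:, :, perm]
        st = swapped.states[0, it]
        st[st >= 0] = perm[st[st >= 0]].astype(np.int8)
        fixed = relabel_states(swapped)
        assert np.allclose(fixed.mu, draws.mu)
        assert np.array_equal(fixed.states, draws.states)

    def test_ordering_channel_ascending_in_every_draw(self, small_fit):
        _, _, _, draws = small_fit
        k = draws.channels.index("negative_affect")
        mu = draws.post_burn(draws.mu)[..., k]
        assert np.all(np.diff(mu, axis=-1) >= 0)


class TestPosteriorSummary:
    def test_requires_enough_draws(self, small_panel):
        panel, _, _ = small_panel
        draws = fit_mhmm(panel, 2, n_iter=120, burn_in=60, chains=1, seed=5)
        with pytest.raises(ValueError, match="100"):
            posterior_summary(draws)

    def test_transition_rows_sum_to_about_one(self, small_fit):
        _, _, _, draws = small_fit
        su = posterior_summary(draws)
        gt = su.group_transitions
        for _, row in gt.groupby("from_state")["median"].sum().items():
            assert abs(row - 1.0) < 0.05  # summaries of simplex draws

    def test_median_close_to_mean_for_symmetric_marginals(self, small_fit):
        _, _, _, draws = small_fit
        mu = draws.post_burn(draws.mu).reshape(-1, 2, 5)
        med = np.median(mu, axis=0)
        assert np.allclose(med, mu.mean(axis=0), atol=1.0)

    def test_round_trip_to_dir(self, tmp_path, small_fit):
        _, _, _, draws = small_fit
        su = posterior_summary(draws)
        su.to_dir(tmp_path / "summary")
        from crisishmm import PosteriorSummary

        back = PosteriorSummary.from_dir(tmp_path / "summary")
        pd.testing.assert_frame_equal(back.group_emissions, su.group_emissions)
        assert back.data_hash == su.data_hash
        mu1, sig1, g1 = su.group_point_params()
        mu2, sig2, g2 = back.group_point_params()
        assert np.allclose(g1, g2)


def test_omega_full_layout():
    cells = np.array([[1.0, 2.0, 3.0],
                      [4.0, 5.0, 6.0],
                      [7.0, 8.0, 9.0],
                      [10.0, 11.0, 12.0]])
    full = _omega_full(cells)
    assert np.all(np.isnan(np.diag(full)))
    assert full[0, 1] == 1.0 and full[1, 0] == 4.0 and full[3, 2] == 12.0


def test_save_draws_writes_chain_files(tmp_path, small_panel):
    panel, _, _ = small_panel
    draws = fit_mhmm(panel, 2, n_iter=60, burn_in=30, chains=2, seed=6)
    save_draws(draws, tmp_path / "draws", thin=5)
    files = sorted(p.name for p in (tmp_path / "draws").iterdir())
    assert files == ["chain_0.csv", "chain_1.csv", "manifest.yaml"]
    df = pd.read_csv(tmp_path / "draws" / "chain_0.csv")
    assert set(df.parameter) >= {"mean", "within_sd", "between_sd", "transition", "subject_mean"}
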