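"""Synthetic ESM generator: design constants, randomness contracts, IO."""

import numpy as np
import pandas as pd
import pytest

from crisishmm import (
    EsmPanel,
    SimConfig,
    apply_missingness,
    default_study_config,
    simulate_panel,
)
from crisishmm.simulate import (
    ConfigError,
    STUDY_STATE_MEANS,
    STUDY_TRANSITION,
    draw_subject_params,
    subject_params_frame,
    _patient_rng,
)


class TestDefaultStudyConfig:
    def test_design_constants(self):
        cfg = default_study_config()
        assert (cfg.n_patients, cfg.n_occasions, cfg.n_states, cfg.n_channels) == (26, 60, 4, 5)
        assert cfg.channel_names == ("self_control", "negative_affect",
                                     "contact_avoidance", "contact_desire",
                                     "suicidal_ideation")

    def test_state_means_match_reported_values(self):
        cfg = default_study_config()
        # lowest state: distinctively low suicidal ideation; highest state:
        # lowest self-control and distinctively low contact desire
        assert cfg.group_means[3, 0] == pytest.approx(13.30)
        assert cfg.group_means[0, 4] == pytest.approx(3.85)
        assert cfg.group_means[3, 3] == pytest.approx(6.67)
        assert np.all(np.diff(cfg.group_means[:, 1]) > 0)  # negative affect ascends

    def test_staying_probabilities(self):
        cfg = default_study_config()
        assert np.allclose(np.diag(cfg.group_transition), (0.84, 0.73, 0.63, 0.57))

    def test_missing_rate(self):
        assert default_study_config().missing_rate == pytest.approx(14.23 / 60, abs=1e-12)

    def test_init_distribution_is_stationary(self):
        cfg = default_study_config()
        assert np.allclose(cfg.init_distribution @ cfg.group_transition,
                           cfg.init_distribution, atol=1e-10)

    def test_recovery_mode_disables_clipping(self):
        assert default_study_config().clip_to_scale
        assert not default_study_config(recovery=True).clip_to_scale


class TestConfigValidation:
    def test_bad_transition_rows_rejected(self):
        with pytest.raises(ConfigError, match="sum to 1"):
            SimConfig(n_states=2, n_channels=1, channel_names=("a",),
                      group_means=[[1], [2]], between_sd=[[1], [1]],
                      within_sd=[[1], [1]], group_transition=[[0.7, 0.2], [0.3, 0.7]])

    def test_bad_missing_rate_rejected(self):
        with pytest.raises(ConfigError, match="missing_rate"):
            default_study_config().__class__(missing_rate=1.0)

    def test_nonpositive_within_sd_rejected(self):
        with pytest.raises(ConfigError, match="within_sd"):
            SimConfig(within_sd=np.zeros((4, 5)))

    def test_yaml_round_trip(self, tmp_path):
        cfg = default_study_config(recovery=True)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = SimConfig.from_yaml(path)
        assert np.allclose(back.group_means, cfg.group_means)
        assert np.allclose(back.group_transition, cfg.group_transition)
        assert back.clip_to_scale == cfg.clip_to_scale
        assert back.channel_names == cfg.channel_names


class TestSimulatePanel:
    def test_full_design_has_1560_slots(self):
        cfg = default_study_config()
        cfg.missing_rate = 0.0
        panel, states, subjects = simulate_panel(cfg)
        assert len(panel.df) == 26 * 60
        for ch in panel.channels:
            assert panel.df[ch].notna().sum() == 1560

    def test_no_random_effects_copies_group_params(self):
        cfg = default_study_config(recovery=True)
        cfg.between_sd = np.zeros((4, 5))
        cfg.transition_re_sd = 0.0
        cfg.missing_rate = 0.0
        _, _, subjects = simulate_panel(cfg)
        for subj in subjects:
            assert np.allclose(subj.means, cfg.group_means)
            assert np.allclose(subj.gamma, cfg.group_transition, atol=1e-12)

    def test_empirical_transitions_match_subject_matrix(self):
        """Long single-patient chain: transition frequencies within 3 MC
        standard errors of the generating matrix."""
        cfg = SimConfig(n_patients=1, n_occasions=5000, seed=42,
                        missing_rate=0.0, clip_to_scale=False)
        _, states, subjects = simulate_panel(cfg)
        s = states["state"].to_numpy() - 1
        counts = np.zeros((4, 4))
        np.add.at(counts, (s[:-1], s[1:]), 1)
        row_n = counts.sum(axis=1, keepdims=True)
        emp = counts / row_n
        g = subjects[0].gamma
        se = np.sqrt(g * (1 - g) / row_n)
        assert np.all(np.abs(emp - g) <= 3 * se + 1e-9)

    def test_true_states_cover_missing_occasions(self):
        cfg = default_study_config()
        panel, states, _ = simulate_panel(cfg)
        assert len(states) == 26 * 60  # defined everywhere, even when masked

    def test_clipping_bounds_scores(self):
        panel, _, _ = simulate_panel(default_study_config())
        vals = panel.df[list(panel.channels)].to_numpy()
        vals = vals[np.isfinite(vals)]
        assert vals.min() >= 1.0 and vals.max() <= 100.0

    def test_deterministic_given_seed(self):
        cfg = default_study_config(seed=9)
        p1, s1, _ = simulate_panel(cfg)
        p2, s2, _ = simulate_panel(default_study_config(seed=9))
        pd.testing.assert_frame_equal(p1.df, p2.df)
        pd.testing.assert_frame_equal(s1, s2)

    def test_patient_streams_stable_under_subsetting(self):
        """Patient i's data depend only on (seed, i), not on the panel size."""
        big = default_study_config(seed=4)
        small = default_study_config(seed=4)
        small.n_patients = 3
        pb, _, _ = simulate_panel(big)
        ps, _, _ = simulate_panel(small)
        pd.testing.assert_frame_equal(
            pb.df[pb.df.patient_id.isin(ps.patient_ids)].reset_index(drop=True), ps.df)

    def test_pooled_state_means_converge_to_group_means(self):
        """Law of large numbers at a larger design: per-state pooled means
        approach the generating group means."""
        cfg = SimConfig(n_patients=200, n_occasions=200, seed=17,
                        missing_rate=0.0, clip_to_scale=False)
        panel, states, _ = simulate_panel(cfg)
        y, _ = panel.to_arrays()
        s = states.pivot(index="patient_id", columns="occasion", values="state")
        s = s.loc[panel.patient_ids].to_numpy() - 1
        for st in range(4):
            pooled = y[s == st].mean(axis=0)
            # between-patient SD 8 over ~200 patients -> SE below ~0.7
            assert np.allclose(pooled, STUDY_STATE_MEANS[st], atol=2.0)


class TestMissingness:
    def test_zero_rate_is_identity(self, small_panel):
        panel, _, _ = small_panel
        out = apply_missingness(panel, 0.0, seed=1)
        pd.testing.assert_frame_equal(out.df, panel.df)

    def test_rows_masked_never_deleted(self, small_panel):
        panel, _, _ = small_panel
        out = apply_missingness(panel, 0.5, seed=1)
        assert len(out.df) == len(panel.df)

    def test_beep_level_missingness(self, small_panel):
        panel, _, _ = small_panel
        out = apply_missingness(panel, 0.4, seed=2)
        na = out.df[list(out.channels)].isna()
        assert (na.all(axis=1) | ~na.any(axis=1)).all()  # whole occasions only

    def test_mean_missing_occasions_matches_study(self):
        """At the study rate, the long-run mean is ~14.23 of 60 occasions."""
        cfg = default_study_config()
        cfg.missing_rate = 0.0
        panel, _, _ = simulate_panel(cfg)
        rate = 14.23 / 60
        means = [
            apply_missingness(panel, rate, seed=s).missing_occasions_per_patient().mean()
            for s in range(200)
        ]
        assert 13.2 < np.mean(means) < 15.3

    def test_invalid_rate_rejected(self, small_panel):
        panel, _, _ = small_panel
        with pytest.raises(ConfigError):
            apply_missingness(panel, 1.0, seed=0)


class TestPanelIO:
    def test_csv_round_trip_bit_exact(self, tmp_path, small_panel):
        panel, _, _ = small_panel
        path = tmp_path / "panel.csv"
        masked = apply_missingness(panel, 0.3, seed=3)
        masked.write_csv(path)
        back = EsmPanel.read_csv(path)
        assert back.channels == masked.channels
        pd.testing.assert_frame_equal(back.df, masked.df, check_dtype=False)

    def test_nonconsecutive_occasions_rejected(self):
        df = pd.DataFrame({
            "patient_id": ["a", "a"], "occasion": [1, 3], "day": [1, 1],
            "beep": [1, 3], "x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="consecutive"):
            EsmPanel(df=df, channels=("x",))

    def test_subject_params_frame_shape(self, small_panel):
        panel, _, subjects = small_panel
        frame = subject_params_frame(subjects, panel.patient_ids, panel.channels)
        m, K, n = 2, 5, panel.n_patients
        assert len(frame) == n * (m * K + m * m)


def test_subject_param_draws_center_on_group(small_config):
    """Random effects are unbiased: subject means average to the group means
    and transition rows average (on logits) to the group rows."""
    rng = np.random.default_rng(0)
    draws = [draw_subject_params(small_config, rng) for _ in range(2000)]
    mean_of_means = np.mean([d.means for d in draws], axis=0)
    assert np.allclose(mean_of_means, small_config.group_means, atol=0.5)


def test_patient_rng_streams_are_distinct():
    a = _patient_rng(0, 0).random(4)
    b = _patient_rng(0, 1).random(4)
    assert not np.allclose(a, b)
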