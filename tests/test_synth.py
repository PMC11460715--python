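"""Generator contracts: structure, seeding, and ground-truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from densefc import synth
from densefc.synth import EffectSpec, InvalidConfigError, SynthConfig


class TestAtlas:
    @pytest.mark.parametrize(
        "n_rois,n_networks",
        [(300, 13), (4, 2), (10, 10)],
    )
    def test_every_roi_labeled_and_communities_nonempty(self, n_rois, n_networks):
        atlas = synth.gen_atlas(n_rois, n_networks, seed=1)
        assert len(atlas) == n_rois
        counts = atlas["network"].value_counts()
        assert len(counts) == n_networks
        assert (counts >= 1).all()
        if n_rois == n_networks:
            assert (counts == 1).all()

    def test_coordinates_unique(self):
        atlas = synth.gen_atlas(50, 5, seed=3)
        coords = atlas[["x", "y", "z"]].to_numpy()
        assert len(np.unique(coords, axis=0)) == 50

    def test_too_few_rois_rejected(self):
        with pytest.raises(InvalidConfigError):
            synth.gen_atlas(3, 5, seed=0)


class TestBehavior:
    def test_white_noise_has_negligible_autocorrelation(self):
        cfg = SynthConfig(n_sessions=4, n_days=400, n_rois=4, n_networks=2,
                          session_days=[20, 30, 40, 50], ar_coefficient=0.0,
                          missing_fraction=0.0, seed=5)
        b = synth.gen_behavior(cfg)
        x = b.truth["total_sleep"].to_numpy()
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 3 / np.sqrt(400)

    def test_ar_coefficient_recovered(self):
        cfg = SynthConfig(n_sessions=4, n_days=500, n_rois=4, n_networks=2,
                          session_days=[20, 30, 40, 50], ar_coefficient=0.8,
                          missing_fraction=0.0, seed=6)
        b = synth.gen_behavior(cfg)
        x = b.truth["restless"].to_numpy()
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert 0.7 <= r1 <= 0.9

    def test_standardized_before_missingness(self, small_config):
        b = synth.gen_behavior(small_config)
        assert np.allclose(b.truth.mean(), 0, atol=1e-12)
        assert np.allclose(b.truth.std(ddof=1), 1, atol=1e-12)

    def test_missingness_fraction_zero_means_complete(self):
        cfg = SynthConfig(n_sessions=4, n_days=60, n_rois=4, n_networks=2,
                          session_days=[20, 30, 40, 50], missing_fraction=0.0, seed=2)
        b = synth.gen_behavior(cfg)
        assert not b.table.isna().any().any()

    def test_ar_coefficient_out_of_range_rejected(self):
        with pytest.raises(InvalidConfigError):
            SynthConfig(ar_coefficient=1.0)


class TestSessions:
    def test_zero_slope_baseline_correlation(self, small_atlas):
        cfg = SynthConfig(n_sessions=12, n_days=80, n_rois=20, n_networks=4,
                          session_days=synth.default_session_days(12),
                          n_time=600, base_within=0.3, seed=9)
        b = synth.gen_behavior(cfg)
        spec = EffectSpec(target_links=[(0, 4)], factor_name="steps",
                          lag_days=0, slope=0.0, base_corr=0.4)
        sessions, truth = synth.gen_sessions(cfg, small_atlas, b, [spec])
        assert np.allclose(truth["generating_corr"], 0.4)
        est = [np.corrcoef(s.data[:, 0], s.data[:, 4])[0, 1] for s in sessions]
        assert abs(np.mean(est) - 0.4) < 0.1

    def test_injected_sign_recovered(self, small_atlas):
        cfg = SynthConfig(n_sessions=30, n_days=133, n_rois=20, n_networks=4,
                          n_time=800, seed=10)
        b = synth.gen_behavior(cfg)
        spec = EffectSpec(target_links=[(0, 4)], factor_name="total_sleep",
                          lag_days=0, slope=0.3, base_corr=0.2)
        sessions, truth = synth.gen_sessions(cfg, small_atlas, b, [spec])
        est = np.array([np.corrcoef(s.data[:, 0], s.data[:, 4])[0, 1] for s in sessions])
        f = b.truth["total_sleep"].loc[cfg.session_days].to_numpy()
        assert np.corrcoef(est, f)[0, 1] > 0

    def test_generating_corr_tracks_factor_monotonically(self):
        spec = EffectSpec(target_links=[(0, 1)], factor_name="total_sleep",
                          lag_days=2, slope=0.5, base_corr=0.2)
        zs = np.linspace(-4, 4, 9)
        rs = [spec.generating_corr(z) for z in zs]
        assert all(-1 < r < 1 for r in rs)
        assert np.all(np.diff(rs) > 0)

    def test_true_coupling_maximal_at_injected_lag(self):
        # generation is deterministic given the factors: the generating link
        # weight is a monotone function of factor(d - L), so its rank
        # correlation across sessions is exactly 1 at lag L and smaller
        # elsewhere
        lag = 3
        cfg = SynthConfig(n_sessions=20, n_days=120, n_rois=8, n_networks=2,
                          session_days=synth.default_session_days(20),
                          n_time=50, seed=12)
        atlas = synth.gen_atlas(8, 2, seed=12)
        b = synth.gen_behavior(cfg)
        spec = EffectSpec(target_links=[(0, 2)], factor_name="restless",
                          lag_days=lag, slope=0.5, base_corr=0.1)
        _, truth = synth.gen_sessions(cfg, atlas, b, [spec])
        g = truth.sort_values("session_day")["generating_corr"].to_numpy()
        days = np.array(sorted(truth["session_day"]))
        rhos = {}
        for L in range(0, 8):
            f = b.truth["restless"].loc[days - L].to_numpy()
            rhos[L] = abs(stats.spearmanr(g, f).statistic)
        assert max(rhos, key=rhos.get) == lag
        assert rhos[lag] == pytest.approx(1.0)

    def test_same_seed_identical_output(self, small_atlas, small_config):
        b = synth.gen_behavior(small_config)
        s1, _ = synth.gen_sessions(small_config, small_atlas, b)
        s2, _ = synth.gen_sessions(small_config, small_atlas, b)
        for a, c in zip(s1, s2):
            np.testing.assert_array_equal(a.data, c.data)

    def test_generated_correlation_matrices_psd(self, small_atlas, small_config):
        # latent-factor construction: sample covariance of long series must be
        # PSD and the implied generating covariance is PSD by construction
        b = synth.gen_behavior(small_config)
        sessions, _ = synth.gen_sessions(small_config, small_atlas, b)
        c = np.corrcoef(sessions[0].data, rowvar=False)
        assert np.linalg.eigvalsh(c).min() > -1e-10


class TestFdAndTrials:
    def test_spike_prob_extremes(self, small_config):
        none = synth.gen_fd(small_config, spike_prob=0.0)
        assert all((fd <= 0.2).all() for fd in none)
        allspikes = synth.gen_fd(small_config, spike_prob=1.0)
        assert all((fd > 0.2).all() for fd in allspikes)

    def test_spike_count_within_binomial_bounds(self):
        cfg = SynthConfig(n_sessions=1, n_days=30, n_rois=4, n_networks=2,
                          session_days=[20], n_time=1000, seed=3)
        fd = synth.gen_fd(cfg, spike_prob=0.1)[0]
        assert 70 <= (fd > 0.2).sum() <= 130

    def test_trial_gaps_in_range(self):
        t = synth.gen_trials(40, (2.0, 10.0), seed=4)
        onsets = t["onset_s"].to_numpy()
        gaps = np.diff(onsets)
        assert (np.diff(onsets) > 0).all()
        assert ((gaps >= 2.0) & (gaps <= 10.0)).all()

    def test_trial_edge_counts(self):
        assert len(synth.gen_trials(0, seed=1)) == 0
        assert len(synth.gen_trials(1, seed=1)) == 1


def test_write_dataset_roundtrip(tiny_dataset):
    from densefc.pipeline import load_dataset

    path, cfg = tiny_dataset
    atlas, behavior, sessions, fds, days, tr, meta = load_dataset(path)
    assert len(sessions) == cfg.n_sessions
    assert list(days) == cfg.session_days
    assert tr == cfg.tr_seconds
    assert sessions[0].shape == (cfg.n_time, cfg.n_rois)
    assert len(meta["realized"]) == cfg.n_sessions  # one effect link per session
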