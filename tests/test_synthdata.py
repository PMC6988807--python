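"""Generator: trial-direction sampling, trace realisation, session structure."""

import numpy as np
import pytest

from pursuitprior import (
    ObserverGenParams,
    TaskConfig,
    read_session,
    sample_trial_direction,
    shrinkage_weight,
    simulate_session,
    simulate_trial,
    write_session,
)


class TestSampleTrialDirection:
    def test_flat_prior_limit(self, rng):
        draws = np.array(
            [sample_trial_direction(20.0, 0.0, 8.0, 1e9, rng=rng) for _ in range(10**5)]
        )
        assert draws.mean() == pytest.approx(20.0, abs=3 * 8.0 / np.sqrt(1e5))
        assert draws.std() == pytest.approx(8.0, rel=0.02)

    def test_degenerate_prior_limit(self, rng):
        draws = [sample_trial_direction(20.0, 5.0, 8.0, 1e-9, rng=rng) for _ in range(100)]
        assert np.allclose(draws, 5.0, atol=1e-6)

    def test_moments_match_observer_prediction(self, rng):
        """Monte Carlo mean/SD reproduce the MAP-ensemble formulas."""
        draws = np.array(
            [
                sample_trial_direction(15.0, 0.0, 14.53, 34.5, rng=rng)
                for _ in range(10**5)
            ]
        )
        assert draws.mean() == pytest.approx(12.74, abs=0.15)
        assert draws.std() == pytest.approx(12.34, abs=0.12)

    def test_motor_noise_adds_in_quadrature(self, rng):
        draws = np.array(
            [
                sample_trial_direction(0.0, 0.0, 8.0, 30.0, motor_noise_sd=5.0, rng=rng)
                for _ in range(10**5)
            ]
        )
        w = shrinkage_weight(8.0, 30.0)
        expected = np.hypot(w * 8.0, 5.0)
        assert draws.std() == pytest.approx(expected, rel=0.02)

    def test_rejects_bad_sds(self):
        with pytest.raises(ValueError):
            sample_trial_direction(0, 0, -1.0, 10.0)
        with pytest.raises(ValueError):
            sample_trial_direction(0, 0, 5.0, 0.0)


class TestSimulateTrial:
    def test_terminal_speed_reaches_target(self):
        cfg = TaskConfig()
        tr = simulate_trial(0.0, 120.0, 1.0, cfg)
        # Terminal speed from the last position step.
        v_end = (tr.eye_h_deg[-1] - tr.eye_h_deg[-2]) / (cfg.dt_ms / 1000.0)
        assert v_end == pytest.approx(cfg.target_speed, rel=0.01)

    def test_same_seed_is_bit_identical(self):
        cfg = TaskConfig()
        a = simulate_trial(30.0, 130.0, 1.0, cfg, rng=np.random.default_rng(7),
                           position_noise_sd=0.01)
        b = simulate_trial(30.0, 130.0, 1.0, cfg, rng=np.random.default_rng(7),
                           position_noise_sd=0.01)
        assert np.array_equal(a.eye_h_deg, b.eye_h_deg)
        assert np.array_equal(a.eye_v_deg, b.eye_v_deg)

    def test_vertical_target_moves_vertically(self):
        cfg = TaskConfig()
        tr = simulate_trial(90.0, 120.0, 1.0, cfg)
        assert np.max(np.abs(tr.eye_h_deg)) < 1e-9
        assert tr.eye_v_deg[-1] > 1.0
        # No movement before latency.
        pre = tr.time_ms < 120.0
        assert np.max(np.abs(tr.eye_v_deg[pre])) < 1e-12

    def test_latency_bounds_enforced(self):
        with pytest.raises(ValueError):
            simulate_trial(0.0, 30.0, 1.0, TaskConfig())


class TestSimulateSession:
    def test_narrow_block_direction_counts(self, quiet_gen):
        cfg = TaskConfig(prior_direction=0.0)
        sess = simulate_session(cfg, quiet_gen, seed=1)
        narrow = sess.meta[sess.meta.block == "narrow"]
        counts = narrow.groupby("theta_s").size()
        assert counts[0.0] == 126
        assert counts[-15.0] == 63
        assert counts[15.0] == 63

    def test_wide_block_direction_counts(self, quiet_gen):
        cfg = TaskConfig(prior_direction=0.0)
        sess = simulate_session(cfg, quiet_gen, seed=1)
        wide = sess.meta[sess.meta.block == "wide"]
        counts = wide.groupby("theta_s").size()
        assert all(counts[d] == 126 for d in (-120.0, 0.0, 120.0))

    def test_no_adaptation_null(self, small_task):
        """With adaptation off, pursuit direction is independent of the
        previous trial's direction (regression slope ~ 0)."""
        gen = ObserverGenParams(saccade_rate=0.0, adaptation_shift=0.0)
        sess = simulate_session(small_task, gen, seed=9, n_block_pairs=20)
        m = sess.meta.dropna(subset=["prev_theta_s"])
        m = m[np.isclose(m.theta_s, small_task.prior_direction)]
        rel_prev = np.sign(
            (m.prev_theta_s - m.theta_s + 180) % 360 - 180
        )
        m = m[rel_prev != 0]
        resid = m.theta_trial - m.theta_s
        slope = np.polyfit(np.sign((m.prev_theta_s - m.theta_s + 180) % 360 - 180),
                           resid, 1)[0]
        se = resid.std() / np.sqrt(len(m))
        assert abs(slope) < 3 * se

    def test_generated_sd_converges_to_map_prediction(self, quiet_gen):
        """Empirical trial-direction SD matches the MAP-ensemble SD within
        Monte-Carlo error at n = 1e4 (motor noise zero)."""
        cfg = TaskConfig(prior_direction=0.0)
        sess = simulate_session(cfg, quiet_gen, seed=21, n_block_pairs=16)
        for block, contrast in [("narrow", "low"), ("narrow", "high"), ("wide", "low")]:
            m = sess.meta
            sub = m[(m.block == block) & (m.contrast == contrast) & (m.theta_s == 0.0)]
            sm = quiet_gen.sigma_m_eff(contrast)
            sp = quiet_gen.sigma_p(block)
            expected = shrinkage_weight(sm, sp) * sm
            n = len(sub)
            se = expected / np.sqrt(2 * n)
            assert sub.theta_trial.std() == pytest.approx(expected, abs=3 * se)

    def test_narrow_sd_below_wide_sd_over_grid(self):
        """Generated spread is smaller under the narrow prior whenever its SD
        is smaller, across a parameter grid."""
        cfg = TaskConfig(prior_direction=0.0)
        for sm_base, spn in [(5.0, 15.0), (8.0, 34.5), (12.0, 30.0)]:
            gen = ObserverGenParams(
                sigma_m_base=sm_base, sigma_p_narrow=spn, sigma_p_wide=1e6,
                saccade_rate=0.0, latency_sd=0.0, gain_sd=0.0, position_noise_sd=0.0,
            )
            sess = simulate_session(cfg, gen, seed=5, n_block_pairs=8)
            m = sess.meta
            common = m[m.theta_s == 0.0]
            sd_n = common[common.block == "narrow"].theta_trial.std()
            sd_w = common[common.block == "wide"].theta_trial.std()
            assert sd_n < sd_w

    def test_direction_difference_ratio_matches_shrinkage_weight(self, quiet_gen):
        """Mean outer-direction separation shrinks by sigma_p^2/(sigma_p^2+sigma_m^2)."""
        cfg = TaskConfig(prior_direction=0.0)
        sess = simulate_session(cfg, quiet_gen, seed=33, n_block_pairs=20)
        m = sess.meta
        sub = m[(m.block == "narrow") & (m.contrast == "low")]
        hi = sub[sub.theta_s == 15.0].theta_trial
        lo = sub[sub.theta_s == -15.0].theta_trial
        ratio = (hi.mean() - lo.mean()) / 30.0
        w = shrinkage_weight(quiet_gen.sigma_m_eff("low"), quiet_gen.sigma_p_narrow)
        se = np.sqrt(hi.var() / len(hi) + lo.var() / len(lo)) / 30.0
        assert ratio == pytest.approx(w, abs=3 * se)

    def test_adaptation_shift_doubles_in_statistic(self, small_task):
        """A +2 deg pull toward the previous direction separates the CCW and
        CW conditional means by ~4 deg."""
        gen = ObserverGenParams(saccade_rate=0.0, adaptation_shift=2.0)
        sess = simulate_session(small_task, gen, seed=11, n_block_pairs=20)
        m = sess.meta.dropna(subset=["prev_theta_s"])
        m = m[np.isclose(m.theta_s, small_task.prior_direction)]
        rel = np.sign((m.prev_theta_s - m.theta_s + 180) % 360 - 180)
        diff = (
            m.theta_trial[rel > 0].mean() - m.theta_trial[rel < 0].mean()
        )
        se = m.theta_trial.std() * np.sqrt(
            1 / (rel > 0).sum() + 1 / (rel < 0).sum()
        )
        assert diff == pytest.approx(4.0, abs=3 * se)

    def test_invalid_direction_geometry_rejected(self):
        with pytest.raises(ValueError):
            TaskConfig(narrow_offsets=(-15.0, 20.0))
        with pytest.raises(ValueError):
            TaskConfig(narrow_offsets=(-120.0, 120.0))  # collides with wide set


class TestSessionIO:
    def test_csv_roundtrip(self, small_session, tmp_path):
        sub = small_session.subset(np.arange(small_session.n_trials) < 5)
        write_session(sub, tmp_path / "sess", fmt="csv")
        back = read_session(tmp_path / "sess")
        assert np.allclose(back.position, sub.position)
        assert list(back.meta.trial_index) == list(sub.meta.trial_index)

    def test_hdf5_roundtrip(self, small_session, tmp_path):
        sub = small_session.subset(np.arange(small_session.n_trials) < 5)
        write_session(sub, tmp_path / "sess.h5", fmt="hdf5")
        back = read_session(tmp_path / "sess.h5")
        assert np.allclose(back.position, sub.position)
        assert list(back.meta.block) == list(sub.meta.block)
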