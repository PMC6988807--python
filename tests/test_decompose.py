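"""Template decomposition: latency, template construction, trial fitting."""

import numpy as np
import pandas as pd
import pytest

from pursuitprior import (
    TaskConfig,
    build_template,
    decompose_session,
    estimate_session_latency,
    fit_trial,
    fit_trials,
)
from pursuitprior.decompose import apply_session_inclusion
from pursuitprior.preprocess import VelocityTraceSet
from pursuitprior.synthdata import _speed_profile


def make_condition(
    n_trials=20,
    direction=45.0,
    latency=120.0,
    gain=1.0,
    speed=15.0,
    noise_sd=0.0,
    seed=0,
    latencies=None,
    gains_hv=None,
):
    """Analytic pursuit condition: tanh-onset velocity along one direction."""
    rng = np.random.default_rng(seed)
    t = np.arange(-300.0, 600.5, 1.0)
    vel = np.zeros((n_trials, t.size, 2))
    for i in range(n_trials):
        lat = latency if latencies is None else latencies[i]
        prof = _speed_profile(t, lat, gain * speed, 60.0)
        gh, gv = (1.0, 1.0) if gains_hv is None else gains_hv[i]
        vel[i, :, 0] = gh * prof * np.cos(np.radians(direction))
        vel[i, :, 1] = gv * prof * np.sin(np.radians(direction))
    if noise_sd > 0:
        vel += rng.normal(0, noise_sd, size=vel.shape)
    meta = pd.DataFrame(
        {"trial_index": range(n_trials), "block": "narrow", "contrast": "high",
         "theta_s": direction}
    )
    return VelocityTraceSet(time_ms=t, velocity=vel, meta=meta)


class TestSessionLatency:
    def test_known_latency_recovered(self):
        vel = make_condition(latency=120.0)
        est = estimate_session_latency(vel.time_ms, vel.speed)
        assert est == pytest.approx(120.0, abs=5.0)

    def test_identical_trials_equal_single_trial(self):
        vel = make_condition(n_trials=12, latency=140.0)
        est_many = estimate_session_latency(vel.time_ms, vel.speed)
        est_one = estimate_session_latency(vel.time_ms, vel.speed[:1], min_trials=1)
        assert est_many == pytest.approx(est_one, abs=1e-9)

    def test_latency_difference_recovered(self):
        e1 = estimate_session_latency(*[(v := make_condition(latency=120.0)).time_ms,
                                        v.speed])
        e2 = estimate_session_latency(*[(v := make_condition(latency=160.0)).time_ms,
                                        v.speed])
        assert e2 - e1 == pytest.approx(40.0, abs=3.0)

    def test_flat_condition_flagged(self):
        vel = make_condition()
        vel.velocity[:] = 0.0
        with pytest.raises(ValueError, match="unusable"):
            estimate_session_latency(vel.time_ms, vel.speed)

    def test_too_few_trials(self):
        vel = make_condition(n_trials=3)
        with pytest.raises(ValueError, match=">= 10"):
            estimate_session_latency(vel.time_ms, vel.speed)


class TestBuildTemplate:
    def test_mean_direction_is_reference(self):
        for direction in (0.0, 30.0, 137.0, -90.0):
            vel = make_condition(direction=direction)
            tpl = build_template(vel, 120.0)
            assert tpl.mean_direction_deg == pytest.approx(45.0, abs=1e-6)

    def test_identical_trials_give_rotated_single_trial(self):
        vel = make_condition(n_trials=15, direction=30.0)
        tpl = build_template(vel, 120.0)
        # The template equals the rotated single trial inside the window.
        win = (vel.time_ms >= 100.0) & (vel.time_ms <= 220.0)
        single = vel.velocity[0, win]
        rot = np.radians(tpl.rotation_deg)
        rh = np.cos(rot) * single[:, 0] - np.sin(rot) * single[:, 1]
        assert np.allclose(tpl.template_h, rh, atol=1e-9)

    def test_gain_one_template_reaches_target_speed_components(self):
        vel = make_condition(direction=45.0, gain=1.0, speed=15.0)
        tpl = build_template(vel, 120.0)
        expected = 15.0 * np.cos(np.radians(45.0))
        assert tpl.template_h[-1] == pytest.approx(expected, rel=0.02)
        assert tpl.template_v[-1] == pytest.approx(expected, rel=0.02)

    def test_refuses_few_trials(self):
        vel = make_condition(n_trials=4)
        with pytest.raises(ValueError, match=">= 10"):
            build_template(vel, 120.0)


class TestFitTrial:
    def test_self_fit_is_exact(self):
        vel = make_condition(direction=30.0)
        tpl = build_template(vel, 120.0)
        kin = fit_trial(vel.velocity[0], vel.time_ms, tpl)
        # Sub-sample parabolic refinement leaves a tiny (<0.01 ms) wobble.
        assert kin.shift_ms == pytest.approx(0.0, abs=0.01)
        assert kin.gain_h == pytest.approx(1.0, abs=1e-3)
        assert kin.gain_v == pytest.approx(1.0, abs=1e-3)
        assert kin.variance_explained == pytest.approx(1.0, abs=1e-6)
        assert kin.direction_deg == pytest.approx(30.0, abs=0.01)

    def test_shift_and_scale_recovered(self):
        """A trial that is the template shifted +10 ms and scaled (1.2, 0.8)
        comes back with those parameters and the implied direction offset."""
        base = make_condition(direction=45.0)
        tpl = build_template(base, 120.0)
        shifted = make_condition(
            n_trials=1, direction=45.0, latency=130.0,
            gains_hv=[(1.2, 0.8)],
        )
        kin = fit_trial(shifted.velocity[0], shifted.time_ms, tpl)
        assert kin.shift_ms == pytest.approx(10.0, abs=1.0)
        assert kin.gain_h == pytest.approx(1.2, abs=0.01)
        assert kin.gain_v == pytest.approx(0.8, abs=0.01)
        expected_dir = 45.0 + np.degrees(np.arctan2(0.8, 1.2)) - 45.0
        assert kin.direction_deg == pytest.approx(expected_dir, abs=0.2)

    def test_white_noise_trial_excluded(self):
        vel = make_condition()
        tpl = build_template(vel, 120.0)
        rng = np.random.default_rng(5)
        noise = rng.normal(0, 5.0, size=vel.velocity[0].shape)
        kin = fit_trial(noise, vel.time_ms, tpl)
        assert kin.variance_explained < 0.70
        assert not kin.included

    def test_recovery_error_bounds(self):
        """Median absolute errors below (1 ms, 0.02, 0.02) for known shifts
        and scales at 1 deg/s velocity noise."""
        base = make_condition(direction=45.0)
        tpl = build_template(base, 120.0)
        rng = np.random.default_rng(17)
        n = 200
        taus = rng.uniform(-30, 30, n)
        gh = rng.uniform(0.8, 1.2, n)
        gv = rng.uniform(0.8, 1.2, n)
        trials = make_condition(
            n_trials=n, direction=45.0, noise_sd=1.0, seed=99,
            latencies=120.0 + taus, gains_hv=np.stack([gh, gv], axis=1),
        )
        kins = fit_trials(trials, tpl)
        err_tau = np.abs(np.array([k.shift_ms for k in kins]) - taus)
        err_a = np.abs(np.array([k.gain_h for k in kins]) - gh)
        err_b = np.abs(np.array([k.gain_v for k in kins]) - gv)
        assert np.median(err_tau) < 1.0
        assert np.median(err_a) < 0.02
        assert np.median(err_b) < 0.02

    def test_variance_explained_decreases_with_noise(self):
        base = make_condition(direction=45.0)
        tpl = build_template(base, 120.0)
        ves = []
        for sd in (0.5, 1.5, 4.0, 10.0):
            trials = make_condition(n_trials=30, noise_sd=sd, seed=int(sd * 10))
            ves.append(np.mean([k.variance_explained for k in fit_trials(trials, tpl)]))
        assert np.all(np.diff(ves) < 0)

    def test_direction_unbiased_under_symmetric_noise(self):
        """The 45-degree rotation makes the direction estimate unbiased."""
        base = make_condition(direction=45.0)
        tpl = build_template(base, 120.0)
        trials = make_condition(n_trials=400, noise_sd=2.0, seed=7)
        kins = fit_trials(trials, tpl)
        dirs = np.array([k.direction_deg for k in kins])
        assert abs(dirs.mean() - 45.0) < 0.2


class TestSessionInclusion:
    @staticmethod
    def kin_frame(n_narrow, n_wide):
        rows = []
        idx = 0
        for block, n in (("narrow", n_narrow), ("wide", n_wide)):
            for _ in range(n):
                rows.append(dict(trial_index=idx, block=block, contrast="high",
                                 theta_s=0.0, direction_deg=0.0, gain=1.0,
                                 latency_ms=120.0, variance_explained=0.9,
                                 included=True))
                idx += 1
        return pd.DataFrame(rows)

    def test_boundary_retained_above_70(self):
        kin, verdict = apply_session_inclusion(self.kin_frame(71, 72), 0.0)
        assert verdict.retained

    def test_boundary_dropped_at_70(self):
        kin, verdict = apply_session_inclusion(self.kin_frame(70, 100), 0.0)
        assert not verdict.retained

    def test_outliers_removed_before_count(self):
        df = self.kin_frame(80, 80)
        df.loc[:7, "direction_deg"] = 120.0  # 8 gross outliers in the narrow block
        df.loc[8:, "direction_deg"] = np.random.default_rng(0).normal(
            0, 5, size=len(df) - 8
        )
        kin, verdict = apply_session_inclusion(df, 0.0)
        assert kin["outlier"].sum() == 8
        assert verdict.n_prior_narrow == 72


class TestDecomposeSession:
    def test_end_to_end_direction_recovery(self, small_session, small_task):
        from pursuitprior import preprocess_session

        vel, _ = preprocess_session(small_session)
        kin, verdict = decompose_session(vel, prior_direction=small_task.prior_direction)
        merged = kin.merge(
            small_session.meta[["trial_index", "theta_trial"]], on="trial_index"
        )
        ok = merged[merged.included]
        err = (ok.direction_deg - ok.theta_trial).abs()
        # Per-trial decomposition error is small next to behavioural spread.
        assert err.median() < 1.5
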