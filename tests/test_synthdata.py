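"""Generator tests: ball physics, gaze construction, swings, schedules,
self-reports and whole-session determinism."""

import numpy as np
import pandas as pd
import pytest

from vrintercept.config import (ConfigError, GazeGenConfig, PhysicsConfig,
                                SelfReportTruth, SessionConfig, SwingGenConfig)
from vrintercept.preprocess import angular_kinematics
from vrintercept.synthdata import (EYE_HEIGHT, build_feedback_schedule,
                                   generate_ball_trajectory, generate_gaze,
                                   generate_selfreports, generate_swing,
                                   simulate_session, simulate_trial)
from vrintercept._angles import vec_to_angles


def post_bounce_speed(traj, physics):
    """Finite-difference vertical speed extrapolated back to the bounce."""
    i = traj.bounce_frame + 2
    dt = traj.t[1] - traj.t[0]
    vy = (traj.pos[i + 1, 1] - traj.pos[i, 1]) / dt
    t_mid = (traj.t[i] + traj.t[i + 1]) / 2
    return vy - physics.gravity * (t_mid - traj.bounce_time)


class TestBallTrajectory:
    @pytest.mark.parametrize("ball_type,expected", [("normal", 5.85), ("elastic", 7.65)])
    def test_post_bounce_vertical_speed(self, cfg, ball_type, expected):
        # restitution of the -9 m/s floor-contact speed: 0.65*9 and 0.85*9
        traj = generate_ball_trajectory(ball_type, cfg.physics)
        assert post_bounce_speed(traj, cfg.physics) == pytest.approx(expected, rel=1e-6)

    def test_pre_bounce_identical_across_types(self, cfg):
        a = generate_ball_trajectory("normal", cfg.physics)
        b = generate_ball_trajectory("elastic", cfg.physics)
        nb = a.bounce_frame
        np.testing.assert_array_equal(a.pos[:nb], b.pos[:nb])

    def test_airborne_acceleration_is_gravity(self, cfg):
        traj = generate_ball_trajectory("normal", cfg.physics)
        dt = traj.t[1] - traj.t[0]
        seg = traj.pos[traj.release_frame + 1:traj.bounce_frame - 1, 1]
        acc = np.diff(seg, 2) / dt**2
        assert np.allclose(acc, cfg.physics.gravity, atol=1e-6)

    def test_bounce_location(self, cfg):
        traj = generate_ball_trajectory("normal", cfg.physics)
        # 3.5 m in front of the start position, on the midline
        assert traj.bounce_point[2] == pytest.approx(3.5)
        assert traj.bounce_point[0] == 0.0
        assert abs(traj.pos[traj.bounce_frame, 1]) < 0.06  # near the floor

    def test_invalid_elasticity_rejected(self):
        with pytest.raises(ConfigError):
            PhysicsConfig(elasticity_normal=1.2)


class TestGaze:
    def test_truth_events_cover_trial(self, cfg):
        traj = generate_ball_trajectory("normal", cfg.physics)
        eye = np.array([-0.75, EYE_HEIGHT, 0.0])
        gcfg = GazeGenConfig(dropout_rate=0.0, fixation_jitter_sd=0.0)
        _, valid, events = generate_gaze(traj, gcfg, eye, np.random.default_rng(0))
        assert len(events) >= 3
        assert events[0].onset == 0 and events[-1].offset == len(traj.t)
        for prev, nxt in zip(events, events[1:]):
            assert prev.offset == nxt.onset
        assert valid.all()

    def test_bounce_fixation_pitch_offset_exact(self, cfg):
        traj = generate_ball_trajectory("normal", cfg.physics)
        eye = np.array([-0.75, EYE_HEIGHT, 0.0])
        gcfg = GazeGenConfig(bounce_fixation_pitch_offset=10.0, fixation_jitter_sd=0.0)
        gaze, _, events = generate_gaze(traj, gcfg, eye, np.random.default_rng(0))
        fix = [e for e in events if e.kind == "fixation" and e.onset > 0][0]
        _, pitch = vec_to_angles(gaze[fix.onset:fix.offset])
        _, bounce_pitch = vec_to_angles(traj.bounce_point - eye)
        assert np.allclose(pitch, bounce_pitch + 10.0, atol=1e-9)

    def test_unit_gain_pursuit_matches_ball_velocity(self, cfg):
        traj = generate_ball_trajectory("normal", cfg.physics)
        eye = np.array([-0.75, EYE_HEIGHT, 0.0])
        gcfg = GazeGenConfig(pursuit_gain=1.0, fixation_jitter_sd=0.0)
        gaze, _, events = generate_gaze(traj, gcfg, eye, np.random.default_rng(0))
        pursuit = [e for e in events if e.kind == "pursuit"][0]
        dt = traj.t[1] - traj.t[0]
        yaw, pitch = vec_to_angles(gaze)
        gvel, _ = angular_kinematics(yaw, pitch, dt)
        byaw, bpitch = vec_to_angles(traj.pos - eye)
        bvel, _ = angular_kinematics(byaw, bpitch, dt)
        sl = slice(pursuit.onset + 1, pursuit.offset - 1)
        np.testing.assert_allclose(gvel[sl], bvel[sl], atol=0.5)

    def test_dropout_inserts_invalid_runs(self, cfg):
        traj = generate_ball_trajectory("normal", cfg.physics)
        eye = np.array([-0.75, EYE_HEIGHT, 0.0])
        gcfg = GazeGenConfig(dropout_rate=0.05, dropout_run_length=4)
        _, valid, _ = generate_gaze(traj, gcfg, eye, np.random.default_rng(0))
        assert (~valid).sum() > 0


class TestSwing:
    def test_configured_peak_recovered(self, rng):
        t = np.arange(200) / 90.0
        pos, truth = generate_swing(SwingGenConfig(peak_speed=4.0, noise_sd=0.0),
                                    t, 150, np.array([0.0, 1.3, 0.4]),
                                    np.array([-0.45, 1.0, 0.2]), rng)
        speeds = np.linalg.norm(np.diff(pos, axis=0), axis=1) * 90.0
        # sampled differentials sit half a frame inside the analytic peak
        assert speeds.max() == pytest.approx(truth.peak_speed, rel=2e-3)
        assert truth.peak_speed == pytest.approx(4.0, rel=0.02)

    def test_zero_amplitude_swing_is_static(self, rng):
        t = np.arange(100) / 90.0
        pos, truth = generate_swing(SwingGenConfig(peak_speed=0.0), t, 80,
                                    np.array([0.0, 1.3, 0.4]),
                                    np.array([-0.45, 1.0, 0.2]), rng)
        assert truth.peak_speed == 0.0
        assert (pos == pos[0]).all()

    def test_backswing_moves_away_before_foreswing(self, rng):
        t = np.arange(250) / 90.0
        aim, rest = np.array([0.0, 1.3, 0.4]), np.array([-0.45, 1.0, 0.2])
        pos, truth = generate_swing(SwingGenConfig(peak_speed=4.0), t, 200,
                                    aim, rest, rng)
        d_rest = np.linalg.norm(rest - aim)
        pre = pos[:truth.foreswing_onset]
        assert np.linalg.norm(pre - aim, axis=1).max() > d_rest + 0.05


class TestSchedule:
    @pytest.mark.parametrize("feedback,n_hits", [("low", 42), ("high", 30)])
    def test_hit_counts(self, feedback, n_hits):
        sched = build_feedback_schedule(feedback, 72, np.random.default_rng(0))
        assert sched.feedback_calls.count("hit") == n_hits

    def test_probe_invariants_over_seeds(self):
        # exercised across 100 seeds x both feedback levels
        for seed in range(100):
            rng = np.random.default_rng(seed)
            for feedback, rate in [("low", 0.58), ("high", 0.42)]:
                s = build_feedback_schedule(feedback, 72, rng)
                calls = np.array(s.feedback_calls)
                assert len(s.probe_trials) == 6
                assert len(set(s.probe_trials)) == 6
                assert (calls[s.probe_trials] == "hit").sum() == 3
                cum = np.cumsum(calls == "hit")
                for p in s.probe_trials:
                    assert abs(cum[p] - rate * (p + 1)) <= 1.0
                frac = s.ball_types.count("normal") / 72
                assert abs(frac - 0.67) <= 1 / 72

    def test_too_few_trials_rejected(self):
        with pytest.raises(ConfigError):
            build_feedback_schedule("low", 8, np.random.default_rng(0))


class TestSelfReports:
    def test_zero_noise_zero_betas_hits_intercepts(self, probe_design):
        truth = SelfReportTruth(
            beta_feedback_on_pof=0, beta_pressure_on_pof=0, beta_interaction_on_pof=0,
            beta_pressure_on_cof=0, beta_feedback_on_cof=0, beta_interaction_on_cof=0,
            beta_pof_on_anx=0, beta_cof_on_anx=0, beta_pofxcof_on_anx=0,
            sd_intercept_pof=0, sd_intercept_cof=0, sd_intercept_anx=0,
            sd_resid_pof=0, sd_resid_cof=0, sd_resid_anx=0)
        out = generate_selfreports(probe_design, truth, np.random.default_rng(0))
        assert (out["pof"] == truth.intercept_pof).all()
        assert (out["cof"] == truth.intercept_cof).all()
        assert (out["anxiety"] == truth.intercept_anx).all()

    def test_clipping_respects_scale_bounds(self, probe_design):
        truth = SelfReportTruth(intercept_anx=9.9, sd_resid_anx=3.0,
                                intercept_pof=5.9, sd_resid_pof=3.0)
        out = generate_selfreports(probe_design, truth, np.random.default_rng(0))
        assert out["anxiety"].between(0, 10).all()
        assert out["pof"].between(0, 6).all()
        assert out["cof"].between(0, 6).all()
        assert (out["anxiety"] == 10).any()   # clipping actually engaged


class TestSession:
    def test_design_counts(self, cfg):
        bundle = simulate_session(cfg, seed=4, participant="p01")
        assert len(bundle.trials) == 288
        assert len(bundle.manifest.probes) == 24
        assert bundle.manifest.trials["is_probe"].sum() == 24

    def test_ball_type_frequency_per_block(self, cfg):
        bundle = simulate_session(cfg, seed=4, participant="p01")
        man = bundle.manifest.trials
        for _, block in man.groupby("block"):
            frac = (block["ball_type"] == "normal").mean()
            assert abs(frac - 0.67) <= 1 / 72

    def test_same_seed_byte_identical(self, cfg, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_session(cfg, seed=9, participant="p01", out_dir=d1)
        simulate_session(cfg, seed=9, participant="p01", out_dir=d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_landmarks_match_truth_on_clean_trials(self, cfg):
        from vrintercept.preprocess import process_trial
        for seed in range(10):
            rng = np.random.default_rng(seed)
            tr = simulate_trial(cfg, "normal" if seed % 2 else "elastic",
                                bool(seed % 3), rng)
            rec = process_trial(tr.frame, cfg.physics)
            assert rec.release_frame == tr.truth.release_frame
            assert rec.bounce_frame == tr.truth.bounce_frame
            assert rec.contact_frame == tr.truth.contact_frame
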