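"""Metric definitions against brute-force oracles and invariance properties."""

import numpy as np
import pytest

import mocapskill as m
from mocapskill.kinematics import KinematicDerivatives
from mocapskill.metrics import (
    GripperEventList,
    convex_hull_area,
    shaft_unit_vectors,
)

from conftest import make_track

FS = 30.0


def deriv_from_positions(pos, sample_rate=FS, vel=None):
    """KinematicDerivatives wrapper around explicit positions (and optional
    velocities) for direct metric testing."""
    pos = np.asarray(pos, dtype=float)
    n = pos.shape[0]
    zeros = np.zeros_like(pos)
    return KinematicDerivatives(
        t=np.arange(n) / sample_rate,
        pos=pos,
        vel=zeros if vel is None else np.asarray(vel, float),
        acc=zeros,
        jerk=zeros,
        sample_rate=sample_rate,
    )


class TestEfficiencyMetrics:
    def test_straight_segment_pythagorean(self):
        pos = np.linspace([0, 0, 0], [3, 4, 0], 50)
        out = m.compute_efficiency_metrics(deriv_from_positions(pos), "z")
        assert out["PL"] == pytest.approx(5.0, abs=1e-12)
        assert out["DPL"] == pytest.approx(0.0, abs=1e-12)
        assert out["WA"] == pytest.approx(0.0, abs=1e-12)
        assert out["OT"] == pytest.approx(49 / FS)

    def test_square_perimeter_hull_area(self):
        corners = np.array(
            [[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]], dtype=float
        )
        pts = np.concatenate(
            [np.linspace(a, b, 20) for a, b in zip(corners[:-1], corners[1:])]
        )
        pos = np.column_stack([pts[:, 0], pts[:, 1], np.zeros(len(pts))])
        out = m.compute_efficiency_metrics(deriv_from_positions(pos), "z")
        assert out["WA"] == pytest.approx(100.0, abs=1e-9)

    def test_random_walk_matches_brute_force_oracles(self):
        rng = np.random.default_rng(0)
        pos = np.cumsum(rng.normal(size=(200, 3)), axis=0)
        out = m.compute_efficiency_metrics(deriv_from_positions(pos), "z")
        pl_oracle = sum(
            float(np.sqrt(np.sum((pos[i + 1] - pos[i]) ** 2)))
            for i in range(len(pos) - 1)
        )
        dpl_oracle = sum(abs(pos[i + 1, 2] - pos[i, 2]) for i in range(len(pos) - 1))
        assert out["PL"] == pytest.approx(pl_oracle, abs=1e-9)
        assert out["DPL"] == pytest.approx(dpl_oracle, abs=1e-9)

    def test_hull_area_matches_shapely_oracle(self):
        from shapely.geometry import MultiPoint

        rng = np.random.default_rng(1)
        pts = rng.normal(size=(120, 2)) * 10
        expected = MultiPoint([tuple(p) for p in pts]).convex_hull.area
        assert convex_hull_area(pts) == pytest.approx(expected, rel=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            m.compute_efficiency_metrics(deriv_from_positions(np.zeros((1, 3))), "z")


class TestSpeedMetrics:
    def test_uniform_linear_motion(self):
        n = 60
        vel = np.tile([3.0, 4.0, 0.0], (n, 1))
        d = deriv_from_positions(np.zeros((n, 3)), vel=vel)
        out = m.compute_speed_metrics(d, "z")
        assert out["v"] == pytest.approx(5.0)
        assert out["a"] == pytest.approx(0.0)
        assert out["DV"] == pytest.approx(0.0)

    def test_depth_axis_motion(self):
        n = 60
        vel = np.tile([0.0, 0.0, 2.0], (n, 1))
        out = m.compute_speed_metrics(deriv_from_positions(np.zeros((n, 3)), vel=vel),
                                      "z")
        assert out["DV"] == pytest.approx(2.0)
        assert out["v"] == pytest.approx(2.0)

    def test_minimum_jerk_mean_speed_is_distance_over_duration(self):
        from mocapskill.simulate import MinimumJerkSegment, minimum_jerk_position

        seg = MinimumJerkSegment(np.zeros(3), np.array([100.0, 0, 0]), 1.0)
        t = np.arange(0, 1 + 1e-9, 1 / FS)
        pos = minimum_jerk_position(seg, t)
        track = make_track(x=pos[:, 0], y=pos[:, 1], z=pos[:, 2])
        d = m.smooth_and_differentiate(track, 9, 3)
        out = m.compute_speed_metrics(d, "z")
        assert out["v"] == pytest.approx(100.0, rel=0.02)


class TestGripperEvents:
    def test_flat_grip_no_events(self):
        track = make_track(x=np.zeros(50), grip=np.zeros(50))
        assert len(m.detect_gripper_events(track, 15, 5)) == 0

    def test_square_wave_counts_cycles(self):
        cycle = [0.0] * 10 + [40.0] * 10
        grip = np.array(cycle * 4)
        track = make_track(x=np.zeros(grip.size), grip=grip)
        events = m.detect_gripper_events(track, 15, 5)
        kinds = events.kinds
        assert kinds.count("open") == 4
        assert kinds.count("close") == 3  # wave ends open; final close never comes
        grip_closed = np.append(grip, [0.0] * 5)
        track = make_track(x=np.zeros(grip_closed.size), grip=grip_closed)
        events = m.detect_gripper_events(track, 15, 5)
        assert events.kinds.count("open") == 4
        assert events.kinds.count("close") == 4

    def test_hysteresis_rejects_subthreshold_noise(self):
        rng = np.random.default_rng(5)
        cycle = [0.0] * 15 + [40.0] * 15
        clean = np.array(cycle * 4 + [0.0] * 5)
        noisy = clean + rng.uniform(-4.0, 4.0, size=clean.size)  # noise < hysteresis
        ev_clean = m.detect_gripper_events(make_track(x=np.zeros(clean.size),
                                                      grip=clean), 15, 5)
        ev_noisy = m.detect_gripper_events(make_track(x=np.zeros(noisy.size),
                                                      grip=noisy), 15, 5)
        assert ev_noisy.kinds == ev_clean.kinds

    def test_alternation_enforced_by_type(self):
        with pytest.raises(ValueError, match="alternate"):
            GripperEventList(times=[0.0, 1.0], kinds=["open", "open"])


class TestBimanualMetrics:
    @staticmethod
    def _pair(pos_r, pos_l, vel_r=None, vel_l=None):
        return (
            deriv_from_positions(pos_r, vel=vel_r),
            deriv_from_positions(pos_l, vel=vel_l),
        )

    def test_identical_speed_profiles_give_bd_one(self):
        rng = np.random.default_rng(6)
        vel = rng.normal(size=(80, 3))
        right, left = self._pair(np.zeros((80, 3)), np.zeros((80, 3)), vel, vel)
        ev = GripperEventList(times=[], kinds=[])
        out = m.compute_bimanual_metrics(right, left, ev, ev)
        assert out["BD"] == pytest.approx(1.0)

    def test_static_tips_distance_metrics(self):
        pos_r = np.tile([5.0, 0.0, 0.0], (60, 1))
        pos_l = np.tile([0.0, 0.0, 0.0], (60, 1))
        right, left = self._pair(pos_r, pos_l)
        ev_r = GripperEventList(times=[0.5, 1.0], kinds=["open", "close"])
        ev_l = GripperEventList(times=[0.7], kinds=["open"])
        out = m.compute_bimanual_metrics(right, left, ev_r, ev_l)
        assert out["ADB"] == pytest.approx(5.0)
        assert out["ADBO"] == pytest.approx(5.0)
        assert out["ROB"] == pytest.approx(2.0)

    def test_undefined_ratios_flagged_not_infinite(self):
        pos = np.tile([1.0, 0.0, 0.0], (60, 1))
        right, left = self._pair(pos, pos)
        ev_r = GripperEventList(times=[0.5], kinds=["open"])
        ev_l = GripperEventList(times=[], kinds=[])
        out = m.compute_bimanual_metrics(right, left, ev_r, ev_l)
        assert np.isnan(out["ROB"])   # no left events
        assert np.isnan(out["RPLB"])  # zero left path length
        assert np.isnan(out["BD"])    # constant speed series

    def test_hand_swap_inverts_ratios_only(self):
        rng = np.random.default_rng(7)
        pos_r = np.cumsum(rng.normal(size=(90, 3)), axis=0)
        pos_l = np.cumsum(rng.normal(size=(90, 3)), axis=0)
        vel_r = rng.normal(size=(90, 3))
        vel_l = rng.normal(size=(90, 3))
        ev_r = GripperEventList(times=[0.5, 1.0, 1.5, 2.0],
                                kinds=["open", "close", "open", "close"])
        ev_l = GripperEventList(times=[0.6, 1.1], kinds=["open", "close"])
        right, left = self._pair(pos_r, pos_l, vel_r, vel_l)
        fwd = m.compute_bimanual_metrics(right, left, ev_r, ev_l)
        rev = m.compute_bimanual_metrics(left, right, ev_l, ev_r)
        assert rev["ROB"] == pytest.approx(1.0 / fwd["ROB"])
        assert rev["RPLB"] == pytest.approx(1.0 / fwd["RPLB"])
        assert rev["BD"] == pytest.approx(fwd["BD"], abs=1e-12)
        assert rev["ADB"] == pytest.approx(fwd["ADB"], abs=1e-12)
        assert rev["ADBO"] == pytest.approx(fwd["ADBO"], abs=1e-12)


class TestAttitudeMetrics:
    def test_roll_triangle_wave_total_variation(self):
        roll = np.concatenate([np.linspace(0, 90, 30), np.linspace(90, 0, 30)[1:]])
        track = make_track(x=np.zeros(roll.size), roll=roll)
        out = m.compute_attitude_metrics(track)
        assert out["AL-Roll"] == pytest.approx(180.0, abs=1e-9)

    def test_wraparound_crossing_counts_short_way(self):
        roll = np.array([350.0, 355.0, 0.0, 5.0, 10.0])
        track = make_track(x=np.zeros(5), roll=roll)
        out = m.compute_attitude_metrics(track)
        assert out["AL-Roll"] == pytest.approx(20.0, abs=1e-9)

    def test_pitchyaw_arc_matches_brute_force(self):
        rng = np.random.default_rng(8)
        pitch = np.cumsum(rng.normal(scale=2.0, size=100))
        yaw = np.cumsum(rng.normal(scale=2.0, size=100))
        track = make_track(x=np.zeros(100), pitch=pitch, yaw=yaw)
        out = m.compute_attitude_metrics(track)
        u = shaft_unit_vectors(pitch, yaw)
        expected = 0.0
        for i in range(len(u) - 1):
            dot = float(np.dot(u[i], u[i + 1]))
            expected += np.degrees(np.arccos(min(1.0, max(-1.0, dot))))
        assert out["AL-PitchYaw"] == pytest.approx(expected, abs=1e-9)

    def test_agra_is_mean_grip(self):
        grip = np.linspace(0, 40, 50)
        track = make_track(x=np.zeros(50), grip=grip)
        assert m.compute_attitude_metrics(track)["AGRA"] == pytest.approx(
            np.mean(grip)
        )


class TestMetricVectorAssembly:
    def test_missing_instrument_named_in_error(self, default_cohort, run_config):
        trial = default_cohort.trials[0]
        partial = [t for t in trial.tracks if t.instrument_id != "clip_applier"]
        with pytest.raises(ValueError, match="clip_applier"):
            m.TrialRecording(trial.trial_id, trial.participant_id, trial.task,
                             trial.n_prior_surgeries, partial)

    def test_noise_free_single_segment_pl(self, noise_free_config, run_config):
        trial = m.simulate_trial(noise_free_config, 1.0, "P1", "T1", 100, seed=5)
        mv = m.compute_metric_vector(trial, run_config)
        track = trial.get_track("scissors", "right")
        disp = np.linalg.norm(track.positions()[-1] - track.positions()[0])
        # smoothed-path PL carries a small filter-edge overshoot at the
        # rest/motion junctions, so the tolerance is looser than the raw
        # tip-path check in test_simulate
        assert mv.values["S_PL"] == pytest.approx(disp, rel=5e-3)

    def test_invariant_sweep_on_cohort(self, default_features):
        vals = default_features.values
        for prefix in ("G", "S", "C"):
            assert (vals[f"{prefix}_PL"] >= vals[f"{prefix}_DPL"]).all()
            assert (vals[f"{prefix}_WA"] >= 0).all()
            assert (vals[f"{prefix}_v"] >= 0).all()
        assert vals["OT"].gt(0).all()
        assert vals["BD"].dropna().between(-1, 1).all()
        assert vals["ROB"].dropna().ge(0).all()

    def test_metric_names_follow_prefix_scheme(self, default_features):
        names = set(default_features.metric_names)
        assert {"G_PL", "S_PL", "C_PL", "OT", "BD", "ROB", "RPLB", "ADB",
                "ADBO"} <= names
        # task-1 cohort has no needle-holder metrics
        assert not any(name.startswith(("R_", "L_")) for name in names)


class TestMetricInvariances:
    """Frame and time-base invariances of the metric suite."""

    @staticmethod
    def _smooth_trajectory(n=400, seed=9):
        # frequencies kept well inside the filter passband so that the
        # double-speed version is still transmitted without attenuation
        rng = np.random.default_rng(seed)
        t = np.arange(n) / FS
        out = np.zeros((n, 3))
        for k in range(3):
            for freq, amp in zip((0.05, 0.12, 0.22), (30, 12, 5)):
                out[:, k] += amp * np.sin(
                    2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi)
                )
        return t, out

    def _metrics_for(self, pos, run_config):
        track = make_track(x=pos[:, 0], y=pos[:, 1], z=pos[:, 2])
        d = m.smooth_and_differentiate(track, run_config.sg_window,
                                       run_config.sg_polyorder)
        return {
            **m.compute_efficiency_metrics(d, "z"),
            **m.compute_speed_metrics(d, "z"),
        }

    def test_translation_invariance(self, run_config):
        _, pos = self._smooth_trajectory()
        base = self._metrics_for(pos, run_config)
        moved = self._metrics_for(pos + np.array([100.0, -50.0, 30.0]), run_config)
        for key in ("PL", "DPL", "WA", "v", "a", "j", "DV"):
            assert moved[key] == pytest.approx(base[key], rel=1e-9)

    def test_rotation_about_depth_axis_preserves_depth_metrics(self, run_config):
        _, pos = self._smooth_trajectory()
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        base = self._metrics_for(pos, run_config)
        rotated = self._metrics_for(pos @ rot.T, run_config)
        for key in ("PL", "DPL", "WA", "v", "a", "j", "DV"):
            assert rotated[key] == pytest.approx(base[key], rel=1e-9)

    def test_general_rotation_preserves_norm_metrics(self, run_config):
        rng = np.random.default_rng(10)
        _, pos = self._smooth_trajectory()
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        base = self._metrics_for(pos, run_config)
        rotated = self._metrics_for(pos @ q.T, run_config)
        for key in ("PL", "v", "a", "j"):
            assert rotated[key] == pytest.approx(base[key], rel=1e-9)

    def test_double_speed_scaling_laws(self, run_config):
        t, pos = self._smooth_trajectory(n=1200)
        half = pos[::2]  # same path traversed in half the time at the same rate
        slow = self._metrics_for(pos, run_config)
        fast = self._metrics_for(half, run_config)
        assert fast["OT"] == pytest.approx(slow["OT"] / 2, rel=0.01)
        assert fast["v"] == pytest.approx(slow["v"] * 2, rel=0.01)
        assert fast["a"] == pytest.approx(slow["a"] * 4, rel=0.01)
        assert fast["j"] == pytest.approx(slow["j"] * 8, rel=0.02)
        assert fast["PL"] == pytest.approx(slow["PL"], rel=0.01)
        assert fast["WA"] == pytest.approx(slow["WA"], rel=0.01)
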