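"""Generator tests: schedules, reach dynamics, latents, pupil traces, disk IO."""

import json

import numpy as np
import pandas as pd
import pytest

import pupiladapt as pa
from pupiladapt.synthetic_cohort import (EXP2_FIELD_SETS, ChannelConfig,
                                         ParticipantParams, PupilParams,
                                         pupil_irf, simulate_light_reflex,
                                         update_latents)

from conftest import MINI_SPEC, exp1_reach_cfg, tangential_speed


# --------------------------------------------------------------------------
# Schedules
# --------------------------------------------------------------------------

class TestSchedules:
    def test_exp1_block_sizes(self, exp1_schedule):
        per_block = exp1_schedule.trials.groupby("block").size()
        assert per_block.tolist() == [59, 59, 59, 44, 59]
        reaching = exp1_schedule.reaching.groupby("block").size()
        assert reaching.tolist() == [55, 55, 55, 40, 55]

    def test_exp1_field_span(self, exp1_schedule):
        r = exp1_schedule.reaching
        on = r.loc[r["B"] != 0, "reach_index"]
        # 11th reaching trial of block 2 through 10th of block 4
        assert on.min() == 66 and on.max() == 175
        assert (r.loc[r["B"] != 0, "B"] == 0.15).all()

    @pytest.mark.parametrize("exp_id", ["exp2A", "exp2B", "exp2C"])
    def test_exp2_sets_match_printed_lists(self, exp_id):
        sched = pa.make_schedule(exp_id, rng=1)
        r = sched.reaching.set_index("reach_index")
        cw = {i for a, b in EXP2_FIELD_SETS[exp_id]["cw"] for i in range(a, b + 1)}
        ccw = {i for a, b in EXP2_FIELD_SETS[exp_id]["ccw"] for i in range(a, b + 1)}
        for i in range(1, sched.n_reaching + 1):
            expected = 0.12 if i in cw else (-0.12 if i in ccw else 0.0)
            assert r.loc[i, "B"] == expected, f"trial {i}"

    def test_exp3_plateaus(self):
        sched = pa.make_schedule("exp3", rng=2)
        b = sched.reaching["B"].to_numpy()
        nz = b[b > 0]
        levels = np.unique(nz)
        # successive plateau levels differ by exactly 5% of 0.12
        assert np.allclose(np.diff(levels), 0.05 * 0.12)
        # each incremental plateau spans 11 reaching trials
        for lev in levels[:-1]:
            assert int((b == lev).sum()) == 11
        assert b[310:].max() == 0.0  # removed at 11th trial of block 7

    def test_change_points_strictly_inside_blocks(self):
        for exp_id in pa.synthetic_cohort.EXPERIMENT_IDS:
            sched = pa.make_schedule(exp_id, rng=3)
            sched.validate()
            starts = {s for s, _ in sched.blocks}
            assert not (set(sched.change_points.tolist()) & starts)

    def test_exp1_change_points(self, exp1_schedule):
        assert exp1_schedule.change_points.tolist() == [66, 176]

    def test_channel_fraction_and_min_gap(self, exp1_schedule):
        r = exp1_schedule.reaching
        assert r["is_channel"].mean() == pytest.approx(0.2, abs=0.01)
        ch_idx = r.loc[r["is_channel"], "reach_index"].to_numpy()
        assert np.diff(ch_idx).min() > 1  # default min-gap of one trial

    def test_channel_and_light_exclusive(self, exp1_schedule):
        t = exp1_schedule.trials
        assert not (t["is_channel"] & t["is_light_reflex"]).any()

    def test_unknown_experiment_raises(self):
        with pytest.raises(ValueError, match="unknown experiment_id"):
            pa.make_schedule("exp9")

    def test_custom_overlapping_sets_raise(self):
        spec = dict(MINI_SPEC, ccw_trials=[(70, 80)])
        with pytest.raises(ValueError, match="overlap"):
            pa.make_schedule(spec, rng=0)

    def test_schedule_seeded_determinism(self):
        a = pa.make_schedule("exp1", rng=5).trials
        b = pa.make_schedule("exp1", rng=5).trials
        pd.testing.assert_frame_equal(a, b)


# --------------------------------------------------------------------------
# Reach dynamics
# --------------------------------------------------------------------------

def _rk4_oracle(B, comp, cfg, rt=0.3, T=0.6, rate_hz=10000.0):
    """Independent fine-step RK4 integration of the same lateral dynamics."""
    t0 = cfg.pre_go + rt
    n = int(round((t0 + T) * rate_hz))
    h = 1.0 / rate_hz
    x = v = 0.0
    t = 0.0

    def vy(tt):
        tau = (tt - t0) / T
        if 0.0 <= tau <= 1.0:
            return cfg.amplitude / T * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
        return 0.0

    def acc(xx, vv, tt):
        f = (B - comp) * vy(tt) - cfg.feedback_kp * xx - cfg.feedback_kd * vv
        return f / cfg.mass

    traj = {}
    for i in range(n + 1):
        traj[round(t, 7)] = (x, v)
        k1x, k1v = v, acc(x, v, t)
        k2x, k2v = v + h / 2 * k1v, acc(x + h / 2 * k1x, v + h / 2 * k1v, t + h / 2)
        k3x, k3v = v + h / 2 * k2v, acc(x + h / 2 * k2x, v + h / 2 * k2v, t + h / 2)
        k4x, k4v = v + h * k3v, acc(x + h * k3x, v + h * k3v, t + h)
        x += h / 6 * (k1x + 2 * k2x + 2 * k3x + k4x)
        v += h / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
        t += h
    return traj


class TestSimulateReach:
    def test_unperturbed_reach_is_straight(self):
        cfg = exp1_reach_cfg()
        ts = pa.simulate_reach({"B": 0.0, "is_channel": False}, 0.0, None, 0,
                               cfg, noise_sd=0.0)
        assert np.all(ts.hand_xy[:, 0] == 0.0)
        assert ts.hand_xy[-1, 1] == pytest.approx(0.12, abs=1e-12)

    def test_lateral_deviation_matches_fine_rk4(self):
        cfg = exp1_reach_cfg(feedback=False)
        ts = pa.simulate_reach({"B": 0.15, "is_channel": False}, 0.0, None, 0,
                               cfg, noise_sd=0.0)
        oracle = _rk4_oracle(0.15, 0.0, cfg)
        speed = tangential_speed(ts)
        ipk = int(np.argmax(speed))
        t_pk = round(float(ts.t[ipk]), 7)
        assert abs(ts.hand_xy[ipk, 0] - oracle[t_pk][0]) < 1e-6

    def test_rk4_oracle_with_feedback(self):
        cfg = exp1_reach_cfg(feedback=True)
        ts = pa.simulate_reach({"B": 0.15, "is_channel": False}, 0.05, None, 0,
                               cfg, noise_sd=0.0)
        oracle = _rk4_oracle(0.15, 0.05, cfg)
        i_end = int(np.searchsorted(ts.t, cfg.pre_go + 0.3 + 0.6))
        t_end = round(float(ts.t[i_end]), 7)
        assert abs(ts.hand_xy[i_end, 0] - oracle[t_end][0]) < 1e-6

    def test_curl_field_delivers_zero_power(self):
        cfg = exp1_reach_cfg()
        ts = pa.simulate_reach({"B": 0.15, "is_channel": False}, 0.03, None,
                               np.random.default_rng(4), cfg, noise_sd=0.02)
        power = np.abs((ts.force_xy * ts.vel_xy).sum(axis=1))
        assert power.max() < 1e-12

    def test_channel_containment(self):
        cfg = exp1_reach_cfg()
        ts = pa.simulate_reach({"B": 0.15, "is_channel": True}, 0.15, None, 0,
                               cfg, noise_sd=0.0)
        assert np.abs(ts.hand_xy[:, 0]).max() < 0.002

    def test_zero_duration_reach_raises(self):
        with pytest.raises(ValueError, match="duration"):
            pa.simulate_reach({"B": 0.0, "is_channel": False}, 0.0, None, 0,
                              exp1_reach_cfg(), move_duration=0.0)

    def test_nonfinite_parameter_raises(self):
        with pytest.raises(ValueError, match="finite"):
            pa.simulate_reach({"B": np.nan, "is_channel": False}, 0.0, None, 0,
                              exp1_reach_cfg())

    def test_events_ordered(self):
        ts = pa.simulate_reach({"B": 0.0, "is_channel": False}, 0.0, None, 0,
                               exp1_reach_cfg(), noise_sd=0.0)
        ev = ts.events
        assert ev["go_cue"] < ev["movement_onset"] < ev["movement_offset"]


# --------------------------------------------------------------------------
# Latent updates
# --------------------------------------------------------------------------

class TestUpdateLatents:
    params = PupilParams()

    def test_fixed_point_relaxation(self):
        p = self.params
        lat = {"tonic": p.tonic_floor + 10.0, "expected_error": 0.01}
        lat2, s = update_latents(lat, 0.01, False, p)
        assert s == pytest.approx(1.0)
        # tonic relaxes geometrically toward the floor
        assert lat2["tonic"] - p.tonic_floor == pytest.approx(
            p.tonic_decay * 10.0)

    def test_block_start_bump_is_additive(self):
        p = self.params
        lat = {"tonic": p.tonic_floor, "expected_error": 0.01}
        relaxed, _ = update_latents(lat, 0.0, False, p)
        bumped, _ = update_latents(lat, 0.0, True, p)
        assert bumped["tonic"] - relaxed["tonic"] == pytest.approx(p.novelty_bump)

    def test_habituation_matches_direct_recursion(self):
        p = PupilParams(habituation_rate=0.5)
        e0 = 0.02
        lat = {"tonic": p.tonic_floor, "expected_error": 0.001}
        expected = 0.001
        for _ in range(40):
            lat, s = update_latents(lat, e0, False, p)
            expected = expected + 0.5 * (e0 - expected)  # brute-force recursion
            assert lat["expected_error"] == pytest.approx(expected, rel=1e-12)
        assert lat["expected_error"] == pytest.approx(e0, rel=1e-6)
        assert s == pytest.approx(1.0, rel=1e-6)

    def test_negative_error_raises(self):
        with pytest.raises(ValueError):
            update_latents({"tonic": 30.0, "expected_error": 0.01}, -1.0,
                           False, self.params)


# --------------------------------------------------------------------------
# Pupil traces
# --------------------------------------------------------------------------

class TestPupilTrace:
    params = ParticipantParams()

    def test_zero_surprise_flat_at_tonic(self):
        t = np.arange(0, 4, 0.005)
        trace, blinks = pa.simulate_pupil_trace(t, 2.0, 0.0, 40.0, self.params,
                                                rng=0, with_noise=False)
        expected_mm = 2.0 + 0.40 * 4.0  # 40% of the 2-6 mm range
        assert np.allclose(trace, expected_mm)
        assert blinks == []

    def test_phasic_peak_at_irf_peak_time(self):
        t = np.arange(0, 5, 0.005)
        onset = 2.0
        trace, _ = pa.simulate_pupil_trace(t, onset, 1.0, 40.0, self.params,
                                           rng=0, with_noise=False)
        t_peak = t[np.argmax(trace)]
        assert abs(t_peak - (onset + self.params.pupil.irf_peak_time)) <= 0.005

    def test_rising_phase_in_dilation_window(self):
        # numeric differentiation of the noiseless normalized trace
        t = np.arange(0, 5, 0.005)
        onset = 2.0
        trace, _ = pa.simulate_pupil_trace(t, onset, 3.0, 40.0, self.params,
                                           rng=0, with_noise=False)
        norm = 100.0 * (trace - 2.0) / 4.0
        vel = np.diff(norm) * 200.0
        sel = (t[:-1] >= onset + 0.3) & (t[:-1] <= onset + 0.7)
        assert vel[sel].mean() > 0

    def test_onset_outside_window_raises(self):
        t = np.arange(0, 1, 0.005)
        with pytest.raises(ValueError):
            pa.simulate_pupil_trace(t, 5.0, 1.0, 40.0, self.params)

    def test_irf_normalized_peak(self):
        tt = np.linspace(0, 5, 20001)
        h = pupil_irf(tt, 10.1, 0.93)
        assert h.max() == pytest.approx(1.0, abs=1e-6)
        assert tt[np.argmax(h)] == pytest.approx(0.93, abs=1e-3)


class TestLightReflex:
    def test_noiseless_extrema_within_one_percent(self):
        p = ParticipantParams()
        dark, bright = simulate_light_reflex(p, rng=0, noise_sd=0.0)
        assert dark.pupil_mm.max() == pytest.approx(p.calib_max_mm, rel=0.01)
        assert bright.pupil_mm.min() == pytest.approx(p.calib_min_mm, rel=0.01)

    def test_zero_stimulus_duration_stays_at_rest(self):
        p = ParticipantParams()
        dark, bright = simulate_light_reflex(p, rng=0, stimulus_duration=0.0,
                                             noise_sd=0.0)
        rest = 0.5 * (p.calib_min_mm + p.calib_max_mm)
        assert np.allclose(dark.pupil_mm, rest)
        assert np.allclose(bright.pupil_mm, rest)

    def test_noisy_extrema_average_within_two_percent(self):
        p = ParticipantParams()
        rng = np.random.default_rng(123)
        maxima, minima = [], []
        for _ in range(5):
            dark, bright = simulate_light_reflex(p, rng=rng, noise_sd=0.01)
            maxima.append(dark.pupil_mm.max())
            minima.append(bright.pupil_mm.min())
        assert np.mean(maxima) == pytest.approx(p.calib_max_mm, rel=0.02)
        assert np.mean(minima) == pytest.approx(p.calib_min_mm, rel=0.02)


# --------------------------------------------------------------------------
# Cohorts and disk round trip
# --------------------------------------------------------------------------

class TestCohort:
    def test_same_seed_byte_identical(self, tmp_path):
        cfgs = [dict(experiment_id=MINI_SPEC, n_participants=2, seed=9,
                     out=tmp_path / d) for d in ("a", "b")]
        for c in cfgs:
            pa.simulate_cohort(c)
        for name in ("schedule.csv", "truth.csv",
                     "participant_000/timeseries.csv",
                     "participant_000/events.csv"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes()), name

    def test_manifest_round_trip(self, tmp_path):
        out = pa.simulate_cohort(dict(experiment_id=MINI_SPEC, n_participants=1,
                                      seed=3, out=tmp_path / "c",
                                      write_timeseries=False))
        man = json.loads((out / "manifest.json").read_text())
        assert man["n_participants"] == 1
        assert man["seed"] == 3
        assert man["b_full"] == MINI_SPEC["b_full"]
        assert man["channel_stiffness"] == 7000.0

    def test_truth_matches_trial_count(self, mini_cohort, mini_schedule):
        for p in mini_cohort.participants:
            assert len(p.trials) == mini_schedule.n_reaching
            assert len(p.truth) == mini_schedule.n_reaching

    def test_learner_adapts(self, mini_cohort):
        truth = mini_cohort.participants[0].truth
        pert = truth[truth["B"] != 0]
        net = (pert["x_f"] + pert["x_s"]).to_numpy()
        assert net[-1] > 0.5  # substantial adaptation by the end

    def test_ccw_participant_mirrors_field(self):
        cohort = pa.generate_cohort("exp1", 2, seed=1)
        # exp1 assigns CW to the first 20; force one CCW via _directions
        dirs = pa.synthetic_cohort._directions("exp1", 28)
        assert (dirs == 1).sum() == 20 and (dirs == -1).sum() == 8

    def test_n_participants_validation(self):
        with pytest.raises(ValueError):
            pa.generate_cohort("exp1", 0, seed=1)
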