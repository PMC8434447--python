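"""Motor-skill-game metrics: segmentation, onset, success, error, summary."""

import numpy as np
import pandas as pd
import pytest

from rtp import (
    GameEvent,
    GameResponse,
    PlayerModel,
    SessionLog,
    TrialConfig,
    ValidationError,
    judge_success,
    movement_error,
    movement_onset,
    movement_time,
    msg_summary,
    segment_responses,
    simulate_msg,
)


def msg_cfg(**kw):
    base = dict(module_kind="MSG", duration_s=60, event_duration_s=2, rng_seed=0)
    base.update(kw)
    return TrialConfig(**base)


def make_response(trajectory, t_appear_ms=0, dt_ms=10, direction="downward"):
    traj = np.asarray(trajectory, dtype=float)
    t = t_appear_ms + np.arange(len(traj)) * dt_ms
    return GameResponse(event_id=0, direction=direction, t_ms=t, trajectory=traj)


def make_event(end_x, dur_ms=2000, kind="target", t_appear_ms=0):
    return GameEvent(event_id=0, kind=kind, t_appear_ms=t_appear_ms,
                     t_disappear_ms=t_appear_ms + dur_ms, spawn_x=end_x,
                     heading="downward", end_x=end_x)


class TestSegmentation:
    def test_60s_trial_yields_30_responses_of_200_samples(self):
        log = simulate_msg(msg_cfg(), PlayerModel(seed=1))
        responses = segment_responses(log)
        assert len(responses) == 30
        assert all(len(r.trajectory) == 200 for r in responses)

    def test_zero_events_yield_empty_list(self):
        log = simulate_msg(msg_cfg(duration_s=0), PlayerModel(seed=1))
        assert segment_responses(log) == []

    def test_hand_built_two_event_log_slices_match_index_arithmetic(self):
        cfg = msg_cfg(duration_s=4)
        log = simulate_msg(cfg, PlayerModel(seed=2))
        responses = segment_responses(log)
        paddle = log.samples["paddle_pos"].to_numpy()
        # index oracle: event i covers rows [i*200, (i+1)*200)
        np.testing.assert_array_equal(responses[0].trajectory, paddle[0:200])
        np.testing.assert_array_equal(responses[1].trajectory, paddle[200:400])
        assert responses[0].t_ms[0] == 0 and responses[1].t_ms[0] == 2000

    def test_missing_window_samples_reported_with_event_id(self):
        cfg = msg_cfg(duration_s=4)
        log = simulate_msg(cfg, PlayerModel(seed=2))
        log.events[1] = GameEvent(event_id=1, kind="target", t_appear_ms=4000,
                                  t_disappear_ms=6000, spawn_x=0.5,
                                  heading="downward", end_x=0.5)
        with pytest.raises(ValidationError, match="event 1"):
            segment_responses(log)


class TestMovementOnset:
    def test_motionless_paddle_yields_null(self):
        resp = make_response(np.full(200, 0.3))
        assert movement_onset(resp, make_event(0.8), msg_cfg()) is None

    def test_step_at_first_moving_sample_detected_there(self):
        traj = np.full(200, 0.2)
        traj[1:] = 0.8  # instantaneous step sustained to the end
        resp = make_response(traj)
        assert movement_onset(resp, make_event(0.8), msg_cfg()) == pytest.approx(10)

    def test_unsustained_blip_ignored(self):
        traj = np.full(200, 0.2)
        traj[50] = 0.8  # single-sample spike, shorter than the 30 ms debounce
        resp = make_response(traj)
        assert movement_onset(resp, make_event(0.8), msg_cfg()) is None

    @pytest.mark.parametrize("react_ms", [200, 300, 500])
    def test_programmed_reaction_time_recovered_zero_noise(self, react_ms):
        cfg = msg_cfg(rng_seed=17)
        player = PlayerModel(seed=17, reaction_time_mean_ms=react_ms,
                             reaction_time_sd_ms=0.0)
        log = simulate_msg(cfg, player)
        events = {e.event_id: e for e in log.events}
        onsets = [
            movement_onset(r, events[r.event_id], cfg)
            for r in segment_responses(log)
        ]
        onsets = [o for o in onsets if o is not None]
        assert onsets, "expected detected onsets"
        # one sample period of tolerance
        assert abs(np.mean(onsets) - react_ms) <= 10 + 1e-9

    def test_onset_bias_small_under_position_noise(self):
        cfg = msg_cfg(duration_s=600, rng_seed=23)  # 300 events
        player = PlayerModel(seed=23, reaction_time_mean_ms=300,
                             reaction_time_sd_ms=0.0, noise_sd=0.02)
        log = simulate_msg(cfg, player)
        events = {e.event_id: e for e in log.events}
        onsets = [movement_onset(r, events[r.event_id], cfg)
                  for r in segment_responses(log)]
        onsets = [o for o in onsets if o is not None]
        assert abs(np.mean(onsets) - 300) < 20


class TestJudgeSuccess:
    def test_paddle_parked_at_arrival_point_catches(self):
        cfg = msg_cfg()
        resp = make_response(np.full(200, 0.62))
        assert judge_success(resp, make_event(0.6), cfg)

    def test_paddle_at_opposite_edge_misses(self):
        cfg = msg_cfg()
        resp = make_response(np.full(200, 0.05))
        assert not judge_success(resp, make_event(0.9), cfg)

    def test_distractor_success_is_avoidance(self):
        cfg = msg_cfg()
        near = make_response(np.full(200, 0.6))
        far = make_response(np.full(200, 0.1))
        ev = make_event(0.6, kind="distractor")
        assert not judge_success(near, ev, cfg)
        assert judge_success(far, ev, cfg)

    def test_agreement_with_brute_force_overlap_check(self):
        # 200 random responses vs an exhaustive arrival-sample overlap check
        cfg = msg_cfg()
        rng = np.random.default_rng(99)
        window = cfg.paddle_halfwidth + cfg.object_radius
        for _ in range(200):
            end_x = rng.uniform(0, 1)
            traj = rng.uniform(0, 1, size=20)
            kind = "target" if rng.random() < 0.5 else "distractor"
            ev = make_event(end_x, dur_ms=200, kind=kind)
            resp = make_response(traj)
            overlap = abs(traj[-1] - end_x) <= window  # oracle
            expected = overlap if kind == "target" else not overlap
            assert judge_success(resp, ev, cfg) == expected


class TestMovementError:
    def test_jump_to_target_and_hold_gives_zero(self):
        traj = np.full(200, 0.2)
        traj[30:] = 0.7
        resp = make_response(traj)
        me = movement_error(resp, make_event(0.7), msg_cfg())
        assert me == pytest.approx(0.0)

    def test_constant_offset_after_onset(self):
        traj = np.full(200, 0.2)
        traj[30:] = 0.8  # onset at 300 ms, then parked at end_x + 0.1
        resp = make_response(traj)
        me = movement_error(resp, make_event(0.7), msg_cfg())
        assert me == pytest.approx(0.1)

    def test_null_onset_reports_missing(self):
        resp = make_response(np.full(200, 0.3))
        assert np.isnan(movement_error(resp, make_event(0.8), msg_cfg()))

    def test_matches_per_sample_average_loop(self):
        cfg = msg_cfg()
        rng = np.random.default_rng(5)
        traj = np.concatenate([np.full(50, 0.2), 0.7 + rng.normal(0, 0.05, 150)])
        resp = make_response(traj)
        ev = make_event(0.7)
        onset = movement_onset(resp, ev, cfg)
        i0 = int(onset // 10)
        expected = sum(abs(p - 0.7) for p in traj[i0:]) / len(traj[i0:])  # oracle
        assert movement_error(resp, ev, cfg) == pytest.approx(expected)

    def test_monotone_in_endpoint_noise(self):
        cfg = msg_cfg(duration_s=200, rng_seed=31)
        mes = []
        for noise in (0.0, 0.01, 0.02, 0.04):
            log = simulate_msg(cfg, PlayerModel(seed=31, noise_sd=noise))
            mes.append(msg_summary(log).mean_movement_error)
        assert all(a <= b + 1e-12 for a, b in zip(mes, mes[1:]))


class TestMovementTime:
    def test_stabilization_is_start_of_final_in_window_run(self):
        cfg = msg_cfg()
        traj = np.full(200, 0.2)
        traj[30:60] = 0.7   # enters window, then leaves
        traj[60:100] = 0.2
        traj[100:] = 0.7    # final entry, holds to arrival
        resp = make_response(traj)
        ev = make_event(0.7)
        resp.onset_ms = movement_onset(resp, ev, cfg)
        mt = movement_time(resp, ev, cfg)
        assert mt == pytest.approx(1000 - resp.onset_ms)

    def test_not_in_window_at_arrival_gives_null(self):
        cfg = msg_cfg()
        traj = np.full(200, 0.2)
        traj[30:100] = 0.7
        traj[100:] = 0.2
        resp = make_response(traj)
        assert movement_time(resp, make_event(0.7), cfg) is None


class TestMSGSummary:
    def test_all_targets_caught_gives_sr_100(self):
        log = simulate_msg(msg_cfg(rng_seed=3), PlayerModel(seed=3))
        assert msg_summary(log).success_rate_pct == 100.0

    def test_half_caught_gives_sr_50(self):
        cfg = msg_cfg(duration_s=4, rng_seed=8)
        log = simulate_msg(cfg, PlayerModel(seed=8))
        # park the paddle far from the second target's arrival point
        sel = log.samples["t_ms"] >= 2000
        far = 1.0 if log.events[1].end_x < 0.5 else 0.0
        log.samples.loc[sel, "paddle_pos"] = far
        assert msg_summary(log).success_rate_pct == 50.0

    def test_sr_tracks_miss_probability(self):
        # 1000 events, miss_prob 0.3 -> SR within 3 points of 70 %
        cfg = msg_cfg(duration_s=2000, rng_seed=41)
        log = simulate_msg(cfg, PlayerModel(seed=41, miss_prob=0.3))
        assert msg_summary(log).success_rate_pct == pytest.approx(70, abs=3)

    def test_sr_invariant_to_event_order(self):
        cfg = msg_cfg(duration_s=20, rng_seed=12)
        log = simulate_msg(cfg, PlayerModel(seed=12, miss_prob=0.4))
        s1 = msg_summary(log)
        shuffled = SessionLog(config=log.config, samples=log.samples,
                              events=list(reversed(log.events)),
                              participant_id=log.participant_id)
        assert msg_summary(shuffled).success_rate_pct == s1.success_rate_pct

    def test_distractors_never_enter_sr_denominator(self):
        cfg = msg_cfg(duration_s=100, rng_seed=9, distractor_fraction=0.4)
        log = simulate_msg(cfg, PlayerModel(seed=9))
        s = msg_summary(log)
        n_targets = sum(1 for e in log.events if e.kind == "target")
        assert s.n_targets == n_targets
        assert s.n_distractors == len(log.events) - n_targets
        assert s.success_rate_pct == 100.0  # all responded targets caught

    def test_zero_target_events_rejected(self):
        cfg = msg_cfg(duration_s=10, distractor_fraction=1.0)
        log = simulate_msg(cfg, PlayerModel(seed=0))
        with pytest.raises(ValidationError, match="target"):
            msg_summary(log)

    def test_per_direction_variation_groups(self):
        cfg = msg_cfg(duration_s=120, rng_seed=14, trajectory_complexity="diagonal")
        log = simulate_msg(cfg, PlayerModel(seed=14, noise_sd=0.01))
        s = msg_summary(log)
        assert set(s.amplitude_cov_pct) <= {"diagonal-left", "diagonal-right"}
        assert all(c >= 0 for c in s.amplitude_cov_pct.values())
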