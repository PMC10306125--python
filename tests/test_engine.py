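import collections

import numpy as np
import pytest

from lickrig.config import ConfigError, SessionConfig
from lickrig.engine import (Event, SpoutModel, TrialSpec, VirtualClock,
                            evaluate_response, run_2afc_trial, run_gng_trial,
                            run_passive_block, run_session, spout_travel_time)
from lickrig.subject import SubjectParams


def stimulus_off_to_window_open(events):
    """Scan a trial's events for the stimulus-off -> window-open interval."""
    t_off = t_open = None
    for e in events:
        if e.channel == "stimulus" and not e.payload.get("on") \
                and e.payload.get("id") != "trial_start_signal":
            t_off = e.time
        if e.channel == "state" and \
                e.payload.get("phase") == "response_window_open":
            t_open = e.time
    assert t_off is not None and t_open is not None
    return t_open - t_off


# ----------------------------------------------------------------------
# Spout model


class TestSpoutTravel:
    def test_servo_40mm(self):
        # 40 mm at the servo's 50 mm/s
        assert spout_travel_time(SpoutModel("servo", 40.0)) == 0.8

    def test_linear_25mm(self):
        # 25 mm at the linear actuator's 25 mm/s
        assert spout_travel_time(SpoutModel("linear", 25.0)) == 1.0

    def test_zero_travel(self):
        assert spout_travel_time(SpoutModel("servo", 0.0)) == 0.0

    def test_speed_override_and_validation(self):
        assert spout_travel_time(SpoutModel("servo", 10.0, 20.0)) == 0.5
        with pytest.raises(ConfigError):
            spout_travel_time(SpoutModel("servo", 10.0, -1.0))

    def test_movement_events_separated_by_travel_time(self):
        config = SessionConfig(task="2afc", n_trials=2, spout_travel_mm=20.0,
                               actuator="servo")
        result = run_session(config, SubjectParams(), seed=0)
        expected = 20.0 / 50.0
        starts = {}
        for e in result.events:
            if e.channel.endswith("spout"):
                if e.payload["action"] == "extend_start":
                    starts[e.channel] = e.time
                elif e.payload["action"] == "extended":
                    assert e.time - starts[e.channel] == pytest.approx(
                        expected)


# ----------------------------------------------------------------------
# Response evaluation


class TestEvaluateResponse:
    def test_requirement_one_first_lick_wins(self):
        side, t = evaluate_response([(0.3, "left"), (0.5, "right")],
                                    (0.0, 2.0), 1)
        assert side == "left" and t == 0.3

    def test_sliding_window_requirement(self):
        licks = [(0.05, "right"), (0.1, "left"), (0.2, "left"),
                 (0.3, "left"), (0.4, "left")]
        side, t = evaluate_response(licks, (0.0, 2.0), 4)
        assert side == "left" and t == 0.4

    def test_sliding_window_brute_force(self, rng):
        """Compare against an exhaustive scan over random lick patterns."""
        for _ in range(200):
            licks = sorted(
                (float(t), side)
                for t, side in zip(rng.uniform(0, 2, 12),
                                   rng.choice(["left", "right"], 12)))
            r = int(rng.integers(1, 5))
            got = evaluate_response(licks, (0.0, 2.0), r)
            # brute force: every subset of r consecutive same-side licks
            best = None
            for spout in ("left", "right"):
                ts = [t for t, s in licks if s == spout]
                for i in range(len(ts) - r + 1):
                    if ts[i + r - 1] - ts[i] <= 1.0:
                        cand = (ts[i + r - 1], spout)
                        if best is None or cand < best:
                            best = cand
                        break
            assert got == ((best[1], best[0]) if best else (None, None))

    def test_no_licks(self):
        assert evaluate_response([], (0.0, 2.0), 1) == (None, None)

    def test_licks_outside_window_ignored(self):
        assert evaluate_response([(5.0, "left")], (0.0, 2.0), 1) == \
            (None, None)


# ----------------------------------------------------------------------
# 2AFC trials


class TestRun2afc:
    def test_lateralized_subject_always_correct(self, lateralized_subject):
        config = SessionConfig(task="2afc", n_trials=100)
        result = run_session(config, lateralized_subject, seed=5)
        labels = {t.outcome.label for t in result.trials}
        assert labels <= {"correct_left", "correct_right"}
        assert all(t.outcome.rewarded for t in result.trials)

    def test_retrial_repeats_same_stimulus(self):
        # a heavily left-biased subject on right trials: the trial repeats
        # with the same stimulus until the correct side is licked
        subject = SubjectParams(alpha=4.0, beta=0.5, guess=0.3, lapse=0.3)
        config = SessionConfig(task="2afc", n_trials=40, retrial_mode=True,
                               percentage_of_right_trials=100.0,
                               override_consec_constraint=True)
        result = run_session(config, subject, seed=11)
        retried = [t for t in result.trials if t.outcome.retries > 0]
        assert retried, "expected at least one retried trial"
        for rec in retried:
            # every retrial presents the original stimulus again
            stim_events = [e for e in result.events
                           if e.channel == "stimulus" and e.payload.get("on")
                           and rec.t_start <= e.time < rec.t_end]
            assert len(stim_events) == 1 + rec.outcome.retries
            assert len({e.payload["id"] for e in stim_events}) == 1
        resolved = [t for t in retried if t.outcome.retrial_resolved]
        for rec in resolved:
            rewards = [e for e in result.events
                       if e.channel == "reward"
                       and e.payload["kind"] == "retrial"
                       and rec.t_start <= e.time < rec.t_end]
            assert len(rewards) == 1

    def test_center_reward_probability(self):
        config = SessionConfig(task="2afc", n_trials=400,
                               percentage_of_center_rewards=100.0)
        result = run_session(config, SubjectParams(engagement=1.0,
                                                   reaction_time_sigma=0.05),
                             seed=2)
        center = [e for e in result.events if e.channel == "reward"
                  and e.payload["kind"] == "center"]
        initiated = [t for t in result.trials
                     if t.outcome.label != "no_response"]
        assert len(center) == len(result.trials)  # every trial initiated

    def test_no_response_timeout(self):
        config = SessionConfig(task="2afc", n_trials=20)
        result = run_session(config, SubjectParams(engagement=0.0), seed=1)
        assert all(t.outcome.label == "no_response" for t in result.trials)
        assert len(result.trials) == 20  # session continues after timeouts

    def test_reward_conservation(self, small_2afc_result):
        result = small_2afc_result
        by_kind = collections.Counter(
            e.payload["kind"] for e in result.events if e.channel == "reward")
        rewarded_outcomes = sum(t.outcome.rewarded for t in result.trials)
        assert by_kind.get("outcome", 0) == rewarded_outcomes
        resolved = sum(t.outcome.retrial_resolved for t in result.trials)
        assert by_kind.get("retrial", 0) == resolved

    def test_tcsa_center_licks_logged(self):
        config = SessionConfig(task="2afc", n_trials=10, tcsa_reward=True,
                               time_center_spout_available_min=2.0,
                               time_center_spout_available_max=2.0)
        result = run_session(config, SubjectParams(), seed=3)
        tcsa = [e for e in result.events if e.channel == "reward"
                and e.payload["kind"] == "tcsa"]
        assert tcsa  # continued center licking during the delay is rewarded


# ----------------------------------------------------------------------
# Go-NoGo trials


class TestRunGng:
    def test_delay_table_offsets(self, gng_delay_config):
        """(1, 5, 6) delay table + 200 ms stimulus: post-offset gaps are
        exactly {0.8, 1.6, 2.4, 3.2, 4.0, 4.8} s."""
        result = run_session(gng_delay_config, SubjectParams(), seed=0)
        intervals = set()
        for rec in result.trials:
            trial_events = [e for e in result.events
                            if rec.t_start <= e.time < rec.t_end]
            intervals.add(round(stimulus_off_to_window_open(trial_events), 9))
        assert intervals == {0.8, 1.6, 2.4, 3.2, 4.0, 4.8}

    def test_correct_rejection_gets_short_iti(self):
        config = SessionConfig(task="gng", n_trials=60,
                               percentage_of_go_trials=50.0,
                               short_iti_min=0.5, short_iti_max=1.0,
                               iti_min=4.0, iti_max=8.0)
        subject = SubjectParams(p_lick_go=1.0, p_lick_nogo=0.0,
                                reaction_time_median_s=0.2,
                                reaction_time_sigma=0.05)
        result = run_session(config, subject, seed=4)
        for rec in result.trials:
            iti_events = [e for e in result.events
                          if e.channel == "state"
                          and e.payload.get("phase") == "iti"
                          and e.payload.get("trial") == rec.spec.index]
            dur = iti_events[0].payload["duration"]
            if rec.outcome.label == "correct_rejection":
                assert 0.5 <= dur <= 1.0
            else:
                assert 4.0 <= dur <= 8.0

    def test_always_licking_subject_hits(self):
        config = SessionConfig(task="gng", n_trials=30,
                               percentage_of_go_trials=100.0)
        subject = SubjectParams(p_lick_go=1.0, reaction_time_median_s=0.2,
                                reaction_time_sigma=0.05)
        result = run_session(config, subject, seed=6)
        assert all(t.outcome.label == "hit" for t in result.trials)
        rewards = [e for e in result.events if e.channel == "reward"]
        assert len(rewards) == 30

    def test_false_alarm_punished(self):
        config = SessionConfig(task="gng", n_trials=30,
                               percentage_of_go_trials=0.0)
        subject = SubjectParams(p_lick_nogo=1.0, reaction_time_median_s=0.2,
                                reaction_time_sigma=0.05)
        result = run_session(config, subject, seed=6)
        assert all(t.outcome.label == "false_alarm" for t in result.trials)
        punish_on = [e for e in result.events if e.channel == "punishment"
                     and e.payload["on"]]
        assert len(punish_on) == 30

    def test_cr_rule_forces_go_after_cr(self):
        config = SessionConfig(task="gng", n_trials=80, cr_rule_on=True,
                               percentage_of_go_trials=30.0)
        subject = SubjectParams(p_lick_go=0.8, p_lick_nogo=0.1)
        result = run_session(config, subject, seed=9)
        for prev, nxt in zip(result.trials, result.trials[1:]):
            if prev.outcome.label == "correct_rejection":
                assert nxt.spec.kind == "go"

    def test_trial_start_cue_precedes_stimulus(self):
        config = SessionConfig(task="gng", n_trials=5,
                               trial_start_signal="tone")
        result = run_session(config, SubjectParams(), seed=0)
        cue_off = [e for e in result.events
                   if e.payload.get("id") == "trial_start_signal"
                   and not e.payload.get("on")]
        stim_on = [e for e in result.events
                   if e.channel == "stimulus" and e.payload.get("on")
                   and e.payload.get("id") != "trial_start_signal"]
        assert len(cue_off) == 5
        for c, s in zip(cue_off, stim_on):
            assert s.time >= c.time  # cue and stimulus never overlap

    def test_too_short_onset_delay_rejected(self):
        config = SessionConfig(task="gng", n_trials=1, delay_period_min=0.1,
                               delay_period_max=0.1,
                               stimulus_duration_ms=200.0)
        with pytest.raises(ConfigError):
            run_session(config, SubjectParams(), seed=0)

    def test_offset_reference_switch(self):
        config = SessionConfig(task="gng", n_trials=6, delay_period_min=1.0,
                               delay_period_max=1.0,
                               delay_reference="offset",
                               stimulus_duration_ms=200.0)
        result = run_session(config, SubjectParams(), seed=0)
        for rec in result.trials:
            trial_events = [e for e in result.events
                            if rec.t_start <= e.time < rec.t_end]
            gap = stimulus_off_to_window_open(trial_events)
            assert gap == pytest.approx(1.0)


# ----------------------------------------------------------------------
# Passive block


class TestPassive:
    def test_combination_equal_counts(self):
        config = SessionConfig(task="passive", n_presentations=8,
                               combination=True)
        result = run_session(config, seed=0)
        ids = [e.payload["id"] for e in result.events
               if e.channel == "stimulus" and e.payload.get("on")]
        counts = collections.Counter(ids)
        assert len(counts) == 4
        assert all(c == 2 for c in counts.values())

    def test_multisensory_visual_first_delay(self):
        config = SessionConfig(task="passive", n_presentations=3,
                               multisensory=True, visual_first=True,
                               delay_between_ms=100.0)
        result = run_session(config, seed=1)
        ons = [e for e in result.events
               if e.channel == "stimulus" and e.payload.get("on")]
        for vis, aud in zip(ons[0::2], ons[1::2]):
            assert vis.payload["modality"] == "visual"
            assert aud.payload["modality"] == "auditory"
            assert aud.time - vis.time == pytest.approx(0.1)

    def test_auditory_first(self):
        config = SessionConfig(task="passive", n_presentations=2,
                               multisensory=True, visual_first=False,
                               delay_between_ms=50.0)
        result = run_session(config, seed=1)
        ons = [e for e in result.events
               if e.channel == "stimulus" and e.payload.get("on")]
        assert ons[0].payload["modality"] == "auditory"
        assert ons[1].time - ons[0].time == pytest.approx(0.05)

    def test_isi_spacing(self):
        config = SessionConfig(task="passive", n_presentations=5, isi_s=2.0,
                               stimulus_duration_ms=200.0)
        result = run_session(config, seed=2)
        onsets = [e.time for e in result.events
                  if e.channel == "stimulus" and e.payload.get("on")]
        assert len(onsets) == 5
        gaps = np.diff(onsets)
        np.testing.assert_allclose(gaps, 2.2)  # isi + stimulus duration


# ----------------------------------------------------------------------
# Session-level invariants


class TestSessionInvariants:
    @pytest.mark.parametrize("task", ["2afc", "gng", "passive"])
    def test_event_monotonicity(self, task):
        config = SessionConfig(task=task, n_trials=40)
        result = run_session(config, SubjectParams(), seed=13)
        times = [e.time for e in result.events]
        assert all(b >= a for a, b in zip(times, times[1:]))

    def test_trial_events_within_trial_bounds(self, small_2afc_result):
        for rec in small_2afc_result.trials:
            assert rec.t_end > rec.t_start

    def test_window_never_opens_before_spout_arrival(self):
        config = SessionConfig(task="gng", n_trials=20, spout_travel_mm=40.0)
        result = run_session(config, SubjectParams(), seed=3)
        arrival = None
        for e in result.events:
            if e.channel == "center_spout" and \
                    e.payload.get("action") == "extended":
                arrival = e.time
            if e.channel == "state" and \
                    e.payload.get("phase") == "response_window_open":
                assert arrival is not None and e.time >= arrival

    @pytest.mark.parametrize("task", ["2afc", "gng", "passive"])
    def test_replay_identical(self, task):
        config = SessionConfig(task=task, n_trials=25)
        subject = SubjectParams(alpha=4.0, beta=0.8)
        a = run_session(config, subject, seed=21)
        b = run_session(config, subject, seed=21)
        assert a.trials == b.trials
        assert a.events == b.events

    def test_different_seeds_differ(self):
        config = SessionConfig(task="2afc", n_trials=25)
        a = run_session(config, SubjectParams(), seed=1)
        b = run_session(config, SubjectParams(), seed=2)
        assert a.events != b.events

    def test_phase_duration_fidelity(self, gng_delay_config):
        """Logged stimulus-onset -> window-open intervals equal the
        scheduled delays exactly (virtual clock, no jitter)."""
        result = run_session(gng_delay_config, SubjectParams(), seed=8)
        for rec in result.trials:
            trial_events = [e for e in result.events
                            if rec.t_start <= e.time < rec.t_end]
            t_on = next(e.time for e in trial_events
                        if e.channel == "stimulus" and e.payload.get("on"))
            t_open = next(e.time for e in trial_events
                          if e.channel == "state"
                          and e.payload.get("phase")
                          == "response_window_open")
            # exact up to float representation of the summed timestamps
            assert t_open - t_on == pytest.approx(rec.spec.post_stim_delay,
                                                  abs=1e-9)
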