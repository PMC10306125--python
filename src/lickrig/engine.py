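"""Discrete-event execution of the 2AFC, Go-NoGo and passive-stimulation
state machines on a virtual clock.

The engine consumes a scheduler-produced :class:`TrialSpec` stream and a
virtual subject, and emits a timestamped event log.  There is no wall-clock
sleeping: time is a float cursor, so scheduled phase durations are exact in
the log.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from . import scheduler as sched
from . import subject as subj
from .config import ConfigError, SessionConfig
from .subject import SubjectParams

LICK_LOCKOUT_S = 0.010  # sensor disabled for 10 ms after a registered lick

#: subset of outcome labels that count as correct
CORRECT_LABELS = frozenset(
    {"hit", "correct_rejection", "correct_left", "correct_right"})


# ----------------------------------------------------------------------
# Core records


@dataclass(frozen=True)
class Event:
    """A timestamped, typed record on the session clock."""

    time: float
    channel: str  # center_lick | left_lick | right_lick | center_spout |
    #               side_spout | stimulus | reward | punishment | state
    payload: dict

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be >= 0")


@dataclass(frozen=True)
class Outcome:
    label: str  # hit | miss | false_alarm | correct_rejection |
    #             correct_left | correct_right | incorrect | no_response
    response_time: float | None
    rewarded: bool
    chosen: str | None = None
    retries: int = 0
    retrial_resolved: bool = False

    @property
    def correct(self) -> bool:
        return self.label in CORRECT_LABELS


@dataclass(frozen=True)
class TrialSpec:
    """One trial's identity and scheduled phase parameters."""

    index: int
    kind: str  # 2afc-left | 2afc-right | go | nogo | passive
    stimulus: object
    stim_start_delay: float
    post_stim_delay: float
    iti: float
    training_flag: bool = True

    def __post_init__(self) -> None:
        if self.stim_start_delay < 0 or self.post_stim_delay < 0:
            raise ConfigError("trial delays must be >= 0")


@dataclass(frozen=True)
class TrialRecord:
    spec: TrialSpec
    outcome: Outcome
    t_start: float
    t_end: float


@dataclass
class SessionResult:
    """Ordered trials with outcomes plus the full event log."""

    task: str
    seed: int
    config: SessionConfig
    trials: list[TrialRecord] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    closed: bool = True


# ----------------------------------------------------------------------
# Clock and spout model


class VirtualClock:
    """Monotonic float time cursor; no wall-clock sleeping."""

    def __init__(self, t0: float = 0.0):
        self.t = float(t0)

    def now(self) -> float:
        return self.t

    def advance(self, dt: float) -> float:
        if dt < 0:
            raise ValueError("cannot advance the clock backwards")
        self.t += dt
        return self.t

    def advance_to(self, t: float) -> float:
        if t < self.t - 1e-12:
            raise ValueError("cannot move the clock backwards")
        self.t = max(self.t, t)
        return self.t


@dataclass(frozen=True)
class SpoutModel:
    """Travel-timing abstraction for the spout actuators: linear actuators
    run at 25 mm/s, the servo assembly at 50 mm/s."""

    actuator: str = "servo"
    travel_mm: float = 10.0
    speed_mm_per_s: float | None = None

    def speed(self) -> float:
        if self.speed_mm_per_s is not None:
            if self.speed_mm_per_s <= 0:
                raise ConfigError("spout speed must be > 0")
            return self.speed_mm_per_s
        if self.actuator == "servo":
            return 50.0
        if self.actuator == "linear":
            return 25.0
        raise ConfigError(f"unknown actuator {self.actuator!r}")


def spout_travel_time(model: SpoutModel) -> float:
    """Seconds between movement start and arrival: travel / speed."""
    if model.travel_mm < 0:
        raise ConfigError("travel_mm must be >= 0")
    return model.travel_mm / model.speed()


def _spout_model(config: SessionConfig) -> SpoutModel:
    speed = config.spout_speed_mm_per_s or None
    return SpoutModel(config.actuator, config.spout_travel_mm, speed)


# ----------------------------------------------------------------------
# Response evaluation


def evaluate_response(licks: Iterable[tuple[float, str]],
                      window: tuple[float, float],
                      required_licks_per_s: int,
                      ) -> tuple[str | None, float | None]:
    """Pick the responding spout from timestamped licks.

    The first spout accumulating ``required_licks_per_s`` licks within any
    1 s sliding sub-window of the response window wins; a requirement of 1
    reduces to first-lick-wins.  Returns (side, decision time) or
    (None, None).
    """
    if required_licks_per_s < 1:
        raise ConfigError("required_licks_per_s must be >= 1")
    t0, t1 = window
    by_spout: dict[str, list[float]] = {}
    for t, spout in licks:
        if t0 <= t <= t1:
            by_spout.setdefault(spout, []).append(t)
    best: tuple[float, str] | None = None
    r = required_licks_per_s
    for spout, times in by_spout.items():
        times.sort()
        for i in range(len(times) - r + 1):
            if times[i + r - 1] - times[i] <= 1.0:
                cand = (times[i + r - 1], spout)
                if best is None or cand < best:
                    best = cand
                break
    if best is None:
        return None, None
    return best[1], best[0]


def debounce(times: Sequence[float], lockout: float = LICK_LOCKOUT_S,
             ) -> list[float]:
    """Thin wrapper over the detector-model debounce (see session_io)."""
    from .session_io import debounce_licks
    return debounce_licks(times, lockout)


# ----------------------------------------------------------------------
# Event assembly helpers


class _Trace:
    """Per-trial event accumulator; sorted (stably) by time on flush so the
    emitted log is non-decreasing in time."""

    def __init__(self) -> None:
        self.events: list[Event] = []

    def emit(self, t: float, channel: str, **payload) -> None:
        self.events.append(Event(float(t), channel, payload))

    def flush(self) -> list[Event]:
        self.events.sort(key=lambda e: e.time)
        return self.events


def _as_streams(rng) -> dict[str, np.random.Generator]:
    if isinstance(rng, np.random.Generator):
        return {"subject": rng, "itis": rng}
    return rng


def _reward(trace: _Trace, t: float, spout: str, kind: str,
            config: SessionConfig) -> None:
    trace.emit(t, "reward", spout=spout, kind=kind,
               open_ms=config.valve_open_time_ms)


def _punish(trace: _Trace, t: float, config: SessionConfig) -> None:
    trace.emit(t, "punishment", on=True, kind=config.punishment_kind)
    trace.emit(t + config.punishment_duration_s, "punishment", on=False,
               kind=config.punishment_kind)


def _stimulus_payload(spec: TrialSpec) -> dict:
    payload: dict = {"id": str(spec.stimulus)}
    if isinstance(spec.stimulus, (int, np.integer)):
        payload["column"] = int(spec.stimulus)
    return payload


# ----------------------------------------------------------------------
# 2AFC trial


def _correct_side(kind: str) -> str:
    return subj.LEFT if kind.endswith("left") else subj.RIGHT


def _attempt_2afc(trace: _Trace, t_open: float, column_x: float,
                  subject: SubjectParams, config: SessionConfig,
                  rng: np.random.Generator) -> tuple[str | None, float | None]:
    """One response-window pass: the subject (maybe) licks a side; the lick
    requirement rule picks the responding spout."""
    if rng.random() >= subject.engagement:
        return None, None
    side = subj.choose_side(column_x, subject, rng)
    window = (t_open, t_open + config.response_window_s)
    train = subj.generate_licks(side, window, subject, rng)
    times = debounce(train.times)
    for lt in times:
        trace.emit(lt, f"{side}_lick")
    return evaluate_response(((lt, side) for lt in times), window,
                             config.required_licks_per_s)


def run_2afc_trial(spec: TrialSpec, subject: SubjectParams,
                   config: SessionConfig, clock: VirtualClock,
                   rng) -> tuple[Outcome, list[Event]]:
    """Run one self-initiated 2AFC trial.

    Phase order: extend center spout -> await initiation lick (rewarded with
    probability "Percentage of Center Rewards") -> prestimulus delay ->
    stimulus -> poststimulus delay with side spouts retracted (center licks
    rewarded once when "TCSA reward" is on) -> extend side spouts and open
    the response window -> classify -> reward/punish -> ITI.  In retrial
    mode an incorrect training-trial choice repeats the same stimulus until
    the correct side is licked (bounded by ``max_retrials``); no new trial
    is scheduled meanwhile.
    """
    if not spec.kind.startswith("2afc"):
        raise ConfigError(f"run_2afc_trial got kind {spec.kind!r}")
    streams = _as_streams(rng)
    sub = streams["subject"]
    trace = _Trace()
    travel = spout_travel_time(_spout_model(config))
    correct = _correct_side(spec.kind)
    column_x = float(spec.stimulus) if isinstance(
        spec.stimulus, (int, float, np.integer, np.floating)) else 0.0

    t = clock.now()
    trace.emit(t, "state", phase="trial_start", trial=spec.index,
               kind=spec.kind, training=spec.training_flag)
    trace.emit(t, "center_spout", action="extend_start")
    t = clock.advance(travel)
    trace.emit(t, "center_spout", action="extended")

    # --- initiation ---
    engaged = sub.random() < subject.engagement
    rt = subj.sample_reaction_time(subject, sub) if engaged else None
    if not engaged or rt > config.initiation_timeout_s:
        t = clock.advance(config.initiation_timeout_s)
        trace.emit(t, "state", phase="no_response", trial=spec.index)
        _retract(trace, clock, "center_spout", travel)
        outcome = Outcome("no_response", None, False)
        _finish_trial(trace, clock, spec.index, spec.iti)
        return outcome, trace.flush()
    t = clock.advance(rt)
    trace.emit(t, "center_lick")
    trace.emit(t, "state", phase="initiated", trial=spec.index)
    if sub.random() < config.percentage_of_center_rewards / 100.0:
        _reward(trace, t, "center", "center", config)

    # --- prestimulus delay and stimulus ---
    t = clock.advance(spec.stim_start_delay)
    stim = _stimulus_payload(spec)
    trace.emit(t, "stimulus", on=True, **stim)
    t = clock.advance(config.stimulus_duration_ms / 1000.0)
    trace.emit(t, "stimulus", on=False, **stim)

    # --- poststimulus delay (side spouts retracted) ---
    window_open = t + spec.post_stim_delay
    if config.tcsa_reward and window_open > t:
        train = subj.generate_licks("center", (t, window_open), subject, sub)
        times = debounce(train.times)
        for lt in times:
            trace.emit(lt, "center_lick")
        if times:  # one reward for continued center licking during the delay
            _reward(trace, times[0], "center", "tcsa", config)

    t_open = _open_side_window(trace, clock, t, window_open, travel)
    trace.emit(t_open, "center_spout", action="retract_start")
    trace.emit(t_open + travel, "center_spout", action="retracted")

    # --- first response attempt ---
    chosen, t_dec = _attempt_2afc(trace, t_open, column_x, subject, config, sub)
    retries = 0
    resolved = False
    if chosen is None:
        outcome = Outcome("no_response", None, False)
    elif chosen == correct:
        label = "correct_left" if correct == subj.LEFT else "correct_right"
        _reward(trace, t_dec, chosen, "outcome", config)
        outcome = Outcome(label, t_dec - t_open, True, chosen)
    else:
        if spec.training_flag:
            _punish(trace, t_dec, config)
        outcome = Outcome("incorrect", t_dec - t_open, False, chosen)
    _close_side_window(trace, clock, t_open, travel, config)

    # --- retrial loop: repeat the same stimulus until the correct side ---
    if (outcome.label == "incorrect" and config.retrial_mode
            and spec.training_flag):
        while retries < config.max_retrials:
            retries += 1
            clock.advance(config.retrial_gap_s)
            t = clock.now()
            trace.emit(t, "state", phase="retrial", trial=spec.index,
                       attempt=retries)
            trace.emit(t, "stimulus", on=True, **stim)
            t = clock.advance(config.stimulus_duration_ms / 1000.0)
            trace.emit(t, "stimulus", on=False, **stim)
            t_open = _open_side_window(trace, clock, t, t + spec.post_stim_delay,
                                       travel)
            chosen, t_dec = _attempt_2afc(trace, t_open, column_x, subject,
                                          config, sub)
            if chosen == correct:
                _reward(trace, t_dec, chosen, "retrial", config)
                resolved = True
            elif chosen is not None:
                _punish(trace, t_dec, config)
            _close_side_window(trace, clock, t_open, travel, config)
            if resolved:
                break
        outcome = replace(outcome, retries=retries, retrial_resolved=resolved)

    _finish_trial(trace, clock, spec.index, spec.iti)
    return outcome, trace.flush()


def _retract(trace: _Trace, clock: VirtualClock, channel: str,
             travel: float) -> None:
    t = clock.now()
    trace.emit(t, channel, action="retract_start")
    trace.emit(t + travel, channel, action="retracted")


def _open_side_window(trace: _Trace, clock: VirtualClock, t_ready: float,
                      window_open: float, travel: float) -> float:
    """Extend the side spout(s) so arrival coincides with the scheduled
    window opening; the window never opens before spout arrival."""
    extend_start = max(t_ready, window_open - travel)
    trace.emit(extend_start, "side_spout", action="extend_start")
    arrive = extend_start + travel
    trace.emit(arrive, "side_spout", action="extended")
    t_open = max(window_open, arrive)
    clock.advance_to(t_open)
    trace.emit(t_open, "state", phase="response_window_open")
    return t_open


def _close_side_window(trace: _Trace, clock: VirtualClock, t_open: float,
                       travel: float, config: SessionConfig) -> None:
    t_close = t_open + config.response_window_s
    clock.advance_to(t_close)
    trace.emit(t_close, "state", phase="response_window_close")
    trace.emit(t_close, "side_spout", action="retract_start")
    trace.emit(t_close + travel, "side_spout", action="retracted")


def _finish_trial(trace: _Trace, clock: VirtualClock, index: int,
                  iti: float) -> None:
    # trailing events (spout arrival, punishment offset) may outlast the
    # response window; the ITI starts after the last of them
    if trace.events:
        clock.advance_to(max(e.time for e in trace.events))
    t = clock.now()
    trace.emit(t, "state", phase="iti", trial=index, duration=iti)
    t = clock.advance(iti)
    trace.emit(t, "state", phase="trial_end", trial=index)


# ----------------------------------------------------------------------
# Go-NoGo trial

_CUE_DURATION_S = 0.1  # trial-start cue length; cue and stimulus never overlap


def run_gng_trial(spec: TrialSpec, subject: SubjectParams,
                  config: SessionConfig, clock: VirtualClock,
                  rng) -> tuple[Outcome, list[Event]]:
    """Run one Go-NoGo trial.

    Trials start automatically (optionally signaled by a start cue), run the
    prestimulus delay and the stimulus, then wait out the delay period —
    referenced to stimulus ONSET by default, so the (1, 5, 6) table with a
    200 ms stimulus gives post-offset gaps of 0.8-4.8 s — before the
    lickspout extends and the response window opens.  A lick scores a hit
    (go, rewarded) or false alarm (nogo, punished); no lick scores a miss or
    correct rejection.  The ITI is sampled by the caller: correct rejections
    use the short range, everything else the long range.
    """
    if spec.kind not in (sched.GO, sched.NOGO):
        raise ConfigError(f"run_gng_trial got kind {spec.kind!r}")
    streams = _as_streams(rng)
    sub = streams["subject"]
    trace = _Trace()
    travel = spout_travel_time(_spout_model(config))

    t = clock.now()
    trace.emit(t, "state", phase="trial_start", trial=spec.index,
               kind=spec.kind)
    if config.trial_start_signal != "none":
        trace.emit(t, "stimulus", on=True, id="trial_start_signal",
                   cue=config.trial_start_signal)
        t = clock.advance(_CUE_DURATION_S)
        trace.emit(t, "stimulus", on=False, id="trial_start_signal",
                   cue=config.trial_start_signal)
    t = clock.advance(spec.stim_start_delay)
    t_on = t
    stim = _stimulus_payload(spec)
    stim["kind"] = spec.kind
    trace.emit(t, "stimulus", on=True, **stim)
    t_off = clock.advance(config.stimulus_duration_ms / 1000.0)
    trace.emit(t_off, "stimulus", on=False, **stim)

    reference = t_on if config.delay_reference == "onset" else t_off
    window_open = reference + spec.post_stim_delay
    if window_open < t_off:
        raise ConfigError(
            "delay period ends before stimulus offset; increase the delay "
            "or switch delay_reference to 'offset'")
    t_open = _open_gng_window(trace, clock, t_off, window_open, travel)

    lick, latency = subj.respond_gng(spec.kind, spec.post_stim_delay,
                                     subject, sub)
    responded = lick and latency is not None and latency <= config.response_window_s
    if responded:
        t_dec = t_open + latency
        window = (t_dec, t_open + config.response_window_s)
        if window[1] > window[0]:
            train = subj.generate_licks("center", window, subject, sub,
                                        reaction_time=0.0)
            for lt in debounce(train.times):
                trace.emit(lt, "center_lick")
        else:
            trace.emit(t_dec, "center_lick")
        if spec.kind == sched.GO:
            _reward(trace, t_dec, "center", "outcome", config)
            outcome = Outcome("hit", latency, True, "lick")
        else:
            _punish(trace, t_dec, config)
            outcome = Outcome("false_alarm", latency, False, "lick")
    else:
        label = "miss" if spec.kind == sched.GO else "correct_rejection"
        outcome = Outcome(label, None, False, None)

    t_close = t_open + config.response_window_s
    clock.advance_to(t_close)
    trace.emit(t_close, "state", phase="response_window_close")
    trace.emit(t_close, "center_spout", action="retract_start")
    trace.emit(t_close + travel, "center_spout", action="retracted")

    # short ITI after a correct rejection, long otherwise
    itis = streams.get("itis", sub)
    if outcome.label == "correct_rejection":
        iti = sched.sample_iti(config.short_iti_min, config.short_iti_max,
                               itis, config.iti_rate or None)
    else:
        iti = sched.sample_iti(config.iti_min, config.iti_max, itis,
                               config.iti_rate or None)
    _finish_trial(trace, clock, spec.index, iti)
    return outcome, trace.flush()


def _open_gng_window(trace: _Trace, clock: VirtualClock, t_ready: float,
                     window_open: float, travel: float) -> float:
    extend_start = max(t_ready, window_open - travel)
    trace.emit(extend_start, "center_spout", action="extend_start")
    arrive = extend_start + travel
    trace.emit(arrive, "center_spout", action="extended")
    t_open = max(window_open, arrive)
    clock.advance_to(t_open)
    trace.emit(t_open, "state", phase="response_window_open")
    return t_open


# ----------------------------------------------------------------------
# Passive stimulation block


_ORIENTATIONS = ("0", "45left", "45right", "90")


def run_passive_block(config: SessionConfig, clock: VirtualClock,
                      rng) -> list[Event]:
    """Emit the passive-stimulation schedule as stimulus on/off alignment
    pulses.

    In "Combination" mode the four orientations are presented randomly via
    a without-replacement sampling pool.  Multisensory mode presents visual
    and auditory stimuli ordered by the "Visual first" flag with the
    configured "delay between (ms)".
    """
    streams = _as_streams(rng)
    gen = streams.get("stimuli", streams["subject"])
    trace = _Trace()
    dur = config.stimulus_duration_ms / 1000.0
    pool = sched.SamplingPool(_ORIENTATIONS) if config.combination else None
    delay_between = config.delay_between_ms / 1000.0

    for i in range(config.n_presentations):
        t = clock.now()
        trace.emit(t, "state", phase="presentation", index=i)
        if config.combination:
            angle = pool.draw(gen)
            vis_id = f"bars_{angle}"
        else:
            vis_id = config.passive_style
        if config.multisensory:
            first, second = ("visual", "auditory") if config.visual_first \
                else ("auditory", "visual")
            onsets = {first: t, second: t + delay_between}
            for modality in (first, second):
                t_on = onsets[modality]
                sid = vis_id if modality == "visual" else "tone"
                trace.emit(t_on, "stimulus", on=True, id=sid,
                           modality=modality)
                trace.emit(t_on + dur, "stimulus", on=False, id=sid,
                           modality=modality)
            t_end = max(onsets.values()) + dur
        else:
            trace.emit(t, "stimulus", on=True, id=vis_id)
            t_end = t + dur
            trace.emit(t_end, "stimulus", on=False, id=vis_id)
        clock.advance_to(t_end)
        if i < config.n_presentations - 1:
            clock.advance(config.isi_s)
    return trace.flush()


# ----------------------------------------------------------------------
# Whole-session driver


def run_session(config: SessionConfig, subject: SubjectParams | None = None,
                seed: int | None = None) -> SessionResult:
    """Run a full session deterministically from one seed.

    All randomness flows through named sub-streams (sides, delays, itis,
    subject, mix, stimuli), so identical config + seed replays to an
    identical :class:`SessionResult`.
    """
    config.validate()
    if subject is None:
        subject = SubjectParams()
    seed = config.seed if seed is None else seed
    streams = sched.substreams(seed)
    clock = VirtualClock()
    result = SessionResult(task=config.task, seed=seed, config=config)
    result.events.append(Event(0.0, "state", {"phase": "session_start"}))

    if config.task == "passive":
        result.events.extend(run_passive_block(config, clock, streams))
    elif config.task == "2afc":
        _run_2afc_session(config, subject, streams, clock, result)
    elif config.task == "gng":
        _run_gng_session(config, subject, streams, clock, result)
    result.events.append(
        Event(clock.now(), "state", {"phase": "session_end"}))
    return result


def _delay_pool_or_fixed(minimum: float, maximum: float, steps: int,
                         variable: bool) -> sched.SamplingPool | float:
    if not variable:
        return float(minimum)
    table = sched.build_delay_table(minimum, maximum, steps)
    return sched.SamplingPool(table.values)


def _draw_delay(source: sched.SamplingPool | float,
                rng: np.random.Generator) -> float:
    if isinstance(source, sched.SamplingPool):
        return float(source.draw(rng))
    return source


def _run_2afc_session(config: SessionConfig, subject: SubjectParams,
                      streams: dict, clock: VirtualClock,
                      result: SessionResult) -> None:
    training_cols = config.training_column_list()
    left_col, right_col = min(training_cols), max(training_cols)
    mid = (left_col + right_col) / 2.0
    mix = sched.TrialMix(config.fraction_training, training_cols,
                         config.novel_column_list()
                         if config.fraction_training < 1 else [])
    mixed = sched.mix_trials(mix, config.n_trials, streams["mix"],
                             exact=config.exact_mix)
    pre = _delay_pool_or_fixed(
        config.stim_start_delay_min, config.stim_start_delay_max,
        config.stim_start_delay_steps, config.variable_stim_start_delay)
    post = _delay_pool_or_fixed(
        config.time_center_spout_available_min,
        config.time_center_spout_available_max,
        config.time_center_spout_available_steps,
        config.variable_time_center_spout_available)
    history = sched.TrialSideHistory()
    p_right = config.percentage_of_right_trials / 100.0
    constraints_on = not config.override_consec_constraint

    for i, mt in enumerate(mixed):
        if mt.training:
            side = sched.next_trial_side(history, p_right, constraints_on,
                                         streams["sides"])
            column = left_col if side == subj.LEFT else right_col
        else:
            column = int(mt.stimulus)
            if column < mid:
                side = subj.LEFT
            elif column > mid:
                side = subj.RIGHT
            else:  # center column: either side counts as correct; coin flip
                side = (subj.RIGHT if streams["sides"].random() < 0.5
                        else subj.LEFT)
        history.append(side)
        spec = TrialSpec(
            index=i, kind=f"2afc-{side}", stimulus=column,
            stim_start_delay=_draw_delay(pre, streams["delays"]),
            post_stim_delay=_draw_delay(post, streams["delays"]),
            iti=sched.sample_iti(config.iti_min, config.iti_max,
                                 streams["itis"], config.iti_rate or None),
            training_flag=mt.training)
        t_start = clock.now()
        outcome, events = run_2afc_trial(spec, subject, config, clock, streams)
        result.events.extend(events)
        result.trials.append(TrialRecord(spec, outcome, t_start, clock.now()))


def _run_gng_session(config: SessionConfig, subject: SubjectParams,
                     streams: dict, clock: VirtualClock,
                     result: SessionResult) -> None:
    table = sched.build_delay_table(
        config.delay_period_min, config.delay_period_max,
        config.delay_period_steps)
    # delays are drawn separately for go and nogo trials, each without
    # replacement from the same defined pool
    pools = {sched.GO: sched.SamplingPool(table.values),
             sched.NOGO: sched.SamplingPool(table.values)}
    p_go = config.percentage_of_go_trials / 100.0
    prev_outcome: str | None = None

    for i in range(config.n_trials):
        kind = sched.next_trial_gng(p_go, config.cr_rule_on, prev_outcome,
                                    streams["sides"])
        spec = TrialSpec(
            index=i, kind=kind, stimulus=(config.go_stimulus
                                          if kind == sched.GO
                                          else config.nogo_stimulus),
            stim_start_delay=config.stim_start_delay_min,
            post_stim_delay=_draw_delay(pools[kind], streams["delays"]),
            iti=0.0)
        t_start = clock.now()
        outcome, events = run_gng_trial(spec, subject, config, clock, streams)
        result.events.extend(events)
        result.trials.append(TrialRecord(spec, outcome, t_start, clock.now()))
        prev_outcome = outcome.label
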