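"""Session-log and settings persistence, the 3-byte device-command codec,
lick debouncing, and the DAQ-style multichannel trace.

Log grammar (version 1) — plain text, one record per line:

    # lickrig-log v1
    [settings]
    <label>=<value>                 (full settings snapshot, sorted)
    [meta]
    seed=<int> / task=<name> / closed=<0|1>
    [trials]
    <json object per trial>
    [events]
    <t.mmm>\t<channel>\t<json payload>
    [end]

Timestamps are written with millisecond precision (the plain-text log is a
convenience record, not a neural-alignment source; the DAQ trace carries
the precise timing).  ``parse_session_log(write_session_log(r))`` is
lossless for all analysis-relevant fields, and a second write is
byte-identical to the first.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import ConfigError, SessionConfig
from .engine import Event, Outcome, SessionResult, TrialRecord, TrialSpec
from .stimuli import column_to_signal_level

LOG_MAGIC = "# lickrig-log v1"

DEFAULT_LOCKOUT_S = 0.010  # sensor disabled 10 ms after a registered lick


class LogParseError(ValueError):
    """Raised with the offending line number for malformed log lines."""


class ProtocolError(ValueError):
    """Raised for malformed device-command byte strings."""


# ----------------------------------------------------------------------
# Lick debouncing


def debounce_licks(raw_times: Sequence[float],
                   lockout: float = DEFAULT_LOCKOUT_S) -> list[float]:
    """Greedy left-to-right lockout pass over sorted lick times.

    A lick is kept only if it falls at least ``lockout`` after the last kept
    lick, capping the output rate at 1/lockout (100 Hz for the default
    10 ms).  Idempotent.  Raises on unsorted input.
    """
    out: list[float] = []
    prev_raw = -np.inf
    tol = 1e-9  # intervals are compared with a float-representation margin
    for t in raw_times:
        if t < prev_raw:
            raise ValueError("raw lick times must be sorted")
        prev_raw = t
        if not out or t - out[-1] >= lockout - tol:
            out.append(float(t))
    return out


# ----------------------------------------------------------------------
# Device-command codec


@dataclass(frozen=True)
class DeviceCommand:
    """A 3-byte serial instruction: device type, device assignment, action
    (e.g. valves / Center / open encodes as [b'k', 1, 1])."""

    device: str
    assignment: int
    action: int

    def __post_init__(self) -> None:
        if len(self.device) != 1 or not 0 <= ord(self.device) < 256:
            raise ProtocolError("device must be a single byte character")
        for name in ("assignment", "action"):
            v = getattr(self, name)
            if not 0 <= v < 256:
                raise ProtocolError(f"{name} must fit in one byte, got {v}")


#: Device/assignment/action vocabulary.  Only the valve command is printed
#: in the protocol description; the rest is the package's own documented
#: extension of the same 3-byte scheme.
DEVICE_TABLE: dict[str, dict] = {
    "k": {"name": "valves",
          "assignments": {1: "center", 2: "left", 3: "right"},
          "actions": {0: "close", 1: "open"}},
    "s": {"name": "spouts",
          "assignments": {1: "center", 2: "sides"},
          "actions": {0: "retract", 1: "extend"}},
    "v": {"name": "led_panel",
          "assignments": {i: f"column_{i}" for i in range(9)},
          "actions": {0: "off", 1: "on"}},
    "a": {"name": "audio",
          "assignments": {1: "left", 2: "right", 3: "both"},
          "actions": {0: "off", 1: "on"}},
    "p": {"name": "punishment",
          "assignments": {1: "noise", 2: "air_puff"},
          "actions": {0: "off", 1: "on"}},
}


def encode_command(cmd: DeviceCommand) -> bytes:
    """Encode as exactly three bytes: [device, assignment, action]."""
    return bytes([ord(cmd.device), cmd.assignment, cmd.action])


def decode_command(data: bytes) -> DeviceCommand:
    """Invert :func:`encode_command`; rejects anything but 3 bytes."""
    if len(data) != 3:
        raise ProtocolError(f"device commands are 3 bytes, got {len(data)}")
    return DeviceCommand(chr(data[0]), data[1], data[2])


def all_table_commands() -> list[DeviceCommand]:
    """Every command expressible in :data:`DEVICE_TABLE`."""
    out = []
    for dev, entry in DEVICE_TABLE.items():
        for a in entry["assignments"]:
            for act in entry["actions"]:
                out.append(DeviceCommand(dev, a, act))
    return out


# ----------------------------------------------------------------------
# Session log


def _trial_to_json(rec: TrialRecord) -> str:
    d = {"spec": asdict(rec.spec), "outcome": asdict(rec.outcome),
         "t_start": rec.t_start, "t_end": rec.t_end}
    return json.dumps(d, sort_keys=True)


def _trial_from_json(line: str) -> TrialRecord:
    d = json.loads(line)
    return TrialRecord(spec=TrialSpec(**d["spec"]),
                       outcome=Outcome(**d["outcome"]),
                       t_start=d["t_start"], t_end=d["t_end"])


def write_session_log(result: SessionResult, path: str | Path) -> None:
    """Write the full session (settings header, trials, events) as text."""
    lines = [LOG_MAGIC, "[settings]"]
    lines += [f"{k}={v}" for k, v in sorted(result.config.to_flat().items())]
    lines += ["[meta]", f"seed={result.seed}", f"task={result.task}",
              f"closed={1 if result.closed else 0}"]
    lines.append("[trials]")
    lines += [_trial_to_json(t) for t in result.trials]
    lines.append("[events]")
    for e in result.events:
        lines.append(f"{e.time:.3f}\t{e.channel}\t"
                     f"{json.dumps(e.payload, sort_keys=True)}")
    lines.append("[end]")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_session_log(path: str | Path) -> SessionResult:
    """Parse a session log back into a :class:`SessionResult`.

    Malformed lines raise :class:`LogParseError` naming the line number; a
    file truncated before ``[end]`` parses into a result flagged unclosed.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or lines[0] != LOG_MAGIC:
        raise LogParseError("line 1: not a lickrig session log")
    section = None
    flat: dict[str, str] = {}
    meta: dict[str, str] = {}
    trials: list[TrialRecord] = []
    events: list[Event] = []
    saw_end = False
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if line.startswith("["):
            section = line.strip().strip("[]")
            if section == "end":
                saw_end = True
            continue
        try:
            if section == "settings":
                key, _, value = line.partition("=")
                flat[key] = value
            elif section == "meta":
                key, _, value = line.partition("=")
                meta[key] = value
            elif section == "trials":
                trials.append(_trial_from_json(line))
            elif section == "events":
                ts, channel, payload = line.split("\t", 2)
                events.append(Event(float(ts), channel, json.loads(payload)))
            else:
                raise ValueError("content outside any section")
        except LogParseError:
            raise
        except Exception as exc:
            raise LogParseError(f"line {i}: {exc}") from exc
    config = SessionConfig.from_flat(flat)
    closed = saw_end and meta.get("closed") == "1"
    if not saw_end:
        warnings.warn("session log truncated; flagging result as unclosed")
    return SessionResult(task=meta.get("task", config.task),
                         seed=int(meta.get("seed", config.seed)),
                         config=config, trials=trials, events=events,
                         closed=closed)


def export_settings_xlsx(config: SessionConfig, path: str | Path) -> None:
    """Companion spreadsheet export: one sheet, key/value columns."""
    from openpyxl import Workbook

    wb = Workbook()
    ws = wb.active
    ws.title = "settings"
    ws.append(["parameter", "value"])
    for k, v in sorted(config.to_flat().items()):
        ws.append([k, v])
    wb.save(str(path))


# ----------------------------------------------------------------------
# Settings store (save / load / default rollback)

DEFAULT_SETTINGS_NAME = "default_settings.cfg"
SETTINGS_NAME = "settings.cfg"


class SettingsStore:
    """Latest-used settings persist across restarts; a shipped
    ``default_settings`` file allows rollback, and a missing or corrupt
    settings file silently falls back to the defaults."""

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self._defaults_path = self.directory / DEFAULT_SETTINGS_NAME
        self._settings_path = self.directory / SETTINGS_NAME
        if not self._defaults_path.exists():
            SessionConfig().save(self._defaults_path)

    def save(self, config: SessionConfig) -> None:
        config.save(self._settings_path)

    def load(self) -> SessionConfig:
        if not self._settings_path.exists():
            return SessionConfig.load(self._defaults_path)
        try:
            return SessionConfig.load(self._settings_path)
        except (ConfigError, ValueError) as exc:
            warnings.warn(f"corrupt settings file ({exc}); loading defaults")
            return SessionConfig.load(self._defaults_path)

    def reset_to_defaults(self) -> SessionConfig:
        config = SessionConfig.load(self._defaults_path)
        config.save(self._settings_path)
        return config


# ----------------------------------------------------------------------
# DAQ-style trace

#: reward channel encoding: low, left; medium, center; high, right
REWARD_LEVELS = {"left": 1.0 / 3.0, "center": 2.0 / 3.0, "right": 1.0}

LICK_PULSE_S = 0.002  # 2 ms pulses, resolvable at the 5 kHz DAQ bandwidth

DAQ_CHANNELS = ("center_spout", "side_spout", "led_panel", "center_licks",
                "left_licks", "right_licks", "rewards", "punishment")


@dataclass
class DaqTrace:
    sample_rate: float
    time: np.ndarray
    channels: dict[str, np.ndarray]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame({"time": self.time, **self.channels})
        df.to_csv(path, index=False)


def render_daq_trace(events: Sequence[Event],
                     sample_rate: float = 5000.0) -> DaqTrace:
    """Render the event log as step-function voltage channels on a uniform
    grid, mirroring what a data-acquisition board would record.

    Spout channels sit high while the spout is extended; lick channels emit
    2 ms pulses; the LED channel encodes the stimulus column as its level;
    the reward channel uses the low/medium/high = left/center/right
    encoding gated by the valve-open window; punishment is a gate between
    its on and offset.
    """
    if sample_rate <= 0:
        raise ConfigError("sample_rate must be > 0")
    t_max = max((e.time for e in events), default=0.0)
    n = int(np.ceil(t_max * sample_rate)) + 2
    time = np.arange(n) / sample_rate
    ch = {name: np.zeros(n) for name in DAQ_CHANNELS}

    def idx(t: float) -> int:
        return min(n - 1, max(0, int(np.ceil(t * sample_rate - 1e-9))))

    def gate(name: str, t0: float, t1: float, level: float = 1.0) -> None:
        ch[name][idx(t0):idx(t1) + 1] = level

    spout_on = {"center_spout": None, "side_spout": None}
    punish_on = None
    for e in events:
        if e.channel in ("center_spout", "side_spout"):
            action = e.payload.get("action")
            if action == "extended":
                spout_on[e.channel] = e.time
            elif action == "retract_start" and spout_on[e.channel] is not None:
                gate(e.channel, spout_on[e.channel], e.time)
                spout_on[e.channel] = None
        elif e.channel in ("center_lick", "left_lick", "right_lick"):
            gate(e.channel + "s", e.time, e.time + LICK_PULSE_S)
        elif e.channel == "stimulus":
            if e.payload.get("on"):
                level = (column_to_signal_level(e.payload["column"])
                         if "column" in e.payload else 1.0)
                e_key = e.payload.get("id")
                spout_on.setdefault(("stim", e_key), None)
                spout_on[("stim", e_key)] = (e.time, level)
            else:
                key = ("stim", e.payload.get("id"))
                start = spout_on.get(key)
                if start is not None:
                    t0, level = start
                    gate("led_panel", t0, e.time, level)
                    spout_on[key] = None
        elif e.channel == "reward":
            level = REWARD_LEVELS.get(e.payload.get("spout"), 1.0)
            dur = e.payload.get("open_ms", 30.0) / 1000.0
            gate("rewards", e.time, e.time + dur, level)
        elif e.channel == "punishment":
            if e.payload.get("on"):
                punish_on = e.time
            elif punish_on is not None:
                gate("punishment", punish_on, e.time)
                punish_on = None
    # close any gates left open at the end of the record
    for key, start in spout_on.items():
        if start is None:
            continue
        if isinstance(key, tuple):
            gate("led_panel", start[0], time[-1], start[1])
        else:
            gate(key, start, time[-1])
    if punish_on is not None:
        gate("punishment", punish_on, time[-1])
    return DaqTrace(sample_rate=sample_rate, time=time, channels=ch)


def recover_pulse_times(trace: DaqTrace, channel: str,
                        threshold: float = 0.5) -> np.ndarray:
    """Rising-edge times of a rendered channel; recovers event times to
    within one sample period."""
    x = trace.channels[channel] > threshold
    edges = np.flatnonzero(x[1:] & ~x[:-1]) + 1
    if x[0]:
        edges = np.concatenate([[0], edges])
    return trace.time[edges]
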