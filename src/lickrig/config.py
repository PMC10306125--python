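"""Session configuration: every GUI-settable parameter needed to run a
session deterministically given a seed.

Configuration files are flat ``key=value`` text.  Keys mirror the control
panel labels verbatim where such labels exist ("Percentage of Go Trials",
"Delay Period (s)", "Override Consec Constraint", ...); parameters that are
set in a group of boxes (minimum, maximum, steps) are written as a single
comma-separated triple under the group's label.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any


class ConfigError(ValueError):
    """Raised for invalid or inconsistent session parameters."""


@dataclass
class SessionConfig:
    # -- session-level --
    task: str = "2afc"  # one of {"2afc", "gng", "passive"}
    n_trials: int = 100
    seed: int = 0

    # -- 2AFC scheduling --
    percentage_of_right_trials: float = 50.0
    percentage_of_center_rewards: float = 0.0
    override_consec_constraint: bool = False
    retrial_mode: bool = False
    max_retrials: int = 25
    retrial_gap_s: float = 1.0
    tcsa_reward: bool = False
    # stimulus mix for psychometric testing (training vs novel columns)
    fraction_training: float = 1.0
    exact_mix: bool = False
    training_columns: str = "0,8"
    novel_columns: str = "1,2,3,4,5,6,7"

    # -- delays (minimum, maximum, steps boxes) --
    stim_start_delay_min: float = 0.5
    stim_start_delay_max: float = 0.5
    stim_start_delay_steps: int = 1
    variable_stim_start_delay: bool = False
    time_center_spout_available_min: float = 1.0
    time_center_spout_available_max: float = 1.0
    time_center_spout_available_steps: int = 1
    variable_time_center_spout_available: bool = False
    delay_period_min: float = 1.0
    delay_period_max: float = 1.0
    delay_period_steps: int = 1
    # whether the GNG "Delay Period" timer is referenced to stimulus onset
    # or offset.  Onset is the default: with the (1, 5, 6) table and a
    # 200 ms stimulus it yields post-offset gaps of 0.8-4.8 s.
    delay_reference: str = "onset"

    # -- stimulus --
    stimulus_duration_ms: float = 200.0
    go_stimulus: str = "go"
    nogo_stimulus: str = "nogo"
    trial_start_signal: str = "none"  # {"none", "light", "tone"}

    # -- GNG scheduling --
    percentage_of_go_trials: float = 50.0
    cr_rule_on: bool = False

    # -- intertrial intervals --
    iti_min: float = 2.0
    iti_max: float = 5.0
    short_iti_min: float = 0.5
    short_iti_max: float = 1.5
    iti_rate: float = 0.0  # 0 -> auto: untruncated mean = (max-min)/3

    # -- response rules --
    response_window_s: float = 2.0
    required_licks_per_s: int = 1
    initiation_timeout_s: float = 30.0

    # -- spout actuation --
    actuator: str = "servo"  # {"servo", "linear"}
    spout_travel_mm: float = 10.0
    spout_speed_mm_per_s: float = 0.0  # 0 -> actuator default (50 or 25)

    # -- reward / punishment --
    valve_open_time_ms: float = 30.0
    punishment_duration_s: float = 1.0
    punishment_kind: str = "noise"

    # -- passive stimulation --
    n_presentations: int = 10
    isi_s: float = 2.0
    combination: bool = False
    multisensory: bool = False
    visual_first: bool = True
    delay_between_ms: float = 100.0
    passive_style: str = "full_panel"

    # ------------------------------------------------------------------

    def validate(self) -> "SessionConfig":
        if self.task not in ("2afc", "gng", "passive"):
            raise ConfigError(f"unknown task {self.task!r}")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        for name in ("percentage_of_right_trials", "percentage_of_go_trials",
                     "percentage_of_center_rewards"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ConfigError(f"{name} must be in [0, 100], got {v}")
        if not 0.0 <= self.fraction_training <= 1.0:
            raise ConfigError("fraction_training must be in [0, 1]")
        for prefix in ("stim_start_delay", "time_center_spout_available",
                       "delay_period"):
            lo = getattr(self, prefix + "_min")
            hi = getattr(self, prefix + "_max")
            steps = getattr(self, prefix + "_steps")
            if steps < 1:
                raise ConfigError(f"{prefix}_steps must be >= 1")
            if hi < lo:
                raise ConfigError(f"{prefix}: maximum < minimum")
        for lo_name, hi_name in (("iti_min", "iti_max"),
                                 ("short_iti_min", "short_iti_max")):
            lo, hi = getattr(self, lo_name), getattr(self, hi_name)
            if lo < 0 or hi < lo:
                raise ConfigError(f"bad ITI range [{lo}, {hi}]")
        if self.delay_reference not in ("onset", "offset"):
            raise ConfigError("delay_reference must be 'onset' or 'offset'")
        if self.actuator not in ("servo", "linear"):
            raise ConfigError("actuator must be 'servo' or 'linear'")
        if self.required_licks_per_s < 1:
            raise ConfigError("required_licks_per_s must be >= 1")
        if self.n_presentations < 1:
            raise ConfigError("n_presentations must be >= 1")
        if self.isi_s < 0:
            raise ConfigError("isi_s must be >= 0")
        return self

    # parsed column helpers -------------------------------------------

    def training_column_list(self) -> list[int]:
        return _parse_int_list(self.training_columns)

    def novel_column_list(self) -> list[int]:
        return _parse_int_list(self.novel_columns)

    def spout_speed(self) -> float:
        """Actuator speed in mm/s; 0 falls back to the actuator default
        (servo 50 mm/s, linear actuator 25 mm/s)."""
        if self.spout_speed_mm_per_s > 0:
            return self.spout_speed_mm_per_s
        return 50.0 if self.actuator == "servo" else 25.0

    # serialization ----------------------------------------------------

    def to_flat(self) -> dict[str, str]:
        """Flat label -> string mapping, suitable for a key=value file."""
        out: dict[str, str] = {}
        consumed: set[str] = set()
        for label, names in _GROUPS.items():
            parts = [_format_value(getattr(self, n)) for n in names]
            out[label] = ",".join(parts)
            consumed.update(names)
        for f in fields(self):
            if f.name in consumed:
                continue
            label = _LABELS.get(f.name, f.name)
            out[label] = _format_value(getattr(self, f.name))
        return out

    @classmethod
    def from_flat(cls, flat: dict[str, str]) -> "SessionConfig":
        kwargs: dict[str, Any] = {}
        types = {f.name: f.type for f in fields(cls)}
        label_to_field = {v: k for k, v in _LABELS.items()}
        for key, raw in flat.items():
            if key in _GROUPS:
                parts = [p.strip() for p in str(raw).split(",")]
                names = _GROUPS[key]
                if len(parts) != len(names):
                    raise ConfigError(
                        f"{key!r} expects {len(names)} comma-separated "
                        f"values, got {raw!r}")
                for name, part in zip(names, parts):
                    kwargs[name] = _parse_value(part, types[name])
                continue
            name = label_to_field.get(key, key)
            if name not in types:
                raise ConfigError(f"unknown configuration key {key!r}")
            kwargs[name] = _parse_value(str(raw), types[name])
        return cls(**kwargs).validate()

    def save(self, path: str | Path) -> None:
        lines = [f"{k}={v}" for k, v in sorted(self.to_flat().items())]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SessionConfig":
        flat: dict[str, str] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"line {i}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            flat[key.strip()] = value.strip()
        return cls.from_flat(flat)

    def replace(self, **changes: Any) -> "SessionConfig":
        return dataclasses.replace(self, **changes)


# Labels matching the control-panel vocabulary.  Fields not listed here are
# written under their own names.
_LABELS = {
    "percentage_of_go_trials": "Percentage of Go Trials",
    "percentage_of_center_rewards": "Percentage of Center Rewards",
    "percentage_of_right_trials": "Percentage of Right Trials",
    "override_consec_constraint": "Override Consec Constraint",
    "cr_rule_on": "CR rule ON",
    "retrial_mode": "Retrial Mode",
    "tcsa_reward": "TCSA reward",
    "variable_stim_start_delay": "Variable Stim Start Delay",
    "variable_time_center_spout_available": "Variable Time Center Spout Available",
    "stimulus_duration_ms": "Stimulus Duration (ms)",
    "trial_start_signal": "Trial Start Signal",
    "visual_first": "Visual first",
    "delay_between_ms": "delay between (ms)",
    "combination": "Combination",
}

# Grouped min/max(/steps) boxes written as one comma-separated value.
_GROUPS = {
    "Stim Start Delay (s)": (
        "stim_start_delay_min", "stim_start_delay_max",
        "stim_start_delay_steps"),
    "Time Center Spout Available": (
        "time_center_spout_available_min", "time_center_spout_available_max",
        "time_center_spout_available_steps"),
    "Delay Period (s)": (
        "delay_period_min", "delay_period_max", "delay_period_steps"),
    "ITI": ("iti_min", "iti_max"),
    "Short ITI": ("short_iti_min", "short_iti_max"),
}


def _format_value(v: Any) -> str:
    if isinstance(v, bool):
        return "1" if v else "0"
    return repr(v) if isinstance(v, float) else str(v)


def _parse_value(raw: str, typ: Any) -> Any:
    typ = str(typ)
    try:
        if "bool" in typ:
            return raw.strip() in ("1", "true", "True", "yes", "on")
        if "int" in typ:
            return int(float(raw))
        if "float" in typ:
            return float(raw)
    except ValueError as exc:
        raise ConfigError(f"cannot parse {raw!r} as {typ}") from exc
    return raw


def _parse_int_list(raw: str) -> list[int]:
    raw = raw.strip()
    if not raw:
        return []
    return [int(p) for p in raw.split(",")]
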