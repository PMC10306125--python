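"""Abstract visual and auditory stimuli.

Visual patterns target a 9x16 LED matrix (three such panels form a crescent
of nine stimulus columns, indexed 0-8 left to right).  The shipped pattern
set covers a full panel, stationary bars at four angles (0 deg, 45 deg left,
45 deg right, 90 deg) and a moving vertical bar of 1-3 pixel width.  Exact
bar geometries are defined by the versioned pattern table in this module;
analyses depend only on stimulus identity, never on pixel art.

Auditory stimuli are tones from a 2-32 kHz library or white noise, rendered
through a 32-point sine lookup table with a phase accumulator — the same
synthesis idiom a microcontroller DAC pipeline would use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import ConfigError

N_ROWS = 9
N_COLS = 16
N_COLUMNS = 9  # stimulus columns along the crescent

ANGLES = ("0", "45left", "45right", "90")

PATTERN_TABLE_VERSION = 1

TONE_MIN_HZ = 2000.0
TONE_MAX_HZ = 32000.0

_LOOKUP_POINTS = 32
_SINE_TABLE = np.sin(2 * np.pi * np.arange(_LOOKUP_POINTS) / _LOOKUP_POINTS)


@dataclass(frozen=True)
class VisualStimulus:
    style: str  # {"full_panel", "stationary_bars", "moving_bar"}
    duration: float
    column_position: int = 4
    angle: str = "0"              # stationary_bars only
    bar_width: int = 1            # moving_bar only, in {1, 2, 3}
    flash_frequency: float | None = None
    frame_period: float = 0.030   # moving-bar frame period (not printed; default 30 ms)

    def __post_init__(self) -> None:
        if self.style not in ("full_panel", "stationary_bars", "moving_bar"):
            raise ConfigError(f"unknown visual style {self.style!r}")
        if not 0 <= self.column_position <= N_COLUMNS - 1:
            raise ConfigError("column_position must be in [0, 8]")
        if self.style == "stationary_bars" and self.angle not in ANGLES:
            raise ConfigError(f"angle must be one of {ANGLES}")
        if self.style == "moving_bar" and self.bar_width not in (1, 2, 3):
            raise ConfigError("moving-bar width must be 1, 2 or 3 pixels")


@dataclass(frozen=True)
class AuditoryStimulus:
    pitch: float | str  # Hz in [2000, 32000], or "noise"
    duration: float
    side: str = "both"  # {"left", "right", "both"}
    presentation_rate: float | None = None

    def __post_init__(self) -> None:
        if self.pitch != "noise":
            p = float(self.pitch)
            if not TONE_MIN_HZ <= p <= TONE_MAX_HZ:
                raise ConfigError(
                    f"tone pitch {p} Hz outside library range "
                    f"[{TONE_MIN_HZ:g}, {TONE_MAX_HZ:g}]")
        if self.side not in ("left", "right", "both"):
            raise ConfigError("side must be left/right/both")


# ----------------------------------------------------------------------
# Pattern table


def _stationary_pattern(angle: str) -> np.ndarray:
    """Bars every 4th diagonal/row/column, versioned pattern-table v1."""
    rows, cols = np.mgrid[0:N_ROWS, 0:N_COLS]
    if angle == "0":           # horizontal bars
        return (rows % 4 == 0).astype(np.uint8)
    if angle == "90":          # vertical bars
        return (cols % 4 == 0).astype(np.uint8)
    if angle == "45left":      # diagonals rising to the left
        return ((rows + cols) % 4 == 0).astype(np.uint8)
    if angle == "45right":     # diagonals rising to the right
        return ((rows - cols) % 4 == 0).astype(np.uint8)
    raise ConfigError(f"unknown angle {angle!r}")


def pattern_table() -> dict[str, np.ndarray]:
    """All stationary patterns keyed by name."""
    table = {"full_panel": np.ones((N_ROWS, N_COLS), dtype=np.uint8)}
    for angle in ANGLES:
        table[f"bars_{angle}"] = _stationary_pattern(angle)
    return table


def save_pattern_table(path: str | Path) -> None:
    """Write the pattern table as plain-text matrix definitions."""
    lines = [f"# lickrig pattern table v{PATTERN_TABLE_VERSION}"]
    for name, mat in pattern_table().items():
        lines.append(f"[{name}]")
        lines.extend("".join(str(v) for v in row) for row in mat)
    Path(path).write_text("\n".join(lines) + "\n")


def load_pattern_table(path: str | Path) -> dict[str, np.ndarray]:
    table: dict[str, np.ndarray] = {}
    name, rows = None, []
    def flush():
        if name is not None:
            table[name] = np.array(rows, dtype=np.uint8)
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            flush()
            name, rows = line.strip("[]"), []
        else:
            rows.append([int(c) for c in line])
    flush()
    return table


# ----------------------------------------------------------------------
# Rendering


def render_frame(stimulus: VisualStimulus, t: float) -> np.ndarray:
    """Render the 9x16 binary frame of ``stimulus`` at time ``t``.

    Pure function of (stimulus, t).  The moving bar advances one pixel
    column per frame period and wraps; stationary patterns are
    time-invariant unless gated by ``flash_frequency`` (on for the first
    half of each flash cycle).
    """
    if not 0.0 <= t < stimulus.duration:
        raise ValueError(
            f"t={t} outside stimulus duration [0, {stimulus.duration})")
    if stimulus.flash_frequency:
        phase = (t * stimulus.flash_frequency) % 1.0
        if phase >= 0.5:
            return np.zeros((N_ROWS, N_COLS), dtype=np.uint8)
    if stimulus.style == "full_panel":
        return np.ones((N_ROWS, N_COLS), dtype=np.uint8)
    if stimulus.style == "stationary_bars":
        return _stationary_pattern(stimulus.angle)
    # moving bar
    frame = np.zeros((N_ROWS, N_COLS), dtype=np.uint8)
    pos = int(t / stimulus.frame_period) % N_COLS
    for w in range(stimulus.bar_width):
        frame[:, (pos + w) % N_COLS] = 1
    return frame


# ----------------------------------------------------------------------
# Tone synthesis


def tone_samples(stimulus: AuditoryStimulus, sample_rate: float,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Synthesize the stimulus waveform at ``sample_rate``.

    Tones run through the 32-point sine lookup table with a fractional phase
    accumulator and linear interpolation between table entries, yielding
    near-pure sines.  White noise returns uniform samples in [-1, 1].
    """
    if sample_rate <= 0:
        raise ConfigError("sample_rate must be > 0")
    n = int(round(stimulus.duration * sample_rate))
    if stimulus.pitch == "noise":
        rng = rng if rng is not None else np.random.default_rng(0)
        return rng.uniform(-1.0, 1.0, n)
    pitch = float(stimulus.pitch)
    if sample_rate <= 2 * pitch:
        raise ConfigError(
            f"sample rate {sample_rate} Hz violates Nyquist for "
            f"{pitch} Hz tone")
    # phase accumulator in table units
    phase = (np.arange(n) * pitch * _LOOKUP_POINTS / sample_rate) % _LOOKUP_POINTS
    idx = phase.astype(int)
    frac = phase - idx
    nxt = (idx + 1) % _LOOKUP_POINTS
    return (1.0 - frac) * _SINE_TABLE[idx] + frac * _SINE_TABLE[nxt]


def spectral_purity(wave: np.ndarray, sample_rate: float, pitch: float,
                    tolerance: float = 0.02) -> float:
    """Fraction of total spectral power within +/- ``tolerance`` (relative)
    of the nominal pitch; diagnostic for the lookup-table synthesis."""
    spectrum = np.abs(np.fft.rfft(wave)) ** 2
    freqs = np.fft.rfftfreq(len(wave), d=1.0 / sample_rate)
    band = np.abs(freqs - pitch) <= tolerance * pitch
    total = spectrum.sum()
    return float(spectrum[band].sum() / total) if total > 0 else 0.0


# ----------------------------------------------------------------------
# Column position <-> DAQ signal level


def column_to_signal_level(column_position: int) -> float:
    """Encode the LED crescent column (0-8) as a normalized output level.

    Nine equally spaced levels on (0, 1]: column c -> (c + 1) / 9.  Strictly
    increasing and invertible; level 0 is reserved for 'no stimulus'.
    """
    if not 0 <= column_position <= N_COLUMNS - 1:
        raise ValueError(f"column {column_position} outside [0, 8]")
    return (column_position + 1) / N_COLUMNS


def signal_level_to_column(level: float) -> int:
    """Invert :func:`column_to_signal_level`."""
    col = int(round(level * N_COLUMNS - 1))
    if not 0 <= col <= N_COLUMNS - 1:
        raise ValueError(f"level {level} does not decode to a column")
    return col
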