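"""Virtual subject: a stochastic agent that turns trial stimuli into lick
trains.

This is a test harness, not a claim about animal behavior: choices follow a
4-parameter logistic psychometric function, Go/NoGo responses follow fixed
(optionally delay-decayed) lick probabilities, and licking is a Poisson-like
burst at ~10 Hz after a log-normal reaction time.  Its purpose is to make
the whole engine testable end to end (parameter recovery, d-prime recovery).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import ConfigError

LEFT = "left"
RIGHT = "right"


def psychometric(x: float | np.ndarray, alpha: float, beta: float,
                 guess: float, lapse: float) -> float | np.ndarray:
    """4-parameter logistic probability of a rightward choice:

        psi(x) = g + (1 - g - l) / (1 + exp(-(x - alpha) / beta))

    alpha is the curve location (choice-distribution mean), beta the
    discrimination sensitivity, g and l the guess and lapse rates.
    """
    from scipy.special import expit  # overflow-safe logistic

    return guess + (1.0 - guess - lapse) * expit((x - alpha) / beta)


@dataclass
class SubjectParams:
    """Psychometric and licking parameters of the virtual subject."""

    alpha: float = 4.0
    beta: float = 1.0
    guess: float = 0.05
    lapse: float = 0.05
    lick_rate_hz: float = 10.0
    reaction_time_median_s: float = 0.3
    reaction_time_sigma: float = 0.35
    engagement: float = 1.0
    # GNG generative lick probabilities
    p_lick_go: float = 0.9
    p_lick_nogo: float = 0.1
    # optional exponential decay of the go/nogo rate separation with delay;
    # 0 disables the decay
    delay_decay_tau_s: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.guess <= 0.5 and 0.0 <= self.lapse <= 0.5):
            raise ConfigError("guess and lapse rates must be in [0, 0.5]")
        if self.guess + self.lapse >= 1.0:
            raise ConfigError("guess + lapse must be < 1")
        if self.beta <= 0:
            raise ConfigError("beta must be > 0")
        if self.lick_rate_hz <= 0:
            raise ConfigError("lick_rate_hz must be > 0")
        if not 0.0 <= self.engagement <= 1.0:
            raise ConfigError("engagement must be in [0, 1]")

    # flat key=value persistence, loadable by the CLI --subject option ----

    def save(self, path: str | Path) -> None:
        lines = [f"{k}={v}" for k, v in sorted(vars(self).items())]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SubjectParams":
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kwargs[key.strip()] = float(value.strip())
        return cls(**kwargs)


@dataclass(frozen=True)
class LickTrain:
    spout: str  # {"left", "center", "right"}
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("lick times must be strictly increasing")


def choose_side(stimulus_x: float, params: SubjectParams,
                rng: np.random.Generator) -> str:
    """Right with probability psi(stimulus_x), left otherwise."""
    p_right = psychometric(stimulus_x, params.alpha, params.beta,
                           params.guess, params.lapse)
    return RIGHT if rng.random() < p_right else LEFT


def gng_lick_probabilities(params: SubjectParams,
                           delay: float = 0.0) -> tuple[float, float]:
    """(p_lick_go, p_lick_nogo), with the rate separation optionally shrunk
    exponentially toward the common mean as the delay grows."""
    p_go, p_nogo = params.p_lick_go, params.p_lick_nogo
    if params.delay_decay_tau_s > 0:
        mid = 0.5 * (p_go + p_nogo)
        sep = (p_go - p_nogo) * math.exp(-delay / params.delay_decay_tau_s)
        p_go, p_nogo = mid + sep / 2.0, mid - sep / 2.0
    return p_go, p_nogo


def sample_reaction_time(params: SubjectParams,
                         rng: np.random.Generator) -> float:
    """Log-normal reaction time with the configured median."""
    mu = math.log(params.reaction_time_median_s)
    return float(rng.lognormal(mean=mu, sigma=params.reaction_time_sigma))


def respond_gng(trial_kind: str, delay: float, params: SubjectParams,
                rng: np.random.Generator) -> tuple[bool, float | None]:
    """Decide whether to lick on a go/nogo trial; returns (lick, latency).

    Lick probability is the stimulus-dependent base rate (optionally
    delay-decayed), scaled by engagement.  Latency is a fresh reaction-time
    sample when the subject licks.
    """
    if delay < 0:
        raise ConfigError("delay must be >= 0")
    p_go, p_nogo = gng_lick_probabilities(params, delay)
    p = p_go if trial_kind == "go" else p_nogo
    p *= params.engagement
    if rng.random() < p:
        return True, sample_reaction_time(params, rng)
    return False, None


def generate_licks(side: str, window: tuple[float, float],
                   params: SubjectParams, rng: np.random.Generator,
                   reaction_time: float | None = None) -> LickTrain:
    """Reaction-time-shifted Poisson burst at ``lick_rate_hz`` on ``side``,
    clipped to ``window``.  The first lick lands at window start + reaction
    time; subsequent inter-lick intervals are exponential."""
    t0, t1 = window
    if t1 <= t0:
        raise ConfigError("window length must be > 0")
    rt = (sample_reaction_time(params, rng)
          if reaction_time is None else reaction_time)
    times: list[float] = []
    t = t0 + rt
    while t < t1:
        times.append(t)
        t += float(rng.exponential(1.0 / params.lick_rate_hz))
    return LickTrain(spout=side, times=tuple(times))
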