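"""Trial sequencing: delay tables, sampling pools, side/Go-NoGo selection
with run-length constraints, intertrial intervals and training/novel mixes.

All randomness flows from one session-level seed through named sub-streams
(see :func:`substreams`) so every component is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Hashable, Sequence

import numpy as np

from .config import ConfigError

LEFT = "left"
RIGHT = "right"
GO = "go"
NOGO = "nogo"

#: default sub-stream names, in spawn order (order is part of the contract:
#: changing it changes every stream).
STREAM_NAMES = ("sides", "delays", "itis", "subject", "mix", "stimuli")


def substreams(seed: int,
               names: Sequence[str] = STREAM_NAMES,
               ) -> dict[str, np.random.Generator]:
    """Spawn one independent, reproducible generator per named stream."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ----------------------------------------------------------------------
# Delay tables


@dataclass(frozen=True)
class DelayTable:
    """An evenly spaced inclusive grid of delays defined by the three
    (minimum, maximum, steps) boxes."""

    minimum: float
    maximum: float
    steps: int
    values: tuple[float, ...]

    def __len__(self) -> int:
        return self.steps


def build_delay_table(minimum: float, maximum: float, steps: int) -> DelayTable:
    """Build the delay grid for the (minimum, maximum, steps) boxes.

    ``steps == 1`` yields ``[minimum]`` regardless of maximum — the
    single-delay idiom (1, 1, 1).  Otherwise values are evenly spaced from
    minimum to maximum inclusive: (1, 6, 6) -> 1, 2, 3, 4, 5, 6 s.
    """
    if steps < 1:
        raise ConfigError(f"steps must be >= 1, got {steps}")
    if maximum < minimum:
        raise ConfigError(f"maximum {maximum} < minimum {minimum}")
    if steps == 1:
        values = (float(minimum),)
    else:
        values = tuple(np.linspace(minimum, maximum, steps).tolist())
    return DelayTable(float(minimum), float(maximum), int(steps), values)


# ----------------------------------------------------------------------
# Without-replacement sampling


class SamplingPool:
    """Draw items randomly without replacement; when the pool is depleted it
    is reshuffled and drawn again, ensuring equal sampling of all items."""

    def __init__(self, items: Sequence[Hashable]):
        if len(items) == 0:
            raise ConfigError("SamplingPool requires at least one item")
        self.items = list(items)
        self._remaining: list[Hashable] = []

    @property
    def remaining(self) -> list[Hashable]:
        return list(self._remaining)

    def draw(self, rng: np.random.Generator) -> Hashable:
        if not self._remaining:
            self._remaining = list(self.items)
            rng.shuffle(self._remaining)
        return self._remaining.pop()


# ----------------------------------------------------------------------
# 2AFC side selection with consecutive-trial constraints


@dataclass
class TrialSideHistory:
    """Ordered record of presented sides, with the two run-structure rules:
    no side more than three times in a row, and no more than four
    back-and-forth switches in a row."""

    sides: list[str] = field(default_factory=list)

    def append(self, side: str) -> None:
        self.sides.append(side)

    def trailing_run(self) -> int:
        """Length of the identical-side run at the end of the history."""
        if not self.sides:
            return 0
        last = self.sides[-1]
        n = 0
        for s in reversed(self.sides):
            if s != last:
                break
            n += 1
        return n

    def trailing_switches(self) -> int:
        """Number of consecutive side switches at the end of the history
        (an alternating run of k+1 trials ends in k switches)."""
        n = 0
        for a, b in zip(reversed(self.sides[:-1]), reversed(self.sides)):
            if a == b:
                break
            n += 1
        return n


def _other(side: str) -> str:
    return LEFT if side == RIGHT else RIGHT


def next_trial_side(history: TrialSideHistory, p_right: float,
                    constraints_on: bool, rng: np.random.Generator) -> str:
    """Draw the next 2AFC side.

    The raw draw is Bernoulli(p_right).  With constraints on, a draw that
    would create a fourth identical trial in a row, or a fifth consecutive
    switch, is forced to the opposite side.  The two rules can never forbid
    both sides at once: a long same-side run ends in zero trailing switches
    and a long switch streak ends in a run of one.
    """
    if not 0.0 <= p_right <= 1.0:
        raise ConfigError(f"p_right must be in [0, 1], got {p_right}")
    draw = RIGHT if rng.random() < p_right else LEFT
    if not constraints_on:
        return draw
    if history.sides:
        last = history.sides[-1]
        if draw == last and history.trailing_run() >= 3:
            return _other(draw)
        if draw != last and history.trailing_switches() >= 4:
            return last
    return draw


def next_trial_gng(p_go: float, cr_rule_on: bool, previous_outcome: str | None,
                   rng: np.random.Generator) -> str:
    """Pick the next GNG trial kind.

    A correct rejection is followed by a Go trial when the CR rule is on;
    otherwise the kind is Bernoulli(p_go) over {go, nogo}.
    """
    if not 0.0 <= p_go <= 1.0:
        raise ConfigError(f"p_go must be in [0, 1], got {p_go}")
    if cr_rule_on and previous_outcome == "correct_rejection":
        return GO
    return GO if rng.random() < p_go else NOGO


# ----------------------------------------------------------------------
# Intertrial intervals


def sample_iti(minimum: float, maximum: float, rng: np.random.Generator,
               rate: float | None = None) -> float:
    """Sample an ITI as minimum + E, with E exponential truncated at
    (maximum - minimum) via inverse-CDF.

    The rate defaults to 3/(maximum-minimum), i.e. the untruncated mean is a
    third of the window so ~95% of the untruncated mass lies inside it.
    """
    if minimum < 0 or maximum < minimum:
        raise ConfigError(f"bad ITI range [{minimum}, {maximum}]")
    span = maximum - minimum
    if span == 0.0:
        return float(minimum)
    scale = 1.0 / rate if rate and rate > 0 else span / 3.0
    u = rng.random()
    # inverse CDF of the exponential truncated to [0, span]
    e = -scale * np.log1p(-u * (1.0 - np.exp(-span / scale)))
    return float(minimum + e)


def truncated_exponential_cdf(x: np.ndarray, minimum: float, maximum: float,
                              rate: float | None = None) -> np.ndarray:
    """CDF of the ITI distribution, for goodness-of-fit checks."""
    span = maximum - minimum
    scale = 1.0 / rate if rate and rate > 0 else span / 3.0
    e = np.clip(np.asarray(x, dtype=float) - minimum, 0.0, span)
    return (1.0 - np.exp(-e / scale)) / (1.0 - np.exp(-span / scale))


# ----------------------------------------------------------------------
# Training / novel stimulus mixing


@dataclass(frozen=True)
class MixedTrial:
    stimulus: Any
    training: bool
    #: retrials and punishments apply only to training trials
    punishable: bool


@dataclass
class TrialMix:
    """Training/test composition of a psychometric-testing session (e.g.
    70% training stimuli, 30% novel stimuli)."""

    fraction_training: float
    training_stimuli: Sequence[Any]
    novel_stimuli: Sequence[Any]

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_training <= 1.0:
            raise ConfigError("fraction_training must be in [0, 1]")
        if self.fraction_training > 0 and not self.training_stimuli:
            raise ConfigError("training stimulus set is empty")
        if self.fraction_training < 1 and not self.novel_stimuli:
            raise ConfigError("novel stimulus set is empty")

    @property
    def fraction_test(self) -> float:
        return 1.0 - self.fraction_training


def mix_trials(mix: TrialMix, n: int, rng: np.random.Generator,
               exact: bool = False) -> list[MixedTrial]:
    """Assign each of ``n`` trials a training or novel stimulus.

    Per-trial Bernoulli(fraction_training) by default; ``exact=True``
    enforces the mix exactly per session (rounded) and shuffles the order.
    Stimulus identities are drawn through :class:`SamplingPool` so every
    stimulus in a set is sampled equally often.  Only training trials are
    flagged punishable/retriable.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if exact:
        n_train = int(round(mix.fraction_training * n))
        flags = np.array([True] * n_train + [False] * (n - n_train))
        rng.shuffle(flags)
    else:
        flags = rng.random(n) < mix.fraction_training
    train_pool = SamplingPool(mix.training_stimuli) if mix.training_stimuli else None
    novel_pool = SamplingPool(mix.novel_stimuli) if mix.novel_stimuli else None
    out = []
    for is_training in flags:
        pool = train_pool if is_training else novel_pool
        assert pool is not None
        out.append(MixedTrial(stimulus=pool.draw(rng),
                              training=bool(is_training),
                              punishable=bool(is_training)))
    return out
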