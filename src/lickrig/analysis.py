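"""Behavioral statistics over parsed session logs: psychometric curve
construction and 4-parameter maximum-likelihood fitting, d-prime, learning
curves, stage-advancement criteria, and lick rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .engine import CORRECT_LABELS, SessionResult, TrialRecord
from .session_io import debounce_licks
from .subject import psychometric

N_COLUMNS = 9

GO_LABELS = frozenset({"hit", "miss"})
NOGO_LABELS = frozenset({"false_alarm", "correct_rejection"})


# ----------------------------------------------------------------------
# Types


@dataclass(frozen=True)
class PsychometricParams:
    alpha: float  # curve location, stimulus-column units
    beta: float   # slope / discrimination sensitivity
    guess: float
    lapse: float

    def predict(self, x):
        return psychometric(np.asarray(x, dtype=float), self.alpha,
                            self.beta, self.guess, self.lapse)


@dataclass(frozen=True)
class FitResult:
    params: PsychometricParams
    nll: float
    converged: bool
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class RateStats:
    hits: int = 0
    misses: int = 0
    false_alarms: int = 0
    correct_rejections: int = 0

    @property
    def n_go(self) -> int:
        return self.hits + self.misses

    @property
    def n_nogo(self) -> int:
        return self.false_alarms + self.correct_rejections

    @property
    def H(self) -> float:
        return self.hits / self.n_go

    @property
    def FA(self) -> float:
        return self.false_alarms / self.n_nogo


@dataclass(frozen=True)
class DPrimeResult:
    value: float | None
    reason: str | None = None


@dataclass(frozen=True)
class SessionSummary:
    session_index: int
    percent_correct: float
    d_prime: float | None = None
    percent_right_by_column: tuple[float, ...] | None = None


# ----------------------------------------------------------------------
# Trial filtering


def responded_trials(trials: Iterable[TrialRecord],
                     include_retrials: bool = False) -> list[TrialRecord]:
    """Trials entering performance denominators.

    No-response trials are always excluded.  Trials that entered the
    retrial loop (``outcome.retries > 0``) are training scaffolding and are
    excluded by default; ``include_retrials=True`` keeps them, scored by
    their first-attempt classification.
    """
    out = []
    for t in trials:
        if t.outcome.label == "no_response":
            continue
        if not include_retrials and t.outcome.retries > 0:
            continue
        out.append(t)
    return out


def percent_correct(trials: Sequence[TrialRecord],
                    include_retrials: bool = False) -> float:
    """100 x correct / responded trials."""
    kept = responded_trials(trials, include_retrials)
    if not kept:
        return float("nan")
    n_correct = sum(t.outcome.correct for t in kept)
    return 100.0 * n_correct / len(kept)


# ----------------------------------------------------------------------
# Psychometric curve


def percent_right_by_column(trials: Iterable[TrialRecord],
                            n_columns: int = N_COLUMNS,
                            include_retrials: bool = False) -> np.ndarray:
    """Fraction of right-side choices per stimulus column 0-8 (as
    percentages); columns with no responded trials are NaN."""
    n_right = np.zeros(n_columns)
    n_total = np.zeros(n_columns)
    for t in responded_trials(trials, include_retrials):
        col = t.spec.stimulus
        if not isinstance(col, (int, np.integer)) or not 0 <= col < n_columns:
            continue
        if t.outcome.chosen not in ("left", "right"):
            continue
        n_total[col] += 1
        n_right[col] += t.outcome.chosen == "right"
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * n_right / n_total
    out[n_total == 0] = np.nan
    return out


def column_counts(trials: Iterable[TrialRecord],
                  n_columns: int = N_COLUMNS,
                  include_retrials: bool = False,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(n_right, n_total) per column, the input shape for fitting."""
    n_right = np.zeros(n_columns, dtype=int)
    n_total = np.zeros(n_columns, dtype=int)
    for t in responded_trials(trials, include_retrials):
        col = t.spec.stimulus
        if not isinstance(col, (int, np.integer)) or not 0 <= col < n_columns:
            continue
        if t.outcome.chosen not in ("left", "right"):
            continue
        n_total[col] += 1
        n_right[col] += t.outcome.chosen == "right"
    return n_right, n_total


def fit_psychometric(n_right: Sequence[float], n_total: Sequence[float],
                     x: Sequence[float] | None = None) -> FitResult:
    """Binomial maximum-likelihood fit of the 4-parameter logistic.

    Parameters are bounded (g, l in [0, 0.5], beta > 0) and the optimizer
    is restarted from a deterministic grid; the best start wins.  Degenerate
    data raise warning flags instead of errors: near-flat data flag
    ``alpha_unidentifiable``, parameters pinned at their bounds flag
    ``boundary_fit``.
    """
    n_right = np.asarray(n_right, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    if x is None:
        x = np.arange(len(n_total), dtype=float)
    x = np.asarray(x, dtype=float)
    mask = n_total > 0
    if mask.sum() < 4:
        raise ValueError("need at least 4 columns with data")
    x, k, n = x[mask], n_right[mask], n_total[mask]

    def nll(theta: np.ndarray) -> float:
        alpha, beta, g, l = theta
        p = np.clip(psychometric(x, alpha, beta, g, l), 1e-9, 1 - 1e-9)
        return float(-(k * np.log(p) + (n - k) * np.log(1 - p)).sum())

    lo, hi = x.min(), x.max()
    span = max(hi - lo, 1.0)
    bounds = [(lo - span, hi + span), (1e-3, 10.0 * span), (0.0, 0.5),
              (0.0, 0.5)]
    starts = [np.array([a, b, 0.05, 0.05])
              for a in (lo + 0.25 * span, (lo + hi) / 2, hi - 0.25 * span)
              for b in (0.1 * span, 0.3 * span, span)]
    best = None
    for theta0 in starts:
        res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta, g, l = best.x
    flags: list[str] = []
    rates = k / n
    if rates.max() - rates.min() < 0.1:
        flags.append("alpha_unidentifiable")
    eps = 1e-6
    if (g > 0.5 - eps or l > 0.5 - eps or beta < bounds[1][0] + eps
            or beta > bounds[1][1] - eps or alpha < bounds[0][0] + eps
            or alpha > bounds[0][1] - eps):
        flags.append("boundary_fit")
    params = PsychometricParams(float(alpha), float(beta), float(g), float(l))
    return FitResult(params, float(best.fun), bool(best.success),
                     tuple(flags))


# ----------------------------------------------------------------------
# Signal detection


def clip_rate(rate: float, n: int) -> float:
    """Log-linear correction: rates clipped to [1/(2N), 1 - 1/(2N)]."""
    lo = 1.0 / (2.0 * n)
    return min(max(rate, lo), 1.0 - lo)


def dprime(rate_stats: RateStats, clip: bool = True) -> DPrimeResult:
    """Discriminability index d' = z(H) - z(FA).

    Rates are clipped away from 0/1 per class before z-scoring so extreme
    sessions stay finite.  Positive when the hit rate exceeds the
    false-alarm rate.  Returns an absent value (with the reason) when a
    trial class is empty.
    """
    if rate_stats.n_go == 0:
        return DPrimeResult(None, "no go trials")
    if rate_stats.n_nogo == 0:
        return DPrimeResult(None, "no nogo trials")
    H, FA = rate_stats.H, rate_stats.FA
    if clip:
        H = clip_rate(H, rate_stats.n_go)
        FA = clip_rate(FA, rate_stats.n_nogo)
    elif H in (0.0, 1.0) or FA in (0.0, 1.0):
        return DPrimeResult(None, "rate at 0 or 1 without clipping")
    value = float(stats.norm.ppf(H) - stats.norm.ppf(FA))
    return DPrimeResult(value)


def rate_stats_from_trials(trials: Iterable[TrialRecord]) -> RateStats:
    counts = {"hit": 0, "miss": 0, "false_alarm": 0, "correct_rejection": 0}
    for t in trials:
        if t.outcome.label in counts:
            counts[t.outcome.label] += 1
    return RateStats(hits=counts["hit"], misses=counts["miss"],
                     false_alarms=counts["false_alarm"],
                     correct_rejections=counts["correct_rejection"])


def dprime_by_delay(trials: Iterable[TrialRecord], clip: bool = True,
                    shared_fa: bool = False) -> dict[float, DPrimeResult]:
    """d' per delay bin.  With ``shared_fa`` the false-alarm rate is pooled
    across all delays; otherwise each bin uses its own nogo trials."""
    bins: dict[float, list[TrialRecord]] = {}
    for t in trials:
        if t.outcome.label in GO_LABELS | NOGO_LABELS:
            bins.setdefault(t.spec.post_stim_delay, []).append(t)
    pooled = rate_stats_from_trials(
        [t for ts in bins.values() for t in ts])
    out = {}
    for delay, ts in sorted(bins.items()):
        rs = rate_stats_from_trials(ts)
        if shared_fa:
            rs = RateStats(hits=rs.hits, misses=rs.misses,
                           false_alarms=pooled.false_alarms,
                           correct_rejections=pooled.correct_rejections)
        out[delay] = dprime(rs, clip)
    return out


# ----------------------------------------------------------------------
# Session summaries, learning curves, advancement


def summarize_session(result: SessionResult, session_index: int = 1,
                      include_retrials: bool = False) -> SessionSummary:
    trials = result.trials
    pc = percent_correct(trials, include_retrials)
    dp = None
    if result.task == "gng":
        dp = dprime(rate_stats_from_trials(trials)).value
    cols = None
    if result.task == "2afc":
        cols = tuple(percent_right_by_column(
            trials, include_retrials=include_retrials).tolist())
    return SessionSummary(session_index, pc, dp, cols)


def learning_curve(summaries: Sequence[SessionSummary] |
                   Sequence[Sequence[SessionSummary]],
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percent correct against session number.

    Accepts one subject's summaries or a list of per-subject lists (of
    possibly different lengths); returns (session numbers, group mean over
    subjects with data at each session, per-subject matrix with NaN
    padding).
    """
    if not summaries:
        raise ValueError("need at least one session")
    if isinstance(summaries[0], SessionSummary):
        subjects = [list(summaries)]
    else:
        subjects = [list(s) for s in summaries]
    n_sessions = max(len(s) for s in subjects)
    mat = np.full((len(subjects), n_sessions), np.nan)
    for i, subject_sessions in enumerate(subjects):
        for j, summary in enumerate(subject_sessions):
            mat[i, j] = summary.percent_correct
    sessions = np.arange(1, n_sessions + 1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=0)
    return sessions, mean, mat


def advancement_criterion(summaries: Sequence[SessionSummary],
                          task: str) -> bool:
    """Stage-advancement rule: stable performance over 3 consecutive days —
    all three sessions >= 75% correct (2AFC) or d' > 1.5 (GNG)."""
    if len(summaries) != 3:
        raise ValueError("advancement requires exactly 3 consecutive "
                         "session summaries")
    if task == "2afc":
        return all(s.percent_correct >= 75.0 for s in summaries)
    if task == "gng":
        return all(s.d_prime is not None and s.d_prime > 1.5
                   for s in summaries)
    raise ValueError(f"unknown task {task!r}")


# ----------------------------------------------------------------------
# Lick raster


@dataclass(frozen=True)
class LickRaster:
    trials: list[np.ndarray] = field(default_factory=list)
    bin_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    rate_hz: np.ndarray = field(default_factory=lambda: np.array([]))


_LICK_CHANNELS = ("center_lick", "left_lick", "right_lick")


def lick_raster(result: SessionResult, align_to: str = "stimulus_on",
                window: tuple[float, float] = (-1.0, 3.0),
                bin_width: float = 0.1) -> LickRaster:
    """Per-trial lick times aligned to an event, after debouncing, plus a
    summary lick-rate histogram.  Trials missing the alignment event are
    skipped with a warning."""
    import warnings

    aligned: list[np.ndarray] = []
    for rec in result.trials:
        t0, t1 = rec.t_start, rec.t_end
        trial_events = [e for e in result.events if t0 <= e.time < t1]
        anchor = None
        for e in trial_events:
            if align_to == "stimulus_on" and e.channel == "stimulus" \
                    and e.payload.get("on"):
                anchor = e.time
                break
            if e.channel == "state" and e.payload.get("phase") == align_to:
                anchor = e.time
                break
        if anchor is None:
            warnings.warn(
                f"trial {rec.spec.index}: no {align_to!r} event; skipped")
            continue
        licks = sorted(e.time for e in trial_events
                       if e.channel in _LICK_CHANNELS)
        rel = np.asarray(debounce_licks(licks)) - anchor
        aligned.append(rel[(rel >= window[0]) & (rel <= window[1])])
    edges = np.arange(window[0], window[1] + bin_width / 2, bin_width)
    if aligned:
        counts = np.histogram(np.concatenate(aligned), bins=edges)[0]
        rate = counts / (len(aligned) * bin_width)
    else:
        rate = np.zeros(len(edges) - 1)
    return LickRaster(trials=aligned, bin_edges=edges, rate_hz=rate)
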