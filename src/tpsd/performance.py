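"""Trial scoring and signal-detection performance for the TPSD task.

Trials are scored Hit / Miss / CR / FA by whether the lick count inside the
response window reaches the response criterion (default: one lick).  The
discriminability index is

    d' = Phi^-1(hit fraction) - Phi^-1(false-alarm fraction)

with a rate that reaches exactly 100% or 0% replaced by 99% or 1% to avoid
infinite z-scores; intermediate rates are never altered.  Session-level
performance is the maximum clamped d' over a sliding 150-trial window
(earliest window on ties), which is also the trial subset used downstream by
the lick-profile and decoding analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .records import SessionRecord, TrialRecord
from .task import SessionConfig

__all__ = [
    "OutcomeRates",
    "PerformanceSummary",
    "LickThreshold",
    "classify_trial",
    "score_session",
    "outcome_rates",
    "dprime",
    "best_window_dprime",
    "best_window_trials",
    "sessions_to_threshold",
    "lick_threshold_from_pretrial",
    "session_performance_frame",
]

#: Extreme rates (exactly 0 or 1) are clamped to [RATE_CLAMP_LO, RATE_CLAMP_HI].
RATE_CLAMP_LO = 0.01
RATE_CLAMP_HI = 0.99
#: Sliding-window length used for session-level d'.
BEST_WINDOW_TRIALS = 150


@dataclass(frozen=True)
class OutcomeRates:
    """Outcome fractions within a trial set; hit+miss = 1 and cr+fa = 1."""

    hit_rate: float
    miss_rate: float
    cr_rate: float
    fa_rate: float
    n_preferred: int
    n_nonpreferred: int


@dataclass(frozen=True)
class PerformanceSummary:
    """Best-window d' for a session, with the window's outcome rates."""

    dprime: float
    window_start: int
    window_length: int
    rates: OutcomeRates
    session_dprime_full: float


@dataclass(frozen=True)
class LickThreshold:
    """Individualized lick criterion: pretrial mean lick count minus 1 SD."""

    threshold: float
    source_session: str


def classify_trial(
    trial: TrialRecord, config: SessionConfig, criterion: int = 1
) -> str:
    """Score one trial as Hit, Miss, CR, or FA.

    A trial counts as a response iff at least ``criterion`` licks fall in the
    half-open response window.
    """
    t = trial.lick_times
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("lick_times must be sorted strictly increasing")
    lo, hi = config.response_window
    respond = int(np.count_nonzero((t >= lo) & (t < hi))) >= criterion
    if trial.stimulus_type == "preferred":
        return "Hit" if respond else "Miss"
    return "FA" if respond else "CR"


def score_session(session: SessionRecord, criterion: int = 1) -> SessionRecord:
    """Score all trials in place (sets ``trial.outcome``); returns the session."""
    for trial in session.trials:
        trial.outcome = classify_trial(trial, session.config, criterion)
    return session


def outcome_rates(trials: list[TrialRecord]) -> OutcomeRates:
    """Outcome fractions over a scored trial list."""
    outcomes = [t.outcome for t in trials]
    if any(o is None for o in outcomes):
        raise ValueError("trials must be scored first (see score_session)")
    n_pref = sum(t.stimulus_type == "preferred" for t in trials)
    n_nonpref = len(trials) - n_pref
    n_hit = outcomes.count("Hit")
    n_fa = outcomes.count("FA")
    hit = n_hit / n_pref if n_pref else np.nan
    fa = n_fa / n_nonpref if n_nonpref else np.nan
    return OutcomeRates(
        hit_rate=hit,
        miss_rate=1.0 - hit if n_pref else np.nan,
        cr_rate=1.0 - fa if n_nonpref else np.nan,
        fa_rate=fa,
        n_preferred=n_pref,
        n_nonpreferred=n_nonpref,
    )


def _clamp_rate(p: float) -> float:
    if p == 0.0:
        return RATE_CLAMP_LO
    if p == 1.0:
        return RATE_CLAMP_HI
    return p


def dprime(hit_fraction: float, fa_fraction: float) -> float:
    """Clamped discriminability index Phi^-1(hit) - Phi^-1(fa).

    Rates of exactly 0 or 1 are replaced by 1% or 99%; intermediate rates
    enter unchanged.
    """
    for p in (hit_fraction, fa_fraction):
        if not 0.0 <= p <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    return float(norm.ppf(_clamp_rate(hit_fraction)) - norm.ppf(_clamp_rate(fa_fraction)))


def _session_arrays(trials: list[TrialRecord]) -> tuple[np.ndarray, np.ndarray]:
    pref = np.array([t.stimulus_type == "preferred" for t in trials])
    if any(t.outcome is None for t in trials):
        raise ValueError("trials must be scored first (see score_session)")
    respond = np.array([t.outcome in ("Hit", "FA") for t in trials])
    return pref, respond


def best_window_dprime(
    trials: list[TrialRecord],
    window: int = BEST_WINDOW_TRIALS,
    step: int = 1,
) -> PerformanceSummary:
    """Maximum clamped d' over sliding windows of ``window`` trials.

    Windows must contain both stimulus types; ties resolve to the earliest
    window.  Sessions shorter than ``window`` are evaluated as a single
    whole-session window.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    n = len(trials)
    if n == 0:
        raise ValueError("trials must be nonempty")
    pref, respond = _session_arrays(trials)
    if pref.all() or (~pref).all():
        raise ValueError("d' undefined: session contains a single stimulus type")

    # Prefix sums for O(1) per-window counts.
    cp = np.concatenate(([0], np.cumsum(pref)))
    ch = np.concatenate(([0], np.cumsum(pref & respond)))
    cn = np.concatenate(([0], np.cumsum(~pref)))
    cf = np.concatenate(([0], np.cumsum(~pref & respond)))

    full = dprime(
        (ch[n] / cp[n]) if cp[n] else np.nan,
        (cf[n] / cn[n]) if cn[n] else np.nan,
    )

    w = min(window, n)
    starts = np.arange(0, n - w + 1, step)
    n_pref_w = cp[starts + w] - cp[starts]
    n_non_w = cn[starts + w] - cn[starts]
    valid = (n_pref_w > 0) & (n_non_w > 0)
    best = None
    for s in starts[valid]:
        h = (ch[s + w] - ch[s]) / (cp[s + w] - cp[s])
        f = (cf[s + w] - cf[s]) / (cn[s + w] - cn[s])
        d = dprime(h, f)
        if best is None or d > best[0]:
            best = (d, int(s))
    d_best, s_best = best
    return PerformanceSummary(
        dprime=d_best,
        window_start=s_best + 1,
        window_length=w,
        rates=outcome_rates(trials[s_best : s_best + w]),
        session_dprime_full=full,
    )


def best_window_trials(
    trials: list[TrialRecord], window: int = BEST_WINDOW_TRIALS
) -> list[TrialRecord]:
    """The trial subset of the best sliding window (used by profiles/decoding)."""
    summary = best_window_dprime(trials, window=window)
    s = summary.window_start - 1
    return trials[s : s + summary.window_length]


def sessions_to_threshold(
    dprime_by_session: list[float], threshold: float
) -> int | None:
    """1-based index of the first session with d' strictly above threshold."""
    if len(dprime_by_session) == 0:
        raise ValueError("dprime_by_session must be nonempty")
    for i, d in enumerate(dprime_by_session, start=1):
        if d > threshold:
            return i
    return None


def lick_threshold_from_pretrial(pretrial: SessionRecord) -> LickThreshold:
    """Individualized lick threshold: mean response-window lick count in the
    last pretrial session minus one sample SD, floored at zero."""
    if len(pretrial.trials) < 2:
        raise ValueError("pretrial session must have >= 2 trials")
    lo, hi = pretrial.config.response_window
    counts = np.array(
        [np.count_nonzero((t.lick_times >= lo) & (t.lick_times < hi)) for t in pretrial.trials],
        dtype=float,
    )
    thr = max(0.0, float(counts.mean() - counts.std(ddof=1)))
    return LickThreshold(threshold=thr, source_session=f"{pretrial.mouse_id}/s{pretrial.session}")


def session_performance_frame(
    sessions: list[SessionRecord],
    criterion: int = 1,
    window: int = BEST_WINDOW_TRIALS,
) -> pd.DataFrame:
    """Per-session performance table across a cohort.

    Scores any unscored sessions, then reports best-window d', the window's
    outcome rates, and full-session d' — one row per mouse-session.
    Pretrial (single-stimulus) sessions are skipped: d' is undefined there.
    """
    rows = []
    for s in sessions:
        if not s.is_scored:
            score_session(s, criterion)
        types = {t.stimulus_type for t in s.trials}
        if len(types) < 2:
            continue
        perf = best_window_dprime(s.trials, window=window)
        rows.append(
            (
                s.mouse_id, s.genotype, s.session, perf.dprime, perf.window_start,
                perf.rates.hit_rate, perf.rates.miss_rate, perf.rates.cr_rate,
                perf.rates.fa_rate, perf.session_dprime_full,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mouse_id", "genotype", "session", "d_prime_best", "window_start",
            "hit_rate", "miss_rate", "cr_rate", "fa_rate", "d_prime_full",
        ],
    )
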