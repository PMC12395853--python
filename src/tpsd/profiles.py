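"""Time-resolved lick-probability profiles.

For each mouse, the per-bin probability is the fraction of trials with at
least one lick in that 0.1 s bin; group profiles average the mouse-level
vectors and carry a normal-approximation confidence band (mean +/- z * SEM,
truncated to [0, 1]).  Outcome-conditioned profiles restrict each session to
its best 150-trial window before stratifying by trial outcome, mirroring the
performance analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .performance import BEST_WINDOW_TRIALS, best_window_trials, score_session
from .records import SessionRecord, TrialRecord

__all__ = [
    "ProfileSeries",
    "bin_edges_for_epoch",
    "lick_probability_profile",
    "group_profile",
    "outcome_conditioned_profiles",
    "profile_frame",
]

DEFAULT_BIN_WIDTH_S = 0.1
DEFAULT_EPOCH = (0.0, 3.0)


@dataclass(frozen=True)
class ProfileSeries:
    """Group-level lick-probability profile with a confidence band."""

    bin_edges: np.ndarray
    per_mouse_probability: np.ndarray  # [mouse x bin]
    group_mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    stratum: str
    confidence: float

    @property
    def n_mice(self) -> int:
        return self.per_mouse_probability.shape[0]

    @property
    def bin_starts(self) -> np.ndarray:
        return self.bin_edges[:-1]


def bin_edges_for_epoch(
    epoch: tuple[float, float] = DEFAULT_EPOCH, bin_width: float = DEFAULT_BIN_WIDTH_S
) -> np.ndarray:
    """Uniform half-open bin edges tiling [epoch_start, epoch_start + n*width)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    lo, hi = epoch
    if hi <= lo:
        raise ValueError("epoch must be a nonempty interval")
    n_bins = int(round((hi - lo) / bin_width))
    n_bins = max(n_bins, 1)
    return lo + bin_width * np.arange(n_bins + 1)


def lick_probability_profile(
    trials: list[TrialRecord],
    bin_width: float = DEFAULT_BIN_WIDTH_S,
    epoch: tuple[float, float] = DEFAULT_EPOCH,
) -> np.ndarray:
    """Per-bin P(>=1 lick) across one mouse's trials.

    Licks outside the epoch are ignored.  Bins are half-open, so a lick at
    exactly 1.0 s falls in the [1.0, 1.1) bin.
    """
    if not trials:
        raise ValueError("trials must be nonempty")
    edges = bin_edges_for_epoch(epoch, bin_width)
    hits = np.zeros(edges.size - 1)
    for t in trials:
        counts, _ = np.histogram(t.lick_times, bins=edges)
        hits += counts > 0
    return hits / len(trials)


def group_profile(
    per_mouse: list[np.ndarray] | np.ndarray,
    bin_edges: np.ndarray,
    confidence: float = 0.95,
    stratum: str = "all",
) -> ProfileSeries:
    """Across-mouse mean profile with a z * SEM confidence band.

    The band is truncated to [0, 1]; ``confidence = 0`` degenerates to the
    mean itself.
    """
    mat = np.asarray(per_mouse, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need probability vectors from >= 2 mice")
    if mat.shape[1] != np.asarray(bin_edges).size - 1:
        raise ValueError("per-mouse vectors do not match the bin grid")
    if not 0.0 <= confidence < 1.0:
        raise ValueError("confidence must lie in [0, 1)")
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    z = norm.ppf(0.5 * (1.0 + confidence)) if confidence > 0 else 0.0
    return ProfileSeries(
        bin_edges=np.asarray(bin_edges, dtype=float),
        per_mouse_probability=mat,
        group_mean=mean,
        ci_low=np.clip(mean - z * sem, 0.0, 1.0),
        ci_high=np.clip(mean + z * sem, 0.0, 1.0),
        stratum=stratum,
        confidence=confidence,
    )


def outcome_conditioned_profiles(
    sessions: list[SessionRecord],
    outcomes: tuple[str, ...] | list[str],
    bin_width: float = DEFAULT_BIN_WIDTH_S,
    epoch: tuple[float, float] = DEFAULT_EPOCH,
    confidence: float = 0.95,
    use_best_window: bool = True,
    window: int = BEST_WINDOW_TRIALS,
) -> dict[str, ProfileSeries]:
    """Group profiles stratified by trial outcome, one session per mouse.

    Each session is restricted to its best 150-trial window (like the
    performance analysis) before filtering to the requested outcomes.  Mice
    with an empty stratum are excluded from that stratum's group mean with a
    warning.
    """
    results: dict[str, ProfileSeries] = {}
    for s in sessions:
        if not s.is_scored:
            score_session(s)
    edges = bin_edges_for_epoch(epoch, bin_width)
    for outcome in outcomes:
        vectors = []
        for s in sessions:
            trials = best_window_trials(s.trials, window=window) if use_best_window else s.trials
            subset = [t for t in trials if t.outcome == outcome]
            if not subset:
                warnings.warn(
                    f"mouse {s.mouse_id}: no {outcome} trials in stratum; excluded",
                    stacklevel=2,
                )
                continue
            vectors.append(lick_probability_profile(subset, bin_width, epoch))
        if len(vectors) >= 2:
            results[outcome] = group_profile(vectors, edges, confidence, stratum=outcome)
        else:
            warnings.warn(f"outcome {outcome}: fewer than 2 mice with data; skipped",
                          stacklevel=2)
    return results


def profile_frame(series: ProfileSeries) -> pd.DataFrame:
    """Tidy per-bin table: bin_start, mean, ci_low, ci_high, n_mice, stratum."""
    return pd.DataFrame(
        {
            "bin_start": series.bin_starts,
            "mean": series.group_mean,
            "ci_low": series.ci_low,
            "ci_high": series.ci_high,
            "n_mice": series.n_mice,
            "stratum": series.stratum,
        }
    )
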