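"""In-memory containers for lick-event data: trials, sessions, cohorts.

A trial holds trial-relative lick timestamps (seconds from stimulus onset);
a session holds the ordered trials of one mouse on one day plus metadata; a
cohort is simply a list of sessions.  Tidy-frame converters back the TSV
serialization in :mod:`tpsd.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import STIMULUS_TYPES, SessionConfig

__all__ = ["TrialRecord", "SessionRecord", "events_frame", "trials_frame"]

OUTCOMES = ("Hit", "Miss", "CR", "FA")


@dataclass
class TrialRecord:
    """One trial: stimulus type, sorted trial-relative lick times, outcome.

    ``outcome`` is None until the trial has been scored (see
    :func:`tpsd.performance.score_session`).
    """

    index: int
    stimulus_type: str
    lick_times: np.ndarray
    outcome: str | None = None

    def __post_init__(self) -> None:
        if self.stimulus_type not in STIMULUS_TYPES:
            raise ValueError(f"stimulus_type must be one of {STIMULUS_TYPES}")
        self.lick_times = np.asarray(self.lick_times, dtype=float)
        if self.lick_times.ndim != 1:
            raise ValueError("lick_times must be one-dimensional")
        if self.lick_times.size and np.any(np.diff(self.lick_times) <= 0):
            raise ValueError("lick_times must be strictly increasing")
        if self.lick_times.size and self.lick_times[0] < 0:
            raise ValueError("lick_times must be >= 0")

    @property
    def n_licks(self) -> int:
        return int(self.lick_times.size)


@dataclass
class SessionRecord:
    """Ordered trials of one mouse in one session, with session metadata."""

    mouse_id: str
    genotype: str
    session: int
    trials: list[TrialRecord]
    config: SessionConfig = field(default_factory=SessionConfig)

    def __post_init__(self) -> None:
        indices = [t.index for t in self.trials]
        if indices != list(range(1, len(self.trials) + 1)):
            raise ValueError("trial indices must be contiguous from 1")

    @property
    def phase(self) -> str:
        return self.config.phase

    @property
    def modality(self) -> str:
        return self.config.modality_condition

    def trials_of_type(self, stimulus_type: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.stimulus_type == stimulus_type]

    @property
    def is_scored(self) -> bool:
        return all(t.outcome is not None for t in self.trials)


def trials_frame(sessions: list[SessionRecord]) -> pd.DataFrame:
    """One row per trial (including zero-lick trials) across sessions."""
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                (s.mouse_id, s.genotype, s.session, s.phase, s.modality,
                 t.index, t.stimulus_type, t.n_licks)
            )
    return pd.DataFrame(
        rows,
        columns=["mouse_id", "genotype", "session", "phase", "modality",
                 "trial", "stimulus_type", "n_licks"],
    )


def events_frame(sessions: list[SessionRecord]) -> pd.DataFrame:
    """One row per lick event across sessions (tidy long format)."""
    rows = []
    for s in sessions:
        for t in s.trials:
            for lt in t.lick_times:
                rows.append(
                    (s.mouse_id, s.genotype, s.session, s.phase, s.modality,
                     t.index, t.stimulus_type, float(lt))
                )
    return pd.DataFrame(
        rows,
        columns=["mouse_id", "genotype", "session", "phase", "modality",
                 "trial", "stimulus_type", "lick_time_s"],
    )
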