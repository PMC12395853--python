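"""Task structure for the temporal-pattern sensory discrimination (TPSD) task.

The TPSD task is a go/no-go discrimination between two audio-visual temporal
patterns that differ only in pulse duration: a rewarded ("preferred") sequence
of four 200 ms pulses and an unrewarded ("nonpreferred") sequence of four
900 ms pulses, each pulse separated by a 200 ms gap.  This module encodes
stimulus patterns, session configuration (timing windows, trial-type ratios)
and randomized session schedules, plus schedule-level arithmetic such as total
stimulus exposure.

All trial-relative times are in seconds with t = 0 at stimulus onset, and all
intervals are half-open [a, b).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "STIMULUS_TYPES",
    "MODALITY_CONDITIONS",
    "StimulusPattern",
    "SessionConfig",
    "SessionSchedule",
    "preferred_pattern",
    "nonpreferred_pattern",
    "pattern_duration",
    "build_schedule",
    "total_stimulus_exposure",
    "write_schedule_tsv",
    "read_schedule_tsv",
]

STIMULUS_TYPES = ("preferred", "nonpreferred")
MODALITY_CONDITIONS = ("multimodal", "audio_only", "visual_only", "control_no_stimulus")
PHASES = ("pretrial", "main")


@dataclass(frozen=True)
class StimulusPattern:
    """A temporal pattern of ``n_pulses`` identical audio-visual pulses.

    Pulses of ``pulse_duration`` seconds are separated by gaps of
    ``gap_duration`` seconds; ``label`` marks the pattern as the rewarded
    ("preferred") or unrewarded ("nonpreferred") sequence.
    """

    n_pulses: int
    pulse_duration: float
    gap_duration: float
    label: str
    visual_on: bool = True
    audio_on: bool = True

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be > 0")
        if self.gap_duration < 0:
            raise ValueError("gap_duration must be >= 0")
        if not (self.visual_on or self.audio_on):
            raise ValueError("at least one of visual_on/audio_on must be set")
        if self.label not in STIMULUS_TYPES:
            raise ValueError(f"label must be one of {STIMULUS_TYPES}")

    @property
    def total_duration(self) -> float:
        """Total pattern duration: n*pulse + (n-1)*gap seconds."""
        return self.n_pulses * self.pulse_duration + (self.n_pulses - 1) * self.gap_duration


def preferred_pattern(visual_on: bool = True, audio_on: bool = True) -> StimulusPattern:
    """The rewarded pattern: 4 x 200 ms pulses with 200 ms gaps (1.4 s total)."""
    return StimulusPattern(4, 0.2, 0.2, "preferred", visual_on, audio_on)


def nonpreferred_pattern(visual_on: bool = True, audio_on: bool = True) -> StimulusPattern:
    """The unrewarded pattern: 4 x 900 ms pulses with 200 ms gaps (4.2 s total)."""
    return StimulusPattern(4, 0.9, 0.2, "nonpreferred", visual_on, audio_on)


def pattern_duration(pattern: StimulusPattern) -> float:
    """Total duration of a stimulus pattern in seconds."""
    return pattern.total_duration


@dataclass(frozen=True)
class SessionConfig:
    """Timing and composition parameters of one TPSD session.

    Defaults follow the standard task: reward dispensed at 1.2 s and available
    until 2 s, licking counted as a response within [1, 2) s, a 6.5-8 s
    timeout after errors, 4 s inter-trial interval, lick events sampled at
    250 Hz, and a 70:30 preferred:nonpreferred trial ratio on 350-trial main
    sessions.
    """

    n_trials: int = 350
    preferred_fraction: float = 0.7
    reward_time: float = 1.2
    reward_end: float = 2.0
    response_window: tuple[float, float] = (1.0, 2.0)
    timeout_range: tuple[float, float] = (6.5, 8.0)
    intertrial_interval: float = 4.0
    lick_sample_rate: float = 250.0
    modality_condition: str = "multimodal"
    phase: str = "main"

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        if self.phase == "pretrial":
            if self.preferred_fraction != 1.0:
                raise ValueError("pretrial sessions present only the preferred stimulus")
        elif not 0.0 < self.preferred_fraction < 1.0:
            raise ValueError("preferred_fraction must lie in (0, 1) for main sessions")
        if not self.reward_time < self.reward_end:
            raise ValueError("reward_time must precede reward_end")
        lo, hi = self.response_window
        if not (0.0 <= lo < hi <= self.reward_end):
            raise ValueError("response_window must be within [0, reward_end]")
        if self.modality_condition not in MODALITY_CONDITIONS:
            raise ValueError(f"modality_condition must be one of {MODALITY_CONDITIONS}")
        if self.lick_sample_rate <= 0:
            raise ValueError("lick_sample_rate must be > 0")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["response_window"] = list(self.response_window)
        data["timeout_range"] = list(self.timeout_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["response_window"] = tuple(data["response_window"])
        data["timeout_range"] = tuple(data["timeout_range"])
        return cls(**data)


def pretrial_config(n_trials: int = 150, **kwargs) -> SessionConfig:
    """A preferred-only pretrial session (150 trials on day 1, 250 after)."""
    return SessionConfig(n_trials=n_trials, preferred_fraction=1.0, phase="pretrial", **kwargs)


@dataclass(frozen=True)
class SessionSchedule:
    """A realized trial-type sequence for one session."""

    trial_types: tuple[str, ...]
    config: SessionConfig

    def __post_init__(self) -> None:
        if len(self.trial_types) != self.config.n_trials:
            raise ValueError("schedule length must equal config.n_trials")
        bad = set(self.trial_types) - set(STIMULUS_TYPES)
        if bad:
            raise ValueError(f"unknown stimulus types: {bad}")

    @property
    def n_preferred(self) -> int:
        return sum(t == "preferred" for t in self.trial_types)

    @property
    def n_nonpreferred(self) -> int:
        return len(self.trial_types) - self.n_preferred


def build_schedule(config: SessionConfig, seed: int | np.random.Generator) -> SessionSchedule:
    """Randomize a session's trial-type order at the configured ratio.

    The preferred-trial count is ``round(preferred_fraction * n_trials)``
    (exact for the task's 70:30 and 60:40 ratios on 250/350 trials); the order
    is a uniform seed-determined permutation.
    """
    rng = np.random.default_rng(seed)
    n = config.n_trials
    n_pref = int(round(config.preferred_fraction * n))
    types = np.array(["preferred"] * n_pref + ["nonpreferred"] * (n - n_pref), dtype=object)
    rng.shuffle(types)
    return SessionSchedule(tuple(types), config)


def total_stimulus_exposure(
    schedule: SessionSchedule,
    pref: StimulusPattern | None = None,
    nonpref: StimulusPattern | None = None,
) -> tuple[float, float]:
    """Total stimulus-on exposure (seconds) for each trial type in a session.

    With the standard patterns a 350-trial 60:40 session yields 294 s of
    preferred and 588 s of nonpreferred exposure.
    """
    pref = pref if pref is not None else preferred_pattern()
    nonpref = nonpref if nonpref is not None else nonpreferred_pattern()
    if pref.label != "preferred" or nonpref.label != "nonpreferred":
        raise ValueError("patterns must be labelled consistently with the schedule")
    return (
        schedule.n_preferred * pref.total_duration,
        schedule.n_nonpreferred * nonpref.total_duration,
    )


def _scheduled_onsets(schedule: SessionSchedule) -> np.ndarray:
    # Nominal onset offsets ignoring timeouts: each trial occupies
    # max(pattern duration, reward_end) followed by the inter-trial interval.
    cfg = schedule.config
    durations = {
        "preferred": max(preferred_pattern().total_duration, cfg.reward_end),
        "nonpreferred": max(nonpreferred_pattern().total_duration, cfg.reward_end),
    }
    block = np.array([durations[t] + cfg.intertrial_interval for t in schedule.trial_types])
    onsets = np.concatenate(([0.0], np.cumsum(block)[:-1]))
    return onsets


def write_schedule_tsv(schedule: SessionSchedule, path: str | Path) -> None:
    """Export a schedule as TSV (trial_index, stimulus_type, scheduled_onset_offset_s)."""
    df = pd.DataFrame(
        {
            "trial_index": np.arange(1, len(schedule.trial_types) + 1),
            "stimulus_type": schedule.trial_types,
            "scheduled_onset_offset_s": _scheduled_onsets(schedule),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_schedule_tsv(path: str | Path, config: SessionConfig) -> SessionSchedule:
    """Read a schedule TSV written by :func:`write_schedule_tsv`."""
    df = pd.read_csv(path, sep="\t")
    expected = ["trial_index", "stimulus_type", "scheduled_onset_offset_s"]
    if list(df.columns) != expected:
        raise ValueError(f"schedule TSV must have columns {expected}")
    return SessionSchedule(tuple(df["stimulus_type"]), config)
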