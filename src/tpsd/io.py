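"""Serialization of lick-event datasets.

A dataset is stored as two UTF-8 tab-separated files: an *events* table with
one timestamped lick per row, and a companion *trials* table with one row per
trial so that zero-lick (Miss/CR) trials stay representable.  Lick times are
trial-relative seconds on the 4 ms recording grid; writing is deterministic,
so identical datasets produce byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .records import SessionRecord, TrialRecord, events_frame, trials_frame
from .task import SessionConfig

__all__ = ["LickEventError", "write_lick_events", "read_lick_events",
           "EVENT_COLUMNS", "TRIAL_COLUMNS"]

logger = logging.getLogger("tpsd")

EVENT_COLUMNS = ["mouse_id", "genotype", "session", "phase", "modality",
                 "trial", "stimulus_type", "lick_time_s"]
TRIAL_COLUMNS = ["mouse_id", "genotype", "session", "phase", "modality",
                 "trial", "stimulus_type", "n_licks"]


class LickEventError(ValueError):
    """Raised in strict mode on any dataset invariant violation."""


def write_lick_events(
    sessions: list[SessionRecord], events_path: str | Path, trials_path: str | Path
) -> None:
    """Write a dataset as the events TSV plus the companion trials TSV."""
    ev = events_frame(sessions)
    tr = trials_frame(sessions)
    ev.to_csv(events_path, sep="\t", index=False, float_format="%.4f")
    tr.to_csv(trials_path, sep="\t", index=False)


def _check_header(df: pd.DataFrame, expected: list[str], path) -> None:
    if list(df.columns) != expected:
        raise LickEventError(f"{path}: header must be exactly {expected}")


def read_lick_events(
    events_path: str | Path,
    trials_path: str | Path,
    strict: bool = True,
    config_factory=None,
) -> list[SessionRecord]:
    """Read and validate a dataset written by :func:`write_lick_events`.

    Strict mode raises :class:`LickEventError` with a row-numbered message on
    the first invariant violation (negative or non-increasing lick times,
    non-contiguous trial indices, inconsistent stimulus types); lenient mode
    drops offending event rows and logs how many were dropped.

    ``config_factory(phase, modality, n_trials, preferred_fraction)`` may be
    supplied to attach custom session configs; by default a standard config
    is inferred from the trials table.
    """
    ev = pd.read_csv(events_path, sep="\t")
    tr = pd.read_csv(trials_path, sep="\t")
    _check_header(ev, EVENT_COLUMNS, events_path)
    _check_header(tr, TRIAL_COLUMNS, trials_path)

    n_dropped = 0
    bad = ev["lick_time_s"] < 0
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
        if strict:
            raise LickEventError(f"{events_path}: negative lick_time_s at line {row}")
        n_dropped += int(bad.sum())
        ev = ev[~bad]

    sessions: list[SessionRecord] = []
    group_cols = ["mouse_id", "genotype", "session", "phase", "modality"]
    ev_groups = {k: g for k, g in ev.groupby(group_cols, sort=False)} if len(ev) else {}
    for key, trg in tr.groupby(group_cols, sort=False):
        mouse_id, genotype, session, phase, modality = key
        trg = trg.sort_values("trial")
        indices = trg["trial"].to_numpy()
        if not np.array_equal(indices, np.arange(1, len(indices) + 1)):
            msg = f"{trials_path}: trial indices not contiguous from 1 for {mouse_id} session {session}"
            if strict:
                raise LickEventError(msg)
            logger.warning(msg)
        stim_by_trial = dict(zip(trg["trial"], trg["stimulus_type"]))

        evg = ev_groups.get(key)
        licks: dict[int, np.ndarray] = {}
        if evg is not None:
            for trial_idx, eg in evg.groupby("trial", sort=True):
                times = eg["lick_time_s"].to_numpy(dtype=float)
                diffs = np.diff(times)
                if np.any(diffs <= 0):
                    pos = int(np.flatnonzero(diffs <= 0)[0])
                    row = int(eg.index[pos + 1]) + 2
                    msg = (f"{events_path}: non-increasing lick_time_s at line {row} "
                           f"({mouse_id} session {session} trial {trial_idx})")
                    if strict:
                        raise LickEventError(msg)
                    keep = np.concatenate(([True], diffs > 0))
                    n_dropped += int((~keep).sum())
                    times = times[keep]
                stim = set(eg["stimulus_type"])
                if stim != {stim_by_trial.get(trial_idx)}:
                    msg = (f"{events_path}: stimulus_type inconsistent with trials table "
                           f"for {mouse_id} session {session} trial {trial_idx}")
                    if strict:
                        raise LickEventError(msg)
                    logger.warning(msg)
                licks[int(trial_idx)] = times

        trials = [
            TrialRecord(
                index=int(i),
                stimulus_type=str(stim_by_trial[i]),
                lick_times=licks.get(int(i), np.empty(0)),
            )
            for i in indices
        ]
        n = len(trials)
        n_pref = sum(t.stimulus_type == "preferred" for t in trials)
        if config_factory is not None:
            config = config_factory(phase, modality, n, n_pref / n if n else 1.0)
        else:
            frac = 1.0 if phase == "pretrial" else min(max(n_pref / n, 1e-9), 1 - 1e-9)
            config = SessionConfig(
                n_trials=n, preferred_fraction=frac,
                modality_condition=str(modality), phase=str(phase),
            )
        sessions.append(
            SessionRecord(mouse_id=str(mouse_id), genotype=str(genotype),
                          session=int(session), trials=trials, config=config)
        )
    if n_dropped:
        logger.warning("read_lick_events: dropped %d invalid event rows", n_dropped)
    return sessions
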