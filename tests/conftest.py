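import numpy as np
import pytest

from tpsd.records import SessionRecord, TrialRecord
from tpsd.task import SessionConfig


def make_trial(index, stimulus_type, licks=(), outcome=None):
    return TrialRecord(index=index, stimulus_type=stimulus_type,
                       lick_times=np.asarray(licks, dtype=float), outcome=outcome)


def make_session(trial_specs, mouse_id="m1", genotype="WT_like", session=1,
                 config=None, phase="main"):
    """trial_specs: list of (stimulus_type, licks) or (stimulus_type, licks, outcome)."""
    if config is None:
        n = len(trial_specs)
        n_pref = sum(1 for spec in trial_specs if spec[0] == "preferred")
        frac = 1.0 if phase == "pretrial" else min(max(n_pref / n, 0.01), 0.99)
        config = SessionConfig(n_trials=n, preferred_fraction=frac, phase=phase)
    trials = [
        make_trial(i + 1, *spec) if len(spec) == 3 else make_trial(i + 1, spec[0], spec[1])
        for i, spec in enumerate(trial_specs)
    ]
    return SessionRecord(mouse_id=mouse_id, genotype=genotype, session=session,
                         trials=trials, config=config)


def scored_trials(types_and_outcomes):
    """Build scored trials directly from (stimulus_type, outcome) pairs."""
    trials = []
    for i, (stype, outcome) in enumerate(types_and_outcomes):
        licks = [1.5] if outcome in ("Hit", "FA") else []
        trials.append(make_trial(i + 1, stype, licks, outcome))
    return trials


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
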