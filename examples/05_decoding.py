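"""Per-time-bin bootstrapped SVM decoding of stimulus type with a shuffled null."""

import numpy as np

from tpsd import decode_session, score_session, simulate_session, wt_like
from tpsd.task import SessionConfig

# Balanced sessions so empirical chance is 50% (with discrete ~7 Hz lick
# events, a 70% majority class cannot be beaten by one 0.067 s bin).
sessions = []
for i in range(4):
    rec = simulate_session(f"m{i}", wt_like(), 12,
                           SessionConfig(n_trials=250, preferred_fraction=0.5),
                           np.random.default_rng(40 + i))
    sessions.append(score_session(rec))

res = decode_session(sessions, n_boot=200, epoch=(0.8, 1.6), seed=5)
for c, acc, nq in zip(res.bin_centers, res.accuracy_mean, res.null_q975):
    flag = "*" if acc > nq else " "
    print(f"  bin {c:.3f} s: accuracy {acc:.3f}  null 97.5% {nq:.3f} {flag}")
print("-> bins where real accuracy exceeds the shuffled-label null's upper")
print("   quantile (*) show when licking predicts the stimulus — before the")
print("   1.2 s reward for expert mice, i.e. anticipatory discrimination.")
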