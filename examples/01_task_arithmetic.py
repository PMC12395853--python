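"""Task structure: pattern durations, schedules, stimulus exposure."""

from tpsd import (SessionConfig, build_schedule, nonpreferred_pattern,
                  pattern_duration, preferred_pattern, total_stimulus_exposure)

pref, nonpref = preferred_pattern(), nonpreferred_pattern()
print(f"preferred pattern   : 4 x 200 ms pulses -> {pattern_duration(pref):.1f} s")
print(f"nonpreferred pattern: 4 x 900 ms pulses -> {pattern_duration(nonpref):.1f} s")

cfg = SessionConfig(n_trials=350, preferred_fraction=0.6)
sched = build_schedule(cfg, seed=0)
exp_p, exp_n = total_stimulus_exposure(sched)
print(f"60:40 probe session : {sched.n_preferred} preferred / "
      f"{sched.n_nonpreferred} nonpreferred trials")
print(f"stimulus exposure   : {exp_p:.0f} s preferred vs {exp_n:.0f} s nonpreferred")
print("-> even with more preferred trials, mice spend twice as long viewing")
print("   the nonpreferred pattern, because it is three times longer.")
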