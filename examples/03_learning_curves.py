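"""Genotype-dependent learning curves in best-window and full-session d'."""

from tpsd import ko_expert_like, session_performance_frame, simulate_cohort, wt_like
from tpsd.performance import sessions_to_threshold

sessions = simulate_cohort([wt_like(), ko_expert_like()], n_mice_per_preset=4,
                           n_sessions=6, master_seed=3)
perf = session_performance_frame(sessions)
print(perf.groupby(["genotype", "session"])["d_prime_full"].mean().round(2).unstack())

for genotype, g in perf.sort_values("session").groupby("genotype"):
    days = []
    for _, m in g.groupby("mouse_id"):
        s = sessions_to_threshold(list(m["d_prime_full"]), 1.0)
        days.append(s if s is not None else ">6")
    print(f"{genotype}: sessions to d' > 1 per mouse: {days}")
print("-> WT-like mice cross the intermediate learning threshold within a few")
print("   sessions; KO-like false-alarm suppression is delayed, so most stay")
print("   below threshold through session 6.")
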