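"""Simulate a small WT-like vs KO-like cohort and write the event tables."""

from pathlib import Path

from tpsd import ko_expert_like, simulate_cohort, wt_like, write_lick_events
from tpsd.records import events_frame, trials_frame

sessions = simulate_cohort([wt_like(), ko_expert_like()], n_mice_per_preset=2,
                           n_sessions=2, master_seed=0)
ev, tr = events_frame(sessions), trials_frame(sessions)
print(f"{len(sessions)} sessions, {len(tr)} trials, {len(ev)} lick events")
print(f"zero-lick (Miss/CR) trials: {(tr['n_licks'] == 0).sum()}")

out = Path("scratch_example")
out.mkdir(exist_ok=True)
write_lick_events(sessions, out / "events.tsv", out / "trials.tsv")
print(f"wrote {out}/events.tsv and {out}/trials.tsv")
print("-> one timestamped lick per row; the companion trials table keeps")
print("   withhold trials representable. Same seed -> byte-identical files.")
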