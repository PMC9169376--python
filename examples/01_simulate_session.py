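"""Simulate a labeled surgical session trace and store it as CSV.

A session alternates laser states (Idle -> Stone -> Tissue ...); the
simulator emits a 100 Hz acceleration-magnitude trace with one state label
per sample, the same shape as the data a logging rig would produce.
"""

import numpy as np

import lithowarn as lw

schedule = [("idle", 10), ("stone", 15), ("idle", 5), ("tissue", 8), ("idle", 5)]
rec = lw.simulate_session(schedule, seed=7)
lw.write_recording(rec, "session.csv")

counts = np.bincount(rec.labels, minlength=3)
print(f"samples: {len(rec)}  duration: {rec.duration_s:.0f} s at {rec.sampling_rate_hz:.0f} Hz")
for state in lw.StateLabel:
    share = counts[int(state)] / len(rec)
    print(f"  {state.display_name:<6} {counts[int(state)]:5d} samples ({share:4.0%})")
print(f"bursts rendered per block: {rec.meta['n_bursts']}")
print("wrote session.csv (columns t_ms, magnitude, label)")
# The per-block burst counts reflect each state's laser pulse rate: zero when
# idle, dense during stone/tissue contact.
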