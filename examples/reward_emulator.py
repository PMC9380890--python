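"""Offline emulation of the closed-loop water-reward rule.

During recording, a 1-s trailing moving average of the bite force above
30 (g averaged over the window) triggered a syringe pump.  This script
replays that rule on a constructed force trace with three biting bouts.
"""

import numpy as np

from clef import RewardRule, SignalTrace, moving_average, reward_triggers

fs = 1000.0
force = np.zeros(int(16 * fs))
for start, level in ((1.0, 60.0), (6.0, 20.0), (10.0, 90.0)):
    force[int(start * fs) : int((start + 2) * fs)] = level
trace = SignalTrace(force, fs=fs, channel="force", units="g")

rule = RewardRule(window=1.0, threshold=30.0)
ma = moving_average(trace, rule.window)
times = reward_triggers(trace, rule)

print(f"rule                 : {rule.window:.0f}-s moving average > {rule.threshold:.0f}")
print(f"peak moving average  : {np.nanmax(ma.samples):.1f}")
print(f"reward triggers at   : {np.round(times, 3).tolist()} s")
# Only the 60-g and 90-g bouts push the 1-s average over 30, so exactly
# two rewards fire; the 20-g bout is below threshold and earns nothing.
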