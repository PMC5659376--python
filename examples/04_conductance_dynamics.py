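"""Channel conductance dynamics during firing of the mature M-cell model.

Simulates the 4-dpf preset (Kv1.1+Kvb2 700 nS, Kv7.4 1400 nS) at 1.5x
rheobase and prints when each conductance reaches half of its own maximum.
The fast Kvb2-associated Kv1.1 conductance engages essentially with the
first spike, whereas Kv7.4 activation builds over tens of milliseconds —
the kinetic division of labor behind spike-onset suppression vs
spike-frequency adaptation.
"""

import numpy as np

from mauthner import (StepStimulus, conductance_timecourses,
                      developmental_presets, find_threshold)

model = developmental_presets("4dpf")
T = find_threshold(model)
out = conductance_timecourses(model, StepStimulus(round(1.5 * T)))
t = out["time_ms"]

print(f"4dpf preset, stimulus {round(1.5 * T)} pA (1.5T)")
print("channel        g_max (nS)   time to half-max (ms)")
for name, g in out["raw_nS"].items():
    peak = np.nanmax(g)
    if peak <= 0:
        continue
    idx = np.nonzero(~np.isnan(g) & (g >= 0.5 * peak))[0][0]
    print(f"{name:12s} {peak:10.1f} {t[idx]:16.2f}")
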