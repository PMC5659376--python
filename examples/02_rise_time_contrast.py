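"""Half-maximal rise times: Kv7.4 vs Kv1.1 vs Kv1.1+Kvb2.

Measures t1/2 (time from step onset to half of the within-step current
peak) for each command from -40 to +50 mV.  Kv7.4 rises tens of times more
slowly than Kv1.1, and Kvb2 coexpression speeds Kv1.1 by about 2 ms —
the two kinetic signatures that let these channels play different roles
in shaping Mauthner-cell firing.
"""

import numpy as np

from mauthner import (VClampProtocol, build_stock_channels, rise_time_half,
                      run_voltage_clamp)

stock = build_stock_channels()
protocol = VClampProtocol()
levels = [v for v in protocol.step_levels_mV if v >= -40]

t_half = {}
for name in ("Kv7.4", "Kv1.1", "Kv1.1+Kvb2"):
    tr = run_voltage_clamp(stock[name], protocol)
    t_half[name] = {v: rise_time_half(tr.trace(v), tr.time_ms,
                                      tr.step_onset_ms, tr.step_offset_ms)
                    for v in levels}

print("V (mV)   Kv7.4    Kv1.1   +Kvb2   (t1/2, ms)")
for v in levels:
    print(f"{v:6.0f} {t_half['Kv7.4'][v]:8.2f} {t_half['Kv1.1'][v]:8.2f} "
          f"{t_half['Kv1.1+Kvb2'][v]:8.2f}")
diff = np.mean([t_half["Kv1.1"][v] - t_half["Kv1.1+Kvb2"][v] for v in levels])
print(f"\nmean Kvb2 speed-up above -40 mV: {diff:.2f} ms")
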