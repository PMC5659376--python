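"""Emulate the two-electrode voltage clamp and fit the G-V relations.

Runs the standard step family (-80 to +50 mV, 10-mV steps, 200 ms) on the
three zebrafish low-threshold K+ channel models, extracts the peak
conductance per step, and fits the Boltzmann G = Gmax/(1 + exp((V1/2-V)/k)).
The printed V1/2 (half-activation voltage) and k (slope factor) are the
model's counterparts of the oocyte measurements: Kv7.4 activates at much
more positive voltages with a shallow slope, while Kvb2 coexpression
slightly broadens the Kv1.1 activation curve.
"""

from mauthner import build_stock_channels, fit_channel_gv

stock = build_stock_channels()
for name in ("Kv7.4", "Kv1.1", "Kv1.1+Kvb2"):
    fit = fit_channel_gv(stock[name])
    print(f"{name:12s} V1/2 = {fit.v_half_mV:7.2f} mV   "
          f"k = {fit.slope_k_mV:5.2f} mV   Gmax = {fit.g_max_uS:5.2f} uS")
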