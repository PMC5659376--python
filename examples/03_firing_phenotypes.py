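"""The firing-phenotype table of the M-cell model.

For each (Kv7.4, Kv1-type) conductance pair the script finds the rheobase
T at 1-pA resolution, simulates 100-ms steps at 1T/1.5T/2T, and classifies
the firing pattern.  The progression reproduces the developmental story:
the bare cochlear-neuron-like cell fires tonically; Kv7.4 produces
adapting phasic bursts (long at 700 nS, short at 1400 nS); fast
Kvb2-associated Kv1.1 shortens bursts further; and only the combination of
both mature conductances yields the M cell's single spike.
"""

from mauthner import (MCellModel, classify_phenotype, compute_metrics,
                      detect_spikes, find_threshold, run_intensity_series)

CASES = [
    (0, 0, False), (0, 150, False),
    (700, 0, False), (700, 150, False),
    (0, 700, True), (1400, 0, False), (1400, 700, False),
    (1400, 700, True),
]

print("gKv7.4  gKv1-type  Kvb2    T(pA)  lat(ms)  APs@1.5T/2T  phenotype")
for g74, g1, kvb2 in CASES:
    model = MCellModel(g_kv74_nS=g74, g_kv1_nS=g1, kvb2=kvb2)
    T = find_threshold(model)
    traces = run_intensity_series(model, T)
    metrics = compute_metrics({k: detect_spikes(v) for k, v in traces.items()}, T)
    label = classify_phenotype(metrics)
    print(f"{g74:6.0f} {g1:9.0f}  {str(kvb2):5s} {T:7d} {metrics.latency_1T_ms:8.2f}"
          f" {metrics.n_spikes[1.5]:6d}/{metrics.n_spikes[2.0]:<4d} {label}")
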