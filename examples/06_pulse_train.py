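"""Firing responses to 500-Hz trains of short pulses (auditory-like input).

Drives model cells with 0.5-ms pulses at 500 Hz for 100 ms — a stand-in
for the high-frequency afferent volleys M cells receive — at a range of
amplitudes, and prints the number of spikes per train.  Tonic models
follow the train at increasing rates, whereas low-threshold K+
conductances restrict firing to the train onset.
"""

from mauthner import (MCellModel, PulseTrainStimulus, detect_spikes,
                      simulate_current_clamp)

MODELS = {
    "tonic (0, 0)": MCellModel(),
    "phasic long (150, 700)": MCellModel(g_kv74_nS=700, g_kv1_nS=150),
    "single-spiking (b2 700, 1400)": MCellModel(g_kv74_nS=1400, g_kv1_nS=700,
                                                kvb2=True),
}

amps = [500, 1000, 1500, 2000, 2500, 3000]
print("APs per 100-ms train (0.5-ms pulses at 500 Hz)")
print("amplitude (pA):", "  ".join(f"{a:5d}" for a in amps))
for name, model in MODELS.items():
    counts = []
    for amp in amps:
        trace = simulate_current_clamp(model, PulseTrainStimulus(float(amp)))
        counts.append(detect_spikes(trace).n_spikes)
    print(f"{name:30s} " + "  ".join(f"{c:5d}" for c in counts))
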