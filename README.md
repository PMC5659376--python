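# mauthner

Hodgkin–Huxley channel generator and firing simulator for the zebrafish
Mauthner (M) cell.

The M cell is a giant hindbrain neuron that fires exactly one action
potential at the onset of an abrupt stimulus, while its segmental homologs
fire tonically. This package models the ionic basis of that difference:
two low-threshold K⁺ conductances — slowly activating Kv7.4/KCNQ4 and fast
Kv1.1, the latter accelerated and enlarged by the auxiliary subunit Kvβ2 —
added to a single-compartment base cell (Nav, high-threshold K⁺, A-type
K⁺, leak) derived from a ventral cochlear nucleus neuron model.

The package provides:

- **Channel models** — single-gate Boltzmann channels for Kv7.4, Kv1.1 and
  Kv1.1+Kvβ2 with activation `m∞(V) = 1/(1 + exp((V½ − V)/k))`,
  bell-shaped `τ(V)`, and Q10 temperature scaling; multi-gate
  Rothman–Manis kinetics for the base cell.
- **A voltage-clamp lab** — an ideal two-electrode clamp on a model
  *Xenopus* oocyte compartment (20 × 20 µm, 12.6 pF) with the standard
  step family (−80…+50 mV, 10-mV steps, 200 ms), P/4 leak subtraction,
  peak-conductance G–V extraction, Boltzmann fitting
  `G = Gmax/[1 + exp((V½ − V)/k)]`, and half-maximal rise times t½.
- **A current-clamp engine** — the 40 × 40 µm (~50 pF) M-cell compartment
  integrated with exponential Euler at a virtual 25 °C, rheobase search at
  1-pA resolution, intensity series at 1T/1.5T/2T, spike detection, ISI
  adaptation ratios, and firing-phenotype classification (tonic, phasic
  bursting long/short, single spiking).
- **Conductance-space sweeps** — firing-parameter maps over the
  (ḡ_Kv7.4 × ḡ_Kv1-type) plane, 21 × 51 = 1071 combinations per Kvβ2 mode.
- **Synthetic fixtures** — seeded noisy oocyte-like recordings with known
  ground truth for validating the whole fitting pipeline.

## Worked example

```sh
python examples/03_firing_phenotypes.py
```

```text
gKv7.4  gKv1-type  Kvb2    T(pA)  lat(ms)  APs@1.5T/2T  phenotype
     0         0  False     145    38.08      4/5    tonic
     0       150  False     165    37.15      4/5    tonic
   700         0  False     222    28.12      2/3    phasic_long
   700       150  False     243    20.43      2/4    phasic_long
     0       700  True      527     7.40      1/2    phasic_short
  1400         0  False     297    21.95      1/2    phasic_short
  1400       700  False     392    13.70      1/3    phasic_short
  1400       700  True      688     8.10      1/1    single_spiking
```

Each row is one model cell: `T` is the rheobase (smallest 100-ms step
current that elicits a spike, found at 1-pA resolution), the latency is
measured to the first spike at 1T, and the phenotype is classified from
the 1.5T and 2T spike trains. Reading down the table reproduces the
developmental progression: the bare base cell is tonic, Kv7.4 alone
converts it to adapting phasic bursts (long at 700 nS, short at 1400 nS),
and only the mature combination — enlarged, Kvβ2-accelerated Kv1.1 *plus*
doubled Kv7.4 — yields the single-spiking M-cell signature. The
(Kv7.4, Kv1-type) pairs (700, 150) and (1400, 700 with Kvβ2) correspond to
the 2-dpf and 4-dpf developmental stages (`developmental_presets("2dpf")`
etc.); a 2× increase in Kv7.4 and a 4.7× increase in Kv1-type conductance
carries the model from one to the other.

Other examples cover the G–V pipeline (`01`), rise-time contrasts (`02`),
per-channel conductance dynamics during firing (`04`), the conductance
sweep (`05`), 500-Hz pulse-train responses (`06`) and noisy-fixture
parameter recovery (`07`). A thin CLI exposes the same operations
(`mauthner vclamp|fit|iclamp|threshold|preset|sweep|fixtures`).

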