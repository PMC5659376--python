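"""Synthetic noisy voltage-clamp recordings with known ground truth.

Emulates the raw two-electrode oocyte recording before leak/capacitance
correction: channel current plus a linear leak (relative to the holding
level), a capacitive transient at the step edges, and additive white
Gaussian noise.  Four quarter-amplitude subsweeps carry the leak and
capacitive components (channels are treated as closed at the quarter
steps, an approximation that holds for steps from -80 mV) so the P/4
pipeline can be tested as a parameter-recovery problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import ChannelModel
from .geometry import CylindricalCompartment, OOCYTE
from .vclamp import CurrentTraceSet, VClampProtocol, run_voltage_clamp

__all__ = ["SyntheticRecordingSpec", "generate_recording", "N_SUBSWEEPS"]

N_SUBSWEEPS = 4


@dataclass(frozen=True)
class SyntheticRecordingSpec:
    """Ground truth + nuisance parameters for one synthetic recording.

    leak_uS: linear leak slope conductance; its current is proportional to
    the command displacement from holding (leak at holding is absorbed in
    the amplifier zero).  cap_amp_uA is the capacitive-transient amplitude
    for a +100 mV step, decaying with cap_tau_ms.  noise_sd is the Gaussian
    noise standard deviation as a fraction of the largest channel-current
    peak; the seed fully determines the output.
    """

    channel: ChannelModel
    leak_uS: float = 2.0
    cap_tau_ms: float = 1.0
    cap_amp_uA: float = 5.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.leak_uS < 0 or self.cap_tau_ms <= 0:
            raise ValueError("invalid leak/capacitance parameters")


def _passive_sweep(
    t: np.ndarray,
    delta_mV: float,
    onset_ms: float,
    offset_ms: float,
    spec: SyntheticRecordingSpec,
) -> np.ndarray:
    """Leak + capacitive transient (uA) for a step of the given amplitude."""
    # 1 uS * 1 mV = 1 nA = 1e-3 uA
    leak = np.where((t >= onset_ms) & (t < offset_ms),
                    spec.leak_uS * delta_mV * 1e-3, 0.0)
    cap = np.zeros_like(t)
    scale = spec.cap_amp_uA * delta_mV / 100.0
    on = t >= onset_ms
    cap[on] += scale * np.exp(-(t[on] - onset_ms) / spec.cap_tau_ms)
    off = t >= offset_ms
    cap[off] -= scale * np.exp(-(t[off] - offset_ms) / spec.cap_tau_ms)
    return leak + cap


def generate_recording(
    spec: SyntheticRecordingSpec,
    protocol: VClampProtocol = VClampProtocol(),
    compartment: CylindricalCompartment = OOCYTE,
    temperature_C: float = 20.0,
):
    """Return (main CurrentTraceSet, list of four subsweep CurrentTraceSets).

    The main sweep is channel + leak + capacitive transient + noise; each
    quarter-amplitude subsweep contains leak + transient + independent
    noise only.
    """
    rng = np.random.default_rng(spec.seed)
    clean = run_voltage_clamp(spec.channel, protocol, compartment, temperature_C)
    t = clean.time_ms
    on, off = clean.step_onset_ms, clean.step_offset_ms
    peak = np.abs(clean.currents_uA).max()
    sd = spec.noise_sd * peak

    main = np.empty_like(clean.currents_uA)
    subs = [np.empty_like(clean.currents_uA) for _ in range(N_SUBSWEEPS)]
    for i, v in enumerate(clean.step_levels_mV):
        dv = v - protocol.holding_mV
        main[i] = (clean.currents_uA[i]
                   + _passive_sweep(t, dv, on, off, spec)
                   + rng.normal(0.0, sd, t.size))
        for s in subs:
            s[i] = (_passive_sweep(t, dv / 4.0, on, off, spec)
                    + rng.normal(0.0, sd, t.size))

    def pack(arr, kind):
        return CurrentTraceSet(
            time_ms=t.copy(),
            step_levels_mV=clean.step_levels_mV.copy(),
            currents_uA=arr,
            step_onset_ms=on,
            step_offset_ms=off,
            meta={**clean.meta, "kind": kind, "seed": spec.seed,
                  "noise_sd": spec.noise_sd, "synthetic": True},
        )

    return pack(main, "main"), [pack(s, f"sub{j}") for j, s in enumerate(subs)]
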