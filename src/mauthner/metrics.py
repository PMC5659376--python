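"""Spike detection, firing-property metrics and phenotype classification.

Spikes are upward crossings of a -20 mV detection level with a 0.5-ms
refractory separation; the spike time is the local voltage maximum after
the crossing, and only spikes inside the stimulus window are counted
(rebound spikes after stimulus offset are excluded).  The phenotype labels
(tonic, phasic bursting long/short, single spiking) are decided from the
1.5T and 2T spike trains:

- single_spiking: exactly one spike at both 1.5T and 2T;
- tonic: firing spans the step (last 2T spike in the final 20% of the
  pulse) without strong adaptation (ISI_last/ISI_1st <= 1.5);
- otherwise phasic, long vs short split at half the stimulus duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrain",
    "FiringMetrics",
    "detect_spikes",
    "compute_metrics",
    "classify_phenotype",
    "DetectionParams",
]

PHENOTYPES = ("tonic", "phasic_long", "phasic_short", "single_spiking", "non_firing")


@dataclass(frozen=True)
class DetectionParams:
    threshold_mV: float = -20.0
    refractory_ms: float = 0.5


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times in ms relative to stimulus onset, strictly increasing."""

    times_ms: tuple
    crossing_times_ms: tuple
    detection: DetectionParams = field(default_factory=DetectionParams)

    @property
    def n_spikes(self) -> int:
        return len(self.times_ms)

    @property
    def isi_ms(self) -> tuple:
        t = self.times_ms
        return tuple(b - a for a, b in zip(t, t[1:]))


@dataclass(frozen=True)
class FiringMetrics:
    threshold_pA: int
    latency_1T_ms: float
    n_spikes: dict          # intensity multiple -> spike count
    isi_2T_ms: tuple
    adaptation_ratio: float | None   # ISI_last/ISI_1st at 2T, needs >= 3 spikes
    last_spike_2T_ms: float | None
    stim_duration_ms: float


def detect_spikes(trace, detection: DetectionParams = DetectionParams()) -> SpikeTrain:
    """Detect spikes in a VoltageTrace within its stimulus window."""
    t = np.asarray(trace.time_ms, dtype=float)
    v = np.asarray(trace.v_mV, dtype=float)
    dts = np.diff(t)
    if dts.size and (dts.max() - dts.min()) > 1e-9 + 1e-6 * dts.mean():
        raise ValueError("spike detection requires a uniform time base")
    thr = detection.threshold_mV
    up = np.nonzero((v[:-1] < thr) & (v[1:] >= thr))[0]
    crossings, peaks = [], []
    last = -np.inf
    for idx in up:
        t_cross = t[idx + 1]
        if t_cross - last < detection.refractory_ms:
            continue
        last = t_cross
        # local maximum: scan forward until v falls back below threshold
        j = idx + 1
        while j + 1 < v.size and v[j + 1] >= thr:
            j += 1
        seg = slice(idx + 1, j + 1)
        k = idx + 1 + int(np.argmax(v[seg]))
        crossings.append(t_cross)
        peaks.append(t[k])
    on, off = trace.stim_window_ms
    keep = [i for i, tc in enumerate(crossings) if on <= tc <= off]
    return SpikeTrain(
        times_ms=tuple(peaks[i] - on for i in keep),
        crossing_times_ms=tuple(crossings[i] - on for i in keep),
        detection=detection,
    )


def compute_metrics(
    trains: dict,
    threshold_pA: int,
    stim_duration_ms: float = 100.0,
) -> FiringMetrics:
    """Firing metrics from spike trains keyed by intensity multiple.

    Latency is the detection-crossing time of the first spike at 1T; the
    ISI sequence and adaptation ratio come from the 2T train.
    """
    if 1.0 not in trains or 2.0 not in trains:
        raise ValueError("metrics require trains at 1T and 2T")
    t1 = trains[1.0]
    if t1.n_spikes < 1:
        raise ValueError(
            "no spike at 1T: contract violation (1T guarantees >= 1 spike)"
        )
    latency = float(t1.crossing_times_ms[0])
    t2 = trains[2.0]
    isi = t2.isi_ms
    ratio = float(isi[-1] / isi[0]) if t2.n_spikes >= 3 else None
    last2 = float(t2.times_ms[-1]) if t2.n_spikes else None
    return FiringMetrics(
        threshold_pA=int(threshold_pA),
        latency_1T_ms=latency,
        n_spikes={m: tr.n_spikes for m, tr in trains.items()},
        isi_2T_ms=isi,
        adaptation_ratio=ratio,
        last_spike_2T_ms=last2,
        stim_duration_ms=stim_duration_ms,
    )


def classify_phenotype(
    metrics: FiringMetrics,
    stim_duration_ms: float | None = None,
    tonic_window_frac: float = 0.2,
    tonic_max_ratio: float = 1.5,
    long_split_frac: float = 0.5,
) -> str:
    """Assign exactly one phenotype label from 1.5T/2T metrics."""
    dur = stim_duration_ms if stim_duration_ms is not None else metrics.stim_duration_ms
    n15 = metrics.n_spikes.get(1.5)
    n2 = metrics.n_spikes.get(2.0)
    if n15 is None or n2 is None:
        raise ValueError("classification requires spike counts at 1.5T and 2T")
    if n2 == 0:
        return "non_firing"
    if n15 == 1 and n2 == 1:
        return "single_spiking"
    last = metrics.last_spike_2T_ms
    spans_pulse = last >= (1.0 - tonic_window_frac) * dur
    weak_adaptation = (
        metrics.adaptation_ratio is not None
        and metrics.adaptation_ratio <= tonic_max_ratio
    )
    if spans_pulse and weak_adaptation:
        return "tonic"
    return "phasic_long" if last >= long_split_frac * dur else "phasic_short"
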