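"""Emulated two-electrode voltage clamp and its trace-analysis pipeline.

The clamp is ideal: the membrane potential follows the command exactly, so
for a single Boltzmann gate the open fraction relaxes exponentially within
each constant-voltage segment and the exponential-Euler update used here is
exact per sample.  Analysis mirrors the oocyte workflow: P/4 leak and
capacitance subtraction, peak conductance per step, Boltzmann fit of the
G-V relation, and half-maximal rise time.

Currents are reported in uA (oocyte scale) and conductances in uS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .channels import ChannelModel
from .gating import steady_state_activation, time_constant
from .geometry import CylindricalCompartment, OOCYTE

__all__ = [
    "VClampProtocol",
    "CurrentTraceSet",
    "BoltzmannFit",
    "run_voltage_clamp",
    "p4_subtract",
    "peak_conductance",
    "fit_boltzmann",
    "rise_time_half",
]

PA_PER_UA = 1e6


@dataclass(frozen=True)
class VClampProtocol:
    """Step protocol: hold, step family, return to hold."""

    holding_mV: float = -80.0
    step_levels_mV: tuple = tuple(range(-80, 51, 10))
    step_duration_ms: float = 200.0
    pre_duration_ms: float = 10.0
    post_duration_ms: float = 50.0
    sample_interval_ms: float = 0.1

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.step_levels_mV)
        if len(levels) == 0:
            raise ValueError("protocol has no step levels")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("step levels must be strictly increasing")
        if self.step_duration_ms <= 0 or self.sample_interval_ms <= 0:
            raise ValueError("durations must be positive")
        object.__setattr__(self, "step_levels_mV", levels)

    @property
    def total_duration_ms(self) -> float:
        return self.pre_duration_ms + self.step_duration_ms + self.post_duration_ms

    def time_ms(self) -> np.ndarray:
        n = int(round(self.total_duration_ms / self.sample_interval_ms)) + 1
        return np.arange(n) * self.sample_interval_ms

    def command_mV(self, level_mV: float) -> np.ndarray:
        t = self.time_ms()
        v = np.full_like(t, self.holding_mV)
        on = self.pre_duration_ms
        off = self.pre_duration_ms + self.step_duration_ms
        v[(t >= on) & (t < off)] = level_mV
        return v


@dataclass
class CurrentTraceSet:
    """Per-step current traces (uA) on one uniform time base (ms)."""

    time_ms: np.ndarray
    step_levels_mV: np.ndarray
    currents_uA: np.ndarray  # shape (n_steps, n_samples)
    step_onset_ms: float
    step_offset_ms: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.step_levels_mV = np.asarray(self.step_levels_mV, dtype=float)
        self.currents_uA = np.asarray(self.currents_uA, dtype=float)
        if self.currents_uA.shape != (self.step_levels_mV.size, self.time_ms.size):
            raise ValueError("trace array shape does not match steps x samples")
        if not np.all(np.isfinite(self.currents_uA)):
            raise ValueError("traces contain non-finite samples")

    def trace(self, level_mV: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.step_levels_mV - level_mV)))
        if abs(self.step_levels_mV[idx] - level_mV) > 1e-6:
            raise KeyError(f"no step at {level_mV} mV")
        return self.currents_uA[idx]


@dataclass(frozen=True)
class BoltzmannFit:
    """Least-squares fit of G = Gmax / (1 + exp((v_half - V)/k))."""

    g_max_uS: float
    v_half_mV: float
    slope_k_mV: float
    residual_norm: float

    def predict(self, v_mV):
        v = np.asarray(v_mV, dtype=float)
        return self.g_max_uS / (1.0 + np.exp((self.v_half_mV - v) / self.slope_k_mV))


def run_voltage_clamp(
    channel: ChannelModel,
    protocol: VClampProtocol = VClampProtocol(),
    compartment: CylindricalCompartment = OOCYTE,
    temperature_C: float = 20.0,
) -> CurrentTraceSet:
    """Simulate the step family on one Boltzmann channel under ideal clamp.

    The gate starts at its steady state for the holding potential; within
    each constant-voltage segment the exponential-Euler gate update is the
    exact solution of dm/dt = (m_inf - m)/tau.
    """
    gate = channel.gate
    if gate is None:
        raise ValueError("voltage clamp emulation requires a Boltzmann channel")
    t = protocol.time_ms()
    dt = protocol.sample_interval_ms
    traces = np.empty((len(protocol.step_levels_mV), t.size))
    for i, level in enumerate(protocol.step_levels_mV):
        v_cmd = protocol.command_mV(level)
        m = np.empty_like(t)
        m[0] = steady_state_activation(protocol.holding_mV, gate)
        minf = steady_state_activation(v_cmd, gate)
        tau = time_constant(v_cmd, gate, temperature_C)
        decay = np.exp(-dt / tau)
        for k in range(1, t.size):
            m[k] = minf[k - 1] + (m[k - 1] - minf[k - 1]) * decay[k - 1]
        i_pA = channel.gbar_nS * m ** gate.exponent_p * (v_cmd - channel.e_rev_mV)
        traces[i] = i_pA / PA_PER_UA
    return CurrentTraceSet(
        time_ms=t,
        step_levels_mV=np.array(protocol.step_levels_mV),
        currents_uA=traces,
        step_onset_ms=protocol.pre_duration_ms,
        step_offset_ms=protocol.pre_duration_ms + protocol.step_duration_ms,
        meta={
            "channel": channel.name,
            "temperature_C": temperature_C,
            "compartment_um": (compartment.length_um, compartment.diameter_um),
            "holding_mV": protocol.holding_mV,
        },
    )


def _baseline(time_ms: np.ndarray, trace: np.ndarray, onset_ms: float) -> float:
    pre = trace[time_ms < onset_ms]
    return float(pre.mean()) if pre.size else float(trace[0])


def p4_subtract(
    main: np.ndarray,
    subsweeps,
    time_ms: np.ndarray | None = None,
    step_onset_ms: float = 0.0,
) -> np.ndarray:
    """P/4 correction: main - 4 * mean(quarter-amplitude subsweeps).

    Each sweep's pre-step baseline is removed before scaling, which makes
    the subtraction exact for any current that is affine in the command
    voltage (linear leak and capacitive transients).
    """
    main = np.asarray(main, dtype=float)
    subs = np.asarray(subsweeps, dtype=float)
    if subs.ndim == 1:
        subs = subs[None, :]
    if subs.shape[-1] != main.shape[-1]:
        raise ValueError("subsweeps and main sweep have mismatched time bases")
    if time_ms is not None:
        time_ms = np.asarray(time_ms, dtype=float)
        if time_ms.size != main.size:
            raise ValueError("time base length mismatch")
        main = main - _baseline(time_ms, main, step_onset_ms)
        subs = subs - np.array(
            [_baseline(time_ms, s, step_onset_ms) for s in subs]
        )[:, None]
    return main - 4.0 * subs.mean(axis=0)


def peak_conductance(
    trace_uA: np.ndarray,
    v_cmd_mV: float,
    e_rev_mV: float,
    time_ms: np.ndarray | None = None,
    window_ms: tuple | None = None,
    smooth_ms: float = 1.0,
) -> float:
    """Peak conductance G = I_peak / (V_cmd - E_rev) in uS.

    I_peak is the extremum of |I| within the step window after a short
    boxcar smooth (noise suppression on recorded traces; a no-op on the
    slowly varying model currents).  For the non-inactivating channels
    here the extremum is the end-of-step value.
    """
    if v_cmd_mV == e_rev_mV:
        raise ValueError("conductance undefined at the reversal potential")
    trace = np.asarray(trace_uA, dtype=float)
    if time_ms is not None:
        time_ms = np.asarray(time_ms, dtype=float)
        if smooth_ms > 0 and time_ms.size > 1:
            dt = time_ms[1] - time_ms[0]
            width = max(1, int(round(smooth_ms / dt)))
            if width > 1:
                kernel = np.ones(width) / width
                # 'same' convolution with edge padding to avoid end bias
                padded = np.pad(trace, (width // 2, width - 1 - width // 2),
                                mode="edge")
                trace = np.convolve(padded, kernel, mode="valid")
        if window_ms is not None:
            mask = (time_ms >= window_ms[0]) & (time_ms <= window_ms[1])
            trace = trace[mask]
    if trace.size == 0:
        raise ValueError("empty step window")
    i_peak = trace[int(np.argmax(np.abs(trace)))]
    # uA / mV = mS; report uS
    return i_peak / (v_cmd_mV - e_rev_mV) * 1000.0


def gv_curve(traces: CurrentTraceSet, e_rev_mV: float, end_mean_ms: float = 10.0):
    """Peak-conductance G-V pairs (V in mV, G in uS) from a trace set.

    For the non-inactivating channels here the peak current is the
    end-of-step value; it is estimated as the mean over the final
    ``end_mean_ms`` of the step, which is unbiased under recording noise
    (a raw per-sample extremum systematically inflates small currents).
    """
    v = traces.step_levels_mV
    t = traces.time_ms
    sel = (t >= traces.step_offset_ms - end_mean_ms) & (t < traces.step_offset_ms)
    if not sel.any():
        raise ValueError("end-of-step window is empty")
    g = np.empty(v.size)
    for i in range(v.size):
        if abs(v[i] - e_rev_mV) < 1e-9:
            g[i] = 0.0
            continue
        i_end = float(traces.currents_uA[i][sel].mean())
        g[i] = i_end / (v[i] - e_rev_mV) * 1000.0  # uA/mV -> uS
    return v.copy(), g


def fit_boltzmann(v_mV, g_uS) -> BoltzmannFit:
    """Fit G = Gmax/(1 + exp((v_half - V)/k)) by least squares."""
    v = np.asarray(v_mV, dtype=float)
    g = np.asarray(g_uS, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 G-V points spanning the rising phase")
    g_top = float(g.max())
    if g_top <= 0:
        raise ValueError("no rising phase: all conductances are <= 0")

    def model(vv, gmax, vh, k):
        return gmax / (1.0 + np.exp((vh - vv) / k))

    half = 0.5 * g_top
    vh0 = float(v[int(np.argmin(np.abs(g - half)))])
    try:
        popt, _ = curve_fit(
            model,
            v,
            g,
            p0=[g_top, vh0, 8.0],
            bounds=([1e-12, -150.0, 0.1], [np.inf, 100.0, 100.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"Boltzmann fit failed to converge (g_max guess {g_top:.3g} uS, "
            f"v_half guess {vh0:.3g} mV): {exc}"
        ) from exc
    resid = float(np.linalg.norm(model(v, *popt) - g))
    return BoltzmannFit(float(popt[0]), float(popt[1]), float(popt[2]), resid)


def fit_channel_gv(
    channel: ChannelModel,
    protocol: VClampProtocol = VClampProtocol(),
    compartment: CylindricalCompartment = OOCYTE,
    temperature_C: float = 20.0,
) -> BoltzmannFit:
    """Full pipeline: clamp emulation -> peak G-V -> Boltzmann fit."""
    traces = run_voltage_clamp(channel, protocol, compartment, temperature_C)
    v, g = gv_curve(traces, channel.e_rev_mV)
    return fit_boltzmann(v, g)


def rise_time_half(
    trace_uA: np.ndarray,
    time_ms: np.ndarray,
    step_onset_ms: float,
    step_offset_ms: float | None = None,
) -> float:
    """Half-maximal rise time t_1/2 (ms) from step onset.

    Time from the onset to the first sample where the baseline-subtracted
    current reaches half of its within-step peak, linearly interpolated
    between samples.
    """
    trace = np.asarray(trace_uA, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    mask = time_ms >= step_onset_ms
    if step_offset_ms is not None:
        mask &= time_ms <= step_offset_ms
    t_win = time_ms[mask]
    i_win = trace[mask] - _baseline(time_ms, trace, step_onset_ms)
    peak = np.abs(i_win).max()
    if peak <= 0:
        raise ValueError("flat trace: rise time undefined")
    sign = np.sign(i_win[int(np.argmax(np.abs(i_win)))])
    y = sign * i_win
    half = 0.5 * peak
    above = np.nonzero(y >= half)[0]
    if above.size == 0:
        raise ValueError("trace never reaches half-maximum")
    j = int(above[0])
    if j == 0:
        return 0.0
    # linear interpolation between samples j-1 and j
    t0, t1 = t_win[j - 1], t_win[j]
    y0, y1 = y[j - 1], y[j]
    t_cross = t0 + (half - y0) / (y1 - y0) * (t1 - t0)
    return float(t_cross - step_onset_ms)
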