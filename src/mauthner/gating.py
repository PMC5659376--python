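"""Hodgkin-Huxley gating primitives for Boltzmann-activation channels.

A gate is described by its steady-state Boltzmann activation
``m_inf(V) = 1 / (1 + exp((v_half - V)/k))`` and a bell-shaped voltage
dependent time constant

``tau(V) = tau_base + tau_amp / (exp((V - v_mid)/slope_up) + exp(-(V - v_mid)/slope_down))``

which is strictly positive and peaks near ``v_mid``.  Gating rates scale
with temperature as ``q10**((T - t_ref)/10)``; time constants divide by the
same factor.  Conductance amplitudes are not temperature scaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TauBell",
    "GateKinetics",
    "steady_state_activation",
    "time_constant",
    "gate_derivative",
    "temperature_factor",
]


@dataclass(frozen=True)
class TauBell:
    """Bell-shaped tau(V) in ms: base + amp / (exp((V-v)/a) + exp(-(V-v)/b))."""

    tau_base_ms: float
    tau_amp_ms: float
    v_mid_mV: float
    slope_up_mV: float
    slope_down_mV: float

    def __post_init__(self) -> None:
        if self.tau_base_ms < 0 or self.tau_amp_ms < 0:
            raise ValueError("tau parameters must be non-negative")
        if self.tau_base_ms == 0 and self.tau_amp_ms == 0:
            raise ValueError("tau(V) would be identically zero")
        if self.slope_up_mV <= 0 or self.slope_down_mV <= 0:
            raise ValueError("tau slopes must be positive")

    def __call__(self, v_mV):
        x = np.asarray(v_mV, dtype=float) - self.v_mid_mV
        return self.tau_base_ms + self.tau_amp_ms / (
            np.exp(x / self.slope_up_mV) + np.exp(-x / self.slope_down_mV)
        )


@dataclass(frozen=True)
class GateKinetics:
    """One activation gate: Boltzmann steady state plus bell tau(V).

    v_half_mV / slope_k_mV are the half-activation voltage and slope factor
    of the steady-state Boltzmann; exponent_p is the HH power on the gate;
    q10 and t_ref_C control the virtual-temperature scaling of rates.
    """

    v_half_mV: float
    slope_k_mV: float
    tau: TauBell
    exponent_p: int = 1
    q10: float = 3.0
    t_ref_C: float = 20.0

    def __post_init__(self) -> None:
        if self.slope_k_mV <= 0:
            raise ValueError("slope_k must be positive")
        if self.exponent_p < 1 or int(self.exponent_p) != self.exponent_p:
            raise ValueError("exponent_p must be a positive integer")
        if self.q10 <= 0:
            raise ValueError("q10 must be positive")


def temperature_factor(q10: float, temperature_C: float, t_ref_C: float) -> float:
    """Rate multiplier q10**((T - t_ref)/10); equals 1 at the reference."""
    return q10 ** ((temperature_C - t_ref_C) / 10.0)


def steady_state_activation(v_mV, gate: GateKinetics):
    """Boltzmann open fraction m_inf(V) = 1/(1 + exp((v_half - V)/k))."""
    v = np.asarray(v_mV, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage must be finite")
    out = 1.0 / (1.0 + np.exp((gate.v_half_mV - v) / gate.slope_k_mV))
    return out if out.ndim else float(out)


def time_constant(v_mV, gate: GateKinetics, temperature_C: float | None = None):
    """tau(V) in ms at the given virtual temperature (default: the gate's reference)."""
    if gate.tau is None:
        raise ValueError(f"gate has no calibrated tau parameters")
    tau = gate.tau(v_mV)
    if temperature_C is not None:
        tau = tau / temperature_factor(gate.q10, temperature_C, gate.t_ref_C)
    return tau if np.ndim(tau) else float(tau)


def gate_derivative(m, v_mV, gate: GateKinetics, temperature_C: float | None = None):
    """First-order relaxation dm/dt = (m_inf(V) - m)/tau(V, T) in 1/ms."""
    m_arr = np.asarray(m, dtype=float)
    if np.any((m_arr < 0.0) | (m_arr > 1.0)):
        raise ValueError("open fraction m must lie in [0, 1]")
    dm = (steady_state_activation(v_mV, gate) - m_arr) / time_constant(
        v_mV, gate, temperature_C
    )
    return dm if dm.ndim else float(dm)
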