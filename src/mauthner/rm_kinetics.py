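"""Base-cell channel kinetics (Nav, high-threshold K, A-type K).

Rate functions follow the ventral cochlear nucleus neuron model of
Rothman & Manis (2003), which is the published starting point for the
Mauthner base cell.  All steady states and time constants are defined at a
reference temperature of 22 C; rates scale with q10 = 3.  A per-channel
``rate_scale`` multiplies all of that channel's rates (divides its time
constants) and is the single calibration knob used to pin the base cell to
its documented firing outcomes (see mcell.CALIBRATION).

Conductances:
    Nav:  gbar * m^3 * h          (activation m, inactivation h)
    Kht:  gbar * (0.85 n^2 + 0.15 p)
    KA:   gbar * a^4 * b * c
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "T_REF_C",
    "Q10",
    "nav_m_inf", "nav_tau_m", "nav_h_inf", "nav_tau_h",
    "kht_n_inf", "kht_tau_n", "kht_p_inf", "kht_tau_p",
    "ka_a_inf", "ka_tau_a", "ka_b_inf", "ka_tau_b", "ka_c_inf", "ka_tau_c",
]

T_REF_C = 22.0
Q10 = 3.0


# --- fast Na+ ---------------------------------------------------------------

def nav_m_inf(v):
    return 1.0 / (1.0 + np.exp(-(v + 38.0) / 7.0))


def nav_tau_m(v):
    return 10.0 / (5.0 * np.exp((v + 60.0) / 18.0)
                   + 36.0 * np.exp(-(v + 60.0) / 25.0)) + 0.04


def nav_h_inf(v):
    return 1.0 / (1.0 + np.exp((v + 65.0) / 6.0))


def nav_tau_h(v):
    return 100.0 / (7.0 * np.exp((v + 60.0) / 11.0)
                    + 10.0 * np.exp(-(v + 60.0) / 25.0)) + 0.6


# --- high-threshold K+ ------------------------------------------------------

def kht_n_inf(v):
    return (1.0 / (1.0 + np.exp(-(v + 15.0) / 5.0))) ** 0.5


def kht_tau_n(v):
    return 100.0 / (11.0 * np.exp((v + 60.0) / 24.0)
                    + 21.0 * np.exp(-(v + 60.0) / 23.0)) + 0.7


def kht_p_inf(v):
    return 1.0 / (1.0 + np.exp(-(v + 23.0) / 6.0))


def kht_tau_p(v):
    return 100.0 / (4.0 * np.exp((v + 60.0) / 32.0)
                    + 5.0 * np.exp(-(v + 60.0) / 22.0)) + 5.0


# --- A-type (transient) K+ --------------------------------------------------

def ka_a_inf(v):
    return (1.0 / (1.0 + np.exp(-(v + 31.0) / 6.0))) ** 0.25


def ka_tau_a(v):
    return 100.0 / (7.0 * np.exp((v + 60.0) / 14.0)
                    + 29.0 * np.exp(-(v + 60.0) / 24.0)) + 0.1


def ka_b_inf(v):
    return (1.0 / (1.0 + np.exp((v + 66.0) / 7.0))) ** 0.5


def ka_tau_b(v):
    return 1000.0 / (14.0 * np.exp((v + 60.0) / 27.0)
                     + 29.0 * np.exp(-(v + 60.0) / 24.0)) + 1.0


def ka_c_inf(v):
    return (1.0 / (1.0 + np.exp((v + 66.0) / 7.0))) ** 0.5


def ka_tau_c(v):
    return 90.0 / (1.0 + np.exp(-(66.0 + v) / 17.0)) + 10.0
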