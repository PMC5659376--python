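"""Integration kernel for the single-compartment M-cell model.

Staggered scheme standard for HH systems: each gate advances one step with
exponential Euler (exact for the locally frozen voltage), then the membrane
potential advances with an implicit (backward-Euler) update using the fresh
gate values, which is unconditionally stable:

    V_{n+1} = (V_n + dt/C * (sum_i g_i E_i + I)) / (1 + dt/C * sum_i g_i)

The kernel is compiled with numba when available and falls back to pure
Python otherwise (identical arithmetic, slower).

State layout: gates = [m, h, n, p, a, b, c, w, u] for Nav(m3h),
Kht(0.85 n^2 + 0.15 p), KA(a^4 b c), Kv7.4(w), Kv1-type(u).

Parameter vector layout (float64, length 33):
  0  C_pF
  1..6  gbar nS: nav, kht, ka, leak, kv74, kv1
  7..9  e_rev mV: e_na, e_k, e_leak
  10..13 rate multipliers (q10 factor x calibration scale):
         nav, kht, ka, low-threshold
  14..20 Kv7.4 gate: v_half, k, tau_base, tau_amp, v_mid, slope_up, slope_down
  21..27 Kv1-type gate: same layout
  28..31 calibration voltage shifts (mV): nav_m, nav_h, kht, ka
         (positive shift moves that gate's voltage dependence rightward)
  32     separate rate multiplier for Nav inactivation (h); params[10]
         then applies to activation (m) only
"""

from __future__ import annotations

import math

import numpy as np

N_PARAMS = 33
N_GATES = 9


def _integrate(v0, gates0, params, i_stim, dt, v_out, g_out, record_g):
    C = params[0]
    g_nav = params[1]
    g_kht = params[2]
    g_ka = params[3]
    g_leak = params[4]
    g_kv74 = params[5]
    g_kv1 = params[6]
    e_na = params[7]
    e_k = params[8]
    e_leak = params[9]
    r_nav = params[10]
    r_kht = params[11]
    r_ka = params[12]
    r_lt = params[13]

    v = v0
    m = gates0[0]
    h = gates0[1]
    n = gates0[2]
    p = gates0[3]
    a = gates0[4]
    b = gates0[5]
    c = gates0[6]
    w = gates0[7]
    u = gates0[8]

    v_out[0] = v
    if record_g:
        g_out[0, 0] = g_nav * m * m * m * h
        g_out[0, 1] = g_kht * (0.85 * n * n + 0.15 * p)
        g_out[0, 2] = g_ka * a * a * a * a * b * c
        g_out[0, 3] = g_kv74 * w
        g_out[0, 4] = g_kv1 * u

    r_nav_h = params[32]
    s_m = params[28]
    s_h = params[29]
    s_kht = params[30]
    s_ka = params[31]

    nt = i_stim.shape[0]
    for k in range(nt):
        # --- gate updates (exponential Euler at frozen v) ---
        # Nav
        vm = v - s_m
        vh = v - s_h
        minf = 1.0 / (1.0 + math.exp(-(vm + 38.0) / 7.0))
        taum = (10.0 / (5.0 * math.exp((vm + 60.0) / 18.0)
                        + 36.0 * math.exp(-(vm + 60.0) / 25.0)) + 0.04) / r_nav
        hinf = 1.0 / (1.0 + math.exp((vh + 65.0) / 6.0))
        tauh = (100.0 / (7.0 * math.exp((vh + 60.0) / 11.0)
                         + 10.0 * math.exp(-(vh + 60.0) / 25.0)) + 0.6) / r_nav_h
        m = minf + (m - minf) * math.exp(-dt / taum)
        h = hinf + (h - hinf) * math.exp(-dt / tauh)
        # Kht
        vk = v - s_kht
        ninf = math.sqrt(1.0 / (1.0 + math.exp(-(vk + 15.0) / 5.0)))
        taun = (100.0 / (11.0 * math.exp((vk + 60.0) / 24.0)
                         + 21.0 * math.exp(-(vk + 60.0) / 23.0)) + 0.7) / r_kht
        pinf = 1.0 / (1.0 + math.exp(-(vk + 23.0) / 6.0))
        taup = (100.0 / (4.0 * math.exp((vk + 60.0) / 32.0)
                         + 5.0 * math.exp(-(vk + 60.0) / 22.0)) + 5.0) / r_kht
        n = ninf + (n - ninf) * math.exp(-dt / taun)
        p = pinf + (p - pinf) * math.exp(-dt / taup)
        # KA
        va = v - s_ka
        ainf = (1.0 / (1.0 + math.exp(-(va + 31.0) / 6.0))) ** 0.25
        taua = (100.0 / (7.0 * math.exp((va + 60.0) / 14.0)
                         + 29.0 * math.exp(-(va + 60.0) / 24.0)) + 0.1) / r_ka
        binf = math.sqrt(1.0 / (1.0 + math.exp((va + 66.0) / 7.0)))
        taub = (1000.0 / (14.0 * math.exp((va + 60.0) / 27.0)
                          + 29.0 * math.exp(-(va + 60.0) / 24.0)) + 1.0) / r_ka
        cinf = binf
        tauc = (90.0 / (1.0 + math.exp(-(66.0 + va) / 17.0)) + 10.0) / r_ka
        a = ainf + (a - ainf) * math.exp(-dt / taua)
        b = binf + (b - binf) * math.exp(-dt / taub)
        c = cinf + (c - cinf) * math.exp(-dt / tauc)
        # Kv7.4
        winf = 1.0 / (1.0 + math.exp((params[14] - v) / params[15]))
        x = v - params[18]
        tauw = (params[16] + params[17] / (math.exp(x / params[19])
                                           + math.exp(-x / params[20]))) / r_lt
        w = winf + (w - winf) * math.exp(-dt / tauw)
        # Kv1-type
        uinf = 1.0 / (1.0 + math.exp((params[21] - v) / params[22]))
        x = v - params[25]
        tauu = (params[23] + params[24] / (math.exp(x / params[26])
                                           + math.exp(-x / params[27]))) / r_lt
        u = uinf + (u - uinf) * math.exp(-dt / tauu)

        # --- implicit voltage update with fresh gates ---
        gna = g_nav * m * m * m * h
        gk = g_kht * (0.85 * n * n + 0.15 * p)
        ga = g_ka * a * a * a * a * b * c
        g74 = g_kv74 * w
        g1 = g_kv1 * u
        gsum = gna + gk + ga + g_leak + g74 + g1
        gesum = (gna * e_na + (gk + ga + g74 + g1) * e_k + g_leak * e_leak)
        # nS * mV / pF = pA / pF = mV/ms
        v = (v + dt / C * (gesum + i_stim[k])) / (1.0 + dt / C * gsum)

        v_out[k + 1] = v
        if record_g:
            g_out[k + 1, 0] = gna
            g_out[k + 1, 1] = gk
            g_out[k + 1, 2] = ga
            g_out[k + 1, 3] = g74
            g_out[k + 1, 4] = g1
        if v > 200.0 or v < -200.0:
            return k + 1  # blow-up at this sample

    gates0[0] = m
    gates0[1] = h
    gates0[2] = n
    gates0[3] = p
    gates0[4] = a
    gates0[5] = b
    gates0[6] = c
    gates0[7] = w
    gates0[8] = u
    return 0


try:  # optional acceleration; the pure-Python kernel is the reference
    from numba import njit

    _integrate = njit(cache=False, fastmath=False)(_integrate)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False


def integrate(v0, gates, params, i_stim, dt, record_conductances=False):
    """Run the kernel; returns (v_trace, g_traces or None); mutates `gates`.

    Raises RuntimeError on numerical blow-up (|V| > 200 mV).
    """
    i_stim = np.ascontiguousarray(i_stim, dtype=np.float64)
    v_out = np.empty(i_stim.size + 1)
    g_out = np.empty((i_stim.size + 1, 5) if record_conductances else (1, 5))
    bad = _integrate(
        float(v0), gates, params, i_stim, float(dt), v_out, g_out,
        bool(record_conductances),
    )
    if bad:
        t_bad = bad * dt
        raise RuntimeError(
            f"membrane potential left [-200, 200] mV at t = {t_bad:.3f} ms "
            f"(dt = {dt} ms); reduce dt or check conductances"
        )
    return v_out, (g_out if record_conductances else None)
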