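import numpy as np
import pytest

from mauthner import (VClampProtocol, fit_boltzmann, fit_channel_gv, gv_curve,
                      p4_subtract, peak_conductance, rise_time_half,
                      run_voltage_clamp)
from mauthner.channels import ChannelModel
from mauthner.gating import GateKinetics, TauBell, steady_state_activation


def _channel(v_half=-35.4, k=7.4, tau_ms=3.0, gbar=30000.0):
    gate = GateKinetics(v_half, k, TauBell(tau_ms, 0.0, -50.0, 20.0, 15.0))
    return ChannelModel("test", gbar, -90.0, "boltzmann", gate)


def test_step_at_reversal_gives_zero_current():
    ch = _channel()
    prot = VClampProtocol(step_levels_mV=(-90.0,), step_duration_ms=50.0)
    traces = run_voltage_clamp(ch, prot)
    step = (traces.time_ms >= 10) & (traces.time_ms < 60)
    assert np.allclose(traces.currents_uA[0][step], 0.0)


def test_step_at_holding_is_constant():
    ch = _channel()
    prot = VClampProtocol(step_levels_mV=(-80.0,), step_duration_ms=50.0)
    traces = run_voltage_clamp(ch, prot)
    assert np.ptp(traces.currents_uA[0]) == pytest.approx(0.0, abs=1e-12)


def test_first_order_rise_matches_closed_form():
    """For p = 1 from m ~ 0: I(t)/I(inf) = 1 - exp(-t/tau)."""
    ch = _channel(v_half=0.0, k=8.0, tau_ms=5.0)
    prot = VClampProtocol(holding_mV=-120.0, step_levels_mV=(50.0,),
                          step_duration_ms=100.0, sample_interval_ms=0.05)
    traces = run_voltage_clamp(ch, prot)
    t = traces.time_ms
    i = traces.trace(50.0)
    sel = (t >= prot.pre_duration_ms) & (t < prot.pre_duration_ms + 100.0)
    ts = t[sel] - prot.pre_duration_ms
    m_inf = steady_state_activation(50.0, ch.gate)
    m0 = steady_state_activation(-120.0, ch.gate)
    expected = ch.gbar_nS * (m_inf + (m0 - m_inf) * np.exp(-ts / 5.0)) * (50.0 + 90.0) / 1e6
    assert np.allclose(i[sel], expected, rtol=1e-9)


class TestP4:
    time = np.arange(0, 100.0, 0.1)

    def _sweeps(self, f, holding=-80.0, v=40.0):
        """Build main + 4 subsweeps from a current law I(t, V_cmd)."""
        main = f(self.time, v)
        subs = [f(self.time, holding + (v - holding) / 4)] * 4
        return main, subs

    def test_pure_ohmic_leak_cancels(self):
        g, e = 2.0, -20.0  # leak reversal far from holding

        def law(t, v_cmd):
            v = np.where((t >= 10) & (t < 60), v_cmd, -80.0)
            return g * (v - e)

        main, subs = self._sweeps(law)
        corrected = p4_subtract(main, subs, self.time, step_onset_ms=10.0)
        assert np.allclose(corrected, 0.0, atol=1e-9)

    def test_affine_in_command_voltage_cancels(self):
        def law(t, v_cmd):
            on = (t >= 10) & (t < 60)
            return 3.0 + 0.05 * np.where(on, v_cmd, -80.0) \
                + 0.7 * np.where(on, v_cmd + 80.0, 0.0) * np.exp(-t / 5.0)

        main, subs = self._sweeps(law)
        corrected = p4_subtract(main, subs, self.time, step_onset_ms=10.0)
        assert np.max(np.abs(corrected)) < 1e-9

    def test_leak_plus_channel_recovers_channel(self):
        rng = np.random.default_rng(7)
        channel = np.where(self.time >= 10, 1 - np.exp(-(self.time - 10) / 8.0), 0.0)

        def law(t, v_cmd):
            on = (t >= 10) & (t < 60)
            return 0.04 * np.where(on, v_cmd + 80.0, 0.0)

        main, subs = self._sweeps(law)
        corrected = p4_subtract(main + channel, subs, self.time, step_onset_ms=10.0)
        assert np.max(np.abs(corrected - channel)) < 1e-9 * channel.max() + 1e-12

    def test_zero_main_gives_zero(self):
        zero = np.zeros_like(self.time)
        assert np.allclose(p4_subtract(zero, [zero] * 4), 0.0)

    def test_mismatched_time_base_rejected(self):
        with pytest.raises(ValueError):
            p4_subtract(np.zeros(100), [np.zeros(50)] * 4)


class TestPeakConductance:
    def test_arithmetic(self):
        trace = np.array([0.0, 1.0, 0.5])
        # 1 uA at (V - E) = 50 mV -> 0.02 mS = 20 uS
        assert peak_conductance(trace, -40.0, -90.0) == pytest.approx(20.0)

    def test_zero_trace(self):
        assert peak_conductance(np.zeros(10), -40.0, -90.0) == 0.0

    def test_reversal_rejected(self):
        with pytest.raises(ValueError):
            peak_conductance(np.ones(10), -90.0, -90.0)

    def test_long_step_approaches_gbar_times_minf(self, stock):
        ch = stock["Kv1.1"]
        prot = VClampProtocol(step_levels_mV=(0.0,), step_duration_ms=400.0)
        traces = run_voltage_clamp(ch, prot)
        g = peak_conductance(traces.trace(0.0), 0.0, ch.e_rev_mV,
                             traces.time_ms,
                             (traces.step_onset_ms, traces.step_offset_ms))
        expected_uS = ch.gbar_nS * steady_state_activation(0.0, ch.gate) / 1000.0
        assert g == pytest.approx(expected_uS, rel=1e-4)


class TestBoltzmannFit:
    def test_noiseless_round_trip(self):
        v = np.arange(-80.0, 51.0, 10.0)
        g = 30.0 / (1 + np.exp((-35.4 - v) / 7.4))
        fit = fit_boltzmann(v, g)
        assert fit.v_half_mV == pytest.approx(-35.4, abs=0.1)
        assert fit.slope_k_mV == pytest.approx(7.4, abs=0.1)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_boltzmann(np.arange(-80.0, 51.0, 10.0), np.zeros(14))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_boltzmann([0.0, 10.0], [1.0, 2.0])

    def test_noisy_recovery(self, rng):
        v = np.arange(-80.0, 51.0, 10.0)
        g = 30.0 / (1 + np.exp((-35.4 - v) / 7.4))
        g_noisy = g + rng.normal(0, 0.02 * g.max(), g.size)
        fit = fit_boltzmann(v, g_noisy)
        assert fit.v_half_mV == pytest.approx(-35.4, abs=1.0)
        assert fit.slope_k_mV == pytest.approx(7.4, abs=0.5)


class TestRiseTime:
    def test_first_order_rise_gives_tau_ln2(self):
        t = np.arange(0, 200.0, 0.01)
        tau = 6.0
        trace = np.where(t >= 20, 1 - np.exp(-(t - 20) / tau), 0.0)
        t_half = rise_time_half(trace, t, 20.0, 190.0)
        # half of the within-step end value, not of the asymptote
        end = 1 - np.exp(-170.0 / tau)
        expected = -tau * np.log(1 - 0.5 * end)
        assert t_half == pytest.approx(expected, abs=0.02)

    def test_instantaneous_step_is_zero_within_one_sample(self):
        t = np.arange(0, 50.0, 0.1)
        trace = np.where(t >= 10, 1.0, 0.0)
        assert rise_time_half(trace, t, 10.0) <= 0.1

    def test_flat_trace_rejected(self):
        t = np.arange(0, 50.0, 0.1)
        with pytest.raises(ValueError):
            rise_time_half(np.zeros_like(t), t, 10.0)

    def test_halving_sample_interval_changes_thalf_under_one_percent(self, stock):
        vals = []
        for si in (0.1, 0.05):
            prot = VClampProtocol(sample_interval_ms=si)
            tr = run_voltage_clamp(stock["Kv1.1"], prot)
            vals.append(rise_time_half(tr.trace(0.0), tr.time_ms,
                                       tr.step_onset_ms, tr.step_offset_ms))
        assert abs(vals[1] - vals[0]) / vals[0] < 0.01


def test_gv_nondecreasing_for_stock_channels(stock, protocol):
    for name in ("Kv7.4", "Kv1.1", "Kv1.1+Kvb2"):
        traces = run_voltage_clamp(stock[name], protocol)
        v, g = gv_curve(traces, stock[name].e_rev_mV)
        order = np.argsort(v)
        assert np.all(np.diff(g[order]) >= -1e-9)


@pytest.mark.parametrize("name, v_half, k", [
    ("Kv7.4", -10.1, 15.4),
    ("Kv1.1", -35.4, 7.4),
    ("Kv1.1+Kvb2", -36.6, 9.4),
])
def test_pipeline_recovers_measured_boltzmann(stock, name, v_half, k):
    """Clamp emulation -> peak G-V -> fit reproduces the oocyte parameters."""
    fit = fit_channel_gv(stock[name])
    assert fit.v_half_mV == pytest.approx(v_half, abs=0.5)
    assert fit.slope_k_mV == pytest.approx(k, abs=0.3)
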