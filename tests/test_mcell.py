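import numpy as np
import pytest

from mauthner import (MCellModel, PulseTrainStimulus, StepStimulus,
                      conductance_timecourses, developmental_presets,
                      find_threshold, run_intensity_series,
                      simulate_current_clamp)
from mauthner.mcell import PRESET_TABLE
from mauthner.metrics import detect_spikes


def test_rest_without_low_threshold_conductances(base_model):
    trace = simulate_current_clamp(base_model, StepStimulus(0.0))
    assert abs(trace.rest_mV + 85.0) < 1.0
    post = trace.v_mV[trace.time_ms >= 0]
    assert np.all(np.abs(post + 85.0) < 1.0)


def test_passive_membrane_time_constant_matches_rc():
    """Leak-only model charges with tau_m = C/g_leak ~ 4.19 ms."""
    m = MCellModel(g_nav_nS=0.0, g_kht_nS=0.0, g_ka_nS=0.0)
    step = StepStimulus(10.0, duration_ms=60.0)
    tr = simulate_current_clamp(m, step, dt_ms=0.0125)
    sel = (tr.time_ms >= 0) & (tr.time_ms < 60)
    v = tr.v_mV[sel] - tr.rest_mV
    t = tr.time_ms[sel]
    v_inf = 10.0 / 12.0  # I/g_leak
    tau = 50.26548245743669 / 12.0
    assert np.allclose(v, v_inf * (1 - np.exp(-t / tau)), atol=0.25 * v_inf * 0.01 + 1e-4)


def test_base_model_fires_tonically_through_the_step(base_model):
    T = find_threshold(base_model)
    tr = run_intensity_series(base_model, T)[2.0]
    train = detect_spikes(tr)
    assert train.n_spikes >= 3
    assert train.times_ms[-1] >= 80.0  # spikes span the 100-ms pulse


def test_threshold_is_minimal_firing_amplitude(base_model):
    T = find_threshold(base_model)
    at_T = simulate_current_clamp(base_model, StepStimulus(float(T)))
    below = simulate_current_clamp(base_model, StepStimulus(float(T - 1)))
    assert detect_spikes(at_T).n_spikes >= 1
    assert detect_spikes(below).n_spikes == 0


def test_threshold_bisection_agrees_with_exhaustive_scan(base_model):
    assert find_threshold(base_model, verify_exhaustive=True) == \
        find_threshold(base_model)


def test_no_spike_below_ceiling_reported():
    # without Nav the cell cannot reach the detection level at 200 pA
    passive = MCellModel(g_nav_nS=0.0)
    with pytest.raises(RuntimeError, match="ceiling"):
        find_threshold(passive, ceiling_pA=200)


def test_intensity_series_amplitudes_rounded(base_model):
    T = find_threshold(base_model)
    traces = run_intensity_series(base_model, T, multiples=(1.0, 1.5, 2.0))
    for mult, tr in traces.items():
        assert tr.stimulus.amplitude_pA == round(mult * T)


def test_dt_halving_preserves_spike_counts_and_latency(base_model):
    T = find_threshold(base_model)
    counts, latencies = {}, {}
    for dt in (0.025, 0.0125):
        traces = run_intensity_series(base_model, T, dt_ms=dt)
        counts[dt] = {m: detect_spikes(tr).n_spikes for m, tr in traces.items()}
        latencies[dt] = detect_spikes(traces[1.0]).crossing_times_ms[0]
    assert counts[0.025] == counts[0.0125]
    assert abs(latencies[0.025] - latencies[0.0125]) / latencies[0.025] < 0.02


def test_presets_settle_near_rest():
    # Kv7.4's small resting activation pulls the 4dpf preset a couple of
    # mV toward E_K; the settling window absorbs the transient
    for stage in ("base", "2dpf", "4dpf"):
        tr = simulate_current_clamp(developmental_presets(stage), StepStimulus(0.0))
        assert abs(tr.rest_mV + 85.0) < 3.0


class TestPresets:
    def test_table_values(self):
        assert PRESET_TABLE["2dpf"] == (700.0, 150.0, False)
        assert PRESET_TABLE["4dpf"] == (1400.0, 700.0, True)

    def test_fold_changes(self):
        two = developmental_presets("2dpf")
        four = developmental_presets("4dpf")
        assert four.g_kv74_nS / two.g_kv74_nS == pytest.approx(2.0)
        assert round(four.g_kv1_nS / two.g_kv1_nS, 1) == 4.7

    def test_pharmacology_suffixes(self):
        m = developmental_presets("2dpf+XE991")
        assert (m.g_kv74_nS, m.g_kv1_nS) == (0.0, 150.0)
        m = developmental_presets("4dpf+DTX")
        assert (m.g_kv74_nS, m.g_kv1_nS) == (1400.0, 0.0)
        m = developmental_presets("4dpf+DTX+XE991")
        assert (m.g_kv74_nS, m.g_kv1_nS) == (0.0, 0.0)

    def test_unknown_labels_rejected(self):
        with pytest.raises(KeyError):
            developmental_presets("6dpf")
        with pytest.raises(KeyError):
            developmental_presets("2dpf+TTX")


class TestConductanceTimecourses:
    def test_zero_conductance_trace_is_zero(self, base_model):
        out = conductance_timecourses(base_model, StepStimulus(300.0))
        assert np.nanmax(out["raw_nS"]["Kv7.4"]) == 0.0

    def test_normalization(self):
        m = developmental_presets("4dpf")
        T = find_threshold(m)
        out = conductance_timecourses(m, StepStimulus(round(1.5 * T)))
        norm = out["normalized"]
        assert np.nanmax(norm["Nav"]) == pytest.approx(1.0)
        k_max = max(np.nanmax(norm[n]) for n in norm if n != "Nav")
        assert k_max == pytest.approx(1.0)
        for arr in norm.values():
            assert np.nanmax(arr) <= 1.0 + 1e-12

    def test_kvb2_activates_before_kv74(self):
        """Fast Kv1.1+Kvb2 reaches half-activation before slow Kv7.4."""
        m = developmental_presets("4dpf")
        T = find_threshold(m)
        out = conductance_timecourses(m, StepStimulus(round(1.5 * T)))
        t = out["time_ms"]

        def t_half(name):
            g = out["raw_nS"][name]
            valid = ~np.isnan(g)
            peak = np.nanmax(g)
            idx = np.nonzero(valid & (g >= 0.5 * peak))[0][0]
            return t[idx]

        assert t_half("Kv1.1+Kvb2") < t_half("Kv7.4")


def test_pulse_train_stimulus_shape():
    stim = PulseTrainStimulus(1000.0)
    t = np.arange(0, 100, 0.025)
    i = stim.current_pA(t)
    # 50 pulses of 0.5 ms at 2-ms period within 100 ms
    assert i.max() == 1000.0
    on_fraction = (i > 0).mean()
    assert on_fraction == pytest.approx(0.25, abs=0.01)
    with pytest.raises(ValueError):
        PulseTrainStimulus(1000.0, pulse_width_ms=3.0, frequency_Hz=500.0)


def test_simulation_is_deterministic(base_model):
    a = simulate_current_clamp(base_model, StepStimulus(300.0))
    b = simulate_current_clamp(MCellModel(), StepStimulus(300.0))
    assert np.array_equal(a.v_mV, b.v_mV)
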