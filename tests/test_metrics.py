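import numpy as np
import pytest

from mauthner import (DetectionParams, FiringMetrics, classify_phenotype,
                      compute_metrics, detect_spikes)
from mauthner.metrics import SpikeTrain


class FakeTrace:
    def __init__(self, time_ms, v_mV, window=(0.0, 100.0)):
        self.time_ms = np.asarray(time_ms, dtype=float)
        self.v_mV = np.asarray(v_mV, dtype=float)
        self.stim_window_ms = window


def _triangle(t, center, width=1.0, peak=-5.0, base=-85.0):
    return base + (peak - base) * np.clip(1 - np.abs(t - center) / width, 0, 1)


class TestDetectSpikes:
    def test_flat_trace_yields_empty_train(self):
        t = np.arange(0, 100, 0.025)
        train = detect_spikes(FakeTrace(t, np.full_like(t, -85.0)))
        assert train.n_spikes == 0

    def test_three_triangular_deflections(self):
        t = np.arange(0, 100, 0.025)
        v = np.full_like(t, -85.0)
        for c in (20.0, 40.0, 60.0):
            v = np.maximum(v, _triangle(t, c))
        train = detect_spikes(FakeTrace(t, v))
        assert train.n_spikes == 3
        assert train.times_ms == pytest.approx((20.0, 40.0, 60.0), abs=0.05)

    def test_spikes_outside_stimulus_window_excluded(self):
        t = np.arange(0, 100, 0.025)
        v = np.maximum(np.full_like(t, -85.0), _triangle(t, 80.0))
        train = detect_spikes(FakeTrace(t, v, window=(0.0, 50.0)))
        assert train.n_spikes == 0

    def test_refractory_separation(self):
        t = np.arange(0, 10, 0.025)
        # two crossings 0.2 ms apart -> one detection at 0.5-ms refractory
        v = np.maximum(_triangle(t, 5.0, width=0.15), _triangle(t, 5.2, width=0.15))
        train = detect_spikes(FakeTrace(t, v, window=(0.0, 10.0)))
        assert train.n_spikes == 1

    def test_nonuniform_time_base_rejected(self):
        t = np.array([0.0, 1.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            detect_spikes(FakeTrace(t, np.zeros(4)))

    def test_idempotent_on_custom_threshold(self):
        t = np.arange(0, 50, 0.025)
        v = np.maximum(np.full_like(t, -85.0), _triangle(t, 25.0))
        p = DetectionParams(threshold_mV=-50.0)
        a = detect_spikes(FakeTrace(t, v), p)
        b = detect_spikes(FakeTrace(t, v), p)
        assert a.times_ms == b.times_ms


def _train(times):
    return SpikeTrain(times_ms=tuple(times), crossing_times_ms=tuple(times))


class TestComputeMetrics:
    def test_regular_train_ratio_one(self):
        trains = {1.0: _train([5.0]), 1.5: _train([5, 15, 25]),
                  2.0: _train([4, 14, 24, 34])}
        m = compute_metrics(trains, 100)
        assert m.adaptation_ratio == pytest.approx(1.0)
        assert m.latency_1T_ms == 5.0

    def test_two_spikes_ratio_undefined(self):
        trains = {1.0: _train([5.0]), 1.5: _train([5.0]), 2.0: _train([4, 30])}
        m = compute_metrics(trains, 100)
        assert m.adaptation_ratio is None
        assert m.isi_2T_ms == (26.0,)

    def test_empty_1T_train_is_contract_violation(self):
        with pytest.raises(ValueError):
            compute_metrics({1.0: _train([]), 2.0: _train([5.0])}, 100)

    def test_increasing_isi_gives_ratio_above_one(self):
        trains = {1.0: _train([5.0]), 1.5: _train([5, 15]),
                  2.0: _train([4, 10, 20, 40])}
        assert compute_metrics(trains, 100).adaptation_ratio > 1


def _metrics(n15, n2, last2, ratio):
    return FiringMetrics(threshold_pA=100, latency_1T_ms=5.0,
                         n_spikes={1.0: 1, 1.5: n15, 2.0: n2},
                         isi_2T_ms=(), adaptation_ratio=ratio,
                         last_spike_2T_ms=last2, stim_duration_ms=100.0)


class TestClassifyPhenotype:
    @pytest.mark.parametrize("m, label", [
        (_metrics(1, 1, 2.0, None), "single_spiking"),
        (_metrics(5, 8, 95.0, 1.0), "tonic"),
        (_metrics(5, 8, 95.0, 3.0), "phasic_long"),   # strong adaptation
        (_metrics(3, 4, 60.0, 1.2), "phasic_long"),   # stops before final 20%
        (_metrics(2, 3, 30.0, 1.2), "phasic_short"),
        (_metrics(1, 0, None, None), "non_firing"),
    ])
    def test_rules(self, m, label):
        assert classify_phenotype(m) == label

    def test_exactly_one_label(self):
        for m in (_metrics(1, 1, 2.0, None), _metrics(4, 6, 90.0, 1.1),
                  _metrics(2, 2, 20.0, None)):
            assert classify_phenotype(m) in (
                "tonic", "phasic_long", "phasic_short", "single_spiking",
                "non_firing")

    def test_incomplete_metrics_rejected(self):
        m = FiringMetrics(100, 5.0, {1.0: 1}, (), None, None, 100.0)
        with pytest.raises(ValueError):
            classify_phenotype(m)
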