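"""Event detection and measurement: thresholds, onset rules, amplitude and
half-duration definitions, transfer pairing, derived measures."""

import numpy as np
import pytest

from cacc import (NeuronConfig, Trace, amplitude_noise_ratio,
                  amplitude_response, detect_aps_ca, detect_aps_wc,
                  detect_spsps, dominant_frequency, event_onset,
                  evoked_amplitude, filter_trace, measure_event,
                  pair_and_transfer)
from cacc.synthesize import ap_template, psp_waveform

RATE = 5000.0


def _insert(samples, idx, waveform):
    end = min(idx + waveform.size, samples.size)
    samples[idx:end] += waveform[: end - idx]


class TestDetectApsWc:
    def test_template_spikes_recovered_at_ground_truth_times(self):
        neuron = NeuronConfig()
        w, pk, _ = ap_template(RATE, neuron)
        v = np.full(int(10 * RATE), -81.3)
        true_peaks = []
        for k in range(10):
            idx = int((0.5 + 0.9 * k) * RATE)
            _insert(v, idx, w)
            true_peaks.append((idx + pk) / RATE)
        aps = detect_aps_wc(Trace(v, RATE, "WC"), resting=-81.3)
        assert len(aps) == 10
        for ev, t_true in zip(aps, true_peaks):
            assert ev.peak_time == pytest.approx(t_true, abs=0.2e-3)

    def test_flat_trace_yields_no_events(self):
        assert detect_aps_wc(Trace(np.full(5000, -80.0), RATE, "WC")) == []

    def test_subthreshold_excursion_ignored(self):
        v = np.full(int(RATE), -80.0)
        t = (np.arange(v.size) - v.size // 2) / RATE
        v += 39.0 * np.exp(-(t ** 2) / (2 * 0.001 ** 2))  # peaks 39 mV above rest
        assert detect_aps_wc(Trace(v, RATE, "WC"), resting=-80.0) == []

    def test_measured_amplitude_matches_template(self):
        neuron = NeuronConfig()
        w, pk, amp = ap_template(RATE, neuron)
        v = np.full(int(2 * RATE), -81.3)
        _insert(v, int(0.5 * RATE), w)
        aps = detect_aps_wc(Trace(v, RATE, "WC"), resting=-81.3)
        assert len(aps) == 1
        assert aps[0].amplitude == pytest.approx(amp, rel=0.02)
        assert aps[0].half_duration == pytest.approx(neuron.ap_half_width * 1e3, rel=0.1)


class TestDetectApsCa:
    def test_single_filtered_spike_found_once(self, median_cell):
        neuron = NeuronConfig()
        w, pk, _ = ap_template(RATE, neuron)
        v = np.full(int(2 * RATE), -81.3)
        _insert(v, int(0.5 * RATE), w)
        ca = filter_trace(median_cell, Trace(v, RATE, "WC"))
        aps = detect_aps_ca(ca)
        assert len(aps) == 1
        assert aps[0].peak_time == pytest.approx((int(0.5 * RATE) + pk) / RATE, abs=2e-3)

    def test_false_positive_rate_on_pure_noise(self):
        # 0.2 mV Gaussian noise at 50 kHz, 1 kHz smoothing: < 0.1 Hz
        rng = np.random.default_rng(0)
        ca = Trace(0.2 * rng.standard_normal(int(20 * 50_000)), 50_000.0, "CA")
        aps = detect_aps_ca(ca, smooth_cutoff=1000.0)
        assert len(aps) / 20.0 < 0.1

    def test_wrong_channel_role_rejected(self):
        with pytest.raises(ValueError):
            detect_aps_ca(Trace(np.zeros(100), RATE, "WC"))


class TestDetectSpsps:
    def _psps(self, amplitudes, rise=1e-3, decay=112e-3, spacing=1.0):
        w, pk = psp_waveform(RATE, rise, decay)
        v = np.full(int((len(amplitudes) + 1) * spacing * RATE), -80.0)
        onsets = []
        for k, a in enumerate(amplitudes):
            idx = int((0.5 + k * spacing) * RATE)
            _insert(v, idx, a * w)
            onsets.append(idx / RATE)
        return Trace(v, RATE, "WC"), onsets

    def test_fast_rise_events_recovered(self):
        tr, onsets = self._psps([2.0] * 20)
        evs = detect_spsps(tr)
        assert len(evs) >= 18
        det = np.array([e.onset for e in evs])
        assert sum(np.min(np.abs(det - o)) < 5e-3 for o in onsets) >= 18

    def test_slow_rise_below_derivative_threshold_ignored(self):
        # ~0.5 mV/ms peak slope stays under the 1 mV/ms detection rule
        tr, _ = self._psps([2.0] * 5, rise=4e-3)
        assert detect_spsps(tr) == []

    def test_quiet_trace_empty(self):
        assert detect_spsps(Trace(np.full(20000, -80.0), RATE, "WC")) == []

    def test_ap_episodes_excluded(self):
        neuron = NeuronConfig()
        w_ap, pk, _ = ap_template(RATE, neuron)
        tr, onsets = self._psps([3.0] * 4, spacing=2.0)
        v = tr.samples.copy()
        _insert(v, int(1.0 * RATE), w_ap)  # one spike between PSPs
        evs = detect_spsps(Trace(v, RATE, "WC"))
        kinds = {e.kind for e in evs}
        assert kinds == {"PSP"}
        det = np.array([e.onset for e in evs])
        assert np.min(np.abs(det - 1.0)) > 5e-3  # nothing at the spike


class TestOnsetAndMeasure:
    def test_onset_of_linear_ramp_found_at_ramp_start(self):
        v = np.full(int(RATE), -80.0)
        ramp_start = int(0.5 * RATE)
        ramp = np.arange(int(0.01 * RATE)) / RATE * 1000.0  # 1 mV/ms for 10 ms
        _insert(v, ramp_start, ramp)
        v[ramp_start + ramp.size:] = v[ramp_start + ramp.size - 1]
        onset, flagged = event_onset(Trace(v, RATE, "WC"),
                                     (ramp_start + ramp.size) / RATE, 0.1,
                                     smooth_cutoff=None)
        assert not flagged
        assert onset == pytest.approx(ramp_start / RATE, abs=1e-3)

    def test_flat_then_peak_uses_flagged_fallback(self):
        v = np.full(int(RATE), -80.0)
        v[int(0.9 * RATE)] = -70.0  # isolated single-sample spike
        onset, flagged = event_onset(Trace(v, RATE, "WC"), 0.5, 10.0,
                                     smooth_cutoff=None)
        assert flagged
        assert onset == pytest.approx(0.5 - 0.1, abs=1e-3)

    def test_triangle_geometry(self):
        # symmetric triangle: amplitude = height, half-duration = base/2
        base_ms = 20.0
        half_base = int(base_ms / 2 * 1e-3 * RATE)
        v = np.full(int(RATE), -80.0)
        apex = int(0.5 * RATE)
        tri = 10.0 * (1 - np.abs(np.arange(-half_base, half_base + 1)) / half_base)
        _insert(v, apex - half_base, tri)
        ev = measure_event(Trace(v, RATE, "WC"), (apex - half_base) / RATE,
                           apex / RATE, smooth_cutoff=None)
        assert ev.amplitude == pytest.approx(10.0, abs=0.01)
        assert ev.half_duration == pytest.approx(base_ms / 2, rel=0.05)
        assert ev.onset_to_peak == pytest.approx(base_ms / 2, rel=0.05)

    def test_sloped_baseline_bias_bounded(self):
        # 0.1 mV/ms baseline drift biases the 1-5 ms-before-onset baseline
        w, pk = psp_waveform(RATE, 1e-3, 30e-3)
        n = int(RATE)
        drift = 0.1 * np.arange(n) / RATE * 1000.0
        v = -80.0 + drift
        onset_idx = int(0.5 * RATE)
        _insert(v, onset_idx, 10.0 * w)
        ev = measure_event(Trace(v, RATE, "WC"), onset_idx / RATE,
                           (onset_idx + pk) / RATE, smooth_cutoff=None)
        # analytic bias of the 1-5 ms pre-onset baseline under drift b:
        # baseline sits b*3ms below onset level, peak gains b*onset_to_peak
        expected_bias = 0.1 * (3.0 + ev.onset_to_peak)
        assert ev.amplitude - 10.0 == pytest.approx(expected_bias, abs=0.1)
        assert abs(ev.amplitude - 10.0) <= 0.8

    def test_negative_event_amplitude_signed(self):
        w, pk = psp_waveform(RATE, 1e-3, 30e-3)
        v = np.full(int(RATE), -60.0)
        _insert(v, int(0.5 * RATE), -2.0 * w)
        ev = measure_event(Trace(v, RATE, "WC"), 0.5, 0.5 + pk / RATE,
                           smooth_cutoff=None)
        assert ev.amplitude == pytest.approx(-2.0, abs=0.05)


class TestEvokedAmplitude:
    def _avg_trace(self, amp):
        w, _ = psp_waveform(RATE, 1e-3, 60e-3)
        v = np.full(int(RATE), -70.0)
        _insert(v, int(0.5 * RATE) + 5, amp * w)
        return Trace(v, RATE, "WC")

    def test_depolarizing_response_sign_and_size(self):
        assert evoked_amplitude(self._avg_trace(1.5), 0.5) == pytest.approx(1.5, abs=0.05)

    def test_hyperpolarizing_response_sign_preserved(self):
        assert evoked_amplitude(self._avg_trace(-2.0), 0.5) == pytest.approx(-2.0, abs=0.05)

    def test_flat_average_is_zero(self):
        tr = Trace(np.full(int(RATE), -70.0), RATE, "WC")
        assert evoked_amplitude(tr, 0.5) == pytest.approx(0.0, abs=1e-9)

    def test_window_outside_trace_rejected(self):
        tr = Trace(np.full(100, -70.0), RATE, "WC")
        with pytest.raises(ValueError):
            evoked_amplitude(tr, 0.01)


class TestDerivedMeasures:
    @pytest.mark.parametrize("half_width_ms,freq", [(1.389, 240.0), (85.5, 3.9),
                                                    (1000.0 / 3.0, 1.0)])
    def test_dominant_frequency_inversions(self, half_width_ms, freq):
        assert dominant_frequency(half_width_ms) == pytest.approx(freq, rel=0.01)

    def test_dominant_frequency_identity(self):
        rng = np.random.default_rng(1)
        for hw in rng.uniform(0.1, 500.0, size=50):
            assert dominant_frequency(hw) * 3.0 * hw * 1e-3 == pytest.approx(1.0, rel=1e-12)

    def test_dominant_frequency_domain(self):
        with pytest.raises(ValueError):
            dominant_frequency(0.0)

    def test_amplitude_noise_ratio(self):
        evs = [measure_event(Trace(np.full(100, 0.0), RATE, "WC"), 0.0, 0.0,
                             smooth_cutoff=None)]
        from dataclasses import replace
        evs = [replace(evs[0], amplitude=2.0)] * 3
        assert amplitude_noise_ratio(evs, 1.0) == pytest.approx(2.0)
        assert amplitude_noise_ratio(evs, 100.0) == pytest.approx(0.02)
        with pytest.raises(ValueError):
            amplitude_noise_ratio([], 1.0)


class TestPairAndTransfer:
    def test_identical_traces_give_unit_transfer(self):
        w, pk = psp_waveform(RATE, 1e-3, 50e-3)
        v = np.full(int(10 * RATE), -80.0)
        for k in range(8):
            _insert(v, int((0.5 + k) * RATE), 3.0 * w)
        wc = Trace(v, RATE, "WC")
        ca = Trace(v.copy(), RATE, "CA")
        evs = detect_spsps(wc)
        pairs, summary = pair_and_transfer(evs, ca, max_lag=20e-3)
        assert summary["n"] == len(evs) >= 7
        assert summary["ratio_median"] == pytest.approx(1.0, abs=0.02)
        assert summary["slope_through_origin"] == pytest.approx(1.0, abs=0.02)
        assert summary["pearson_r"] == pytest.approx(1.0, abs=0.01)

    def test_noiseless_ratio_matches_filtered_waveform_oracle(self, median_cell):
        w, pk = psp_waveform(RATE, 1e-3, 112e-3)
        v = np.full(int(10 * RATE), -80.0)
        for k in range(8):
            _insert(v, int((0.5 + k) * RATE), 3.0 * w)
        wc = Trace(v, RATE, "WC")
        ca = filter_trace(median_cell, wc)
        evs = detect_spsps(wc)
        pairs, summary = pair_and_transfer(evs, ca, max_lag=50e-3)
        # oracle: attenuation of the bare waveform through the same filter
        iso = np.concatenate([np.full(2000, -80.0), -80.0 + 3.0 * w,
                              np.full(2000, -80.0)])
        ca_iso = filter_trace(median_cell, Trace(iso, RATE, "WC")).samples
        expected = (ca_iso.max() - ca_iso[:1000].mean()) / 3.0
        assert summary["ratio_median"] == pytest.approx(expected, rel=0.10)

    def test_uncorrelated_noise_trace_has_no_correlation(self):
        rng = np.random.default_rng(2)
        w, pk = psp_waveform(RATE, 1e-3, 50e-3)
        v = np.full(int(20 * RATE), -80.0)
        for k in range(18):
            _insert(v, int((0.5 + k) * RATE), rng.uniform(2, 5) * w)
        wc = Trace(v, RATE, "WC")
        ca = Trace(0.5 * rng.standard_normal(v.size), RATE, "CA")
        evs = detect_spsps(wc)
        _, summary = pair_and_transfer(evs, ca, max_lag=20e-3)
        assert abs(summary["pearson_r"]) < 0.5
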