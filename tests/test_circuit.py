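"""Transfer-function model: closed-form limits, oracle equivalence of the two
derivations, time-domain filtering, and parameter recovery by refitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cacc import (FrequencyResponse, PatchCircuitParams, Trace,
                  amplitude_response, complex_transfer, dc_transfer,
                  filter_trace, fit_transfer, hf_transfer,
                  single_channel_depolarization)


def random_params(rng):
    return PatchCircuitParams(
        R_seal=float(rng.uniform(1.0, 100.0)),
        R_patch=float(rng.uniform(0.5, 20.0)),
        C_patch=float(rng.uniform(0.1, 5.0)),
        C_elec=float(rng.uniform(1.0, 20.0)),
    )


class TestAmplitudeResponse:
    def test_example_cell_low_frequency(self, example_cell):
        # 0.884 at 0.1 Hz, i.e. the transfer approaches 0.9 below 1 Hz
        assert amplitude_response(example_cell, 0.1) == pytest.approx(0.884, abs=5e-4)
        assert round(amplitude_response(example_cell, 0.1), 1) == 0.9

    def test_example_cell_high_frequency(self, example_cell):
        assert amplitude_response(example_cell, 1000.0) == pytest.approx(0.103, abs=1e-3)
        assert round(hf_transfer(example_cell), 1) == 0.1

    def test_ideal_seal_is_transparent(self):
        ideal = PatchCircuitParams(R_seal=1e6, R_patch=1.0, C_patch=1.0, C_elec=1e-6)
        f = np.geomspace(0.01, 1e4, 50)
        assert np.allclose(amplitude_response(ideal, f), 1.0, atol=1e-4)

    def test_negative_frequency_rejected(self, example_cell):
        with pytest.raises(ValueError):
            amplitude_response(example_cell, -1.0)
        with pytest.raises(ValueError):
            complex_transfer(example_cell, -1.0)

    def test_group_median_consistency_with_event_transfers(self, median_cell):
        # model AR at the AP and sPSP dominant frequencies falls inside the
        # experimentally observed transfer-coefficient interquartile ranges
        assert 0.10 <= amplitude_response(median_cell, 240.0) <= 0.24
        assert 0.41 <= amplitude_response(median_cell, 3.9) <= 0.79


class TestLimits:
    def test_dc_transfer_is_resistive_divider(self, example_cell, median_cell):
        assert dc_transfer(example_cell) == pytest.approx(0.8839, abs=1e-4)
        assert dc_transfer(median_cell) == pytest.approx(0.7586, abs=1e-4)

    def test_dc_limit_matches_response_at_zero(self, example_cell):
        assert amplitude_response(example_cell, 0.0) == pytest.approx(
            dc_transfer(example_cell), rel=1e-12)

    def test_vanishing_patch_resistance(self):
        p = PatchCircuitParams(R_seal=10.0, R_patch=1e-9, C_patch=0.8, C_elec=7.0)
        assert dc_transfer(p) == pytest.approx(1.0)

    def test_hf_transfer_is_capacitive_divider(self, example_cell):
        assert hf_transfer(example_cell) == pytest.approx(0.1026, abs=1e-4)
        equal = PatchCircuitParams(R_seal=10.0, R_patch=5.0, C_patch=2.0, C_elec=2.0)
        assert hf_transfer(equal) == pytest.approx(0.5)
        tiny_elec = PatchCircuitParams(R_seal=10.0, R_patch=5.0, C_patch=2.0, C_elec=1e-9)
        assert hf_transfer(tiny_elec) == pytest.approx(1.0)

    def test_limits_bracket_response_for_random_parameters(self):
        rng = np.random.default_rng(7)
        f = np.geomspace(1e-3, 1e5, 60)
        for _ in range(200):
            p = random_params(rng)
            ar = amplitude_response(p, f)
            assert amplitude_response(p, 0.0) == pytest.approx(dc_transfer(p), rel=1e-9)
            assert amplitude_response(p, 1e9) == pytest.approx(hf_transfer(p), rel=1e-3)
            if dc_transfer(p) > hf_transfer(p):
                assert np.all(np.diff(ar) <= 1e-12)  # monotone non-increasing


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    r_seal=st.floats(0.5, 200.0), r_patch=st.floats(0.1, 50.0),
    c_patch=st.floats(0.05, 10.0), c_elec=st.floats(0.5, 50.0),
    f=st.floats(0.0, 1e5),
)
def test_response_bounded_by_divider_limits(r_seal, r_patch, c_patch, c_elec, f):
    """AR(f) always lies between the capacitive and resistive divider limits
    (whichever ordering), and the two independent derivations agree."""
    p = PatchCircuitParams(r_seal, r_patch, c_patch, c_elec)
    ar = amplitude_response(p, f)
    lo, hi = sorted((dc_transfer(p), hf_transfer(p)))
    assert lo - 1e-12 <= ar <= hi + 1e-12
    assert abs(abs(complex_transfer(p, f)) - ar) <= 1e-10 * ar


class TestComplexTransferOracle:
    def test_modulus_matches_closed_form_over_random_draws(self):
        # the complex-divider derivation and the closed-form expression must
        # agree to 1e-10 relative error — each is the other's oracle
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = random_params(rng)
            f = float(10 ** rng.uniform(-2, 4))
            h = abs(complex_transfer(p, f))
            ar = amplitude_response(p, f)
            assert abs(h - ar) <= 1e-10 * ar

    def test_zero_frequency_gain_is_real_dc(self, example_cell):
        h0 = complex_transfer(example_cell, 0.0)
        assert h0.imag == pytest.approx(0.0, abs=1e-15)
        assert h0.real == pytest.approx(dc_transfer(example_cell))
        assert np.angle(complex_transfer(example_cell, 1e-9)) == pytest.approx(0.0, abs=1e-6)

    def test_modulus_at_ap_dominant_frequency(self, example_cell):
        assert abs(complex_transfer(example_cell, 240.0)) == pytest.approx(0.103, abs=1e-3)


class TestFilterTrace:
    RATE = 50_000.0

    def _trace(self, samples):
        return Trace(np.asarray(samples, float), self.RATE, "WC")

    def test_steady_state_gain_is_dc_transfer(self, example_cell):
        wc = self._trace(np.full(int(self.RATE), -80.0))
        ca = filter_trace(example_cell, wc)
        assert ca.channel_role == "CA"
        expected = -80.0 * dc_transfer(example_cell)
        assert ca.samples[-1] == pytest.approx(expected, rel=1e-3)
        assert ca.samples[0] == pytest.approx(expected, rel=1e-3)  # no start transient

    @pytest.mark.parametrize("freq", [0.1, 1.0, 10.0, 100.0, 1000.0])
    def test_sinusoid_attenuation_matches_amplitude_response(self, example_cell, freq):
        cycles = max(4.0, freq * 2.0)
        n = int(cycles / freq * self.RATE)
        t = np.arange(n) / self.RATE
        wc = self._trace(np.sin(2 * np.pi * freq * t))
        out = filter_trace(example_cell, wc).samples
        tail = out[n // 2:]
        amp = (tail.max() - tail.min()) / 2.0
        assert amp == pytest.approx(amplitude_response(example_cell, freq), rel=0.01)

    def test_linearity_on_sum_of_sinusoids(self, median_cell):
        n = int(4 * self.RATE)
        t = np.arange(n) / self.RATE
        s1, s2 = np.sin(2 * np.pi * 2 * t), 0.5 * np.sin(2 * np.pi * 40 * t)
        out_sum = filter_trace(median_cell, self._trace(s1 + s2)).samples
        out_parts = (filter_trace(median_cell, self._trace(s1)).samples
                     + filter_trace(median_cell, self._trace(s2)).samples)
        scale = np.max(np.abs(out_sum))
        assert np.max(np.abs(out_sum - out_parts)) <= 0.005 * scale

    def test_patch_current_offset_added_after_filtering(self, example_cell):
        wc = self._trace(np.zeros(1000))
        ca = filter_trace(example_cell, wc, patch_current_offset=9.0)
        assert np.allclose(ca.samples, 9.0)

    def test_rejects_non_wc_input(self, example_cell):
        lfp = Trace(np.zeros(10), 1000.0, "LFP")
        with pytest.raises(ValueError):
            filter_trace(example_cell, lfp)


class TestSingleChannel:
    def test_worked_potassium_channel_example(self):
        current, dv = single_channel_depolarization(100.0, 90.0, 1.0)
        assert current == pytest.approx(9.0)
        assert dv == pytest.approx(9.0)


class TestFitTransfer:
    def _table(self, params, noise_sigma=0.0, rng=None, n=25):
        f = np.geomspace(0.1, 100.0, n)
        r = amplitude_response(params, f)
        if noise_sigma:
            r = r * np.exp(noise_sigma * rng.standard_normal(f.size))
        return FrequencyResponse(f, r)

    def test_noiseless_recovery_of_example_cell(self, example_cell):
        fit = fit_transfer(self._table(example_cell), C_elec_fixed=7.0)
        assert fit.converged
        assert fit.params.R_seal == pytest.approx(55.6, rel=0.01)
        assert fit.params.R_patch == pytest.approx(7.3, rel=0.01)
        assert fit.params.C_patch == pytest.approx(0.8, rel=0.01)
        assert fit.fixed_mask["C_elec"] is True

    def test_recovery_under_multiplicative_noise(self, example_cell):
        # 1% log-normal noise on the ratios, 100 Monte-Carlo repeats
        rng = np.random.default_rng(5)
        for _ in range(100):
            fit = fit_transfer(self._table(example_cell, 0.01, rng), C_elec_fixed=7.0)
            assert fit.params.R_seal == pytest.approx(55.6, rel=0.10)
            assert fit.params.C_patch == pytest.approx(0.8, rel=0.10)

    def test_insufficient_points_rejected(self, example_cell):
        f = np.array([1.0, 10.0])
        fr = FrequencyResponse(f, amplitude_response(example_cell, f))
        with pytest.raises(ValueError, match="at least 3"):
            fit_transfer(fr, C_elec_fixed=7.0)

    def test_explicit_initialisation_is_honoured(self, example_cell, median_cell):
        fit = fit_transfer(self._table(example_cell), C_elec_fixed=7.0, init=median_cell)
        assert fit.params.R_seal == pytest.approx(55.6, rel=0.01)


class TestParamInvariants:
    def test_derived_ratios_consistent(self, example_cell):
        assert example_cell.K_R == pytest.approx(55.6 / 7.3, rel=1e-12)
        assert example_cell.K_C == pytest.approx(7.0 / 0.8, rel=1e-12)
        assert example_cell.tau == pytest.approx(7.3 * 0.8 * 1e-3, rel=1e-12)  # seconds

    @pytest.mark.parametrize("field", ["R_seal", "R_patch", "C_patch", "C_elec"])
    def test_nonpositive_elements_rejected(self, field):
        kwargs = dict(R_seal=10.0, R_patch=5.0, C_patch=1.0, C_elec=7.0)
        kwargs[field] = 0.0
        with pytest.raises(ValueError):
            PatchCircuitParams(**kwargs)
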