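"""Pulse synthesis, Fourier tooling, analytic oracles, comparison metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemoflow.rheology import RheologyParams
from hemoflow.waveforms import (Waveform, WaveformSpec, flow_rate_from_velocity,
                                fourier_decompose, fourier_reconstruct,
                                poiseuille_wss, synthesize_pulse,
                                systolic_metrics, waveform_from_csv,
                                waveform_percent_difference, waveform_to_csv,
                                womersley_velocity, womersley_wall_shear)


class TestSynthesizePulse:
    def test_default_pressure_pulse_extrema(self):
        w = synthesize_pulse(WaveformSpec(), n_samples=200)
        k = int(np.argmax(w.values))
        assert w.times[k] == pytest.approx(0.14)
        assert w.values[k] == pytest.approx(140.0)
        assert np.min(w.values) == pytest.approx(80.0)

    def test_flat_spec_rejected(self):
        with pytest.raises(ValueError):
            WaveformSpec(systolic_level=90.0, diastolic_level=90.0)

    def test_peak_time_outside_period_rejected(self):
        with pytest.raises(ValueError):
            WaveformSpec(peak_time=1.2)

    def test_deterministic_per_seed(self):
        spec = WaveformSpec(unit="m/s", systolic_level=0.5,
                            diastolic_level=0.05)
        a = synthesize_pulse(spec, seed=7)
        b = synthesize_pulse(spec, seed=7)
        c = synthesize_pulse(spec, seed=8)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    @given(st.floats(min_value=0.05, max_value=0.9),
           st.integers(min_value=4, max_value=12),
           st.integers(min_value=0, max_value=1000))
    @settings(max_examples=30, deadline=None)
    def test_extrema_attained_for_random_specs(self, peak_time, harmonics,
                                               seed):
        # sample on a grid containing the peak time
        spec = WaveformSpec(peak_time=round(peak_time, 2),
                            harmonic_count=harmonics, unit="m/s",
                            systolic_level=1.0, diastolic_level=0.1)
        w = synthesize_pulse(spec, seed=seed, n_samples=100)
        assert np.max(w.values) == pytest.approx(1.0, abs=1e-12)
        assert np.min(w.values) == pytest.approx(0.1, abs=1e-12)
        assert w.times[int(np.argmax(w.values))] == pytest.approx(
            spec.peak_time)


class TestFourier:
    def test_constant_waveform(self):
        w = Waveform(values=np.full(64, 3.0), period=1.0, unit="Pa")
        c = fourier_decompose(w, 5)
        assert c[0] == pytest.approx(3.0)
        assert np.allclose(c[1:], 0.0)

    def test_pure_cosine_single_harmonic(self):
        t = np.arange(64) / 64
        w = Waveform(values=np.cos(2 * np.pi * t), period=1.0, unit="Pa")
        c = fourier_decompose(w, 4)
        assert c[1] == pytest.approx(0.5)
        assert abs(c[0]) < 1e-14 and np.allclose(c[2:], 0.0, atol=1e-14)

    def test_round_trip_band_limited(self):
        rng = np.random.default_rng(0)
        coeffs = rng.normal(size=6) + 1j * rng.normal(size=6)
        coeffs[0] = coeffs[0].real
        w = fourier_reconstruct(coeffs, 128, 1.0)
        back = fourier_decompose(w, 5)
        assert np.allclose(back, coeffs, atol=1e-10)

    def test_too_many_harmonics_rejected(self):
        w = Waveform(values=np.zeros(10) + 1.0, period=1.0, unit="Pa")
        with pytest.raises(ValueError):
            fourier_decompose(w, 6)


class TestWomersley:
    RADIUS = 0.002

    def test_steady_term_is_poiseuille(self, newtonian):
        g0 = -150.0
        r = np.linspace(0, self.RADIUS, 33)
        u = womersley_velocity(self.RADIUS, [g0], newtonian, r, 0.3)
        exact = -g0 * (self.RADIUS**2 - r**2) / (4 * newtonian.mu_inf)
        assert np.allclose(u, exact, rtol=1e-12)
        # centreline = 2 x mean velocity
        assert u[0] == pytest.approx(2 * (-g0 * self.RADIUS**2
                                          / (8 * newtonian.mu_inf)))

    def test_no_slip_at_wall(self, newtonian):
        g = [-100.0, -200.0 + 0j, 50.0j]
        for t in (0.0, 0.2, 0.77):
            assert womersley_velocity(self.RADIUS, g, newtonian,
                                      self.RADIUS, t) == pytest.approx(
                                          0.0, abs=1e-12)

    def test_oscillatory_values_against_bessel_series(self, newtonian):
        # frozen from a 40-digit mpmath Bessel evaluation
        g = [0.0, -200.0 + 0j]
        cases = [
            (0.0, 0.2, 0.03281351938837298),
            (0.0012, 0.2, 0.02084794202256171),
            (0.0018, 0.05, 0.0066233010928118096),
        ]
        for r, t, expected in cases:
            assert womersley_velocity(self.RADIUS, g, newtonian, r, t) == \
                pytest.approx(expected, rel=1e-10)

    def test_non_newtonian_rejected(self, blood):
        with pytest.raises(ValueError):
            womersley_velocity(self.RADIUS, [-100.0], blood, 0.0, 0.0)

    def test_wall_shear_consistent_with_velocity_gradient(self, newtonian):
        g = [-100.0, -200.0 + 0j]
        h = 1e-7
        for t in (0.1, 0.4):
            du = (womersley_velocity(self.RADIUS, g, newtonian,
                                     self.RADIUS - h, t)
                  - womersley_velocity(self.RADIUS, g, newtonian,
                                       self.RADIUS, t))
            tau_fd = newtonian.mu_inf * du / h
            tau = womersley_wall_shear(self.RADIUS, g, newtonian, t)
            assert tau == pytest.approx(tau_fd, rel=1e-4)


class TestPoiseuilleWss:
    def test_zero_flow(self):
        assert poiseuille_wss(0.0, 0.01, 0.0035) == 0.0

    def test_linearity_in_flow(self):
        a = poiseuille_wss(1e-4, 0.0126, 0.0035)
        b = poiseuille_wss(2e-4, 0.0126, 0.0035)
        assert b == pytest.approx(2 * a)

    def test_hand_evaluated_value(self):
        assert poiseuille_wss(1e-4, 0.0126, 0.0035) == pytest.approx(
            0.22277503862139265, rel=1e-12)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            poiseuille_wss(1e-4, 0.0, 0.0035)


class TestFlowRateConversion:
    def test_unit_velocity_descending_aorta(self):
        w = Waveform(values=np.ones(32), period=1.0, unit="m/s")
        q = flow_rate_from_velocity(w, 25.2)
        assert q.unit == "mL/s"
        assert np.allclose(q.values, 498.75924968391557, rtol=1e-12)

    def test_zero_velocity(self):
        w = Waveform(values=np.zeros(32), period=1.0, unit="m/s")
        assert np.all(flow_rate_from_velocity(w, 25.2).values == 0.0)

    def test_wrong_unit_rejected(self):
        w = Waveform(values=np.ones(32), period=1.0, unit="mmHg")
        with pytest.raises(ValueError):
            flow_rate_from_velocity(w, 25.2)


class TestPercentDifference:
    def test_identical_is_zero(self):
        w = synthesize_pulse(WaveformSpec(), n_samples=100)
        assert waveform_percent_difference(w, w) == 0.0

    def test_uniform_scaling(self):
        w = synthesize_pulse(WaveformSpec(), n_samples=100)
        scaled = Waveform(values=1.1 * w.values, period=w.period, unit=w.unit)
        assert waveform_percent_difference(scaled, w) == pytest.approx(10.0)
        anchor = Waveform(values=1.31 * w.values, period=w.period,
                          unit=w.unit)
        assert waveform_percent_difference(anchor, w) == pytest.approx(31.0)

    def test_brute_force_norms(self):
        a = Waveform(values=np.array([1.0, 2.0, 3.0, 4.0]), period=1.0,
                     unit="mL/s")
        b = Waveform(values=np.array([1.5, 2.0, 2.5, 4.5]), period=1.0,
                     unit="mL/s")
        num = np.sqrt(0.5**2 + 0.0 + 0.5**2 + 0.5**2)
        den = np.sqrt(1.5**2 + 2.0**2 + 2.5**2 + 4.5**2)
        assert waveform_percent_difference(a, b) == pytest.approx(
            100 * num / den, rel=1e-12)

    def test_unit_mismatch_rejected(self):
        a = Waveform(values=np.ones(8), period=1.0, unit="mL/s")
        b = Waveform(values=np.ones(8), period=1.0, unit="m/s")
        with pytest.raises(ValueError):
            waveform_percent_difference(a, b)


class TestSystolicMetrics:
    def test_identical_waveforms(self):
        w = synthesize_pulse(WaveformSpec(), n_samples=100)
        m = systolic_metrics(w, w)
        assert m["amplification"] == 0.0
        assert m["peak_lead"] == 0.0

    def test_scaled_and_shifted_pair(self):
        w = synthesize_pulse(WaveformSpec(), n_samples=100)
        shifted = Waveform(values=1.25 * np.roll(w.values, -1),
                           period=w.period, unit=w.unit)
        m = systolic_metrics(shifted, w)
        assert m["amplification"] == pytest.approx(25.0, abs=1e-9)
        assert m["peak_lead"] == pytest.approx(0.01, abs=1e-9)

    def test_nonpositive_reference_rejected(self):
        ref = Waveform(values=-np.ones(16), period=1.0, unit="mmHg")
        with pytest.raises(ValueError):
            systolic_metrics(ref, ref)


class TestCsvRoundTrip:
    def test_waveform_round_trip(self, tmp_path):
        w = synthesize_pulse(WaveformSpec(unit="m/s", systolic_level=0.4,
                                          diastolic_level=0.05),
                             n_samples=64)
        path = tmp_path / "wave.csv"
        waveform_to_csv(w, path)
        back = waveform_from_csv(path)
        assert back.unit == "m/s"
        assert back.period == w.period
        assert np.allclose(back.values, w.values, atol=1e-12)

    def test_missing_unit_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,value\n0.0,1.0\n0.5,2.0\n")
        with pytest.raises(ValueError, match="unit"):
            waveform_from_csv(path)
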