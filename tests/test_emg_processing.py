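"""Conditioning chain: filters, activation dynamics, normalization, dead band."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myoelbow import (
    ActivationParams,
    DegenerateMVCError,
    EMGTrace,
    ParameterError,
    StabilityError,
    activation_dynamics,
    activation_nonlinearity,
    compute_mvc,
    dead_band_rectify,
    highpass_filter,
    lowpass_smooth,
    make_filter_coefficients,
    normalize_mvc,
    rectify,
)

FS = 1000.0


def _amplitude(x):
    """Steady-state sinusoid amplitude estimated from the signal tail."""
    return math.sqrt(2.0) * float(np.std(x))


def _trace(samples, stage="raw", fs=FS):
    return EMGTrace(np.asarray(samples, dtype=float), fs, stage)


class TestEMGTrace:
    def test_invariants_enforced(self):
        with pytest.raises(ParameterError):
            EMGTrace(np.array([1.0, np.inf]), FS)
        with pytest.raises(ParameterError):
            EMGTrace(np.array([1.0]), -1.0)
        with pytest.raises(ParameterError):
            EMGTrace(np.array([-0.1]), FS, "rectified")
        with pytest.raises(ParameterError):
            EMGTrace(np.array([1.2]), FS, "activation")
        with pytest.raises(ParameterError):
            EMGTrace(np.array([]), FS)


class TestHighpass:
    def test_removes_dc(self):
        trace = _trace(np.full(10_000, 5.0))
        out = highpass_filter(trace, 10.0, 4)
        assert out.stage == "highpassed"
        assert len(out) == len(trace)
        assert abs(np.mean(out.samples[-1000:])) < 1e-3

    def test_passband_sinusoid_unattenuated(self):
        # oracle: analog 4th-order Butterworth high-pass magnitude at f/fc = 10
        t = np.arange(int(10 * FS)) / FS
        trace = _trace(np.sin(2 * np.pi * 100.0 * t))
        out = highpass_filter(trace, 10.0, 4)
        expected = 1.0 / math.sqrt(1.0 + (10.0 / 100.0) ** 8)
        measured = _amplitude(out.samples[-2000:])
        assert abs(measured - expected) / expected < 0.01

    def test_stopband_sinusoid_attenuated_70db(self):
        # 4th order rolls off 80 dB/decade; 1 Hz is a decade below 10 Hz
        t = np.arange(int(10 * FS)) / FS
        trace = _trace(np.sin(2 * np.pi * 1.0 * t))
        out = highpass_filter(trace, 10.0, 4)
        assert _amplitude(out.samples[-5000:]) < 10 ** (-70 / 20)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            highpass_filter(_trace(np.zeros(10)), 500.0, 4)


class TestRectify:
    @pytest.mark.parametrize(
        "signal, expected",
        [
            ([-1.0, 2.0, -3.0], [1.0, 2.0, 3.0]),
            ([0.0, 0.0], [0.0, 0.0]),
            ([0.5, 1.5], [0.5, 1.5]),
        ],
    )
    def test_examples(self, signal, expected):
        out = rectify(_trace(signal, "highpassed"))
        assert out.stage == "rectified"
        np.testing.assert_allclose(out.samples, expected)


class TestFilterCoefficients:
    def test_pure_delay(self):
        c = make_filter_coefficients(0.0, 0.0, 0)
        assert (c.alpha, c.beta1, c.beta2) == (1.0, 0.0, 0.0)

    def test_default_poles(self):
        c = make_filter_coefficients(-0.5, -0.5)
        assert c.beta1 == -1.0
        assert c.beta2 == 0.25
        assert c.alpha == 0.25

    def test_unstable_pole_rejected(self):
        with pytest.raises(StabilityError):
            make_filter_coefficients(0.9, 1.1)

    @settings(max_examples=100, derandomize=True)
    @given(
        g1=st.floats(-0.99, 0.99),
        g2=st.floats(-0.99, 0.99),
        d=st.integers(0, 100),
    )
    def test_coefficient_identities(self, g1, g2, d):
        c = make_filter_coefficients(g1, g2, d)
        assert c.beta1 == pytest.approx(g1 + g2)
        assert c.beta2 == pytest.approx(g1 * g2)
        assert c.alpha - c.beta1 - c.beta2 == pytest.approx(1.0)


class TestActivationDynamics:
    def test_unit_step_settles_to_one(self):
        coeffs = make_filter_coefficients(-0.5, -0.5, 0)
        e = _trace(np.ones(2000), "rectified")
        u = activation_dynamics(e, coeffs)
        assert u.samples[-1] == pytest.approx(1.0, abs=1e-9)

    def test_zero_input_zero_output(self):
        coeffs = make_filter_coefficients()
        u = activation_dynamics(_trace(np.zeros(500), "rectified"), coeffs)
        assert np.all(u.samples == 0.0)

    def test_delay_shifts_impulse(self):
        coeffs = make_filter_coefficients(-0.5, -0.5, 10)
        x = np.zeros(100)
        x[0] = 1.0
        u = activation_dynamics(_trace(x, "rectified"), coeffs)
        assert np.all(u.samples[:10] == 0.0)
        assert u.samples[10] != 0.0

    def test_matches_brute_force_difference_equation(self):
        # oracle: direct sample-by-sample evaluation of the recurrence
        rng = np.random.default_rng(7)
        x = np.abs(rng.standard_normal(300))
        coeffs = make_filter_coefficients(-0.3, 0.6, 5)
        u = activation_dynamics(_trace(x, "rectified"), coeffs)
        ref = np.zeros_like(x)
        for t in range(x.size):
            e_del = x[t - coeffs.delay_samples] if t >= coeffs.delay_samples else 0.0
            u1 = ref[t - 1] if t >= 1 else 0.0
            u2 = ref[t - 2] if t >= 2 else 0.0
            ref[t] = coeffs.alpha * e_del - coeffs.beta1 * u1 - coeffs.beta2 * u2
        np.testing.assert_allclose(u.samples, ref, atol=1e-10)

    def test_unity_dc_gain_for_random_stable_poles(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            g1, g2 = rng.uniform(-0.9, 0.9, size=2)
            coeffs = make_filter_coefficients(g1, g2, 0)
            e = _trace(np.full(3000, 0.7), "rectified")
            u = activation_dynamics(e, coeffs)
            assert u.samples[-1] == pytest.approx(0.7, abs=1e-6)


class TestLowpass:
    def test_unity_dc_gain(self):
        u = _trace(np.full(30_000, 0.5), "excitation")
        out = lowpass_smooth(u, 1.0, 2)
        assert abs(out.samples[-1] - 0.5) < 1e-3

    def test_suppresses_fast_ripple(self):
        # 2nd-order Butterworth at 50x the cutoff attenuates by ~(50)^2
        t = np.arange(int(30 * FS)) / FS
        u = _trace(0.5 + 0.1 * np.sin(2 * np.pi * 50.0 * t), "excitation")
        out = lowpass_smooth(u, 1.0, 2)
        tail = out.samples[-1000:]
        ripple = (tail.max() - tail.min()) / 2.0
        assert ripple < 1e-3

    def test_zero_in_zero_out(self):
        out = lowpass_smooth(_trace(np.zeros(100), "excitation"), 1.0, 2)
        assert np.all(out.samples == 0.0)


class TestActivationNonlinearity:
    def test_endpoints(self):
        params = ActivationParams(R=1.0, A=2.0)
        u0 = _trace([0.0, 2.0], "excitation")  # u = 0 and u = R*A
        a = activation_nonlinearity(u0, params)
        assert a.samples[0] == pytest.approx(0.0)
        assert a.samples[1] == pytest.approx(1.0)

    def test_known_value(self):
        # (e - 1)/(e^2 - 1) for R = 1, A = 2 at u = 1
        params = ActivationParams(R=1.0, A=2.0)
        a = activation_nonlinearity(_trace([1.0], "excitation"), params)
        expected = (math.e - 1.0) / (math.e**2 - 1.0)
        assert a.samples[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.2689, abs=1e-4)

    def test_strictly_monotone_on_domain(self):
        params = ActivationParams(R=2.0, A=0.5)
        u = _trace(np.linspace(0.0, params.R * params.A, 500), "excitation")
        a = activation_nonlinearity(u, params)
        assert np.all(np.diff(a.samples) > 0)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ParameterError):
            ActivationParams(R=1.0, A=0.0)


class TestMVC:
    def test_identical_trials_match_single_trial(self):
        rng = np.random.default_rng(0)
        trial = _trace(rng.standard_normal(3000))
        one = compute_mvc([trial])
        five = compute_mvc([trial] * 5)
        assert one == five

    def test_maximum_over_trials(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(3000)
        scales = [0.4, 0.9, 0.6, 0.7, 0.8]
        trials = [_trace(s * base) for s in scales]
        peaks = [compute_mvc([t]) for t in trials]
        assert compute_mvc(trials) == max(peaks)
        assert np.argmax(peaks) == 1

    def test_empty_and_degenerate(self):
        with pytest.raises(ParameterError):
            compute_mvc([])
        with pytest.raises(DegenerateMVCError):
            compute_mvc([_trace(np.zeros(3000))])


class TestNormalizeMVC:
    def test_divides_and_clamps(self):
        u = _trace([0.45, 0.9], "excitation")
        out = normalize_mvc(u, 0.9)
        np.testing.assert_allclose(out.samples, [0.5, 1.0])
        clamped = normalize_mvc(_trace([1.2], "excitation"), 1.0)
        np.testing.assert_allclose(clamped.samples, [1.0])

    def test_zero_signal_and_invalid_mvc(self):
        out = normalize_mvc(_trace(np.zeros(5), "excitation"), 0.5)
        assert np.all(out.samples == 0.0)
        with pytest.raises(ParameterError):
            normalize_mvc(_trace([1.0], "excitation"), 0.0)


class TestDeadBand:
    def test_suppresses_jitter_around_constant(self):
        rng = np.random.default_rng(2)
        x = 0.5 * (1.0 + 0.005 * rng.uniform(-1, 1, 1000))
        out = dead_band_rectify(x, 0.02)
        assert np.all(out[1:] == out[1])

    def test_large_step_passes(self):
        x = np.concatenate([np.zeros(10), np.full(10, 0.5)])
        out = dead_band_rectify(x, 0.02)
        assert out[9] == 0.0
        assert out[10] == 0.5

    def test_ramp_tracked_with_bounded_lag(self):
        # staircase oracle: output lags the ramp by at most one band width
        t = np.arange(5000) / FS
        ramp = 0.1 * t  # 10 %/s
        out = dead_band_rectify(ramp, 0.01)
        band = np.maximum(0.01 * out, 0.01)
        assert np.all(ramp - out <= band + 1e-12)
        assert np.all(out <= ramp + 1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        x = np.clip(np.cumsum(rng.normal(0, 0.01, 2000)) + 0.5, 0, 1)
        once = dead_band_rectify(x, 0.02)
        twice = dead_band_rectify(once, 0.02)
        np.testing.assert_array_equal(once, twice)

    def test_zero_band_is_identity(self):
        x = np.array([0.1, 0.2, 0.15])
        np.testing.assert_array_equal(dead_band_rectify(x, 0.0), x)

    def test_invalid_band_rejected(self):
        with pytest.raises(ParameterError):
            dead_band_rectify(np.zeros(3), 0.5)


class TestFullChain:
    def test_bounded_output_for_random_inputs(self, config):
        """Any bounded raw input maps to activation in [0, 1]."""
        rng = np.random.default_rng(42)
        coeffs = make_filter_coefficients()
        params = ActivationParams()
        for _ in range(1000):
            raw = _trace(rng.uniform(-1, 1) * rng.standard_normal(500))
            u = activation_dynamics(rectify(highpass_filter(raw)), coeffs)
            u = lowpass_smooth(u)
            u = normalize_mvc(u, 0.5)
            a = activation_nonlinearity(u, params)
            assert np.all(a.samples >= 0.0)
            assert np.all(a.samples <= 1.0)
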