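"""Lumped ADE time-domain solver: closed forms, steady-state equivalence
with the frequency domain, and numerical convergence."""

import numpy as np
import pytest

import debyesim as ds
from debyesim import EPS0


class TestSources:
    def test_sine_value_and_derivative_consistent(self):
        src = ds.SourceSignal.sine(1e3, amplitude=50.0)
        t = np.linspace(0, 5e-3, 1000)
        dt = 1e-9
        num = (src.value(t + dt) - src.value(t - dt)) / (2 * dt)
        np.testing.assert_allclose(src.derivative(t), num, rtol=1e-4, atol=1e-3)

    def test_pulse_burst_shape(self):
        src = ds.SourceSignal.pulse_burst()  # 4 x 100 us @ 50 V, 8 us edges
        assert src.value(50e-6) == pytest.approx(50.0)     # plateau, pulse 1
        assert src.value(150e-6) == pytest.approx(0.0)     # gap
        assert src.value(204e-6) == pytest.approx(25.0)    # mid-rise, pulse 2
        assert src.value(4e-6) == pytest.approx(25.0)      # mid-rise, pulse 1
        assert src.value(1e-3) == pytest.approx(0.0)       # after the burst
        assert src.derivative(4e-6) == pytest.approx(50.0 / 8e-6)

    def test_pulse_value_continuous(self):
        src = ds.SourceSignal.pulse_burst()
        t = np.linspace(0, 810e-6, 200001)
        v = src.value(t)
        assert np.max(np.abs(np.diff(v))) < 50.0 / 8e-6 * (t[1] - t[0]) * 1.01

    def test_custom_requires_derivative(self):
        with pytest.raises(ds.timedomain.SourceError):
            ds.SourceSignal.custom(lambda t: t, None, 1.0, 1e-6)


class TestSimulateLumped:
    def test_zero_source_zero_current(self, n4_model, cylinder):
        src = ds.SourceSignal.custom(lambda t: np.zeros_like(np.asarray(t, float)),
                                     lambda t: np.zeros_like(np.asarray(t, float)),
                                     amplitude=0.0, max_step=1e-5, duration=1e-3)
        res = ds.simulate_lumped(n4_model, cylinder, src)
        assert np.max(np.abs(res.current)) < 1e-15

    def test_single_pole_step_response_closed_form(self, cylinder):
        # near-step field: 10 ns ramp against a 10 us pole
        tau, d_eps, sigma_s = 1e-5, 1e4, 1e-3
        model = ds.DebyeMultipole(sigma_s, 1.0, (ds.DebyePole(d_eps, tau),))
        src = ds.SourceSignal.pulse_burst(n_pulses=1, width=8e-5, period=1e-4,
                                          amplitude=50.0, transition=1e-8)
        res = ds.simulate_lumped(model, cylinder, src, t_end=6e-5)
        E0 = 50.0 / cylinder.length
        mask = (res.t > 2e-8) & (res.t < 5e-5)
        t = res.t[mask]
        # strip the conduction part; the eps_inf displacement term is zero
        # on the plateau
        j_e = res.current[mask] / cylinder.area - sigma_s * E0
        analytic = (EPS0 * d_eps / tau) * E0 * np.exp(-t / tau)
        np.testing.assert_allclose(j_e, analytic, rtol=1e-3)

    def test_auxiliary_state_decays_after_source_off(self, cylinder):
        tau = 1e-5
        model = ds.DebyeMultipole(1e-3, 1.0, (ds.DebyePole(1e4, tau),))
        src = ds.SourceSignal.pulse_burst(n_pulses=1, width=2e-5, period=4e-5,
                                          amplitude=50.0, transition=1e-8)
        res = ds.simulate_lumped(model, cylinder, src, t_end=4e-5)
        # after the pulse, J_e = -c e(t): pure exponential decay with tau
        mask = res.t > 2.1e-5
        j_e = res.current[mask] / cylinder.area
        ratio = j_e[1:] / j_e[:-1]
        expected = np.exp(-np.diff(res.t[mask]) / tau)
        np.testing.assert_allclose(ratio, expected, rtol=1e-2)

    def test_steady_state_matches_frequency_domain(self, n4_model, cylinder):
        f = 1e5
        src = ds.SourceSignal.sine(f, 50.0, periods=5)
        res = ds.simulate_lumped(n4_model, cylinder, src)
        amp, phase = ds.extract_amplitude_phase(res, f)
        current = 50.0 * n4_model.terminal_admittance(cylinder, f)
        assert amp == pytest.approx(abs(current), rel=5e-3)
        assert phase == pytest.approx(np.degrees(np.angle(current)), abs=0.2)

    def test_random_model_lti_equivalence(self, cylinder):
        rng = np.random.default_rng(5)
        model = ds.DebyeMultipole(
            sigma_s=0.05, eps_inf=20.0,
            poles=(ds.DebyePole(2e3, 3e-6), ds.DebyePole(4e2, 5e-8)))
        for f in (3e3, 3e5):
            src = ds.SourceSignal.sine(f, 10.0, periods=5)
            res = ds.simulate_lumped(model, cylinder, src)
            amp, phase = ds.extract_amplitude_phase(res, f)
            current = 10.0 * model.terminal_admittance(cylinder, f)
            assert amp == pytest.approx(abs(current), rel=5e-3)
            assert phase == pytest.approx(np.degrees(np.angle(current)), abs=0.2)

    def test_halving_max_step_converged(self, n4_model, cylinder):
        f = 1e3
        src = ds.SourceSignal.sine(f, 50.0, periods=2)
        r1 = ds.simulate_lumped(n4_model, cylinder, src, max_step_scale=1.0)
        r2 = ds.simulate_lumped(n4_model, cylinder, src, max_step_scale=0.5)
        i2 = np.interp(r1.t, r2.t, r2.current)
        sup = np.max(np.abs(r1.current - i2)) / np.max(np.abs(r1.current))
        assert sup < 1e-3

    def test_superposition(self, n4_model, cylinder):
        f1, f2 = 1e3, 3e3
        t_end = 2e-3
        s1 = ds.SourceSignal.sine(f1, 30.0)
        s2 = ds.SourceSignal.sine(f2, 20.0)
        both = ds.SourceSignal.custom(
            lambda t: s1.value(t) + s2.value(t),
            lambda t: s1.derivative(t) + s2.derivative(t),
            amplitude=50.0, max_step=1e-6, duration=t_end)
        r1 = ds.simulate_lumped(n4_model, cylinder, s1, t_end=t_end)
        r2 = ds.simulate_lumped(n4_model, cylinder, s2, t_end=t_end)
        rb = ds.simulate_lumped(n4_model, cylinder, both, t_end=t_end)
        i_sum = (np.interp(rb.t, r1.t, r1.current)
                 + np.interp(rb.t, r2.t, r2.current))
        scale = np.max(np.abs(rb.current))
        # skip the first microseconds: the sub-microsecond switch-on
        # transient is too fast for cross-grid interpolation
        mask = rb.t > 1e-5
        np.testing.assert_allclose(rb.current[mask], i_sum[mask],
                                   atol=2e-3 * scale)

    def test_cole_cole_rejected(self, cylinder):
        cc = ds.cole_cole(0.02, 10.0, [(1e3, 1e-5, 0.2)])
        with pytest.raises(ds.timedomain.SourceError):
            ds.simulate_lumped(cc, cylinder, ds.SourceSignal.sine(1e3))


class TestStaticComparator:
    def test_plateau_current(self, cylinder):
        src = ds.SourceSignal.pulse_burst()
        res = ds.simulate_static_conductivity(2.159e-2, cylinder, src)
        mask = (res.t > 20e-6) & (res.t < 90e-6)
        np.testing.assert_allclose(res.current[mask], 0.05804, rtol=2e-4)

    def test_current_is_scalar_multiple_of_voltage(self, cylinder):
        src = ds.SourceSignal.pulse_burst()
        res = ds.simulate_static_conductivity(0.03, cylinder, src)
        k = 0.03 * cylinder.area / cylinder.length
        np.testing.assert_allclose(res.current, k * res.voltage, rtol=1e-14)

    def test_zero_source(self, cylinder):
        src = ds.SourceSignal.custom(lambda t: 0.0 * np.asarray(t, float),
                                     lambda t: 0.0 * np.asarray(t, float),
                                     amplitude=0.0, max_step=1e-5, duration=1e-4)
        res = ds.simulate_static_conductivity(0.03, cylinder, src)
        assert np.all(res.current == 0)


class TestAmplitudePhaseExtraction:
    def test_pure_synthetic_recovered(self):
        f = 1e4
        w = 2 * np.pi * f
        t = np.linspace(0, 5 / f, 5000)
        res = ds.TimeSimResult(t, 2.0 * np.sin(w * t + np.deg2rad(30.0)),
                               50.0 * np.sin(w * t))
        amp, phase = ds.extract_amplitude_phase(res, f)
        assert amp == pytest.approx(2.0, abs=1e-9)
        assert phase == pytest.approx(30.0, abs=1e-9)

    def test_dc_offset_ignored(self):
        f = 1e4
        w = 2 * np.pi * f
        t = np.linspace(0, 5 / f, 5000)
        res = ds.TimeSimResult(t, 0.7 + 2.0 * np.sin(w * t + np.deg2rad(-10.0)),
                               50.0 * np.sin(w * t))
        amp, phase = ds.extract_amplitude_phase(res, f)
        assert amp == pytest.approx(2.0, abs=1e-9)
        assert phase == pytest.approx(-10.0, abs=1e-9)

    def test_window_longer_than_trace_rejected(self):
        f = 1e4
        t = np.linspace(0, 2 / f, 100)
        res = ds.TimeSimResult(t, np.sin(t), np.sin(t))
        with pytest.raises(ValueError):
            ds.extract_amplitude_phase(res, f, window=5.0)
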