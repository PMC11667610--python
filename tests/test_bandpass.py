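import math

import numpy as np
import pytest

from sccdyn.bandpass import (
    BandpassParams,
    OffsetModel,
    effective_params,
    frequency_response,
    normalized_gain_curve,
    operating_gain,
    sinusoid_response,
    step_accel_response,
    step_velocity_response,
)

from conftest import ode_response, rel_max_err


class TestEffectiveParams:
    def test_identity_at_zero_offset(self, published_model):
        p = effective_params(published_model, 0.0)
        assert p.K == pytest.approx(published_model.K0)
        assert p.tau_L == pytest.approx(published_model.tau_L0)
        assert p.tau_S == published_model.tau_S

    def test_tau_multiplier_at_far_offset(self):
        m = OffsetModel(K0=1.0, tau_L0=1.0, alpha=0.002143, beta1=0.01295, beta2=0.000059)
        assert float(m.tau_multiplier(103.0)) == pytest.approx(0.77927, abs=1e-5)

    def test_gain_multiplier_at_far_offset(self):
        m = OffsetModel(K0=1.0, tau_L0=1.0, alpha=0.002143, beta1=0.01295, beta2=0.000059)
        assert float(m.gain_multiplier(103.0)) == pytest.approx(2.9598, abs=1e-4)

    def test_vanishing_tau_multiplier_rejected(self):
        m = OffsetModel(K0=1.0, tau_L0=1.0, alpha=0.01)
        with pytest.raises(ValueError, match="alpha"):
            effective_params(m, 150.0)


class TestFrequencyResponse:
    def test_zero_at_dc(self, centered_params):
        assert abs(frequency_response(centered_params, 0.0)) == 0.0

    def test_high_frequency_rolloff(self, centered_params):
        mags = [abs(frequency_response(centered_params, f)) for f in (1e3, 1e5, 1e7)]
        assert mags[0] > mags[1] > mags[2]
        assert mags[2] < 1e-4 * operating_gain(centered_params, 10.0)

    def test_operating_point_magnitude(self):
        # |K s / ((tau_L s + 1)(tau_S s + 1))| at s = j 2 pi 10 for K = 1,
        # tau_L = 1.03, tau_S = 0.01; frozen from a numerical modulus oracle
        p = BandpassParams(K=1.0, tau_L=1.03, tau_S=0.01)
        assert operating_gain(p, 10.0) == pytest.approx(0.82197, abs=1e-5)


class TestTimeDomainResponses:
    """Closed forms against the independent state-space ODE oracle."""

    t = np.linspace(0.0, 10.0, 10_001)

    def test_step_velocity_matches_ode_oracle(self, centered_params):
        w0 = 10.0
        closed = step_velocity_response(centered_params, w0, self.t)
        oracle = ode_response(centered_params, lambda _t: w0, self.t)
        assert rel_max_err(closed, oracle) < 1e-8

    def test_step_accel_matches_ode_oracle(self, centered_params):
        a = 10.0
        closed = step_accel_response(centered_params, a, self.t)
        oracle = ode_response(centered_params, lambda _t: a * _t, self.t)
        assert rel_max_err(closed, oracle) < 1e-8

    def test_sinusoid_matches_ode_oracle(self, centered_params):
        w_amp, f = 0.5, 10.0
        t = np.linspace(0.0, 2.0, 20_001)
        closed = sinusoid_response(centered_params, w_amp, f, t)
        oracle = ode_response(
            centered_params, lambda _t: w_amp * math.sin(2 * math.pi * f * _t), t
        )
        assert rel_max_err(closed, oracle) < 1e-8

    def test_step_velocity_boundary_values(self, centered_params):
        y = step_velocity_response(centered_params, 10.0, self.t)
        assert y[0] == 0.0
        assert abs(y[-1]) < 1e-4 * np.max(y)  # returns to zero

    def test_single_exponential_limit(self):
        # tau_S -> 0: delta(t) = K w0 exp(-t/tau_L) / tau_L, so at t = tau_L
        # the value is K w0 e^{-1} / tau_L
        p = BandpassParams(K=2.0, tau_L=1.5, tau_S=1e-7)
        val = step_velocity_response(p, 3.0, np.array([1.5]))[0]
        assert val == pytest.approx(2.0 * 3.0 * math.exp(-1) / 1.5, rel=1e-5)

    def test_confluent_time_constants(self):
        p = BandpassParams(K=1.0, tau_L=0.5 + 1e-12, tau_S=0.5)
        t = np.linspace(0, 5, 501)
        y = step_velocity_response(p, 1.0, t)
        # K w0 t exp(-t/tau)/tau^2 peaks at t = tau with value K w0 e^-1 / tau
        assert np.max(y) == pytest.approx(math.exp(-1) / 0.5, rel=1e-4)

    def test_step_accel_final_value(self, centered_params):
        # delta(inf) = K a by the final-value theorem
        t = np.array([100.0 * centered_params.tau_L])
        a = 10.0
        val = step_accel_response(centered_params, a, t)[0]
        assert val == pytest.approx(centered_params.K * a, rel=1e-4)

    @pytest.mark.parametrize(
        "response, kwargs",
        [
            (step_velocity_response, {}),
            (step_accel_response, {}),
        ],
    )
    def test_linearity_of_step_responses(self, centered_params, response, kwargs):
        t = np.linspace(0, 5, 501)
        base = response(centered_params, 10.0, t, **kwargs)
        for c in (2.0, 3.0):
            np.testing.assert_allclose(response(centered_params, c * 10.0, t), c * base, rtol=1e-14)

    def test_accel_responses_scale_1_2_3(self, centered_params):
        # tripling the acceleration triples the deflection at every instant
        t = np.linspace(0, 8, 801)
        r10 = step_accel_response(centered_params, 10.0, t)
        r20 = step_accel_response(centered_params, 20.0, t)
        r30 = step_accel_response(centered_params, 30.0, t)
        np.testing.assert_allclose(r20, 2.0 * r10, rtol=1e-14)
        np.testing.assert_allclose(r30, 3.0 * r10, rtol=1e-14)

    def test_sinusoid_steady_state_amplitude(self, centered_params):
        w_amp, f = 0.5, 10.0
        t = np.arange(0.0, 7.0, 1e-4)
        y = sinusoid_response(centered_params, w_amp, f, t)
        tail = y[t > 6.9]
        expected = operating_gain(centered_params, f) * w_amp
        assert 0.5 * (tail.max() - tail.min()) == pytest.approx(expected, rel=1e-4)

    def test_sinusoid_zero_input(self, centered_params):
        assert np.all(sinusoid_response(centered_params, 0.0, 10.0, self.t) == 0.0)

    def test_sinusoid_gain_invariant_under_amplitude(self, centered_params):
        t = np.linspace(0, 1, 1001)
        y1 = sinusoid_response(centered_params, 0.5, 10.0, t)
        y3 = sinusoid_response(centered_params, 1.5, 10.0, t)
        np.testing.assert_allclose(y3, 3.0 * y1, rtol=1e-13, atol=1e-15)


class TestNormalizedGainCurve:
    def test_reference_row_is_unity(self, published_model):
        d = [3.0, 13.0, 53.0]
        f = np.logspace(-1, 2, 31)
        curves = normalized_gain_curve(published_model, d, f)
        np.testing.assert_allclose(curves[0], 1.0, rtol=1e-14)

    def test_monotone_in_offset_at_passband(self, published_model):
        d = [3.0, 13.0, 23.0, 33.0, 43.0, 53.0, 103.0]
        curves = normalized_gain_curve(published_model, d, [10.0])
        assert np.all(np.diff(curves[:, 0]) > 0)

    def test_passband_ratio_matches_model_ratio(self, published_model):
        # exact ratio at the operating point: gain-multiplier ratio times
        # the tau-induced magnitude ratio (approximately the gain-multiplier
        # ratio alone in the flat-passband approximation)
        d = [3.0, 33.0]
        f = 10.0
        curves = normalized_gain_curve(published_model, d, [f])
        h3 = operating_gain(effective_params(published_model, 3.0), f)
        h33 = operating_gain(effective_params(published_model, 33.0), f)
        assert curves[1, 0] == pytest.approx(h33 / h3, rel=1e-12)
        quad_ratio = float(
            published_model.gain_multiplier(33.0) / published_model.gain_multiplier(3.0)
        )
        assert curves[1, 0] == pytest.approx(quad_ratio, rel=0.1)

    def test_missing_reference_rejected(self, published_model):
        with pytest.raises(ValueError, match="reference"):
            normalized_gain_curve(published_model, [13.0, 23.0], [10.0])
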