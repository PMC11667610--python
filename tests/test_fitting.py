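import numpy as np
import pytest

from sccdyn.bandpass import OffsetModel, effective_params, operating_gain
from sccdyn.datasets import (
    CANONICAL_D_CM,
    CANONICAL_GAIN,
    CANONICAL_TAU_L_S,
    canonical_gain_observations,
    canonical_tau_observations,
    load_bundled_observations,
)
from sccdyn.fitting import (
    ObservationSet,
    assemble_modified_model,
    fit_all_families,
    fit_family,
    mse,
    select_model,
)


def normal_equations(d, y, degree):
    """Closed-form OLS oracle via the normal equations."""
    X = np.vander(d, degree + 1, increasing=True)
    return np.linalg.solve(X.T @ X, X.T @ y)


@pytest.fixture(scope="module")
def tau_obs():
    return canonical_tau_observations()


@pytest.fixture(scope="module")
def gain_obs():
    return canonical_gain_observations()


class TestObservationSet:
    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            ObservationSet(d_values=[3, 13], y_values=[1.0, 0.9], kind="tau_L")

    def test_strictly_increasing_d(self):
        with pytest.raises(ValueError):
            ObservationSet(d_values=[3, 3, 13], y_values=[1, 1, 1], kind="tau_L")

    def test_csv_round_trip(self, tau_obs, tmp_path):
        path = tmp_path / "obs.csv"
        tau_obs.to_csv(path)
        back = ObservationSet.from_csv(path)
        np.testing.assert_allclose(back.y_values, tau_obs.y_values)
        assert back.kind == "tau_L"

    def test_bundled_fixtures_match_tables(self, tau_obs, gain_obs):
        np.testing.assert_allclose(load_bundled_observations("tau_L").y_values, tau_obs.y_values)
        np.testing.assert_allclose(load_bundled_observations("gain").y_values, gain_obs.y_values)


class TestFitFamily:
    def test_linear_matches_normal_equations(self, tau_obs):
        fit = fit_family(tau_obs, "linear")
        a, b = normal_equations(CANONICAL_D_CM, CANONICAL_TAU_L_S, 1)
        assert fit.coefficients["a"] == pytest.approx(a, rel=1e-10)
        assert fit.coefficients["b"] == pytest.approx(b, rel=1e-10)

    def test_quadratic_matches_normal_equations(self, gain_obs):
        fit = fit_family(gain_obs, "quadratic")
        c = normal_equations(CANONICAL_D_CM, CANONICAL_GAIN, 2)
        for key, ref in zip(("c0", "c1", "c2"), c):
            assert fit.coefficients[key] == pytest.approx(ref, rel=1e-10)

    def test_alpha_from_canonical_tau_pairs(self, tau_obs):
        # -slope/intercept of the tau_L offset law, to the 4 printed digits
        fit = fit_family(tau_obs, "linear")
        assert fit.normalized["alpha"] == pytest.approx(0.002143, abs=5e-7)

    def test_beta2_from_canonical_gain_pairs(self, gain_obs):
        fit = fit_family(gain_obs, "quadratic")
        assert fit.normalized["beta2"] == pytest.approx(0.000059, abs=5e-7)

    def test_beta1_close_to_printed_value(self, gain_obs):
        # printed 0.01295 came from unrounded simulation outputs; OLS on the
        # rounded table pairs lands at ≈0.01291
        fit = fit_family(gain_obs, "quadratic")
        assert fit.normalized["beta1"] == pytest.approx(0.01291, abs=5e-5)
        assert fit.normalized["beta1"] == pytest.approx(0.01295, rel=5e-3)

    def test_exact_linear_data_recovered(self):
        d = np.array([3.0, 13.0, 23.0, 43.0, 103.0])
        obs = ObservationSet(d, 1.0 - 0.002 * d, kind="tau_L")
        fit = fit_family(obs, "linear")
        assert fit.coefficients["a"] == pytest.approx(1.0, rel=1e-12)
        assert fit.coefficients["b"] == pytest.approx(-0.002, rel=1e-12)
        assert fit.mse == pytest.approx(0.0, abs=1e-28)

    def test_exponential_recovers_exact_exponential(self):
        d = np.array([3.0, 13.0, 23.0, 43.0, 103.0])
        obs = ObservationSet(d, 1.1 * np.exp(-0.004 * d), kind="tau_L")
        fit = fit_family(obs, "exponential")
        assert fit.coefficients["A"] == pytest.approx(1.1, rel=1e-8)
        assert fit.coefficients["k"] == pytest.approx(0.004, rel=1e-8)

    def test_too_few_points_rejected(self):
        obs = ObservationSet([3.0, 13.0, 23.0], [1.0, 0.9, 0.8], kind="tau_L")
        with pytest.raises(ValueError, match="at least"):
            fit_family(obs, "quadratic")

    def test_unknown_family_rejected(self, tau_obs):
        with pytest.raises(ValueError, match="family"):
            fit_family(tau_obs, "cubic")

    def test_shift_invariance_of_linear_residuals(self, tau_obs):
        # reparametrizing d by a constant shift changes the coefficients but
        # not the residuals, hence not the MSE
        fit0 = fit_family(tau_obs, "linear")
        shifted = ObservationSet(
            tau_obs.d_values + 17.0, tau_obs.y_values, kind="tau_L"
        )
        fit1 = fit_family(shifted, "linear")
        assert fit1.mse == pytest.approx(fit0.mse, rel=1e-9)


class TestMse:
    def test_canonical_tau_linear_mse(self, tau_obs):
        # SSE/n convention reproduces the printed 5.73e-6 s²
        assert fit_family(tau_obs, "linear").mse == pytest.approx(5.73e-6, rel=5e-3)

    def test_canonical_tau_quadratic_mse(self, tau_obs):
        assert fit_family(tau_obs, "quadratic").mse == pytest.approx(2.34e-6, rel=5e-3)

    def test_zero_residuals(self):
        assert mse(np.zeros(5)) == 0.0

    def test_divisor_is_n(self):
        assert mse([1.0, 2.0, 3.0, 0.0]) == pytest.approx(14.0 / 4.0)


class TestSelectModel:
    def test_default_policy_prefers_linear_tau(self, tau_obs):
        fits = fit_all_families(tau_obs)
        chosen = select_model(fits, policy="published-default")
        assert chosen.family == "linear"
        # even though the quadratic MSE is smaller
        assert min(fits, key=lambda f: f.mse).family == "quadratic"

    def test_default_policy_prefers_quadratic_gain(self, gain_obs):
        assert select_model(fit_all_families(gain_obs)).family == "quadratic"

    def test_min_mse_policy(self, tau_obs):
        chosen = select_model(fit_all_families(tau_obs), policy="min-mse")
        assert chosen.family == "quadratic"

    def test_mixed_kinds_rejected(self, tau_obs, gain_obs):
        with pytest.raises(ValueError):
            select_model([fit_family(tau_obs, "linear"), fit_family(gain_obs, "quadratic")])


class TestAssembleModifiedModel:
    def test_canonical_assembly(self, tau_obs, gain_obs):
        model = assemble_modified_model(
            fit_family(tau_obs, "linear"), fit_family(gain_obs, "quadratic")
        )
        assert model.alpha == pytest.approx(0.002143, abs=5e-7)
        assert model.beta2 == pytest.approx(0.000059, abs=5e-7)
        assert model.tau_S == 0.01
        assert model.d_ref == 0.0

    def test_identity_at_anchor(self, tau_obs, gain_obs):
        model = assemble_modified_model(
            fit_family(tau_obs, "linear"), fit_family(gain_obs, "quadratic")
        )
        p = effective_params(model, 0.0)
        assert p.K == pytest.approx(model.K0)
        assert p.tau_L == pytest.approx(model.tau_L0)

    def test_wrong_families_rejected(self, tau_obs, gain_obs):
        with pytest.raises(ValueError):
            assemble_modified_model(
                fit_family(tau_obs, "quadratic"), fit_family(gain_obs, "quadratic")
            )


class TestParameterRecovery:
    MODEL = OffsetModel(
        K0=0.1684, tau_L0=1.0338, tau_S=0.01, alpha=0.002143, beta1=0.01295, beta2=0.000059
    )

    def _observations(self, rng=None, noise=0.0):
        d = CANONICAL_D_CM
        tau = self.MODEL.tau_L0 * self.MODEL.tau_multiplier(d)
        gain = self.MODEL.K0 * self.MODEL.gain_multiplier(d)
        if rng is not None and noise > 0:
            tau = tau * (1.0 + noise * rng.standard_normal(d.size))
            gain = gain * (1.0 + noise * rng.standard_normal(d.size))
        return (
            ObservationSet(d, tau, kind="tau_L", source="synthetic"),
            ObservationSet(d, gain, kind="gain", source="synthetic"),
        )

    def test_noise_free_recovery_is_exact(self):
        obs_tau, obs_gain = self._observations()
        model = assemble_modified_model(
            fit_family(obs_tau, "linear"), fit_family(obs_gain, "quadratic")
        )
        assert model.alpha == pytest.approx(self.MODEL.alpha, rel=1e-6)
        assert model.beta1 == pytest.approx(self.MODEL.beta1, rel=1e-6)
        assert model.beta2 == pytest.approx(self.MODEL.beta2, rel=1e-6)

    def test_recovery_under_one_percent_noise(self):
        # 1% multiplicative Gaussian noise at the seven canonical offsets,
        # 1000 seeded replicates: mean recovered constants within 5%
        rng = np.random.default_rng(20240101)
        alphas, beta1s, beta2s = [], [], []
        for _ in range(1000):
            obs_tau, obs_gain = self._observations(rng, noise=0.01)
            m = assemble_modified_model(
                fit_family(obs_tau, "linear"), fit_family(obs_gain, "quadratic")
            )
            alphas.append(m.alpha)
            beta1s.append(m.beta1)
            beta2s.append(m.beta2)
        assert np.mean(alphas) == pytest.approx(self.MODEL.alpha, rel=0.05)
        assert np.mean(beta1s) == pytest.approx(self.MODEL.beta1, rel=0.05)
        assert np.mean(beta2s) == pytest.approx(self.MODEL.beta2, rel=0.05)
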