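import numpy as np
import pytest

import hemofluid as hf
from hemofluid.calibration import (
    CALIBRATED_VARIABLES,
    FREE_PARAMS,
    CalibrationConfig,
    default_bounds_and_scales,
    log_likelihood,
    neg_log_likelihood,
    objective,
    residuals,
    sigma_mle,
)


@pytest.fixture(scope="module")
def lr2_noiseless(lr2_synthetic):
    lr2, protocol, result, _ = lr2_synthetic
    series = hf.sample_measurements(result, 5.0, {v: 0.0 for v in hf.MEASURED_VARIABLES},
                                    subject_id="LR2")
    return lr2, protocol, series


class TestResiduals:
    def test_noiseless_self_fit_residuals_vanish(self, lr2_noiseless):
        lr2, protocol, series = lr2_noiseless
        res = residuals(lr2, series, protocol, sim_dt=0.05)
        for var in hf.MEASURED_VARIABLES:
            scale = np.mean(series.values[var])
            assert np.max(np.abs(res[var])) < 1e-5 * scale

    def test_constant_offset_passes_through(self, lr2_noiseless):
        lr2, protocol, series = lr2_noiseless
        shifted = hf.MeasurementSeries(
            series.times,
            {v: (a + 2.0 if v == "hr" else a.copy()) for v, a in series.values.items()},
        )
        res = residuals(lr2, shifted, protocol, sim_dt=0.05)
        np.testing.assert_allclose(res["hr"], 2.0, atol=1e-5)

    def test_residual_sd_matches_injected_noise(self, lr2_synthetic):
        lr2, protocol, _, series = lr2_synthetic  # default noise, seed 7
        res = residuals(lr2, series, protocol, sim_dt=0.05)
        for var, frac in hf.DEFAULT_NOISE_SD.items():
            injected = frac * series.values[var][0]
            # K = 37 samples; the empirical SD is itself noisy
            assert abs(np.std(res[var]) / injected - 1.0) < 0.30, var

    def test_simulation_failure_propagates(self, lr2_noiseless):
        lr2, protocol, series = lr2_noiseless
        lethal = hf.FluidProtocol.from_events(180.0, loss_events=[(0, 120, 0.1)])
        with pytest.raises(RuntimeError, match="simulation failed"):
            residuals(lr2, series, lethal)


class TestSigmaAndLikelihood:
    def test_sigma_closed_form(self):
        assert sigma_mle(np.array([1.0, -1.0, 1.0, -1.0])) == 1.0

    def test_sigma_floor_on_degenerate_residuals(self):
        assert sigma_mle(np.zeros(10), floor=1e-6) == 1e-6

    def test_sigma_sampling_distribution(self):
        rng = np.random.default_rng(5)
        e = rng.normal(0.0, 2.0, size=10_000)
        assert 1.94 <= sigma_mle(e) <= 2.06

    def test_sigma_needs_two_residuals(self):
        with pytest.raises(ValueError):
            sigma_mle(np.array([1.0]))

    def test_log_likelihood_worked_examples(self):
        e = np.array([1.0, -1.0, 1.0, -1.0])  # K=4, sum e^2 = 4
        assert log_likelihood(e, 1.0) == pytest.approx(-2 * np.log(2 * np.pi) - 2)
        assert log_likelihood(np.zeros(2), 1.0) == pytest.approx(-np.log(2 * np.pi))
        with pytest.raises(ValueError):
            log_likelihood(e, 0.0)

    def test_concentrated_likelihood_identity(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            e = rng.normal(0, rng.uniform(0.5, 3.0), size=rng.integers(5, 50))
            s = sigma_mle(e)
            direct = log_likelihood(e, s)
            K = e.size
            closed = -(K / 2) * (np.log(2 * np.pi) + np.log(s**2) + 1.0)
            assert direct == pytest.approx(closed, rel=1e-12)

    def test_concentrated_sigma_maximizes_likelihood(self):
        # for any residual set, L* at sigma_hat >= L* at any other sigma
        rng = np.random.default_rng(3)
        for _ in range(10):
            e = rng.normal(0, 2.0, size=30)
            s_hat = sigma_mle(e)
            best = log_likelihood(e, s_hat)
            for s in (0.3, 0.9, 1.7, 2.9, 8.0):
                assert log_likelihood(e, s) <= best + 1e-12


class TestObjective:
    def test_penalty_linear_in_beta(self, lr2_noiseless):
        lr2, protocol, series = lr2_noiseless
        cfg0 = CalibrationConfig(beta=0.0)
        cfg1 = CalibrationConfig(beta=1e-3)
        cfg2 = CalibrationConfig(beta=2e-3)
        f0 = objective(lr2, series, protocol, 0.0, cfg0)
        f1 = objective(lr2, series, protocol, 1e-3, cfg1)
        f2 = objective(lr2, series, protocol, 2e-3, cfg2)
        _, scales, _ = default_bounds_and_scales()
        x = np.array([getattr(lr2, n) / scales[n] for n in FREE_PARAMS])
        pen_unit = float(x @ x)
        assert f1 - f0 == pytest.approx(2e-3 * pen_unit, rel=1e-9)
        assert f2 - f1 == pytest.approx(f1 - f0, rel=1e-9)

    def test_noiseless_objective_at_sigma_floor(self, lr2_noiseless):
        lr2, protocol, series = lr2_noiseless
        cfg = CalibrationConfig(beta=0.0, sim_dt=0.05)
        K = len(series.times)
        floor = CalibrationConfig().sigma_floor
        bound = sum(K / 2 * (np.log(2 * np.pi) + np.log(floor**2))
                    for _ in CALIBRATED_VARIABLES)
        val = objective(lr2, series, protocol, 0.0, cfg)
        assert bound <= val < bound + 4 * K  # within the +K/2 SSE allowance

    def test_failure_maps_to_large_finite_value(self, lr2_noiseless):
        lr2, protocol, series = lr2_noiseless
        lethal = hf.FluidProtocol.from_events(180.0, loss_events=[(0, 120, 0.1)])
        val = objective(lr2, series, lethal, 1e-3)
        assert np.isfinite(val) and val >= 1e11


class TestFit:
    def test_needs_two_samples_per_variable(self, lr2_noiseless):
        lr2, protocol, series = lr2_noiseless
        vals = {v: np.where(np.arange(len(series.times)) == 0, a, np.nan)
                for v, a in series.values.items()}
        vals["co"] = series.values["co"].copy()
        with pytest.raises(ValueError):
            sparse = hf.MeasurementSeries(series.times, vals)
            hf.fit(sparse, protocol, {"BV0": lr2.BV0, "HCT0": lr2.HCT0, "SV0": lr2.SV0})

    def test_baselines_required(self, lr2_noiseless):
        lr2, protocol, series = lr2_noiseless
        with pytest.raises(ValueError, match="BV0"):
            hf.fit(series, protocol, {"HCT0": lr2.HCT0, "SV0": lr2.SV0})

    def test_truth_is_stationary_on_noiseless_data(self, lr2_noiseless):
        lr2, protocol, series = lr2_noiseless
        cfg = CalibrationConfig(n_starts=1, seed=0, beta=0.0, init=[lr2])
        result = hf.fit(series, protocol,
                        {"BV0": lr2.BV0, "HCT0": lr2.HCT0, "SV0": lr2.SV0}, cfg)
        rel = np.abs(result.params.to_array() - lr2.to_array()) / np.maximum(
            np.abs(lr2.to_array()), 1e-9)
        assert np.max(rel) < 1e-3
        for var in CALIBRATED_VARIABLES:
            assert result.nrmse[var] < 0.01

    def test_fixed_baselines_honoured(self, lr2_synthetic):
        lr2, protocol, _, series = lr2_synthetic
        cfg = CalibrationConfig(n_starts=2, seed=1, maxiter=40, n_explore_per_start=8)
        result = hf.fit(series, protocol,
                        {"BV0": lr2.BV0, "HCT0": lr2.HCT0, "SV0": lr2.SV0}, cfg)
        assert result.params.BV0 == lr2.BV0
        assert result.params.HCT0 == lr2.HCT0
        assert result.params.SV0 == lr2.SV0
        assert len(result.start_objectives) == 2

    def test_stronger_regularization_shrinks_parameters(self, lr2_synthetic):
        lr2, protocol, _, series = lr2_synthetic
        base = {"BV0": lr2.BV0, "HCT0": lr2.HCT0, "SV0": lr2.SV0}
        _, scales, _ = default_bounds_and_scales()
        norms = []
        for beta in (1e-3, 1e2):
            cfg = CalibrationConfig(beta=beta, n_starts=1, seed=0, init=[lr2],
                                    maxiter=150)
            result = hf.fit(series, protocol, base, cfg)
            x = np.array([getattr(result.params, n) / scales[n] for n in FREE_PARAMS])
            norms.append(float(np.sqrt(x @ x)))
        assert norms[1] <= norms[0] + 1e-9

    def test_result_json_round_trip(self, tmp_path, lr2_noiseless):
        lr2, protocol, series = lr2_noiseless
        cfg = CalibrationConfig(n_starts=1, seed=0, init=[lr2], maxiter=5)
        result = hf.fit(series, protocol,
                        {"BV0": lr2.BV0, "HCT0": lr2.HCT0, "SV0": lr2.SV0}, cfg)
        path = tmp_path / "fit.json"
        result.to_json(path)
        again = hf.CalibrationResult.from_json(path)
        np.testing.assert_array_equal(again.params.to_array(), result.params.to_array())
        assert again.neg_ll == result.neg_ll
        assert again.sigma == result.sigma
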