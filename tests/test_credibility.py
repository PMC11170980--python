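import numpy as np
import pandas as pd
import pytest

import hemofluid as hf
from hemofluid import MeasurementSeries, PredictionEnvelope
from hemofluid.credibility import _nrmse_matrix


def make_series(times, **overrides):
    base = {"hct": 20.0, "hr": 70.0, "sv": 0.05, "co": 3.5, "bp": 75.0}
    values = {}
    for var in hf.MEASURED_VARIABLES:
        v = overrides.get(var, base[var])
        values[var] = np.full(len(times), float(v)) if np.isscalar(v) else np.asarray(v, float)
    return MeasurementSeries(np.asarray(times, float), values)


class TestErrorMetrics:
    def test_identical_series_have_zero_error(self):
        v = np.array([10.0, 12.0, 9.0])
        assert hf.nrmse(v, v) == 0.0
        assert hf.nmae(v, v) == 0.0

    def test_worked_example(self):
        obs = np.array([10.0, 10.0])
        sim = np.array([12.0, 8.0])
        assert hf.nrmse(obs, sim) == pytest.approx(20.0)
        assert hf.nmae(obs, sim) == pytest.approx(20.0)

    def test_agrees_with_literal_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            K = rng.integers(2, 40)
            obs = rng.uniform(5, 50, K)
            sim = obs + rng.normal(0, 3, K)
            literal_rmse = 100 * np.sqrt(np.sum((obs - sim) ** 2) / K) / np.mean(obs)
            literal_mae = 100 * (np.sum(np.abs(obs - sim)) / K) / np.mean(obs)
            assert abs(hf.nrmse(obs, sim) - literal_rmse) <= 1e-12
            assert abs(hf.nmae(obs, sim) - literal_mae) <= 1e-12
            assert hf.nmae(obs, sim) <= hf.nrmse(obs, sim) + 1e-12

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            hf.nrmse(np.array([1.0, -1.0]), np.array([0.0, 0.0]))

    def test_missing_values_skipped(self):
        obs = np.array([10.0, np.nan, 10.0])
        sim = np.array([12.0, 99.0, 8.0])
        assert hf.nrmse(obs, sim) == pytest.approx(20.0)


class TestPhysiologicalFilter:
    def make_outputs(self, hr_peak):
        # (1, T, 6) trajectory constant except an HR excursion
        T = 10
        out = np.tile(np.array([2.3, 21.6, 70.0, 0.05, 3.5, 77.0]), (1, T, 1))
        out[0, 5, 2] = hr_peak
        return out

    def test_hr_peak_above_range_excluded(self):
        keep, pct = hf.physiological_filter(self.make_outputs(310.0))
        assert not keep[0] and pct == 0.0

    def test_boundary_values_kept(self):
        keep, _ = hf.physiological_filter(self.make_outputs(300.0))
        assert keep[0]

    def test_percentage_arithmetic(self):
        outs = np.concatenate([self.make_outputs(70.0)] * 6 +
                              [self.make_outputs(301.0)] * 4)
        _, pct = hf.physiological_filter(outs)
        assert pct == pytest.approx(60.0)

    def test_failed_simulations_excluded(self):
        outs = self.make_outputs(70.0)
        keep, _ = hf.physiological_filter(outs, ok=np.array([False]))
        assert not keep[0]

    def test_all_constrained_variables_checked(self):
        for col, bad in ((1, 51.0), (3, 0.11), (5, 151.0), (1, -0.5)):
            outs = self.make_outputs(70.0)
            outs[0, 3, col] = bad
            keep, _ = hf.physiological_filter(outs)
            assert not keep[0], (col, bad)
        # CO is unconstrained
        outs = self.make_outputs(70.0)
        outs[0, 3, 4] = 500.0
        keep, _ = hf.physiological_filter(outs)
        assert keep[0]


class TestRelevanceFilter:
    def sims_with_nrmse(self, series, targets):
        """One simulation per target: constant offset giving that NRMSE."""
        K = len(series.times)
        sims = np.zeros((len(targets), K, 6))
        for i, per_var in enumerate(targets):
            for var, col in zip(hf.MEASURED_VARIABLES, (1, 2, 3, 4, 5)):
                obs = series.values[var]
                sims[i, :, col] = obs * (1.0 + per_var[var] / 100.0)
        return sims

    def test_uniform_24_is_relevant(self):
        series = make_series(np.arange(0, 50, 5))
        sims = self.sims_with_nrmse(series, [{v: 24.0 for v in hf.MEASURED_VARIABLES}])
        mask, pct, nr = hf.relevance_filter(sims, series)
        assert mask[0] and pct == 100.0
        np.testing.assert_allclose(nr[0], 24.0, rtol=1e-9)

    def test_single_variable_failure_disqualifies(self):
        series = make_series(np.arange(0, 50, 5))
        targets = [{"hct": 24.0, "hr": 26.0, "sv": 5.0, "co": 5.0, "bp": 5.0}]
        mask, pct, _ = hf.relevance_filter(self.sims_with_nrmse(series, targets), series)
        assert not mask[0] and pct == 0.0


class TestEnvelope:
    def test_single_simulation_collapses_band(self):
        series = make_series(np.arange(0, 30, 5))
        sims = np.random.default_rng(1).uniform(1, 2, size=(1, 6, 6))
        env = hf.build_envelope(sims, series.times)
        for var in hf.MEASURED_VARIABLES:
            np.testing.assert_array_equal(env.lower[var], env.upper[var])

    def test_two_simulations_span(self):
        times = np.arange(0, 30, 5)
        lo = np.full((1, 6, 6), 1.0)
        hi = np.full((1, 6, 6), 3.0)
        env = hf.build_envelope(np.concatenate([lo, hi]), times)
        for var in hf.MEASURED_VARIABLES:
            np.testing.assert_array_equal(env.lower[var], 1.0)
            np.testing.assert_array_equal(env.upper[var], 3.0)

    def test_envelope_monotone_under_supersets(self):
        times = np.arange(0, 40, 5)
        rng = np.random.default_rng(5)
        sims = rng.uniform(1, 10, size=(30, len(times), 6))
        env_sub = hf.build_envelope(sims[:10], times)
        env_all = hf.build_envelope(sims, times)
        for var in hf.MEASURED_VARIABLES:
            assert np.all(env_all.lower[var] <= env_sub.lower[var])
            assert np.all(env_all.upper[var] >= env_sub.upper[var])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="no relevant"):
            hf.build_envelope(np.empty((0, 5, 6)), np.arange(5.0))


class TestCoverageAndNis:
    def band(self, times, lo, hi):
        return PredictionEnvelope(
            np.asarray(times, float),
            {v: np.full(len(times), float(lo)) for v in hf.MEASURED_VARIABLES},
            {v: np.full(len(times), float(hi)) for v in hf.MEASURED_VARIABLES},
            n_relevant=2,
        )

    def test_full_and_zero_coverage(self):
        times = np.arange(0, 30, 5)
        series = make_series(times, hct=20, hr=20, sv=20, co=20, bp=20)
        assert hf.coverage(self.band(times, 10, 30), series) == 100.0
        assert hf.coverage(self.band(times, 1, 5), series) == 0.0

    def test_coverage_monotone_in_envelope(self):
        times = np.arange(0, 40, 5)
        rng = np.random.default_rng(9)
        sims = rng.uniform(15, 25, size=(40, len(times), 6))
        series = make_series(times, hct=20, hr=20, sv=20, co=20, bp=20)
        prev = -1.0
        for n in (2, 10, 40):
            cov = hf.coverage(hf.build_envelope(sims[:n], times), series)
            assert cov >= prev
            prev = cov

    def test_nis_branches_worked_examples(self):
        times = [0.0, 5.0]
        inside = make_series(times, hct=10, hr=10, sv=10, co=10, bp=10)
        below = make_series(times, hct=4, hr=4, sv=4, co=4, bp=4)
        above = make_series(times, hct=16, hr=16, sv=16, co=16, bp=16)
        band = self.band(times, 8.0, 12.0)
        assert hf.nis(band, inside)["hct"] == pytest.approx(0.4)
        assert hf.nis(band, below)["hr"] == pytest.approx(41.0)
        assert hf.nis(band, above)["bp"] == pytest.approx(10.25)

    def test_nis_continuous_at_band_edges(self):
        times = [0.0, 5.0]
        band = self.band(times, 8.0, 12.0)
        at_edge = hf.nis(band, make_series(times, **{v: 8.0 for v in hf.MEASURED_VARIABLES}))
        just_in = hf.nis(band, make_series(times, **{v: 8.0 + 1e-9 for v in hf.MEASURED_VARIABLES}))
        assert at_edge["sv"] == pytest.approx(just_in["sv"], rel=1e-6)

    def test_inside_score_is_relative_width(self):
        times = [0.0, 5.0]
        series = make_series(times, **{v: 10.0 for v in hf.MEASURED_VARIABLES})
        assert hf.nis(self.band(times, 9.0, 11.0), series)["co"] == pytest.approx(0.2)


class TestBestVirtualSubject:
    def test_identical_simulation_wins_with_zero_error(self):
        times = np.arange(0, 30, 5)
        series = make_series(times)
        K = len(times)
        exact = np.zeros((1, K, 6))
        for var, col in zip(hf.MEASURED_VARIABLES, (1, 2, 3, 4, 5)):
            exact[0, :, col] = series.values[var]
        off = exact * 1.10
        best = hf.best_virtual_subject(np.concatenate([off, exact]), series)
        assert best["index"] == 1
        assert best["avg_nrmse"] == pytest.approx(0.0, abs=1e-9)
        assert best["max_nmae"] == pytest.approx(0.0, abs=1e-9)

    def test_argmin_on_average_nrmse(self):
        times = np.arange(0, 30, 5)
        series = make_series(times)
        K = len(times)
        sims = np.zeros((2, K, 6))
        for var, col in zip(hf.MEASURED_VARIABLES, (1, 2, 3, 4, 5)):
            sims[0, :, col] = series.values[var] * 1.12
            sims[1, :, col] = series.values[var] * 1.10
        best = hf.best_virtual_subject(sims, series)
        assert best["index"] == 1

    def test_tie_break_on_max_then_index(self):
        times = np.arange(0, 30, 5)
        series = make_series(times)
        K = len(times)
        sims = np.zeros((2, K, 6))
        # same average NRMSE (10%), but sim 1 concentrates error in one variable
        for var, col in zip(hf.MEASURED_VARIABLES, (1, 2, 3, 4, 5)):
            sims[0, :, col] = series.values[var] * 1.10
        for var, col, f in zip(hf.MEASURED_VARIABLES, (1, 2, 3, 4, 5),
                               (1.30, 1.05, 1.05, 1.05, 1.05)):
            sims[1, :, col] = series.values[var] * f
        best = hf.best_virtual_subject(sims, series)
        assert best["index"] == 0  # lower maximum wins the tie
        dup = np.concatenate([sims[:1], sims[:1]])
        assert hf.best_virtual_subject(dup, series)["index"] == 0  # then lowest index


class TestAssess:
    def test_self_recovery_with_generator_in_cohort(self, lr2, reference_subjects):
        # zero-noise test data generated at the assessment step size, so the
        # generating subject reproduces its own measurements exactly
        protocol = hf.make_sheep_protocol(params=lr2,
                                          weight_kg=lr2.BV0 * 1000 / 60)
        result = hf.simulate(lr2, protocol, 1.0,
                             hf.SolverConfig(method="rk4", dt=0.1))
        series = hf.sample_measurements(result, 5.0,
                                        {v: 0.0 for v in hf.MEASURED_VARIABLES})
        cohort = [lr2, reference_subjects[3], reference_subjects[5]]
        report = hf.assess(series, protocol, cohort)
        assert report.pct_coverage == 100.0
        assert report.best_subject["avg_nrmse"] < 0.05
        assert report.nis is not None
        assert not report.flags

    def test_all_nonphysiological_cohort_flagged(self, lr2):
        protocol, result, series = hf.make_synthetic_subject_data(lr2, seed=3)
        giant_sv = lr2.replace(SV0=0.15, r_SV=0.15)  # SV range is (0, 0.1] l
        report = hf.assess(series, protocol, [giant_sv])
        assert report.pct_physiological == 0.0
        assert "no-physiological-subjects" in report.flags

    def test_no_relevant_subjects_flagged(self, lr2, reference_subjects):
        protocol, result, series = hf.make_synthetic_subject_data(lr2, seed=3)
        # a physiological but unresponsive subject: flat trajectories cannot
        # track the perturbed test data within 25% on every variable
        flat = reference_subjects[3].replace(G_V_T=0.0, G_V_L=0.0, G_U_T=0.0,
                                             G_BV=0.0, G_HR=0.0)
        report = hf.assess(series, protocol, [flat])
        assert report.pct_physiological > 0.0
        assert "no-relevant-subjects" in report.flags
        assert report.nis is None and report.pct_coverage is None

    def test_report_round_trips_through_serialization(self, tmp_path, lr2, reference_subjects):
        protocol, result, _ = hf.make_synthetic_subject_data(lr2, seed=3)
        series = hf.sample_measurements(result, 5.0, seed=4)
        cohort = hf.generate_cohort(reference_subjects, lr2.baselines(),
                                    hf.CohortConfig(size=150, seed=6))
        report = hf.assess(series, protocol, cohort)
        assert report.envelope is not None
        env_path = tmp_path / "envelope.csv"
        report.envelope.to_csv(env_path)
        df = pd.read_csv(env_path)
        rebuilt = PredictionEnvelope(
            series.times,
            {v: df[df.variable == v].lower.to_numpy() for v in hf.MEASURED_VARIABLES},
            {v: df[df.variable == v].upper.to_numpy() for v in hf.MEASURED_VARIABLES},
            n_relevant=report.n_relevant,
        )
        recomputed = hf.nis(rebuilt, series)
        for var in hf.MEASURED_VARIABLES:
            assert recomputed[var] == pytest.approx(report.nis[var], rel=1e-9)
        assert hf.coverage(rebuilt, series) == pytest.approx(report.pct_coverage)
        report.to_json(tmp_path / "report.json")
        import json
        payload = json.loads((tmp_path / "report.json").read_text())
        assert payload["cohort"]["pct_physiological"] == report.pct_physiological
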