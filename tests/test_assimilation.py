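import numpy as np
import pandas as pd
import pytest

from pollenda import (
    CovarianceConfig,
    ObsOperator,
    StationSeries,
    StopConfig,
    background_correlation,
    cost_and_gradient,
    fit_lcurve,
    minimize_truncated,
    scalar_station_assimilate,
    xi_opt_closed_form,
)
from pollenda.assimilation import background_cholesky, correlation_matrix


class TestBackgroundCorrelation:
    def test_identity_at_zero_distance(self):
        assert background_correlation(5.0, 50.0, 5.0, 50.0, 250.0) == pytest.approx(1.0)

    def test_one_correlation_length(self):
        # pick two points 250 km apart along a meridian: 250/111.19 degrees
        dlat = 250.0 / 111.19
        c = background_correlation(0.0, 50.0, 0.0, 50.0 + dlat, 250.0)
        assert c == pytest.approx(np.exp(-1.0), rel=1e-3)

    def test_two_correlation_lengths(self):
        dlat = 500.0 / 111.19
        c = background_correlation(0.0, 50.0, 0.0, 50.0 + dlat, 250.0)
        assert c == pytest.approx(np.exp(-4.0), rel=1e-3)

    def test_matrix_symmetric_positive_definite(self, grid_small):
        c = correlation_matrix(grid_small, 250.0)
        assert np.allclose(c, c.T)
        np.linalg.cholesky(c)  # must not raise


class TestClosedFormOptimum:
    def test_perfect_correlation_is_ratio_of_means(self):
        assert xi_opt_closed_form(10.0, 5.0, 0.8, 0.8) == pytest.approx(2.0)

    def test_uncorrelated_unit_variance_halves(self):
        assert xi_opt_closed_form(1.0, 1.0, 0.0, 1.0) == pytest.approx(0.5)

    def test_constant_series(self):
        assert xi_opt_closed_form(6.0, 3.0, 0.0, 0.0) == pytest.approx(2.0)

    def test_zero_model_mean_rejected(self):
        with pytest.raises(ValueError):
            xi_opt_closed_form(1.0, 0.0, 0.0, 0.0)


class TestScalarAssimilation:
    def test_matches_least_squares_ratio(self):
        rng = np.random.default_rng(1)
        z = rng.uniform(1, 10, 50)
        y = 1.7 * z * (1 + 0.1 * rng.standard_normal(50))
        xi = scalar_station_assimilate(y, z)
        assert xi == pytest.approx(float((y * z).sum() / (z * z).sum()), rel=1e-6)

    def test_strong_background_pins_to_one(self):
        z = np.ones(20)
        y = 3.0 * z
        xi = scalar_station_assimilate(y, z, background_variance=1e-9)
        assert xi == pytest.approx(1.0, abs=1e-3)


class TestLCurveFit:
    def test_roundtrip_exact_hyperbola(self):
        a, b, c = 3.0, 40.0, 2.0
        x = np.linspace(0.0, 30.0, 12)
        y = a + b / (x + c)
        params, slope0, stop = fit_lcurve(x, y)
        assert params is not None
        assert params[0] == pytest.approx(a, abs=1e-6)
        assert params[1] == pytest.approx(b, rel=1e-6)
        assert params[2] == pytest.approx(c, rel=1e-6)

    def test_stop_before_flat_tail(self):
        x = np.linspace(0.0, 50.0, 40)
        y = 1.0 + 100.0 / (x + 1.0)
        _, _, stop = fit_lcurve(x, y)
        assert 0 < stop < 39

    def test_two_points_degenerate(self):
        params, _, stop = fit_lcurve(np.array([0.0, 1.0]), np.array([5.0, 4.0]))
        assert params is None and stop == 1


class TestCostAndGradient:
    @pytest.fixture()
    def tiny_problem(self, scenario_small):
        cfg, scen, fg = scenario_small
        series = [
            StationSeries(
                r.station_id, r.lon, r.lat,
                scen.obs[r.station_id]["value"], scen.obs[r.station_id]["valid"],
            )
            for _, r in scen.stations.table.iterrows()
        ][:3]
        op = ObsOperator(scen.transport, fg.emission.rate, series, scen.window)
        L = background_cholesky(cfg.grid, cfg.cov)
        return cfg, op, L

    def test_background_term_zero_at_background(self, tiny_problem):
        cfg, op, L = tiny_problem
        zeta = np.zeros(op.grid.n_cells)
        _, _, _, j_bg = cost_and_gradient(zeta, op, cfg.cov, L)
        assert j_bg == 0.0

    def test_perfect_model_zero_obs_term(self, tiny_problem):
        cfg, op, L = tiny_problem
        op_perfect = op
        op_perfect.y = op.apply(np.ones(op.grid.shape))
        j, _, j_obs, j_bg = cost_and_gradient(
            np.zeros(op.grid.n_cells), op_perfect, cfg.cov, L
        )
        assert j == pytest.approx(0.0, abs=1e-20)

    def test_gradient_matches_finite_differences(self, tiny_problem):
        """Adjoint gradient against central differences on a handful of
        cells (the independent derivative oracle)."""
        cfg, op, L = tiny_problem
        rng = np.random.default_rng(0)
        zeta = 0.1 * rng.standard_normal(op.grid.n_cells)
        _, grad, _, _ = cost_and_gradient(zeta, op, cfg.cov, L)
        eps = 1e-6
        for cell in [5, 17, 23, 30, 41]:
            zp = zeta.copy(); zp[cell] += eps
            zm = zeta.copy(); zm[cell] -= eps
            jp, _, _, _ = cost_and_gradient(zp, op, cfg.cov, L)
            jm, _, _, _ = cost_and_gradient(zm, op, cfg.cov, L)
            fd = (jp - jm) / (2 * eps)
            assert grad[cell] == pytest.approx(fd, rel=1e-5, abs=1e-10)

    def test_overflow_flagged(self, tiny_problem):
        cfg, op, L = tiny_problem
        zeta = np.full(op.grid.n_cells, 800.0)
        with pytest.raises(FloatingPointError):
            cost_and_gradient(zeta, op, cfg.cov, L)


class TestMinimizeTruncated:
    def test_no_observations_returns_background(self, scenario_small):
        cfg, scen, fg = scenario_small
        op = ObsOperator(scen.transport, fg.emission.rate, [], scen.window)
        res = minimize_truncated(op, cfg.cov, cfg.stop)
        assert np.all(res.xi == 1.0)

    def test_observations_equal_model_stay_at_background(self, scenario_small):
        cfg, scen, fg = scenario_small
        series = [
            StationSeries(
                r.station_id, r.lon, r.lat,
                scen.obs[r.station_id]["value"], scen.obs[r.station_id]["valid"],
            )
            for _, r in scen.stations.table.iterrows()
        ][:4]
        op = ObsOperator(scen.transport, fg.emission.rate, series, scen.window)
        op.y = op.apply(np.ones(op.grid.shape))   # first-guess output as data
        res = minimize_truncated(op, cfg.cov, StopConfig(max_iterations=10))
        assert np.allclose(res.xi, 1.0, atol=1e-6)

    def test_obs_term_dominates_background_at_stop(self, scenario_small):
        """With the default covariance magnitudes the data term of the cost
        exceeds the background term by orders of magnitude."""
        cfg, scen, fg = scenario_small
        series = [
            StationSeries(
                r.station_id, r.lon, r.lat,
                scen.obs[r.station_id]["value"], scen.obs[r.station_id]["valid"],
            )
            for _, r in scen.stations.table.iterrows()
        ]
        op = ObsOperator(scen.transport, fg.emission.rate, series, scen.window)
        res = minimize_truncated(op, cfg.cov, cfg.stop)
        d = res.diagnostics
        k = d.stop_index
        if k > 0 and d.j_bg[k] > 0:
            assert d.j_obs[k] / d.j_bg[k] >= 100.0
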