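"""Reproducible synthetic-truth experiments.

Each function runs one self-contained observing-system simulation
experiment — generate a known truth, observe it imperfectly, run the
method, measure what came back — and returns plain numbers.  They are
the package's own evidence base: the test suite asserts on them and the
acceptance script reports them.

Problem sizes are chosen so every experiment completes in seconds to a
couple of minutes on one CPU while preserving the geometry that matters
(multiple stations per truth correlation length, a full flowering
season, an 80/20 station split).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assimilation import (
    ObsOperator,
    StopConfig,
    minimize_truncated,
    scalar_station_assimilate,
    xi_opt_closed_form,
)
from .grid import GridSpec
from .observations import StationSeries, average_2day
from .phenology import simulate_emission
from .pipeline import (
    RunConfig,
    build_calibration,
    build_year_scenario,
    run_da,
    run_final,
    run_first_guess,
    subseed,
)
from .synthetic import MeteoConfig, NoiseConfig, gen_meteo
from .transport import LinearTransport


def replicate_median(fn, seed: int, n_replicates: int = 3, **kwargs) -> dict:
    """Run a stochastic experiment ``n_replicates`` times with seeds
    derived from ``seed`` and return the per-key median of the numeric
    results (plus the raw replicates under "replicates").

    The single-draw experiments are noisy by nature; the median over a
    small fixed set of replicates is the quantity the package's checks
    assert on.
    """
    reps = [fn(subseed(seed, 101, k), **kwargs) for k in range(n_replicates)]
    out: dict = {"replicates": reps}
    for key, val in reps[0].items():
        if isinstance(val, (int, float)) and not isinstance(val, bool):
            out[key] = float(np.median([r[key] for r in reps]))
    return out


def _mild_weather() -> MeteoConfig:
    """Warm, dry, rain-free weather that never limits pollen release."""
    return MeteoConfig(
        t_base_K=290.0, seasonal_trend_K_per_day=0.1, noise_sigma_K=1.0,
        q_base_pct=40.0, q_sigma_pct=3.0, wet_day_prob=0.0,
        wind_speed_scale_m_s=3.0,
    )


def adjoint_identity(seed: int = 0, nx: int = 8, ny: int = 6, n_days: int = 20) -> float:
    """Relative error of the transport dot-product identity
    <forward(e), w> == <e, adjoint(w)> on random fields."""
    grid = GridSpec(0.0, float(nx), 45.0, 45.0 + ny, nx, ny)
    meteo = gen_meteo(grid, n_days, subseed(seed, 11))
    tr = LinearTransport.from_meteo(meteo)
    rng = np.random.default_rng(subseed(seed, 12))
    e = rng.random((n_days, ny, nx))
    w = rng.random((n_days, ny, nx))
    a = float(np.vdot(tr.forward(e), w))
    b = float(np.vdot(e, tr.adjoint(w)))
    return abs(a - b) / max(abs(a), 1e-300)


def footprint_union(scen, station_ids, threshold: float = 0.1) -> np.ndarray:
    """Boolean mask of producing cells appreciably seen by the given
    stations: summed adjoint footprints above ``threshold`` of their
    maximum, intersected with the taxon's presence area."""
    tbl = scen.stations.table.set_index("station_id")
    total = np.zeros(scen.transport.grid.shape)
    for sid in station_ids:
        row = tbl.loc[sid]
        total += scen.transport.station_footprint(row.lon, row.lat, scen.window)
    return (total > threshold * total.max()) & (scen.landscape.phi > 0.01)


def recovery_experiment(
    seed: int = 0,
    years: tuple[int, ...] = (2000, 2001, 2002),
    noise_sigma: float = 0.3,
) -> dict:
    """Multi-year parameter recovery under noisy observations.

    A smooth synoptic-scale truth correction field in [0.5, 2] drives
    each year's season; 30 coverage-oriented stations observe it with
    multiplicative lognormal noise (sigma 0.3) and occasional missing
    days.  Each year is assimilated independently; the returned
    ``eval_rmse_ratio`` pools the evaluation-station residuals (stop
    iteration vs background) across years, and ``xi_truth_correlation``
    pools recovered-vs-true correction values over the footprint-union
    cells of all years.
    """
    cfg = RunConfig(
        grid=GridSpec(0.0, 15.0, 46.0, 58.0, 30, 24),   # 0.5 deg cells
        n_stations=30,
        clustering=0.0,
        station_layout="stratified",
        noise=NoiseConfig(lognormal_sigma=noise_sigma, missing_prob=0.05),
        years=tuple(years),
        xi_smooth_cells=12.0,                           # ~600 km at 0.5 deg
        seed=seed,
    )
    num = den = 0.0
    xi_all, truth_all = [], []
    per_year = []
    for year in cfg.years:
        scen = build_year_scenario(cfg, year)
        fg = run_first_guess(scen)
        da = run_da(scen, fg, cfg)
        d = da.result.diagnostics
        er = d.eval_rmse
        n_bins = max(len(da.eval_ids), 1)
        num += er[d.stop_index] ** 2 * n_bins
        den += er[0] ** 2 * n_bins
        mask = footprint_union(scen, da.assim_ids)
        xi_all.append(da.result.xi[mask])
        truth_all.append(scen.xi_true[mask])
        per_year.append(
            {"year": year, "stop": int(d.stop_index),
             "eval_ratio": float(er[d.stop_index] / er[0]),
             "assim_ratio": float(da.result.rmse_ratio_assim),
             "xi_corr": float(np.corrcoef(da.result.xi[mask], scen.xi_true[mask])[0, 1])}
        )
    xi_all = np.concatenate(xi_all)
    truth_all = np.concatenate(truth_all)
    return {
        "eval_rmse_ratio": float(np.sqrt(num / den)),
        "xi_truth_correlation": float(np.corrcoef(xi_all, truth_all)[0, 1]),
        "n_cells": int(xi_all.size),
        "per_year": per_year,
    }


def recovery_summary(seed: int = 0, n_replicates: int = 3) -> dict:
    """Median year-level outcome of the recovery experiment over
    ``n_replicates`` independent replicates (3 assimilation years each):
    the statistic the package's checks assert on."""
    replicates = []
    entries = []
    for k in range(n_replicates):
        r = recovery_experiment(subseed(seed, 101, k))
        replicates.append(r)
        entries.extend(r["per_year"])
    return {
        "median_eval_ratio": float(np.median([e["eval_ratio"] for e in entries])),
        "median_xi_corr": float(np.median([e["xi_corr"] for e in entries])),
        "n_year_draws": len(entries),
        "replicates": replicates,
    }


def overfit_experiment(seed: int = 0, noise_sigma: float = 0.5) -> dict:
    """Truncation as over-fitting protection on a sparse noisy network.

    Six stations assimilate a noisy season; six independent held-out
    stations evaluate.  Returns the evaluation RMSE at the L-curve stop
    index and at full convergence: the watchdog exists to make the
    former no worse than the latter.
    """
    cfg = RunConfig(
        grid=GridSpec(0.0, 12.0, 47.0, 57.0, 12, 10),
        n_stations=12,
        clustering=0.0,
        station_layout="stratified",
        noise=NoiseConfig(lognormal_sigma=noise_sigma, missing_prob=0.1),
        stop=StopConfig(max_iterations=60),
        seed=seed,
    )
    scen = build_year_scenario(cfg, 2000)
    fg = run_first_guess(scen)
    series = {
        row.station_id: StationSeries(
            row.station_id, row.lon, row.lat,
            scen.obs[row.station_id]["value"], scen.obs[row.station_id]["valid"],
        )
        for _, row in scen.stations.table.iterrows()
    }
    ids = sorted(series)
    rng = np.random.default_rng(subseed(seed, 21))
    order = rng.permutation(len(ids))
    assim = [ids[k] for k in order[:6]]
    evl = [ids[k] for k in order[6:]]
    op = ObsOperator(scen.transport, fg.emission.rate, [series[s] for s in assim], scen.window)
    eval_op = ObsOperator(scen.transport, fg.emission.rate, [series[s] for s in evl], scen.window)
    res = minimize_truncated(op, cfg.cov, cfg.stop, eval_op=eval_op)
    er = res.diagnostics.eval_rmse
    return {
        "eval_rmse_stop": float(er[res.diagnostics.stop_index]),
        "eval_rmse_full": float(er[-1]),
        "eval_rmse_background": float(er[0]),
        "stop_index": int(res.diagnostics.stop_index),
        "n_iterations": int(len(er) - 1),
    }


def bias_law_experiment(seed: int = 0, n_draws: int = 200, n_steps: int = 60) -> dict:
    """Monte-Carlo verification of the analytic single-station optimum.

    For each draw, correlated normalized anomalies (mu, nu) with random
    correlation and variance build a model series z and an observation
    series y; the scalar log-transformed assimilation with a weak
    background must land on the closed-form optimum
    (y_bar/z_bar)(1 + cov)/(1 + var).  The perfect-correlation and
    zero-correlation limits are returned separately.
    """
    rng = np.random.default_rng(subseed(seed, 31))
    errs = []
    for _ in range(n_draws):
        z_bar = rng.uniform(5.0, 50.0)
        y_bar = rng.uniform(5.0, 50.0)
        s_mu = rng.uniform(0.2, 1.0)
        s_nu = rng.uniform(0.2, 1.0)
        r = rng.uniform(-0.5, 1.0)
        cov = np.array([[s_mu**2, r * s_mu * s_nu], [r * s_mu * s_nu, s_nu**2]])
        mu, nu = rng.multivariate_normal([0, 0], cov, size=n_steps).T
        mu -= mu.mean()
        nu -= nu.mean()
        z = z_bar * (1.0 + mu)
        y = y_bar * (1.0 + nu)
        xi_hat = scalar_station_assimilate(y, z)
        xi_ref = xi_opt_closed_form(
            y_bar, z_bar, float(np.mean(mu * nu)), float(np.mean(mu * mu))
        )
        errs.append(abs(xi_hat - xi_ref) / xi_ref)
    # limits: perfectly correlated anomalies; uncorrelated at unit variance
    t = np.linspace(0, 2 * np.pi, n_steps, endpoint=False)
    mu = np.sqrt(2.0) * np.sin(t)                      # unit variance, zero mean
    nu_perp = np.sqrt(2.0) * np.cos(t)                 # orthogonal to mu
    xi_perfect = scalar_station_assimilate(10.0 * (1 + mu), 5.0 * (1 + mu))
    xi_zero = scalar_station_assimilate(10.0 * (1 + nu_perp), 10.0 * (1 + mu))
    return {
        "mean_abs_rel_err": float(np.mean(errs)),
        "xi_perfect_correlation": float(xi_perfect),   # exact: 10/5 = 2
        "xi_zero_correlation": float(xi_zero),         # exact: 1/(1+1) = 0.5
    }


def _direct_gls_solve(a: np.ndarray, y: np.ndarray, obs_var: float,
                      b_inv: np.ndarray) -> np.ndarray:
    """Generalized-least-squares optimum of the linearized problem in
    xi-space: min ||A xi - y||^2/Phi + (xi-1)^T B^-1 (xi-1)."""
    h = a.T @ a / obs_var + b_inv
    rhs = a.T @ (y - a @ np.ones(a.shape[1])) / obs_var
    return 1.0 + np.linalg.solve(h, rhs)


def linear_oracle_experiment(seed: int = 0) -> dict:
    """Full-convergence 4D-VAR against the explicit source-receptor GLS
    solve, on a 10x10 grid with 20 stations and a 120-day window.

    With noise-free observations the two routes minimize the same data
    misfit; the relative RMSE between them over cells where the direct
    solution is positive measures the equivalence.
    """
    from scipy.linalg import cho_solve

    cfg = RunConfig(
        grid=GridSpec(0.0, 10.0, 47.0, 57.0, 10, 10),
        n_stations=20,
        clustering=0.0,
        station_layout="stratified",
        noise=NoiseConfig(lognormal_sigma=0.0, missing_prob=0.0),
        stop=StopConfig(max_iterations=8000, gtol=0.0),
        seed=seed,
    )
    taxon_year = 2000
    scen = build_year_scenario(cfg, taxon_year)
    # trim the window to exactly 120 days
    window = (scen.window[0], scen.window[0] + pd.Timedelta(days=119))
    scen.window = window
    fg = run_first_guess(scen)
    series = [
        StationSeries(
            row.station_id, row.lon, row.lat,
            scen.obs[row.station_id]["value"], scen.obs[row.station_id]["valid"],
        )
        for _, row in scen.stations.table.iterrows()
    ]
    op = ObsOperator(scen.transport, fg.emission.rate, series, window)

    from scipy.optimize import minimize

    from .assimilation import background_cholesky

    L = background_cholesky(cfg.grid, cfg.cov)
    sb = np.sqrt(cfg.cov.background_scale)

    def fun(w):
        zeta = sb * (L @ w)
        xi = np.exp(zeta)
        resid = op.y - op.apply(xi.reshape(cfg.grid.shape))
        grad_zeta = -op.adjoint(resid / cfg.cov.obs_variance).ravel() * xi
        j = 0.5 * float(resid @ resid) / cfg.cov.obs_variance + 0.5 * float(w @ w)
        return j, sb * (L.T @ grad_zeta) + w

    sol = minimize(
        fun, np.zeros(cfg.grid.n_cells), jac=True, method="L-BFGS-B",
        options={"maxiter": cfg.stop.max_iterations, "gtol": 0.0, "ftol": 1e-16},
    )
    xi_var = np.exp(sb * (L @ sol.x))
    b_inv = cho_solve((L, True), np.eye(cfg.grid.n_cells)) / cfg.cov.background_scale
    a = op.matrix()
    xi_gls = _direct_gls_solve(a, op.y, cfg.cov.obs_variance, b_inv)
    pos = xi_gls > 0
    diff = xi_var[pos] - xi_gls[pos]
    rel_rmse = float(np.sqrt(np.mean(diff**2)) / np.sqrt(np.mean(xi_gls[pos] ** 2)))
    return {
        "rel_rmse": rel_rmse,
        "n_positive": int(pos.sum()),
        "n_cells": int(xi_gls.size),
        "truth_rmse_var": float(np.sqrt(np.mean((xi_var - scen.xi_true.ravel()) ** 2))),
    }


def budget_linearity_experiment(seed: int = 0) -> dict:
    """Seasonal emission budget and xi-linearity under non-limiting
    weather: per-cell released total vs S*phi*xi*N_tot, and the maximum
    relative deviation of forward concentrations from exact doubling
    when xi doubles."""
    from .synthetic import gen_landscape, gen_truth_xi
    from .taxa import load_taxon

    grid = GridSpec(0.0, 10.0, 46.0, 54.0, 10, 8)
    taxon = load_taxon("birch")
    meteo = gen_meteo(grid, 120, subseed(seed, 41), params=_mild_weather(),
                      start="2000-03-01")
    landscape = gen_landscape(grid, taxon, subseed(seed, 42))
    xi = gen_truth_xi(grid, subseed(seed, 43), 0.5, 2.0)
    em1 = simulate_emission(meteo, landscape, taxon, xi)
    expected = landscape.cell_area_m2 * landscape.phi * xi * taxon.n_total
    prod = landscape.phi > 0.01
    budget_err = float(
        np.max(np.abs(em1.seasonal_budget[prod] / expected[prod] - 1.0))
    )
    em2 = simulate_emission(meteo, landscape, taxon, 2.0 * xi)
    tr = LinearTransport.from_meteo(meteo, taxon)
    c1 = tr.forward(em1.rate)
    c2 = tr.forward(em2.rate)
    nz = c1 > 1e-12 * c1.max()
    linearity_err = float(np.max(np.abs(c2[nz] / c1[nz] - 2.0)))
    return {"budget_max_rel_err": budget_err, "linearity_max_rel_err": linearity_err}


def calibration_experiment(seed: int = 0) -> dict:
    """Closed-loop bias calibration: the model runs uniformly 2x high
    (true correction 0.5 everywhere, first guess 1), observations are
    noise-free.  After SPIn-ratio calibration the final run must be
    unbiased: median station ratio r_st near 1 and decile-wise quantile
    agreement between observed and final concentrations.
    """
    from .calibration import validate_ratio_rst

    cfg = RunConfig(
        grid=GridSpec(0.0, 10.0, 47.0, 55.0, 10, 8),
        n_stations=12,
        clustering=0.0,
        station_layout="stratified",
        noise=NoiseConfig(lognormal_sigma=0.0, missing_prob=0.0),
        xi_range=(0.5, 0.5),
        seed=seed,
    )
    scen = build_year_scenario(cfg, 2000)
    fg = run_first_guess(scen)

    class _FgAsDa:
        series = fg.series

    cal_map, points = build_calibration({2000: scen}, {2000: _FgAsDa()}, cfg.grid)
    final = run_final(scen, np.ones(cfg.grid.shape), cal_map)
    rst = validate_ratio_rst(scen.obs, final.series)
    obs_all, mdl_all = [], []
    for sid, frame in scen.obs.items():
        m = final.series[sid].reindex(frame.index)
        ok = frame["valid"].to_numpy().astype(bool) & m.notna().to_numpy()
        obs_all.append(frame["value"].to_numpy()[ok])
        mdl_all.append(m.to_numpy()[ok])
    o = np.concatenate(obs_all)
    m = np.concatenate(mdl_all)
    deciles = np.arange(0.1, 1.0, 0.1)
    qo = np.quantile(o, deciles)
    qm = np.quantile(m, deciles)
    keep = qo > 0
    return {
        "median_rst": float(rst.r_st.median()),
        "quantile_max_rel_dev": float(np.max(np.abs(qm[keep] / qo[keep] - 1.0))),
        "mean_rs": float(points.r_s.mean()),
    }


def twoday_averaging_experiment(
    seed: int = 0, n_rep: int = 500, n_days: int = 90, noise_sd: float = 1.0
) -> dict:
    """Monte-Carlo check that 2-day averaging raises the model-observation
    Pearson correlation for series = shared seasonal signal + independent
    daily noise."""
    rng = np.random.default_rng(subseed(seed, 51))
    t = np.arange(n_days)
    signal = np.exp(-0.5 * ((t - n_days / 2) / (n_days / 8)) ** 2)  # season bump
    dates = pd.date_range("2000-04-01", periods=n_days)
    valid = pd.Series(True, index=dates)
    r_daily, r_2day = [], []
    for _ in range(n_rep):
        y = signal + noise_sd * rng.standard_normal(n_days)
        x = signal + noise_sd * rng.standard_normal(n_days)
        r_daily.append(np.corrcoef(x, y)[0, 1])
        xb, xv = average_2day(pd.Series(x, index=dates), valid, dates[0])
        yb, yv = average_2day(pd.Series(y, index=dates), valid, dates[0])
        r_2day.append(np.corrcoef(xb[xv & yv], yb[xv & yv])[0, 1])
    return {
        "mean_corr_daily": float(np.mean(r_daily)),
        "mean_corr_2day": float(np.mean(r_2day)),
        "gain": float(np.mean(r_2day) - np.mean(r_daily)),
    }
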