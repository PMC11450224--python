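"""Three-run reanalysis protocol on synthetic scenarios.

For each year and taxon: (1) a *first-guess* run with the unconstrained
source (xi = 1) provides the reference skill and the unit-correction
emission the inversion needs; (2) the *assimilation* run screens and
splits the station data, minimizes the season cost function, and yields
the annual correction map xi with its L-curve diagnostics; (3) after a
climatological bias calibration against the whole-period SPIn, the
*final* run applies both corrections with an otherwise identical setup,
so first-guess and final fields are directly comparable.  One year is
one independent assimilation problem; only the landscape and the
calibration map are shared across years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assimilation import (
    AssimilationResult,
    CovarianceConfig,
    ObsOperator,
    StopConfig,
    background_cholesky,
    minimize_truncated,
)
from .calibration import compute_ratio_rs, interpolate_rbf, validate_ratio_rst
from .grid import GridSpec
from .observations import (
    SpinValue,
    StationSeries,
    average_2day,
    compute_spin,
    sample_model,
    split_assim_eval,
    station_year_passes,
)
from .phenology import EmissionField, simulate_emission
from .synthetic import (
    LandscapeConfig,
    MeteoConfig,
    NoiseConfig,
    gen_landscape,
    gen_meteo,
    gen_observations,
    gen_station_network,
    gen_truth_xi,
)
from .taxa import TaxonParams, load_taxon
from .transport import ConcentrationField, LinearTransport

log = logging.getLogger(__name__)


def subseed(master: int, *tags: int) -> int:
    """Deterministic sub-seed below 2^31 derived from a master seed."""
    s = int(master) % (2**31)
    for t in tags:
        s = (s * 1_000_003 + int(t) + 12345) % (2**31)
    return s


@dataclass
class RunConfig:
    """Everything one reanalysis experiment needs, seeds included."""

    taxon: str = "birch"
    years: tuple[int, ...] = (2000,)
    grid: GridSpec = field(default_factory=lambda: GridSpec(-10.0, 30.0, 35.0, 65.0, 40, 30))
    n_stations: int = 30
    clustering: float = 0.3
    isolation_km: float = 300.0
    station_layout: str = "uniform"
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    meteo: MeteoConfig = field(default_factory=MeteoConfig)
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    cov: CovarianceConfig = field(default_factory=CovarianceConfig)
    stop: StopConfig = field(default_factory=StopConfig)
    xi_range: tuple[float, float] = (0.5, 2.0)
    xi_smooth_cells: float = 6.0       # truth-field scale: ~600 km at 1 deg (synoptic)
    rbf_smoothing: float = 10.0
    diffusion_m2_s: float = 5000.0
    mixing_height_m: float = 1000.0
    seed: int = 0


@dataclass
class YearScenario:
    """All synthetic inputs for one year, plus the assembled transport."""

    year: int
    taxon: TaxonParams
    meteo: "object"
    landscape: "object"
    stations: "object"
    xi_true: np.ndarray
    transport: LinearTransport
    truth_conc: ConcentrationField            # daily means
    obs: dict[str, pd.DataFrame]
    window: tuple[pd.Timestamp, pd.Timestamp]


@dataclass
class FirstGuess:
    emission: EmissionField                   # unit-correction (xi = 1)
    conc: ConcentrationField                  # daily means
    series: dict[str, pd.Series]


@dataclass
class DAOutput:
    result: AssimilationResult
    audit: pd.DataFrame                       # per-station accept/reject with reason
    assim_ids: list[str]
    eval_ids: list[str]
    conc: ConcentrationField                  # DA-run daily concentrations
    series: dict[str, pd.Series]


@dataclass
class DiagnosticsBundle:
    spin_correlation: pd.DataFrame            # station_id x run -> inter-annual SPIn corr
    quantiles: pd.DataFrame                   # decile table obs vs runs
    rst: pd.DataFrame                         # per-station obs/model ratio (final run)
    twoday_correlation: pd.DataFrame          # per station-year-run 2-day corr
    footprint_union: dict[int, np.ndarray] | None = None


def build_year_scenario(config: RunConfig, year: int) -> YearScenario:
    taxon = load_taxon(config.taxon)
    start = taxon.start_date(year)
    window = taxon.window(year)
    n_days = (window[1] - start).days + 1
    freq = "h" if taxon.hourly else "D"
    meteo = gen_meteo(
        config.grid, n_days, subseed(config.seed, year, 1), params=config.meteo,
        start=str(start.date()), freq=freq,
    )
    landscape = gen_landscape(
        config.grid, taxon, subseed(config.seed, 2), params=config.landscape
    )
    stations = gen_station_network(
        config.grid, config.n_stations, subseed(config.seed, 3),
        clustering=config.clustering, isolation_km=config.isolation_km,
        layout=config.station_layout,
    )
    xi_true = gen_truth_xi(
        config.grid, subseed(config.seed, year, 4),
        lo=config.xi_range[0], hi=config.xi_range[1],
        smooth_cells=config.xi_smooth_cells,
    )
    transport = LinearTransport.from_meteo(
        meteo, taxon,
        diffusion_m2_s=config.diffusion_m2_s, mixing_height_m=config.mixing_height_m,
    )
    emission_true = simulate_emission(meteo, landscape, taxon, xi_true)
    conc_true = ConcentrationField(
        grid=config.grid, times=meteo.times, values=transport.forward(emission_true.rate)
    ).daily_mean()
    obs = gen_observations(
        conc_true.values, conc_true.times, config.grid, stations,
        config.noise, subseed(config.seed, year, 5),
    )
    return YearScenario(
        year=year, taxon=taxon, meteo=meteo, landscape=landscape, stations=stations,
        xi_true=xi_true, transport=transport, truth_conc=conc_true, obs=obs, window=window,
    )


def _station_series(scen: YearScenario) -> list[StationSeries]:
    out = []
    for _, row in scen.stations.table.iterrows():
        frame = scen.obs[row.station_id]
        out.append(
            StationSeries(
                station_id=row.station_id, lon=row.lon, lat=row.lat,
                values=frame["value"], valid=frame["valid"], isolated=bool(row.isolated),
            )
        )
    return out


def _sample_all(scen: YearScenario, conc: ConcentrationField) -> dict[str, pd.Series]:
    return {
        row.station_id: sample_model(conc, row.lon, row.lat)
        for _, row in scen.stations.table.iterrows()
    }


def run_first_guess(scen: YearScenario) -> FirstGuess:
    """Unconstrained reference run with xi identically 1."""
    emission = simulate_emission(scen.meteo, scen.landscape, scen.taxon, 1.0)
    conc = ConcentrationField(
        grid=scen.transport.grid, times=scen.meteo.times,
        values=scen.transport.forward(emission.rate),
    ).daily_mean()
    return FirstGuess(emission=emission, conc=conc, series=_sample_all(scen, conc))


def run_da(scen: YearScenario, fg: FirstGuess, config: RunConfig, chol_L=None) -> DAOutput:
    """Screen, split, and assimilate one year's observations."""
    all_series = _station_series(scen)
    audit_rows = []
    accepted: list[StationSeries] = []
    for ss in all_series:
        ok, reason = station_year_passes(ss, fg.series[ss.station_id], scen.window)
        audit_rows.append(
            {"station_id": ss.station_id, "year": scen.year, "accepted": ok, "reason": reason}
        )
        if ok:
            accepted.append(ss)
    audit = pd.DataFrame(audit_rows)

    if not accepted:
        log.warning("year %d: no stations accepted; correction left at background", scen.year)
        empty_op = ObsOperator(scen.transport, fg.emission.rate, [], scen.window)
        result = minimize_truncated(empty_op, config.cov, config.stop, chol_L=chol_L)
        return DAOutput(result, audit, [], [], fg.conc, dict(fg.series))

    mandatory = [s.station_id for s in accepted if s.isolated]
    assim_ids, eval_ids = split_assim_eval(
        [s.station_id for s in accepted], mandatory, subseed(config.seed, scen.year, 6)
    )
    by_id = {s.station_id: s for s in accepted}
    op = ObsOperator(
        scen.transport, fg.emission.rate, [by_id[s] for s in assim_ids], scen.window
    )
    eval_op = (
        ObsOperator(scen.transport, fg.emission.rate, [by_id[s] for s in eval_ids], scen.window)
        if eval_ids
        else None
    )
    result = minimize_truncated(op, config.cov, config.stop, eval_op=eval_op, chol_L=chol_L)
    conc = ConcentrationField(
        grid=scen.transport.grid, times=scen.meteo.times,
        values=scen.transport.forward(fg.emission.rate * result.xi[None]),
    ).daily_mean()
    return DAOutput(result, audit, assim_ids, eval_ids, conc, _sample_all(scen, conc))


def build_calibration(
    scenarios: dict[int, YearScenario],
    da_outputs: dict[int, DAOutput],
    grid: GridSpec,
    smoothing: float = 10.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Whole-period SPIn ratio per station and its RBF map."""
    spin_obs: list[SpinValue] = []
    spin_mdl: list[SpinValue] = []
    any_scen = next(iter(scenarios.values()))
    for year, scen in scenarios.items():
        da = da_outputs[year]
        for _, row in scen.stations.table.iterrows():
            frame = scen.obs[row.station_id]
            spin_obs.append(
                compute_spin(frame["value"], frame["valid"], scen.window,
                             station_id=row.station_id)
            )
            m = da.series[row.station_id]
            spin_mdl.append(
                compute_spin(m, frame["valid"].reindex(m.index, fill_value=False),
                             scen.window, min_days=0, station_id=row.station_id)
            )
    points = compute_ratio_rs(spin_mdl, spin_obs, any_scen.stations.table)
    return interpolate_rbf(points, grid, smoothing), points


def run_final(
    scen: YearScenario, xi: np.ndarray, calibration_map: np.ndarray | None = None
) -> FirstGuess:
    """Final run: emission scaled by the annual correction and divided by
    the climatological bias map; otherwise identical to the first guess."""
    emission = simulate_emission(scen.meteo, scen.landscape, scen.taxon, xi)
    if calibration_map is not None:
        corr = np.maximum(calibration_map, 1e-3)
        emission = EmissionField(
            grid=emission.grid, times=emission.times,
            rate=emission.rate / corr[None],
            seasonal_budget=emission.seasonal_budget / corr,
            step_seconds=emission.step_seconds,
        )
    conc = ConcentrationField(
        grid=scen.transport.grid, times=scen.meteo.times,
        values=scen.transport.forward(emission.rate),
    ).daily_mean()
    return FirstGuess(emission=emission, conc=conc, series=_sample_all(scen, conc))


def downscale_xi(xi_coarse: np.ndarray, coarse: GridSpec, fine: GridSpec) -> np.ndarray:
    """Bilinear down-scaling of a correction map from a coarser DA grid to
    the source grid (nearest-neighbour at the margins); value-preserving
    for a constant map."""
    from scipy.interpolate import RegularGridInterpolator

    f = RegularGridInterpolator(
        (coarse.lat_centers, coarse.lon_centers), xi_coarse,
        method="linear", bounds_error=False, fill_value=None,
    )
    lon2d, lat2d = fine.mesh()
    return f(np.stack([lat2d.ravel(), lon2d.ravel()], axis=1)).reshape(fine.shape)


def compute_diagnostics(
    scenarios: dict[int, YearScenario],
    runs: dict[str, dict[int, dict[str, pd.Series]]],
    min_years_for_spin: int = 4,
    footprints: bool = False,
) -> DiagnosticsBundle:
    """Validation diagnostics across years for named runs (typically
    'first_guess', 'da', 'final').

    Inter-annual SPIn correlations include only stations with more than
    3 years of valid observations; quantile tables sort observations and
    predictions independently.
    """
    run_names = list(runs)
    years = sorted(scenarios)
    any_scen = scenarios[years[0]]
    station_ids = list(any_scen.stations.table.station_id)

    spin_obs: dict[str, dict[int, SpinValue]] = {s: {} for s in station_ids}
    spin_run: dict[str, dict[str, dict[int, float]]] = {
        r: {s: {} for s in station_ids} for r in run_names
    }
    twoday_rows = []
    for year in years:
        scen = scenarios[year]
        for sid in station_ids:
            frame = scen.obs[sid]
            sv = compute_spin(frame["value"], frame["valid"], scen.window, station_id=sid)
            spin_obs[sid][year] = sv
            for r in run_names:
                m = runs[r][year][sid]
                mv = compute_spin(
                    m, frame["valid"].reindex(m.index, fill_value=False),
                    scen.window, min_days=0, station_id=sid,
                )
                spin_run[r][sid][year] = mv.value
                ob, ov = average_2day(frame["value"], frame["valid"], scen.window[0])
                mb, mvv = average_2day(m, frame["valid"].reindex(m.index, fill_value=False),
                                       scen.window[0])
                k = min(len(ob), len(mb))
                co = ov[:k] & mvv[:k]
                if co.sum() >= 3 and np.std(ob[:k][co]) > 0 and np.std(mb[:k][co]) > 0:
                    rr = float(np.corrcoef(ob[:k][co], mb[:k][co])[0, 1])
                    twoday_rows.append(
                        {"station_id": sid, "year": year, "run": r, "corr": rr}
                    )

    spin_rows = []
    for sid in station_ids:
        valid_years = [y for y in years if spin_obs[sid][y].usable]
        if len(valid_years) < min_years_for_spin:
            continue
        o = np.array([spin_obs[sid][y].value for y in valid_years])
        row = {"station_id": sid, "n_years": len(valid_years)}
        for r in run_names:
            m = np.array([spin_run[r][sid][y] for y in valid_years])
            row[r] = (
                float(np.corrcoef(o, m)[0, 1]) if np.std(o) > 0 and np.std(m) > 0 else np.nan
            )
        spin_rows.append(row)

    # decile table from independently sorted co-valid daily values
    deciles = np.arange(0.1, 1.0, 0.1)
    qrows = []
    for r in run_names:
        obs_all, mdl_all = [], []
        for year in years:
            scen = scenarios[year]
            for sid in station_ids:
                frame = scen.obs[sid]
                m = runs[r][year][sid].reindex(frame.index)
                ok = frame["valid"].to_numpy().astype(bool) & m.notna().to_numpy()
                obs_all.append(frame["value"].to_numpy()[ok])
                mdl_all.append(m.to_numpy()[ok])
        o = np.concatenate(obs_all)
        m = np.concatenate(mdl_all)
        for q in deciles:
            qrows.append(
                {"run": r, "quantile": round(float(q), 1),
                 "obs": float(np.quantile(o, q)), "model": float(np.quantile(m, q))}
            )

    final_run = run_names[-1]
    rst_frames = []
    for year in years:
        scen = scenarios[year]
        rst_frames.append(validate_ratio_rst(scen.obs, runs[final_run][year]))
    rst_all = pd.concat(rst_frames).groupby("station_id", as_index=False).mean()

    fp = None
    if footprints:
        fp = {}
        for year in years:
            scen = scenarios[year]
            total = np.zeros(scen.transport.grid.shape)
            for _, row in scen.stations.table.iterrows():
                total += scen.transport.station_footprint(row.lon, row.lat, scen.window)
            fp[year] = total

    return DiagnosticsBundle(
        spin_correlation=pd.DataFrame(spin_rows),
        quantiles=pd.DataFrame(qrows),
        rst=rst_all,
        twoday_correlation=pd.DataFrame(twoday_rows),
        footprint_union=fp,
    )


@dataclass
class ReanalysisOutput:
    scenarios: dict[int, YearScenario]
    first_guess: dict[int, FirstGuess]
    da: dict[int, DAOutput]
    calibration_map: np.ndarray
    calibration_points: pd.DataFrame
    final: dict[int, FirstGuess]
    diagnostics: DiagnosticsBundle


def run_reanalysis(config: RunConfig, footprints: bool = False) -> ReanalysisOutput:
    """The full three-run protocol over all configured years."""
    scenarios: dict[int, YearScenario] = {}
    fgs: dict[int, FirstGuess] = {}
    das: dict[int, DAOutput] = {}
    chol_L = background_cholesky(config.grid, config.cov)
    for year in config.years:
        log.info("year %d: building scenario", year)
        scen = build_year_scenario(config, year)
        scenarios[year] = scen
        fgs[year] = run_first_guess(scen)
        log.info("year %d: assimilating", year)
        das[year] = run_da(scen, fgs[year], config, chol_L=chol_L)

    cal_map, cal_points = build_calibration(scenarios, das, config.grid, config.rbf_smoothing)
    finals = {
        year: run_final(scenarios[year], das[year].result.xi, cal_map)
        for year in config.years
    }
    diags = compute_diagnostics(
        scenarios,
        {
            "first_guess": {y: fgs[y].series for y in config.years},
            "da": {y: das[y].series for y in config.years},
            "final": {y: finals[y].series for y in config.years},
        },
        footprints=footprints,
    )
    return ReanalysisOutput(
        scenarios=scenarios, first_guess=fgs, da=das,
        calibration_map=cal_map, calibration_points=cal_points,
        final=finals, diagnostics=diags,
    )
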