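"""Synthetic study inputs.

Generates everything the real reanalysis would take from a meteorological
reanalysis, land-cover inventories, and an aerobiological station
network, with the statistical structure the method relies on:

* gridded meteorology with a southward-warm latitudinal gradient, a
  seasonal warming trend, autocorrelated weather noise, divergence-free
  winds from a random streamfunction, and event-like precipitation;
* tree-cover fraction maps and heat-sum threshold maps consistent with
  the taxon's heat-sum unit (K day or K hour);
* a smooth "true" per-cell seasonal release correction field xi;
* Hirst-style daily station count series with multiplicative lognormal
  noise and missing days.

Every generator is a pure function of (config, seed): the same seed
yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grid import GridSpec, haversine_km, pairwise_distance_km
from .taxa import TaxonParams


# ---------------------------------------------------------------------------
# containers

@dataclass
class MeteoFields:
    """Gridded meteorology time series, shape (nt, ny, nx) per variable.

    T in K, wind components u/v and speed U in m/s, convective velocity
    scale wstar in m/s, relative humidity q in %, precipitation rate P in
    mm/hour.  ``freq`` is "D" (daily) or "h" (hourly).
    """

    grid: GridSpec
    times: pd.DatetimeIndex
    T: np.ndarray
    u: np.ndarray
    v: np.ndarray
    wstar: np.ndarray
    q: np.ndarray
    P: np.ndarray
    freq: str = "D"

    @property
    def U(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    @property
    def step_seconds(self) -> float:
        return 86400.0 if self.freq == "D" else 3600.0

    def daily_times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(np.unique(self.times.normalize()))


@dataclass
class Landscape:
    """Static per-cell landscape for one taxon: tree-cover fraction phi,
    flowering start/end heat-sum thresholds, and cell area."""

    grid: GridSpec
    phi: np.ndarray            # (ny, nx), 0..1
    H_fs: np.ndarray           # (ny, nx), K day or K hour
    H_fe: np.ndarray           # (ny, nx), same unit
    cell_area_m2: np.ndarray   # (ny, nx)


@dataclass
class StationNetwork:
    """Point observation sites inside the grid-center hull."""

    table: pd.DataFrame        # columns: station_id, lon, lat, isolated

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class MeteoConfig:
    """Climate of the synthetic domain (northern-hemisphere configuration)."""

    t_base_K: float = 283.0            # daily-mean T at the southern edge, start of record
    lat_gradient_K_per_deg: float = 0.7
    seasonal_trend_K_per_day: float = 0.08
    noise_sigma_K: float = 2.0
    noise_ar1: float = 0.8
    noise_smooth_cells: float = 2.0
    diurnal_amplitude_K: float = 4.0   # hourly mode only
    wind_speed_scale_m_s: float = 4.0
    wind_ar1: float = 0.7
    wstar_max_m_s: float = 1.5
    q_base_pct: float = 60.0
    q_sigma_pct: float = 15.0
    wet_day_prob: float = 0.15
    wet_rate_mean_mm_h: float = 1.0


@dataclass
class NoiseConfig:
    """Observation-error model for the synthetic Hirst-style counts."""

    lognormal_sigma: float = 0.3
    missing_prob: float = 0.05


@dataclass
class TruthScenario:
    """The synthetic analogue of the unknown real correction field."""

    xi_true: np.ndarray                # (ny, nx), > 0
    stations: StationNetwork
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0


# ---------------------------------------------------------------------------
# helpers

def _smooth_field(rng: np.random.Generator, shape, smooth_cells: float) -> np.ndarray:
    """Zero-mean unit-variance smooth Gaussian random field."""
    f = gaussian_filter(rng.standard_normal(shape), smooth_cells, mode="reflect")
    f -= f.mean()
    s = f.std()
    return f / s if s > 0 else f


# ---------------------------------------------------------------------------
# generators

def gen_meteo(
    grid: GridSpec,
    n_days: int,
    seed: int,
    params: MeteoConfig | None = None,
    start: str = "2000-01-01",
    freq: str = "D",
) -> MeteoFields:
    """Generate gridded synthetic meteorology.

    Daily resolution by default; ``freq="h"`` produces hourly fields with
    a sinusoidal diurnal temperature cycle superimposed, for taxa whose
    heat sum accumulates on hourly mean temperature.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if freq not in ("D", "h"):
        raise ValueError("freq must be 'D' or 'h'")
    p = params or MeteoConfig()
    rng = np.random.default_rng(seed)
    ny, nx = grid.shape
    nt = n_days if freq == "D" else n_days * 24
    times = pd.date_range(start, periods=nt, freq=freq)
    day_frac = np.arange(nt) / (1.0 if freq == "D" else 24.0)

    _, lat2d = grid.mesh()
    t_lat = p.t_base_K - p.lat_gradient_K_per_deg * (lat2d - grid.lat_min)

    # AR(1)-in-time, spatially smooth temperature noise (daily innovation scale)
    ar = p.noise_ar1 if freq == "D" else p.noise_ar1 ** (1 / 24)
    innov = p.noise_sigma_K * np.sqrt(1 - ar**2)
    T = np.empty((nt, ny, nx))
    noise = p.noise_sigma_K * _smooth_field(rng, (ny, nx), p.noise_smooth_cells)
    for t in range(nt):
        if t > 0:
            noise = ar * noise + innov * _smooth_field(rng, (ny, nx), p.noise_smooth_cells)
        T[t] = t_lat + p.seasonal_trend_K_per_day * day_frac[t] + noise
    if freq == "h":
        hour = times.hour.to_numpy()
        T += (p.diurnal_amplitude_K / 2 * np.sin(2 * np.pi * (hour - 9) / 24.0))[:, None, None]

    # winds from an AR(1) random streamfunction -> divergence-free flow
    u = np.empty((nt, ny, nx))
    v = np.empty((nt, ny, nx))
    psi = _smooth_field(rng, (ny, nx), 3.0)
    war = p.wind_ar1 if freq == "D" else p.wind_ar1 ** (1 / 24)
    for t in range(nt):
        if t > 0:
            psi = war * psi + np.sqrt(1 - war**2) * _smooth_field(rng, (ny, nx), 3.0)
        gy, gx = np.gradient(psi)
        scale = p.wind_speed_scale_m_s / max(np.hypot(gx, gy).mean(), 1e-12)
        u[t] = -gy * scale
        v[t] = gx * scale

    wstar = p.wstar_max_m_s * rng.random((nt, ny, nx))
    q = np.clip(
        p.q_base_pct
        + p.q_sigma_pct * np.stack([_smooth_field(rng, (ny, nx), 2.0) for _ in range(nt)]),
        0.0,
        100.0,
    )
    wet = rng.random((nt, ny, nx)) < (
        p.wet_day_prob if freq == "D" else p.wet_day_prob / 4
    )
    P = np.where(wet, rng.exponential(p.wet_rate_mean_mm_h, (nt, ny, nx)), 0.0)

    return MeteoFields(grid=grid, times=times, T=T, u=u, v=v, wstar=wstar, q=q, P=P, freq=freq)


@dataclass
class LandscapeConfig:
    """Shape of the synthetic landscape maps."""

    phi_mean: float = 0.15            # mean tree-cover fraction where present
    phi_smooth_cells: float = 3.0
    h_fs_base_K_day: float = 120.0    # flowering-start threshold at the southern edge
    h_fs_lat_slope_K_day_per_deg: float = 4.0
    delta_h_K_day: float = 60.0       # H_fe - H_fs, constant
    h_noise_K_day: float = 5.0


def gen_landscape(
    grid: GridSpec,
    taxon: TaxonParams,
    seed: int,
    params: LandscapeConfig | None = None,
) -> Landscape:
    """Generate tree cover and heat-sum threshold maps for one taxon.

    The flowering-start threshold increases with latitude; thresholds are
    expressed in the taxon's own heat-sum unit (K day for daily
    accumulation, K hour for hourly — conversion factor 24).  Where the
    taxon has a southern exclusion latitude (birch), phi is zeroed south
    of it.
    """
    p = params or LandscapeConfig()
    rng = np.random.default_rng(seed)
    ny, nx = grid.shape
    _, lat2d = grid.mesh()

    raw = _smooth_field(rng, (ny, nx), p.phi_smooth_cells)
    phi = np.clip(p.phi_mean * (1.0 + raw), 0.0, 1.0)
    if taxon.lat_cut_south_deg is not None:
        phi = np.where(lat2d < taxon.lat_cut_south_deg, 0.0, phi)

    unit = 24.0 if taxon.hourly else 1.0   # K hour per K day
    h_fs = (
        p.h_fs_base_K_day
        + p.h_fs_lat_slope_K_day_per_deg * (lat2d - grid.lat_min)
        + p.h_noise_K_day * _smooth_field(rng, (ny, nx), p.phi_smooth_cells)
    )
    h_fs = np.maximum(h_fs, 10.0) * unit
    h_fe = h_fs + p.delta_h_K_day * unit

    return Landscape(grid=grid, phi=phi, H_fs=h_fs, H_fe=h_fe, cell_area_m2=grid.cell_area_m2())


def gen_truth_xi(
    grid: GridSpec, seed: int, lo: float = 0.5, hi: float = 2.0, smooth_cells: float = 3.0
) -> np.ndarray:
    """Smooth positive "true" correction field with values spanning [lo, hi]."""
    if not 0 < lo <= hi:
        raise ValueError("need 0 < lo <= hi")
    if lo == hi:
        return np.full(grid.shape, float(lo))
    rng = np.random.default_rng(seed)
    f = _smooth_field(rng, grid.shape, smooth_cells)
    f = (f - f.min()) / max(f.max() - f.min(), 1e-12)
    # log span keeps the field positive and multiplicatively symmetric
    return np.exp(np.log(lo) + f * (np.log(hi) - np.log(lo)))


def gen_station_network(
    grid: GridSpec,
    n_stations: int,
    seed: int,
    clustering: float = 0.0,
    isolation_km: float = 300.0,
    layout: str = "uniform",
) -> StationNetwork:
    """Place stations inside the grid-center hull.

    ``layout="uniform"`` draws independent uniform locations;
    ``layout="stratified"`` jitters stations around a regular lattice,
    mimicking a monitoring network engineered for domain coverage.  With
    ``clustering`` in (0, 1], that fraction of stations is drawn near a
    few cluster centers (mimicking dense national networks) and the last
    station is pushed to the location maximizing its nearest-neighbour
    distance, guaranteeing at least one "isolated" site.  A station is
    flagged isolated when its nearest neighbour is farther than
    ``isolation_km``.
    """
    if n_stations < 1:
        raise ValueError("n_stations must be >= 1")
    if n_stations > grid.n_cells:
        raise ValueError("more stations than grid cells")
    if layout not in ("uniform", "stratified"):
        raise ValueError("layout must be 'uniform' or 'stratified'")
    rng = np.random.default_rng(seed)
    lc, tc = grid.lon_centers, grid.lat_centers
    lon_lo, lon_hi = lc[0], lc[-1]
    lat_lo, lat_hi = tc[0], tc[-1]

    if layout == "stratified":
        aspect = (lon_hi - lon_lo) / (lat_hi - lat_lo)
        ncol = max(1, int(round(np.sqrt(n_stations * aspect))))
        nrow = int(np.ceil(n_stations / ncol))
        xs = lon_lo + (np.arange(ncol) + 0.5) / ncol * (lon_hi - lon_lo)
        ys = lat_lo + (np.arange(nrow) + 0.5) / nrow * (lat_hi - lat_lo)
        pts = [(x, y) for y in ys for x in xs][:n_stations]
        jx = 0.35 * (lon_hi - lon_lo) / ncol
        jy = 0.35 * (lat_hi - lat_lo) / nrow
        lons = [float(np.clip(x + rng.uniform(-jx, jx), lon_lo, lon_hi)) for x, _ in pts]
        lats = [float(np.clip(y + rng.uniform(-jy, jy), lat_lo, lat_hi)) for _, y in pts]
        return _finalize_network(lons, lats, isolation_km)

    def uniform_point():
        return (rng.uniform(lon_lo, lon_hi), rng.uniform(lat_lo, lat_hi))

    lons, lats = [], []
    n_clustered = int(round(clustering * n_stations))
    if n_clustered > 0:
        n_centers = max(1, n_clustered // 4)
        centers = [uniform_point() for _ in range(n_centers)]
        spread_lon = (lon_hi - lon_lo) * 0.05
        spread_lat = (lat_hi - lat_lo) * 0.05
        for k in range(n_clustered):
            clon, clat = centers[k % n_centers]
            lons.append(np.clip(clon + rng.normal(0, spread_lon), lon_lo, lon_hi))
            lats.append(np.clip(clat + rng.normal(0, spread_lat), lat_lo, lat_hi))
    n_free = n_stations - n_clustered - (1 if clustering > 0 and n_stations > 1 else 0)
    for _ in range(max(n_free, 0)):
        lo, la = uniform_point()
        lons.append(lo)
        lats.append(la)
    if clustering > 0 and n_stations > 1:
        # push one station to the candidate point farthest from all others
        cands = [uniform_point() for _ in range(256)]
        placed_lon = np.asarray(lons)
        placed_lat = np.asarray(lats)
        scores = [
            float(haversine_km(placed_lon, placed_lat, clon, clat).min())
            for clon, clat in cands
        ]
        best = cands[int(np.argmax(scores))]
        lons.append(best[0])
        lats.append(best[1])

    return _finalize_network(lons, lats, isolation_km)


def _finalize_network(lons, lats, isolation_km: float) -> StationNetwork:
    lons = np.asarray(lons)
    lats = np.asarray(lats)
    if len(lons) > 1:
        d = pairwise_distance_km(lons, lats)
        np.fill_diagonal(d, np.inf)
        isolated = d.min(axis=1) > isolation_km
    else:
        isolated = np.array([True])
    table = pd.DataFrame(
        {
            "station_id": [f"ST{k:03d}" for k in range(len(lons))],
            "lon": lons,
            "lat": lats,
            "isolated": isolated,
        }
    )
    return StationNetwork(table=table)


def gen_observations(
    conc_daily: np.ndarray,
    days: pd.DatetimeIndex,
    grid: GridSpec,
    stations: StationNetwork,
    noise: NoiseConfig,
    seed: int,
) -> dict[str, "pd.DataFrame"]:
    """Synthetic daily station counts from a gridded daily truth field.

    Each station's series is the bilinear sample of the truth multiplied
    by mean-unbiased lognormal noise exp(sigma*Z - sigma^2/2), with days
    knocked out at the configured missing probability.  Returns a mapping
    station_id -> DataFrame(date-indexed: value, valid).
    """
    rng = np.random.default_rng(seed)
    nt = conc_daily.shape[0]
    flat = conc_daily.reshape(nt, -1)
    out: dict[str, pd.DataFrame] = {}
    for _, row in stations.table.iterrows():
        idx, w = grid.bilinear_weights(row.lon, row.lat)   # raises if outside
        truth = flat[:, idx] @ w
        sig = noise.lognormal_sigma
        if sig > 0:
            vals = truth * np.exp(sig * rng.standard_normal(nt) - sig**2 / 2)
        else:
            vals = truth.copy()
        valid = rng.random(nt) >= noise.missing_prob
        out[row.station_id] = pd.DataFrame(
            {"value": np.maximum(vals, 0.0), "valid": valid}, index=days
        )
    return out
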