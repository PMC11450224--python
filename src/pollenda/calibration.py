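"""Post-assimilation bias calibration of the mean release strength.

Assimilating imperfectly correlated series biases the season totals low
(the scalar optimum scales with the model-observation correlation), so
after the assimilation the mean source strength is recalibrated: the
whole-period model/observation SPIn ratio r_s is computed per station,
interpolated over the domain with a linear-kernel radial basis function,
and the seasonal emission is divided by the resulting smooth map.  The
final validation ratio r_st (observed over modelled, summed over
co-valid days only) checks that the recalibrated fields are unbiased.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator

from .grid import GridSpec
from .observations import SpinValue

log = logging.getLogger(__name__)


def compute_ratio_rs(
    spin_mdl: list[SpinValue],
    spin_obs: list[SpinValue],
    stations: pd.DataFrame,
) -> pd.DataFrame:
    """Per-station whole-period SPIn ratio r_s = sum(model)/sum(obs).

    Only station-years flagged usable (>= 30 valid observation days)
    enter either sum; no correlation screening is applied here.
    Stations whose observed SPIn sums to zero are excluded.  ``stations``
    supplies lon/lat per station_id.  Returns columns
    station_id, lon, lat, r_s, n_years.
    """
    obs_ok = {(s.station_id, s.year): s.value for s in spin_obs if s.usable}
    mdl_all = {(s.station_id, s.year): s.value for s in spin_mdl}
    rows = []
    for sid in sorted({k[0] for k in obs_ok}):
        years = [yr for (s, yr) in obs_ok if s == sid and (s, yr) in mdl_all]
        if not years:
            continue
        so = sum(obs_ok[(sid, yr)] for yr in years)
        sm = sum(mdl_all[(sid, yr)] for yr in years)
        if so <= 0:
            log.info("station %s excluded from calibration: zero observed SPIn", sid)
            continue
        rec = stations.loc[stations.station_id == sid].iloc[0]
        rows.append(
            {"station_id": sid, "lon": rec.lon, "lat": rec.lat,
             "r_s": sm / so, "n_years": len(years)}
        )
    return pd.DataFrame(rows, columns=["station_id", "lon", "lat", "r_s", "n_years"])


def interpolate_rbf(points: pd.DataFrame, grid: GridSpec, smoothing: float = 10.0) -> np.ndarray:
    """Linear-kernel RBF inter/extrapolation of station ratios to the
    grid (ny, nx).  A single point degenerates to a constant field."""
    if len(points) == 0:
        raise ValueError("no calibration points: cannot build a correction map")
    lon2d, lat2d = grid.mesh()
    if len(points) == 1:
        return np.full(grid.shape, float(points.r_s.iloc[0]))
    xy = np.column_stack([points.lon.to_numpy(), points.lat.to_numpy()])
    # degree-1 polynomial tail (the default for the linear kernel) keeps the
    # extrapolation bounded and reproduces constant fields exactly
    try:
        rbf = RBFInterpolator(
            xy, points.r_s.to_numpy(), kernel="linear", smoothing=smoothing,
            degree=1 if len(points) >= 3 else 0,
        )
    except np.linalg.LinAlgError:
        # collinear stations make the degree-1 monomial block singular
        rbf = RBFInterpolator(
            xy, points.r_s.to_numpy(), kernel="linear", smoothing=smoothing, degree=0
        )
    out = rbf(np.column_stack([lon2d.ravel(), lat2d.ravel()]))
    return out.reshape(grid.shape)


def apply_calibration(
    emission_map: np.ndarray, correction: np.ndarray, floor: float = 1e-3
) -> np.ndarray:
    """Divide the seasonal emission by the r_s map (model-over-obs ratio
    above 1 means the model runs high, so emission is reduced).  The
    correction is clipped below at ``floor``; a non-positive correction
    cell after clipping is an error."""
    corr = np.maximum(np.asarray(correction, float), floor)
    if np.any(corr <= 0):
        raise ValueError("calibration map must be strictly positive")
    if emission_map.shape != corr.shape:
        raise ValueError("emission and correction shapes differ")
    return emission_map / corr


def validate_ratio_rst(
    obs: dict[str, pd.DataFrame], mdl: dict[str, pd.Series]
) -> pd.DataFrame:
    """Whole-period per-station ratio of observed to modelled totals,
    summed over co-valid observed days and the exactly co-located model
    values; stations with a zero model sum are skipped.  Returned as
    columns station_id, r_st (observed / modelled)."""
    rows = []
    for sid, frame in obs.items():
        if sid not in mdl:
            continue
        m = mdl[sid].reindex(frame.index)
        ok = frame["valid"].to_numpy().astype(bool) & m.notna().to_numpy()
        so = float(frame["value"].to_numpy()[ok].sum())
        sm = float(m.to_numpy()[ok].sum())
        if sm <= 0:
            log.info("station %s skipped in validation: zero model total", sid)
            continue
        rows.append({"station_id": sid, "r_st": so / sm})
    return pd.DataFrame(rows, columns=["station_id", "r_st"])
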