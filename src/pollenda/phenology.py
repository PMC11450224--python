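"""Heat-sum pollen development and meteorology-modulated release.

The source term distinguishes two stages.  *Development* of the
ready-to-fly pollen stock is driven purely by accumulated heat: once the
heat sum H (temperature excess over the taxon cut-off, summed from the
taxon's start day) approaches the flowering-start threshold H_fs, pollen
matures at a rate proportional to (T - T_co)/(H_fe - H_fs), gated by a
start ramp p_fs over the threshold's uncertainty band and an end ramp
p_fe that winds the season down.  *Release* of the accumulated stock
into the air depends on the current weather: an exponential depletion
with time constant tau, amplified by wind and convection and suppressed
by high humidity and rain.

Two structural properties the downstream assimilation relies on are
enforced by construction:

* budget — under non-limiting weather the seasonal total released per
  cell equals S * phi * xi * N_tot.  The end ramp is therefore evaluated
  on the cumulative *potential* development fraction (the released
  fraction had nothing limited the season) rather than on the realized
  one: reading p_fe as the survival function of per-tree season-end
  thresholds uniform over (1-delta_N, 1+delta_N), the population total
  then integrates to exactly N_tot instead of overshooting to
  (1+delta_N) N_tot;
* linearity — development and release rates are both proportional to
  xi, and the phenological timing (H, ramps) is independent of it, so
  the full-season emission field scales exactly linearly with the
  per-cell correction xi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import Landscape, MeteoFields
from .taxa import TaxonParams


def p_start(h_ratio, delta_h: float):
    """Probability that flowering has started, given H/H_fs.

    Piecewise-linear ramp: 0 below 1-delta_h, 1 above 1+delta_h, 0.5 at
    threshold.
    """
    h_ratio = np.asarray(h_ratio, float)
    return np.clip((h_ratio - (1.0 - delta_h)) / (2.0 * delta_h), 0.0, 1.0)


def p_end(progress, delta_n: float):
    """Probability that flowering has *not yet* ended.

    Ramp from 1 at progress 1-delta_n down to 0 at 1+delta_n;
    development hard-stops beyond the band.  ``progress`` is the
    cumulative potential development fraction (see module docstring).
    """
    progress = np.asarray(progress, float)
    return np.clip(((1.0 + delta_n) - progress) / (2.0 * delta_n), 0.0, 1.0)


def _p_end_cumulative(progress, delta_n: float):
    """Integral of the end ramp from 0 to ``progress``.

    Piecewise quadratic, saturating at exactly 1: integrating the ramp in
    closed form per time step (rather than sampling it) is what makes the
    seasonal budget exact regardless of step length.
    """
    d = np.asarray(progress, float)
    s = np.clip((d - (1.0 - delta_n)) / (2.0 * delta_n), 0.0, 1.0)
    return np.minimum(d, 1.0 - delta_n) + 2.0 * delta_n * (s - 0.5 * s * s)


def threshold_factor(v, v_low: float, v_high: float):
    """Release suppression factor: 1 at/below v_low, 0 at/above v_high."""
    if not v_low < v_high:
        raise ValueError("v_low must be below v_high")
    v = np.asarray(v, float)
    return np.clip((v_high - v) / (v_high - v_low), 0.0, 1.0)


def wind_factor(U, wstar, taxon: TaxonParams):
    """Wind/convection release amplification, 1 at calm, saturating to
    the taxon's maximum scaling as (U + w*) grows past the saturation
    level."""
    drive = np.asarray(U, float) + np.asarray(wstar, float)
    return 1.0 + (taxon.wind_max_scale - 1.0) * (1.0 - np.exp(-drive / taxon.wind_saturation_m_s))


def accumulate_heat_sum(
    temps_K: np.ndarray, times: pd.DatetimeIndex, taxon: TaxonParams
) -> np.ndarray:
    """Heat-sum series for one location.

    Increment per step is max(T - T_co, 0) times the step length, in
    K day for daily series and K hour for hourly ones; steps before the
    taxon's start day contribute nothing.
    """
    temps_K = np.asarray(temps_K, float)
    start = taxon.start_date(times[0].year)
    if times[0] > start:
        raise ValueError("meteo record starts after the heat-accumulation start day")
    active = (times >= start).to_numpy() if hasattr(times >= start, "to_numpy") else np.asarray(times >= start)
    inc = np.maximum(temps_K - taxon.cutoff_temperature_K, 0.0) * active
    return np.cumsum(inc)


@dataclass
class EmissionField:
    """Gridded emission rates (grains/s per cell) plus the seasonal
    per-cell budget (grains)."""

    grid: "object"
    times: pd.DatetimeIndex
    rate: np.ndarray            # (nt, ny, nx), grains s-1
    seasonal_budget: np.ndarray  # (ny, nx), grains
    step_seconds: float


@dataclass
class PhenologyState:
    """Per-cell phenology state carried through the season."""

    H: np.ndarray          # heat sum (K day or K hour)
    progress: np.ndarray   # cumulative potential development fraction
    p_rdy: np.ndarray      # ready-to-fly stock (grains)
    released: np.ndarray   # cumulative released (grains)


def simulate_emission(
    meteo: MeteoFields,
    landscape: Landscape,
    taxon: TaxonParams,
    xi: np.ndarray | float = 1.0,
) -> EmissionField:
    """Run the two-stage source term over the whole meteo record.

    ``xi`` is the per-cell unitless seasonal release correction
    (scalar or (ny, nx)); emission is exactly linear in it.
    """
    if taxon.hourly and meteo.freq != "h":
        raise ValueError(f"{taxon.name} accumulates an hourly heat sum; hourly meteo required")
    grid = meteo.grid
    ny, nx = grid.shape
    xi = np.broadcast_to(np.asarray(xi, float), (ny, nx))
    if np.any(xi <= 0):
        raise ValueError("xi must be strictly positive")

    dt = meteo.step_seconds
    step_len = 1.0          # in the heat-sum unit (1 day or 1 hour)
    start = taxon.start_date(meteo.times[0].year)
    t_co = taxon.cutoff_temperature_K
    d_h = taxon.heatsum_uncertainty
    d_n = taxon.n_total_uncertainty

    total_cap = landscape.cell_area_m2 * landscape.phi * xi * taxon.n_total  # grains
    delta_H = landscape.H_fe - landscape.H_fs
    producing = landscape.phi > 0
    if np.any(producing & (delta_H <= 0)):
        raise ValueError("H_fe must exceed H_fs wherever the taxon is present")
    inv_dH = np.where(delta_H > 0, 1.0 / np.where(delta_H > 0, delta_H, 1.0), 0.0)

    state = PhenologyState(
        H=np.zeros((ny, nx)),
        progress=np.zeros((ny, nx)),
        p_rdy=np.zeros((ny, nx)),
        released=np.zeros((ny, nx)),
    )
    avail_frac = 1.0 - np.exp(-dt / taxon.release_time_s)
    rate = np.zeros((len(meteo.times), ny, nx))

    for t, when in enumerate(meteo.times):
        if when < start:
            continue
        dH = np.maximum(meteo.T[t] - t_co, 0.0) * step_len
        state.H += dH
        pfs = p_start(state.H / landscape.H_fs, d_h)
        d_progress = dH * inv_dH * pfs
        new_progress = state.progress + d_progress
        development = total_cap * (
            _p_end_cumulative(new_progress, d_n) - _p_end_cumulative(state.progress, d_n)
        )                                                   # grains this step
        state.progress = new_progress
        state.p_rdy += development

        f = (
            wind_factor(meteo.U[t], meteo.wstar[t], taxon)
            * threshold_factor(meteo.q[t], taxon.humidity_low_pct, taxon.humidity_high_pct)
            * threshold_factor(meteo.P[t], 0.0, taxon.precip_threshold_mm_h)
        )
        emitted = state.p_rdy * np.minimum(avail_frac * f, 1.0)
        state.p_rdy -= emitted
        state.released += emitted
        rate[t] = emitted / dt

    return EmissionField(
        grid=grid,
        times=meteo.times,
        rate=rate,
        seasonal_budget=state.released.copy(),
        step_seconds=dt,
    )
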