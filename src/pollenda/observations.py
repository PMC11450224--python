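"""Observation operator, averaging, quality filters, SPIn, station split.

Daily station counts are the observational currency of the whole
pipeline.  Before assimilation they are averaged into non-overlapping
2-day bins (anchored at the taxon's assimilation-window start), which
suppresses the day-to-day sampling noise the season-total inversion does
not need but would be penalized for; station-years are then screened for
completeness (>= 30 valid days), signal (>= 5 non-zero days), and model
adequacy (2-day Pearson correlation strictly above 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transport import ConcentrationField

MIN_VALID_DAYS = 30
MIN_NONZERO_DAYS = 5
MIN_CORRELATION = 0.3


@dataclass
class StationSeries:
    """Daily values at one site with validity flags."""

    station_id: str
    lon: float
    lat: float
    values: pd.Series          # date-indexed daily means
    valid: pd.Series           # boolean, same index
    isolated: bool = False

    def __post_init__(self) -> None:
        if not self.values.index.is_monotonic_increasing or self.values.index.has_duplicates:
            raise ValueError("dates must be unique and ordered")

    def window(self, t0: pd.Timestamp, t1: pd.Timestamp) -> "StationSeries":
        m = (self.values.index >= t0) & (self.values.index <= t1)
        return StationSeries(
            self.station_id, self.lon, self.lat, self.values[m], self.valid[m], self.isolated
        )


@dataclass
class SpinValue:
    """Seasonal Pollen Integral: sum of valid daily means over a window,
    pollen day m-3."""

    station_id: str
    year: int
    value: float
    n_valid_days: int
    usable: bool


def sample_model(conc: ConcentrationField, lon: float, lat: float) -> pd.Series:
    """Bilinear sample of the near-surface field at a point, aggregated
    to daily means; linear in the field."""
    daily = conc.daily_mean()
    idx, w = daily.grid.bilinear_weights(lon, lat)
    flat = daily.values.reshape(len(daily.times), -1)
    return pd.Series(flat[:, idx] @ w, index=daily.times)


def average_2day(
    values: pd.Series, valid: pd.Series, window_start: pd.Timestamp
) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping 2-day bin means anchored at ``window_start``.

    A bin with one valid day takes that day's value; a bin with no valid
    day is invalid.  Returns (bin_values, bin_valid) over the bins
    covering the series' date range from the anchor onward.
    """
    days = values.index
    offset = (days - window_start).days.to_numpy()
    keep = offset >= 0
    offset = offset[keep]
    vals = values.to_numpy()[keep]
    ok = valid.to_numpy()[keep].astype(bool)
    if offset.size == 0:
        return np.empty(0), np.empty(0, bool)
    bins = offset // 2
    n_bins = bins.max() + 1
    s = np.zeros(n_bins)
    c = np.zeros(n_bins)
    np.add.at(s, bins[ok], vals[ok])
    np.add.at(c, bins[ok], 1.0)
    bin_valid = c > 0
    with np.errstate(invalid="ignore"):
        bin_vals = np.where(bin_valid, s / np.where(c > 0, c, 1.0), np.nan)
    return bin_vals, bin_valid


def station_year_passes(
    obs: StationSeries,
    mdl: pd.Series,
    window: tuple[pd.Timestamp, pd.Timestamp],
) -> tuple[bool, str]:
    """Accept/reject one station-year against the three screening rules.

    ``mdl`` is the model daily series sampled at the station.  The rules
    commute; all are evaluated inside the assimilation window.
    """
    o = obs.window(*window)
    if len(o.values) == 0 or not o.valid.any():
        return False, "no co-valid data"
    n_valid = int(o.valid.sum())
    if n_valid < MIN_VALID_DAYS:
        return False, f"completeness: {n_valid} < {MIN_VALID_DAYS} valid days"
    n_nonzero = int(((o.values > 0) & o.valid).sum())
    if n_nonzero < MIN_NONZERO_DAYS:
        return False, f"signal: {n_nonzero} < {MIN_NONZERO_DAYS} non-zero days"
    m = mdl.reindex(o.values.index)
    ob, ov = average_2day(o.values, o.valid, window[0])
    mb, mv = average_2day(m, o.valid & m.notna(), window[0])
    co = ov & mv
    if co.sum() < 3:
        return False, "no co-valid data"
    x, y = ob[co], mb[co]
    if np.std(x) == 0 or np.std(y) == 0:
        return False, "correlation: degenerate series"
    r = float(np.corrcoef(x, y)[0, 1])
    if not r > MIN_CORRELATION:
        return False, f"correlation: {r:.3f} <= {MIN_CORRELATION}"
    return True, "accepted"


def split_assim_eval(
    station_ids: list[str],
    mandatory: list[str],
    seed: int,
    eval_fraction: float = 0.2,
    regions: dict[str, list[str]] | None = None,
    max_redraws: int = 50,
) -> tuple[list[str], list[str]]:
    """Semi-random 80/20 split into assimilation and evaluation subsets.

    Mandatory (spatially isolated) stations always assimilate; the rest
    are split randomly.  If ``regions`` maps region names to station
    lists, the split is redrawn while any region has all its stations in
    evaluation.  Deterministic for a given seed.
    """
    unknown = set(mandatory) - set(station_ids)
    if unknown:
        raise ValueError(f"mandatory stations not in the accepted set: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    free = [s for s in station_ids if s not in set(mandatory)]
    if len(free) < 2:
        if free:
            import logging

            logging.getLogger(__name__).warning(
                "fewer than 2 non-mandatory stations; evaluation set left empty"
            )
        return list(station_ids), []
    n_eval = max(1, int(round(eval_fraction * len(station_ids))))
    n_eval = min(n_eval, len(free) - 1)
    for _ in range(max_redraws):
        eval_set = list(rng.choice(free, size=n_eval, replace=False))
        if regions:
            bad = any(
                set(members) and set(members) <= set(eval_set) for members in regions.values()
            )
            if bad:
                continue
        assim = [s for s in station_ids if s not in set(eval_set)]
        return assim, eval_set
    assim = [s for s in station_ids if s not in set(eval_set)]
    return assim, eval_set


def compute_spin(
    values: pd.Series,
    valid: pd.Series,
    window: tuple[pd.Timestamp, pd.Timestamp],
    min_days: int = MIN_VALID_DAYS,
    station_id: str = "",
) -> SpinValue:
    """Seasonal Pollen Integral over the window: sum of valid daily
    means, flagged unusable when fewer than ``min_days`` days are valid."""
    t0, t1 = window
    m = (values.index >= t0) & (values.index <= t1)
    v = values[m]
    ok = valid[m].astype(bool)
    n = int(ok.sum())
    return SpinValue(
        station_id=station_id,
        year=int(t0.year),
        value=float(v[ok].sum()),
        n_valid_days=n,
        usable=n >= min_days,
    )
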