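"""Linear 2-D advection-diffusion-deposition transport with an exact
discrete adjoint.

The dispersion stand-in treats pollen as vertically well-mixed within a
boundary layer of fixed mixing height: emission flux (grains/s per cell)
is converted to a concentration tendency by dividing by cell area times
mixing height, then advected with first-order upwind fluxes on the
divergence-free synthetic wind, diffused explicitly, and removed by a
first-order deposition sink derived from Stokes settling of the pollen
grain.  Lateral boundaries are open for outflow with zero inflow.

Each meteorology step is assembled as one sparse substep matrix applied
a CFL-limited number of times, so the forward map is an explicit linear
operator; the adjoint applies the transposes in reverse order and
therefore satisfies the dot-product identity to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .grid import EARTH_RADIUS_KM, GridSpec
from .synthetic import MeteoFields
from .taxa import TaxonParams

G = 9.81
AIR_VISCOSITY = 1.8e-5  # Pa s


def stokes_settling_velocity(diameter_um: float, density_kg_m3: float) -> float:
    """Terminal settling velocity (m/s) of a spherical grain in still air."""
    d = diameter_um * 1e-6
    return density_kg_m3 * G * d * d / (18.0 * AIR_VISCOSITY)


@dataclass
class ConcentrationField:
    """Near-surface concentration, grains m-3, shape (nt, ny, nx)."""

    grid: GridSpec
    times: pd.DatetimeIndex
    values: np.ndarray

    def daily_mean(self) -> "ConcentrationField":
        """Aggregate an hourly field to daily means (identity for daily)."""
        days = pd.DatetimeIndex(np.unique(self.times.normalize()))
        if len(days) == len(self.times):
            return self
        out = np.empty((len(days), *self.grid.shape))
        norm = self.times.normalize()
        for k, d in enumerate(days):
            out[k] = self.values[norm == d].mean(axis=0)
        return ConcentrationField(grid=self.grid, times=days, values=out)


@dataclass
class LinearTransport:
    """Assembled linear transport operator for one meteo record.

    ``step_ops[t]`` maps the concentration vector (flattened ny*nx) from
    the start to the end of meteo step ``t``; emission injected at step
    ``t`` is mixed in before the step's transport is applied.
    """

    grid: GridSpec
    times: pd.DatetimeIndex
    step_seconds: float
    mixing_height_m: float
    deposition_rate_s: float
    source_factor: np.ndarray          # dt / (area * h), per cell, flattened
    step_ops: list = field(repr=False, default_factory=list)  # (substep, transpose, n_sub)

    @classmethod
    def from_meteo(
        cls,
        meteo: MeteoFields,
        taxon: TaxonParams | None = None,
        diffusion_m2_s: float = 5000.0,
        mixing_height_m: float = 1000.0,
        deposition_rate_s: float | None = None,
        cfl_max: float = 0.8,
    ) -> "LinearTransport":
        grid = meteo.grid
        ny, nx = grid.shape
        n = ny * nx
        # constant metric at the domain-mean latitude keeps the upwind
        # stencil uniform; fine at desk scale
        lat0 = np.deg2rad(0.5 * (grid.lat_min + grid.lat_max))
        dx = EARTH_RADIUS_KM * 1e3 * np.deg2rad(grid.dlon) * np.cos(lat0)
        dy = EARTH_RADIUS_KM * 1e3 * np.deg2rad(grid.dlat)

        if deposition_rate_s is None:
            if taxon is None:
                deposition_rate_s = 1e-5
            else:
                vs = stokes_settling_velocity(taxon.grain_diameter_um, taxon.grain_density_kg_m3)
                deposition_rate_s = vs / mixing_height_m

        dt = meteo.step_seconds
        ops = []
        for t in range(len(meteo.times)):
            u = meteo.u[t]
            v = meteo.v[t]
            courant = dt * (np.abs(u).max() / dx + np.abs(v).max() / dy)
            n_sub = max(1, int(np.ceil(courant / cfl_max)))
            # explicit diffusion stability
            dt_sub = dt / n_sub
            while dt_sub * diffusion_m2_s * (2 / dx**2 + 2 / dy**2) > 0.9:
                n_sub += 1
                dt_sub = dt / n_sub
            step = _substep_matrix(u, v, dx, dy, dt_sub, diffusion_m2_s, deposition_rate_s)
            ops.append((step, step.T.tocsr(), n_sub))

        area = grid.cell_area_m2().ravel()
        source_factor = dt / (area * mixing_height_m)
        return cls(
            grid=grid,
            times=meteo.times,
            step_seconds=dt,
            mixing_height_m=mixing_height_m,
            deposition_rate_s=deposition_rate_s,
            source_factor=source_factor,
            step_ops=ops,
        )

    # -- linear maps -------------------------------------------------------

    def forward(self, emission_rate: np.ndarray) -> np.ndarray:
        """Concentration (nt, ny, nx) from emission rate (nt, ny, nx) in
        grains/s per cell.  Linear in the emission."""
        nt = len(self.times)
        if emission_rate.shape[0] != nt:
            raise ValueError("emission time axis does not match transport record")
        e = emission_rate.reshape(nt, -1)
        c = np.zeros(e.shape[1])
        out = np.empty_like(e)
        for t in range(nt):
            m, _, n_sub = self.step_ops[t]
            c = c + self.source_factor * e[t]
            for _ in range(n_sub):
                c = m @ c
            out[t] = c
        return out.reshape(emission_rate.shape)

    def adjoint(self, weights: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`forward`: emission-shaped sensitivities
        from concentration-shaped weights."""
        nt = len(self.times)
        if weights.shape[0] != nt:
            raise ValueError("weight time axis does not match transport record")
        w = weights.reshape(nt, -1)
        out = np.empty_like(w)
        carry = np.zeros(w.shape[1])
        for t in range(nt - 1, -1, -1):
            _, mt, n_sub = self.step_ops[t]
            z = w[t] + carry
            for _ in range(n_sub):
                z = mt @ z
            out[t] = self.source_factor * z
            carry = z
        return out.reshape(weights.shape)

    def station_footprint(
        self, lon: float, lat: float, window: tuple[pd.Timestamp, pd.Timestamp]
    ) -> np.ndarray:
        """Seasonal sensitivity map (ny, nx) of a station to unit emission
        rate, summed over the window: one adjoint run seeded with the
        station's bilinear sampling kernel on every step in the window."""
        idx, wgt = self.grid.bilinear_weights(lon, lat)
        nt = len(self.times)
        w = np.zeros((nt, self.grid.n_cells))
        t0, t1 = window
        in_win = (self.times >= t0) & (self.times <= t1)
        w[np.nonzero(in_win)[0][:, None], idx[None, :]] = wgt[None, :]
        sens = self.adjoint(w.reshape(nt, *self.grid.shape))
        return sens.sum(axis=0)


def _substep_matrix(u, v, dx, dy, dt, kdiff, kdep) -> sp.csr_matrix:
    """One explicit substep: I + dt*(upwind advection + diffusion), scaled
    by the deposition decay factor.  Open outflow, zero inflow."""
    ny, nx = u.shape
    n = ny * nx
    idx = np.arange(n).reshape(ny, nx)
    diag = np.zeros((ny, nx))
    rows, cols, vals = [], [], []

    def add(r, c, w):
        rows.append(np.asarray(r).ravel())
        cols.append(np.asarray(c).ravel())
        vals.append(np.asarray(w).ravel())

    # east-west interior faces between (j,i) and (j,i+1); upwind donor cell
    uf = 0.5 * (u[:, :-1] + u[:, 1:]) * dt / dx
    pos, neg = np.maximum(uf, 0.0), np.minimum(uf, 0.0)
    a, b = idx[:, :-1], idx[:, 1:]
    add(b, a, pos)
    diag[:, :-1] -= pos
    add(a, b, -neg)
    diag[:, 1:] += neg
    # north-south interior faces between (j,i) and (j+1,i)
    vf = 0.5 * (v[:-1, :] + v[1:, :]) * dt / dy
    pos, neg = np.maximum(vf, 0.0), np.minimum(vf, 0.0)
    a, b = idx[:-1, :], idx[1:, :]
    add(b, a, pos)
    diag[:-1, :] -= pos
    add(a, b, -neg)
    diag[1:, :] += neg
    # open boundaries: outflow across a domain edge removes mass, no inflow
    diag[:, 0] += np.minimum(u[:, 0] * dt / dx, 0.0)
    diag[:, -1] -= np.maximum(u[:, -1] * dt / dx, 0.0)
    diag[0, :] += np.minimum(v[0, :] * dt / dy, 0.0)
    diag[-1, :] -= np.maximum(v[-1, :] * dt / dy, 0.0)

    # diffusion (no diffusive flux through the edges)
    ax = kdiff * dt / dx**2
    ay = kdiff * dt / dy**2
    for aa, bb, w in (
        (idx[:, :-1], idx[:, 1:], ax),
        (idx[:-1, :], idx[1:, :], ay),
    ):
        ones = np.full(aa.size, w)
        add(aa, bb, ones)
        add(bb, aa, ones)
    diag[:, :-1] -= ax
    diag[:, 1:] -= ax
    diag[:-1, :] -= ay
    diag[1:, :] -= ay

    add(idx, idx, 1.0 + diag)
    m = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return (np.exp(-kdep * dt) * m).tocsr()
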