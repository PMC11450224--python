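import numpy as np
import pandas as pd
import pytest

from pollenda import GridSpec, LinearTransport, gen_meteo, load_taxon
from pollenda.synthetic import MeteoConfig
from pollenda.transport import stokes_settling_velocity


def _calm_meteo(grid, n_days, wind=0.0):
    return gen_meteo(
        grid, n_days, seed=5,
        params=MeteoConfig(wind_speed_scale_m_s=wind, wet_day_prob=0.0,
                           noise_sigma_K=0.0),
        start="2000-04-01",
    )


class TestForward:
    def test_zero_emission_zero_concentration(self, transport_small):
        nt = len(transport_small.times)
        e = np.zeros((nt, *transport_small.grid.shape))
        assert np.all(transport_small.forward(e) == 0.0)

    def test_linearity(self, transport_small):
        rng = np.random.default_rng(3)
        nt = len(transport_small.times)
        shape = (nt, *transport_small.grid.shape)
        e1, e2 = rng.random(shape), rng.random(shape)
        c = transport_small.forward(e1 + e2)
        c12 = transport_small.forward(e1) + transport_small.forward(e2)
        assert np.allclose(c, c12, rtol=1e-12, atol=1e-12)

    def test_mass_conserved_without_wind_and_deposition(self):
        grid = GridSpec(0.0, 6.0, 47.0, 51.0, 6, 4)
        meteo = _calm_meteo(grid, 30, wind=0.0)
        tr = LinearTransport.from_meteo(meteo, deposition_rate_s=0.0)
        e = np.zeros((30, *grid.shape))
        e[0, 2, 3] = 1e6  # one pulse, grains/s over the first day
        conc = tr.forward(e)
        # the operator's metric is the constant-cell one; its conserved
        # quantity is the plain concentration sum
        mass = conc.sum(axis=(1, 2))
        assert np.allclose(mass[1:], mass[0], rtol=1e-6)

    def test_deposition_strictly_reduces_mass(self):
        grid = GridSpec(0.0, 6.0, 47.0, 51.0, 6, 4)
        meteo = _calm_meteo(grid, 20, wind=0.0)
        tr = LinearTransport.from_meteo(meteo, taxon=load_taxon("birch"))
        e = np.zeros((20, *grid.shape))
        e[0, 1, 1] = 1e6
        conc = tr.forward(e)
        mass = conc.sum(axis=(1, 2))
        assert np.all(np.diff(mass) < 0)

    def test_concentration_nonnegative(self, transport_small):
        rng = np.random.default_rng(1)
        nt = len(transport_small.times)
        e = rng.random((nt, *transport_small.grid.shape))
        assert transport_small.forward(e).min() >= 0.0


class TestAdjoint:
    def test_dot_product_identity(self, transport_small):
        rng = np.random.default_rng(0)
        nt = len(transport_small.times)
        shape = (nt, *transport_small.grid.shape)
        e = rng.random(shape)
        w = rng.random(shape)
        a = float(np.vdot(transport_small.forward(e), w))
        b = float(np.vdot(e, transport_small.adjoint(w)))
        assert a != 0.0
        assert abs(a - b) / abs(a) <= 1e-10

    def test_adjoint_of_zero_is_zero(self, transport_small):
        nt = len(transport_small.times)
        w = np.zeros((nt, *transport_small.grid.shape))
        assert np.all(transport_small.adjoint(w) == 0.0)

    def test_adjoint_linearity(self, transport_small):
        rng = np.random.default_rng(2)
        nt = len(transport_small.times)
        shape = (nt, *transport_small.grid.shape)
        w1, w2 = rng.random(shape), rng.random(shape)
        lhs = transport_small.adjoint(2.0 * w1 + w2)
        rhs = 2.0 * transport_small.adjoint(w1) + transport_small.adjoint(w2)
        assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-12)


class TestFootprint:
    def test_positive_at_station_cell(self, transport_small):
        t0, t1 = transport_small.times[0], transport_small.times[-1]
        fp = transport_small.station_footprint(3.5, 49.5, (t0, t1))
        grid = transport_small.grid
        j = np.argmin(np.abs(grid.lat_centers - 49.5))
        i = np.argmin(np.abs(grid.lon_centers - 3.5))
        assert fp[j, i] > 0
        assert fp.min() >= 0

    def test_zero_length_window_zero_map(self, transport_small):
        t1 = transport_small.times[0] - pd.Timedelta(days=1)
        fp = transport_small.station_footprint(3.5, 49.5, (t1, t1))
        assert np.all(fp == 0.0)

    def test_footprint_matches_brute_force_unit_pulses(self):
        """The adjoint footprint must equal, cell by cell, the window-summed
        station concentration from a unit emission pulse in that cell."""
        grid = GridSpec(0.0, 4.0, 47.0, 50.0, 4, 3)
        meteo = _calm_meteo(grid, 8, wind=3.0)
        tr = LinearTransport.from_meteo(meteo)
        lon, lat = 2.3, 48.4
        window = (tr.times[0], tr.times[-1])
        fp = tr.station_footprint(lon, lat, window)
        idx, wgt = grid.bilinear_weights(lon, lat)
        nt = len(tr.times)
        brute = np.zeros(grid.shape)
        for j in range(grid.ny):
            for i in range(grid.nx):
                e = np.zeros((nt, *grid.shape))
                e[:, j, i] = 1.0     # unit emission rate throughout
                conc = tr.forward(e).reshape(nt, -1)
                brute[j, i] = (conc[:, idx] @ wgt).sum()
        assert np.allclose(fp, brute, rtol=1e-10, atol=1e-12)


def test_stokes_settling_magnitude():
    # ~1 cm/s for a 22 micron grain at 800 kg/m3
    v = stokes_settling_velocity(22.0, 800.0)
    assert 0.005 < v < 0.02


def test_explicit_matrix_matches_matrix_free(transport_small):
    """Source-receptor linearity: stacking forward runs of basis emissions
    reproduces any forward run (exact matrix representation)."""
    rng = np.random.default_rng(4)
    grid = transport_small.grid
    nt = len(transport_small.times)
    e = np.zeros((nt, *grid.shape))
    cells = [(1, 2), (3, 4), (5, 1)]
    coef = [2.0, -1.0, 0.5]
    acc = np.zeros((nt, *grid.shape))
    for (j, i), c in zip(cells, coef):
        basis = np.zeros((nt, *grid.shape))
        basis[:, j, i] = 1.0
        e[:, j, i] = c
        acc += c * transport_small.forward(basis)
    assert np.allclose(transport_small.forward(e), acc, rtol=1e-12, atol=1e-12)
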