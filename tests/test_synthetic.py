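import numpy as np
import pandas as pd
import pytest

from pollenda import (
    GridSpec,
    NoiseConfig,
    gen_landscape,
    gen_meteo,
    gen_observations,
    gen_station_network,
    gen_truth_xi,
    load_taxon,
)
from pollenda.grid import pairwise_distance_km


class TestMeteo:
    def test_same_seed_bit_identical(self, grid_small):
        a = gen_meteo(grid_small, 10, seed=7)
        b = gen_meteo(grid_small, 10, seed=7)
        for f in ("T", "u", "v", "wstar", "q", "P"):
            assert np.array_equal(getattr(a, f), getattr(b, f))

    def test_southern_edge_warmer(self, meteo_small):
        g = meteo_small.grid
        south = meteo_small.T[:, 0, :].mean()
        north = meteo_small.T[:, -1, :].mean()
        assert south > north

    def test_physical_ranges(self, meteo_small):
        assert meteo_small.q.min() >= 0 and meteo_small.q.max() <= 100
        assert meteo_small.P.min() >= 0
        assert np.all(meteo_small.U >= 0)

    def test_time_axis_gap_free(self, meteo_small):
        dt = np.diff(meteo_small.times.asi8)
        assert np.all(dt == dt[0])

    def test_rejects_nonpositive_days(self, grid_small):
        with pytest.raises(ValueError):
            gen_meteo(grid_small, 0, seed=1)

    def test_hourly_mode_has_diurnal_cycle(self, grid_small):
        m = gen_meteo(grid_small, 3, seed=1, freq="h")
        assert len(m.times) == 72
        by_hour = pd.Series(m.T.mean(axis=(1, 2)), index=m.times).groupby(
            lambda t: t.hour
        ).mean()
        assert by_hour.max() - by_hour.min() > 1.0  # K


class TestLandscape:
    def test_birch_absent_south_of_cut(self):
        grid = GridSpec(-5.0, 5.0, 35.0, 45.0, 10, 10)
        ls = gen_landscape(grid, load_taxon("birch"), seed=3)
        _, lat2d = grid.mesh()
        assert np.all(ls.phi[lat2d < 40.0] == 0.0)

    def test_thresholds_ordered_where_present(self, landscape_small):
        m = landscape_small.phi > 0
        assert np.all(landscape_small.H_fe[m] > landscape_small.H_fs[m])
        assert np.all(landscape_small.H_fs[m] > 0)

    def test_start_threshold_increases_with_latitude(self, grid_small, birch):
        ls = gen_landscape(grid_small, birch, seed=5)
        south = ls.H_fs[0].mean()
        north = ls.H_fs[-1].mean()
        assert north > south

    def test_hourly_taxon_uses_k_hour_unit(self, grid_small):
        daily = gen_landscape(grid_small, load_taxon("birch"), seed=1)
        hourly = gen_landscape(grid_small, load_taxon("alder"), seed=1)
        # K hour thresholds are ~24x the K day ones
        ratio = hourly.H_fs.mean() / daily.H_fs.mean()
        assert 15 < ratio < 35

    def test_determinism(self, grid_small, birch):
        a = gen_landscape(grid_small, birch, seed=9)
        b = gen_landscape(grid_small, birch, seed=9)
        assert np.array_equal(a.phi, b.phi)
        assert np.array_equal(a.H_fs, b.H_fs)


class TestTruthField:
    def test_range_and_positivity(self, grid_small):
        xi = gen_truth_xi(grid_small, seed=2, lo=0.5, hi=2.0)
        assert xi.min() == pytest.approx(0.5)
        assert xi.max() == pytest.approx(2.0)
        assert np.all(xi > 0)

    def test_degenerate_constant(self, grid_small):
        xi = gen_truth_xi(grid_small, seed=2, lo=0.5, hi=0.5)
        assert np.all(xi == 0.5)


class TestStationNetwork:
    def test_count_and_domain(self, grid_small):
        net = gen_station_network(grid_small, 12, seed=4)
        assert len(net) == 12
        assert net.table[["lon", "lat"]].drop_duplicates().shape[0] == 12
        assert np.all(grid_small.contains(net.table.lon, net.table.lat))

    def test_clustered_network_has_isolated_station(self, grid_small):
        net = gen_station_network(grid_small, 10, seed=4, clustering=0.8,
                                  isolation_km=150.0)
        assert net.table.isolated.any()

    def test_same_seed_same_network(self, grid_small):
        a = gen_station_network(grid_small, 6, seed=1, clustering=0.5)
        b = gen_station_network(grid_small, 6, seed=1, clustering=0.5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_too_many_stations_rejected(self, grid_small):
        with pytest.raises(ValueError):
            gen_station_network(grid_small, grid_small.n_cells + 1, seed=1)

    def test_stratified_layout_covers_domain(self, grid_small):
        net = gen_station_network(grid_small, 12, seed=2, layout="stratified")
        d = pairwise_distance_km(net.table.lon.to_numpy(), net.table.lat.to_numpy())
        np.fill_diagonal(d, np.inf)
        # jittered lattice: no two stations collapse onto each other
        assert d.min() > 30.0


class TestObservations:
    def test_noise_free_equals_sampled_truth(self, grid_small):
        days = pd.date_range("2000-04-01", periods=20)
        conc = np.full((20, *grid_small.shape), 3.5)
        net = gen_station_network(grid_small, 4, seed=1)
        obs = gen_observations(conc, days, grid_small, net,
                               NoiseConfig(0.0, 0.0), seed=0)
        for frame in obs.values():
            assert np.allclose(frame["value"], 3.5)
            assert frame["valid"].all()

    def test_all_missing(self, grid_small):
        days = pd.date_range("2000-04-01", periods=10)
        conc = np.ones((10, *grid_small.shape))
        net = gen_station_network(grid_small, 3, seed=1)
        obs = gen_observations(conc, days, grid_small, net,
                               NoiseConfig(0.3, 1.0), seed=0)
        for frame in obs.values():
            assert not frame["valid"].any()

    def test_reproducible_noise(self, grid_small):
        days = pd.date_range("2000-04-01", periods=15)
        conc = np.ones((15, *grid_small.shape))
        net = gen_station_network(grid_small, 3, seed=1)
        a = gen_observations(conc, days, grid_small, net, NoiseConfig(0.5, 0.1), seed=9)
        b = gen_observations(conc, days, grid_small, net, NoiseConfig(0.5, 0.1), seed=9)
        for sid in a:
            pd.testing.assert_frame_equal(a[sid], b[sid])
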