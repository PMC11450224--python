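import numpy as np
import pandas as pd
import pytest

from pollenda import (
    ConcentrationField,
    StationSeries,
    average_2day,
    compute_spin,
    sample_model,
    split_assim_eval,
    station_year_passes,
)


def _series(values, valid=None, start="2000-03-10"):
    idx = pd.date_range(start, periods=len(values))
    v = pd.Series(np.asarray(values, float), index=idx)
    ok = pd.Series(True if valid is None else list(valid), index=idx)
    return v, ok


class TestAverage2Day:
    def test_plain_bins(self):
        v, ok = _series([1, 3, 5, 7])
        bins, bv = average_2day(v, ok, v.index[0])
        assert np.allclose(bins, [2, 6])
        assert bv.all()

    def test_single_valid_day_keeps_its_value(self):
        v, ok = _series([4, 8], valid=[True, False])
        bins, bv = average_2day(v, ok, v.index[0])
        assert bins[0] == pytest.approx(4.0)
        assert bv[0]

    def test_fully_missing_bin_invalid(self):
        v, ok = _series([4, 8], valid=[False, False])
        _, bv = average_2day(v, ok, v.index[0])
        assert not bv[0]

    def test_anchor_shifts_binning(self):
        v, ok = _series([1, 3, 5, 7])
        bins, bv = average_2day(v, ok, v.index[1])
        # the day before the anchor is dropped; bins are then (3,5) and (7,)
        assert np.allclose(bins[bv], [4.0, 7.0])


class TestStationYearFilters:
    def _obs(self, n_valid, n_zero=0, corr_break=False, seed=0):
        rng = np.random.default_rng(seed)
        n = 80
        base = 10.0 + 5.0 * np.sin(np.arange(n) / 5.0)
        vals = base.copy()
        if n_zero:
            vals[:n_zero] = 0.0
        valid = np.zeros(n, bool)
        valid[:n_valid] = True
        v, ok = _series(vals, valid)
        mdl = pd.Series(
            rng.permutation(base) if corr_break else base + rng.normal(0, 0.1, n),
            index=v.index,
        )
        ss = StationSeries("S", 1.0, 50.0, v, ok)
        window = (v.index[0], v.index[-1])
        return ss, mdl, window

    def test_29_valid_days_rejected(self):
        ss, mdl, window = self._obs(29)
        ok, reason = station_year_passes(ss, mdl, window)
        assert not ok and "completeness" in reason

    def test_30_days_but_4_nonzero_rejected(self):
        ss, mdl, window = self._obs(30)
        # zero out all but 4 of the valid days
        ss.values.iloc[:26] = 0.0
        ok, reason = station_year_passes(ss, mdl, window)
        assert not ok and "signal" in reason

    def test_low_correlation_rejected(self):
        ss, mdl, window = self._obs(60, corr_break=True)
        ok, reason = station_year_passes(ss, mdl, window)
        assert not ok and "correlation" in reason

    def test_good_station_accepted(self):
        ss, mdl, window = self._obs(60)
        ok, reason = station_year_passes(ss, mdl, window)
        assert ok and reason == "accepted"

    def test_empty_overlap(self):
        ss, mdl, window = self._obs(0)
        ok, reason = station_year_passes(ss, mdl, window)
        assert not ok and reason == "no co-valid data"

    def test_filters_commute(self):
        """Order independence: the outcome only depends on the data, and
        each failing rule alone already rejects."""
        ss, mdl, window = self._obs(29, corr_break=True)
        ok, _ = station_year_passes(ss, mdl, window)
        assert not ok


class TestSplit:
    def test_mandatory_always_assimilated(self):
        ids = [f"S{i}" for i in range(10)]
        assim, evl = split_assim_eval(ids, ["S0", "S3"], seed=1)
        assert "S0" in assim and "S3" in assim
        assert len(assim) == 8 and len(evl) == 2
        assert set(assim) | set(evl) == set(ids)

    def test_all_mandatory_empty_eval(self):
        ids = ["A", "B"]
        assim, evl = split_assim_eval(ids, ids, seed=1)
        assert assim == ids and evl == []

    def test_deterministic(self):
        ids = [f"S{i}" for i in range(12)]
        a1 = split_assim_eval(ids, ["S1"], seed=7)
        a2 = split_assim_eval(ids, ["S1"], seed=7)
        assert a1 == a2

    def test_region_coverage_redraw(self):
        ids = [f"S{i}" for i in range(10)]
        regions = {"west": ["S9"]}
        for seed in range(10):
            _, evl = split_assim_eval(ids, [], seed=seed, regions=regions)
            assert "S9" not in evl

    def test_unknown_mandatory_rejected(self):
        with pytest.raises(ValueError):
            split_assim_eval(["A"], ["Z"], seed=0)


class TestSpin:
    def test_sum_of_daily_means(self):
        v, ok = _series([10, 20, 30])
        spin = compute_spin(v, ok, (v.index[0], v.index[-1]), min_days=2)
        assert spin.value == pytest.approx(60.0)
        assert spin.usable

    def test_all_zero_season(self):
        v, ok = _series([0] * 40)
        spin = compute_spin(v, ok, (v.index[0], v.index[-1]))
        assert spin.value == 0.0 and spin.usable

    def test_29_days_flagged_unusable(self):
        v, ok = _series([1.0] * 29)
        spin = compute_spin(v, ok, (v.index[0], v.index[-1]), min_days=30)
        assert not spin.usable


class TestSampleModel:
    def test_uniform_field_any_station(self, grid_small):
        times = pd.date_range("2000-04-01", periods=5)
        conc = ConcentrationField(
            grid=grid_small, times=times, values=np.full((5, *grid_small.shape), 2.5)
        )
        s = sample_model(conc, 3.1, 50.2)
        assert np.allclose(s, 2.5)

    def test_cell_center_value(self, grid_small):
        times = pd.date_range("2000-04-01", periods=2)
        vals = np.zeros((2, *grid_small.shape))
        vals[:, 2, 3] = 7.0
        conc = ConcentrationField(grid=grid_small, times=times, values=vals)
        s = sample_model(conc, grid_small.lon_centers[3], grid_small.lat_centers[2])
        assert np.allclose(s, 7.0)

    def test_linear_in_field(self, grid_small):
        rng = np.random.default_rng(0)
        times = pd.date_range("2000-04-01", periods=4)
        a = rng.random((4, *grid_small.shape))
        b = rng.random((4, *grid_small.shape))
        ca = ConcentrationField(grid=grid_small, times=times, values=a)
        cb = ConcentrationField(grid=grid_small, times=times, values=b)
        cab = ConcentrationField(grid=grid_small, times=times, values=a + 2 * b)
        s = sample_model(cab, 4.2, 51.3)
        assert np.allclose(
            s, sample_model(ca, 4.2, 51.3) + 2 * sample_model(cb, 4.2, 51.3)
        )

    def test_outside_grid_rejected(self, grid_small):
        times = pd.date_range("2000-04-01", periods=2)
        conc = ConcentrationField(
            grid=grid_small, times=times, values=np.ones((2, *grid_small.shape))
        )
        with pytest.raises(ValueError):
            sample_model(conc, 100.0, 50.0)
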