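"""Period rasters, point extraction and window climate covariates."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from climdebt import make_periods, window_temp_trend
from climdebt.climate import (build_period_rasters, extract_temperature,
                              window_climate)
from climdebt.periods import median_years

PERIODS = make_periods()


def monthly_cube(values, lon=None, lat=None):
    """(year, month, lat, lon) DataArray from a broadcastable array."""
    years = np.arange(1990, 2020)
    months = np.arange(1, 13)
    lon = np.array([0.25, 0.75]) if lon is None else lon
    lat = np.array([40.25, 40.75]) if lat is None else lat
    data = np.broadcast_to(values, (years.size, months.size, lat.size, lon.size))
    return xr.DataArray(data.copy(), coords={"year": years, "month": months,
                                             "lat": lat, "lon": lon},
                        dims=("year", "month", "lat", "lon"))


class TestPeriodRasters:
    def test_constant_field(self):
        cube = monthly_cube(5.0)
        out = build_period_rasters(cube, range(1, 13), PERIODS)
        assert np.allclose(out.values, 5.0)

    def test_month_index_mean_march_september(self):
        cube = monthly_cube(np.arange(1, 13, dtype=float)[None, :, None, None])
        out = build_period_rasters(cube, range(3, 10), PERIODS)
        assert np.allclose(out.values, 6.0)  # mean(3..9)

    def test_linear_warming_consecutive_period_steps(self):
        w = 0.03
        years = np.arange(1990, 2020, dtype=float)
        cube = monthly_cube((w * (years - 1990))[:, None, None, None])
        out = build_period_rasters(cube, range(1, 13), PERIODS)
        steps = np.diff(out.mean(("lat", "lon")).values)
        assert np.allclose(steps, 5 * w, atol=1e-12)

    def test_missing_months_rejected(self):
        cube = monthly_cube(1.0).sel(month=slice(1, 6))
        with pytest.raises(ValueError):
            build_period_rasters(cube, range(1, 13), PERIODS)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        cube = monthly_cube(rng.normal(size=(30, 12, 2, 2)))
        a, c = 2.5, -3.0
        left = build_period_rasters(a * cube + c, range(1, 13), PERIODS)
        right = a * build_period_rasters(cube, range(1, 13), PERIODS) + c
        assert np.allclose(left.values, right.values, atol=1e-12)

    def test_winter_pairs_december_with_following_january(self):
        # December value = year + 0.5, January value = year
        years = np.arange(1990, 2020, dtype=float)
        cube = monthly_cube(0.0)
        cube.loc[{"month": 12}] = years[:, None, None]
        cube.loc[{"month": 12}] += 0.5
        cube.loc[{"month": 1}] = years[:, None, None]
        out = build_period_rasters(cube, {12, 1}, PERIODS, winter=True)
        # period 0: Jan 1990..1994 (1990..1994) + Dec 1990..1993 (1990.5..1993.5)
        expected0 = np.mean([1990, 1991, 1992, 1993, 1994,
                             1990.5, 1991.5, 1992.5, 1993.5])
        assert out.sel(period=0).values == pytest.approx(expected0)
        # period 1: Jan 1995..1999 + Dec 1994..1998
        expected1 = np.mean([1995, 1996, 1997, 1998, 1999,
                             1994.5, 1995.5, 1996.5, 1997.5, 1998.5])
        assert out.sel(period=1).values == pytest.approx(expected1)


def period_rasters_by_index():
    """Period rasters whose value equals 10 + period index, on a 2x2 grid."""
    cube = monthly_cube(0.0)
    for p in PERIODS:
        cube.loc[{"year": slice(p.start_year, p.end_year)}] = 10.0 + p.index
    return build_period_rasters(cube, range(1, 13), PERIODS)


class TestExtraction:
    def test_reads_value_of_record_period_raster(self):
        ras = period_rasters_by_index()
        rec = pd.DataFrame({"decimalLongitude": [0.3], "decimalLatitude": [40.6],
                            "year": [1996], "period_index": [1]})
        out = extract_temperature(rec, ras)
        assert out.iloc[0] == pytest.approx(11.0)  # 1995-1999 raster, not yearly

    def test_cell_mean_returned(self):
        ras = period_rasters_by_index() * 0 + 9.5
        rec = pd.DataFrame({"decimalLongitude": [0.7], "decimalLatitude": [40.2],
                            "period_index": [3]})
        assert extract_temperature(rec, ras).iloc[0] == pytest.approx(9.5)

    def test_off_grid_and_ocean_missing(self):
        ras = period_rasters_by_index()
        land = xr.DataArray(np.array([[True, False], [True, True]]),
                            coords={"lat": ras.lat, "lon": ras.lon},
                            dims=("lat", "lon"))
        rec = pd.DataFrame({
            "decimalLongitude": [5.0, 0.7], "decimalLatitude": [40.2, 40.2],
            "period_index": [0, 0]})
        out = extract_temperature(rec, ras, land=land)
        assert out.isna().all()  # outside extent; ocean cell

    def test_agrees_with_brute_force_nearest_cell(self):
        rng = np.random.default_rng(5)
        lon = np.arange(40) * 0.5 + 0.25
        lat = np.arange(30) * 0.5 + 30.25
        cube = monthly_cube(rng.normal(size=(30, 12, 30, 40)), lon=lon, lat=lat)
        ras = build_period_rasters(cube, range(1, 13), PERIODS)
        pts = pd.DataFrame({
            "decimalLongitude": rng.uniform(0, 20, 1000),
            "decimalLatitude": rng.uniform(30, 45, 1000),
            "period_index": rng.integers(0, 6, 1000)})
        fast = extract_temperature(pts, ras)
        data = ras.transpose("period", "lat", "lon").values
        for i in range(0, 1000, 37):
            r = pts.iloc[i]
            j = np.argmin(np.abs(lat - r["decimalLatitude"]))
            k = np.argmin(np.abs(lon - r["decimalLongitude"]))
            assert fast.iloc[i] == pytest.approx(
                data[int(r["period_index"]), j, k], abs=1e-12)


class TestWindowClimate:
    def test_uniform_fields(self):
        ras = period_rasters_by_index() * 0 + 12.0
        hii = xr.DataArray(np.full((2, 2), 20.0),
                           coords={"lat": ras.lat, "lon": ras.lon},
                           dims=("lat", "lon"))
        win = pd.DataFrame({"window_id": [0], "lon": [0.5], "lat": [40.5]})
        wc = window_climate(win, ras, hii, PERIODS)
        assert wc["mean_temp"].iloc[0] == pytest.approx(12.0)
        assert wc["hii"].iloc[0] == pytest.approx(20.0)
        assert wc["temp_trend"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_equal_count_mixture(self):
        ras = period_rasters_by_index() * 0
        ras.loc[{"lat": ras.lat[0]}] = 10.0
        ras.loc[{"lat": ras.lat[1]}] = 14.0
        hii = xr.DataArray(np.zeros((2, 2)), coords={"lat": ras.lat, "lon": ras.lon},
                           dims=("lat", "lon"))
        win = pd.DataFrame({"window_id": [0], "lon": [0.5], "lat": [40.5]})
        wc = window_climate(win, ras, hii, PERIODS)
        assert wc["mean_temp"].iloc[0] == pytest.approx(12.0)

    def test_no_land_flagged_unusable(self):
        ras = period_rasters_by_index()
        land = xr.DataArray(np.zeros((2, 2), bool),
                            coords={"lat": ras.lat, "lon": ras.lon},
                            dims=("lat", "lon"))
        hii = land.astype(float)
        win = pd.DataFrame({"window_id": [0], "lon": [0.5], "lat": [40.5]})
        wc = window_climate(win, ras, hii, PERIODS, land=land)
        assert not wc["usable"].iloc[0]


class TestTemperatureTrend:
    def test_exact_line(self):
        means = [10.0, 10.1, 10.2, 10.3, 10.4, 10.5]
        assert window_temp_trend(means, median_years(PERIODS)) == \
            pytest.approx(0.02, abs=1e-12)

    def test_constant_is_zero(self):
        assert window_temp_trend([7.0] * 6, median_years(PERIODS)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_two_point_slope(self):
        assert window_temp_trend([10.0, 10.5], [1992.0, 1997.0]) == \
            pytest.approx(0.1, abs=1e-12)

    def test_single_period_undefined(self):
        out = window_temp_trend([10.0, np.nan, np.nan, np.nan, np.nan, np.nan],
                                median_years(PERIODS))
        assert np.isnan(out)

    def test_synthetic_world_trend_equals_warming_rate(self, tiny_world):
        cfg, land, _, _ = tiny_world
        from climdebt import build_windows
        ras = build_period_rasters(land.temp, range(1, 13), cfg.periods)
        wins = build_windows(land.continent, land.region, land.land)
        wc = window_climate(wins, ras, land.hii, cfg.periods, land=land.land)
        assert np.allclose(wc["temp_trend"], cfg.warming_rate, atol=1e-9)


class TestUnitsAndWeighting:
    def test_kelvin_converted_celsius_untouched(self):
        from climdebt.climate import ensure_celsius
        cube = monthly_cube(288.15)
        assert np.allclose(ensure_celsius(cube).values, 15.0)
        cube_c = monthly_cube(15.0)
        assert np.allclose(ensure_celsius(cube_c).values, 15.0)

    def test_area_weighting_tilts_toward_low_latitude(self):
        ras = period_rasters_by_index() * 0
        ras.loc[{"lat": ras.lat[0]}] = 10.0   # southern row, larger cos weight
        ras.loc[{"lat": ras.lat[1]}] = 14.0
        hii = xr.DataArray(np.zeros((2, 2)), coords={"lat": ras.lat, "lon": ras.lon},
                           dims=("lat", "lon"))
        win = pd.DataFrame({"window_id": [0], "lon": [0.5], "lat": [40.5]})
        flat = window_climate(win, ras, hii, PERIODS)
        weighted = window_climate(win, ras, hii, PERIODS, area_weighted=True)
        assert flat["mean_temp"].iloc[0] == pytest.approx(12.0)
        assert weighted["mean_temp"].iloc[0] < 12.0
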