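"""Sliding windows, occurrence assignment, STI and CTI."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from climdebt import (assign_occurrences, build_assemblages, build_windows,
                      compute_cti, compute_sti)
from climdebt.geo import EARTH_RADIUS_KM, haversine_km


def flat_maps(nlon=10, nlat=10, lon0=0.0, lat0=40.0, land=None):
    lon = lon0 + np.arange(nlon) + 0.5
    lat = lat0 + np.arange(nlat) + 0.5
    coords = {"lat": lat, "lon": lon}
    if land is None:
        land = np.ones((nlat, nlon), bool)
    land_da = xr.DataArray(land, coords=coords, dims=("lat", "lon"))
    cont = xr.DataArray(np.where(np.arange(nlon) < nlon // 2, "west", "east")
                        [None, :].repeat(nlat, 0), coords=coords,
                        dims=("lat", "lon"))
    reg = xr.DataArray((np.arange(nlat)[:, None] // 5).repeat(nlon, 1),
                       coords=coords, dims=("lat", "lon"))
    return cont, reg, land_da


def lat_offset_km(km):
    """Degrees of latitude subtending a given meridian arc."""
    return np.degrees(km / EARTH_RADIUS_KM)


class TestBuildWindows:
    def test_full_land_lattice_count(self):
        cont, reg, land = flat_maps()
        wins = build_windows(cont, reg, land)
        assert len(wins) == 100  # 10 x 10 degree extent, 1-degree lattice

    def test_ecoregion_is_largest_in_buffer(self):
        cont, reg, land = flat_maps()
        wins = build_windows(cont, reg, land).set_index("window_id")
        # a centroid at lat 44.5 sees rows 40.5..48.5-ish; region 0 covers
        # five rows below 45, region 1 four above -> region 0 wins
        mid = wins[(wins["lat"] == 44.5) & (wins["lon"] == 4.5)]
        assert mid["ecoregion"].iloc[0] == 0

    def test_all_sea_windows_dropped(self):
        land = np.ones((10, 10), bool)
        land[:, 5:] = False  # eastern half is sea
        cont, reg, land_da = flat_maps(land=land)
        wins = build_windows(cont, reg, land_da)
        # windows further than 200 km east of the last land column vanish
        assert wins["lon"].max() < 5.5 + lat_offset_km(200.0) + 1e-9
        assert len(wins) < 100

    def test_extent_restriction_monotone(self):
        cont, reg, land = flat_maps()
        full = build_windows(cont, reg, land)
        sub = build_windows(cont, reg, land, lat_range=(42.0, 47.0))
        assert set(map(tuple, sub[["lon", "lat"]].values)) <= \
            set(map(tuple, full[["lon", "lat"]].values))


class TestAssignOccurrences:
    def windows(self):
        return pd.DataFrame({"window_id": [0, 1], "lon": [5.5, 6.5],
                             "lat": [44.5, 44.5]})

    def records(self, lons, lats):
        return pd.DataFrame({"species": "s", "decimalLongitude": lons,
                             "decimalLatitude": lats})

    def test_record_at_centroid_is_member(self):
        m = assign_occurrences(self.records([5.5], [44.5]), self.windows())
        assert (0, 0) in set(map(tuple, m[["window_id", "record"]].values))

    def test_radius_rule_199_in_201_out(self):
        lat_in = 44.5 + lat_offset_km(199.0)
        lat_out = 44.5 + lat_offset_km(201.0)
        m = assign_occurrences(self.records([5.5, 5.5], [lat_in, lat_out]),
                               self.windows())
        members = set(map(tuple, m[["window_id", "record"]].values))
        assert (0, 0) in members and (0, 1) not in members

    def test_overlapping_windows_share_records(self):
        # a point ~78 km from both centroids (1 degree apart at lat 44.5)
        m = assign_occurrences(self.records([6.0], [44.5]), self.windows())
        assert set(m["window_id"]) == {0, 1}

    def test_membership_matches_haversine(self, tiny_world):
        cfg, land, _, records = tiny_world
        cont, reg = land.continent, land.region
        wins = build_windows(cont, reg, land.land).iloc[:5]
        m = assign_occurrences(records, wins)
        got = set(map(tuple, m[["window_id", "record"]].values))
        for _, w in wins.iterrows():
            d = haversine_km(records["decimalLongitude"], records["decimalLatitude"],
                             w["lon"], w["lat"])
            expect = set((int(w["window_id"]), int(i))
                         for i in records.index[d <= 200.0])
            assert {t for t in got if t[0] == w["window_id"]} == expect


class TestSti:
    def test_mean_of_extracted_temperatures(self):
        rec = pd.DataFrame({"species": ["a"] * 3 + ["b"]})
        temps = pd.Series([8.0, 10.0, 12.0, 7.3])
        sti = compute_sti(rec, temps).set_index("species")
        assert sti.loc["a", "sti"] == pytest.approx(10.0)
        assert sti.loc["a", "n_records"] == 3
        assert sti.loc["b", "sti"] == pytest.approx(7.3)

    def test_species_without_extractable_temps_dropped(self):
        rec = pd.DataFrame({"species": ["a", "b"]})
        temps = pd.Series([9.0, np.nan])
        sti = compute_sti(rec, temps)
        assert sti["species"].tolist() == ["a"]
        assert sti.attrs["species_dropped"] == ["b"]


def assemblage_rows(window_id, period, species, n=1):
    return [{"window_id": window_id, "period_index": period, "species": s,
             "n": n} for s in species]


class TestCti:
    def sti_table(self, mapping):
        return pd.DataFrame({"species": list(mapping), "sti": list(mapping.values()),
                             "n_records": 1})

    def test_unweighted_mean_of_distinct_species(self):
        asm = pd.DataFrame(assemblage_rows(0, 0, ["a", "b", "c"]))
        out = compute_cti(asm, self.sti_table({"a": 10.0, "b": 12.0, "c": 14.0}))
        assert out["cti"].iloc[0] == pytest.approx(12.0)
        assert out["weight"].iloc[0] == pytest.approx(np.log(3))

    def test_single_species_yields_nothing(self):
        asm = pd.DataFrame(assemblage_rows(0, 0, ["a"]))
        out = compute_cti(asm, self.sti_table({"a": 10.0}))
        assert out.empty

    def test_duplicate_occurrences_change_weight_not_cti(self):
        asm1 = pd.DataFrame(assemblage_rows(0, 0, ["a", "b"], n=1))
        asm2 = pd.DataFrame(assemblage_rows(0, 0, ["a", "b"], n=5))
        sti = self.sti_table({"a": 10.0, "b": 14.0})
        out1, out2 = compute_cti(asm1, sti), compute_cti(asm2, sti)
        assert out1["cti"].iloc[0] == out2["cti"].iloc[0] == pytest.approx(12.0)
        assert out2["n_occ"].iloc[0] == 10 and out1["n_occ"].iloc[0] == 2

    def test_matches_brute_force_on_random_assemblages(self):
        # independent oracle: python-level mean over the distinct-species list
        rng = np.random.default_rng(12)
        species = [f"s{i}" for i in range(200)]
        sti_map = dict(zip(species, rng.normal(12, 3, 200)))
        rows = []
        for w in range(1000):
            k = rng.integers(2, 30)
            rows += assemblage_rows(w, 0, rng.choice(species, k, replace=False))
        out = compute_cti(pd.DataFrame(rows), self.sti_table(sti_map))
        asm = pd.DataFrame(rows)
        for _, r in out.iloc[::97].iterrows():
            present = asm[(asm["window_id"] == r["window_id"])]["species"]
            brute = sum(sti_map[s] for s in present) / len(present)
            assert abs(r["cti"] - brute) < 1e-12

    def test_cti_bounded_by_sti_range(self, pipeline_result):
        res = pipeline_result
        sti = res.sti.set_index("species")["sti"]
        merged = res.assemblages.merge(res.sti[["species", "sti"]], on="species")
        grp = merged.groupby(["window_id", "period_index"])["sti"]
        bounds = grp.agg(["min", "max"])
        joined = res.cti.set_index(["window_id", "period_index"]).join(bounds)
        assert (joined["cti"] >= joined["min"] - 1e-12).all()
        assert (joined["cti"] <= joined["max"] + 1e-12).all()


class TestRecovery:
    def test_sti_recovers_true_sti_for_most_species(self, recovery_result):
        from climdebt.synthetic import true_sti
        res = recovery_result
        truth = true_sti(res.landscape, res.pool)
        m = res.sti.set_index("species").join(truth).dropna()
        frac = (np.abs(m["sti"] - m["true_sti"]) < 0.5).mean()
        assert frac >= 0.9

    def test_window_cti_slope_tracks_warming(self, recovery_result):
        # lambda = 1: per-window OLS CTI slopes regress ~1:1 on temp trends
        from climdebt.periods import median_years
        res = recovery_result
        yrs = median_years(res.config.periods)
        piv = res.cti.pivot(index="window_id", columns="period_index",
                            values="cti")
        piv = piv[piv.notna().sum(axis=1) == 6]
        slopes = np.array([np.polyfit(yrs, row, 1)[0] for row in piv.to_numpy()])
        bt = (res.window_climate.set_index("window_id")["temp_trend"]
              .reindex(piv.index).to_numpy())
        coef = np.polyfit(bt, slopes, 1)[0]
        assert coef == pytest.approx(1.0, abs=0.15)


class TestMinSpeciesScope:
    def test_window_scope_keeps_single_species_periods(self):
        rows = (assemblage_rows(0, 0, ["a", "b"]) + assemblage_rows(0, 1, ["a"])
                + assemblage_rows(1, 0, ["a"]))
        sti = pd.DataFrame({"species": ["a", "b"], "sti": [10.0, 14.0],
                            "n_records": 1})
        per = compute_cti(pd.DataFrame(rows), sti, min_species_scope="period")
        win = compute_cti(pd.DataFrame(rows), sti, min_species_scope="window")
        # period scope: only (0, 0) qualifies; window scope: window 0 as a
        # whole holds two species, so its one-species period keeps a CTI,
        # while window 1 (one species ever) stays excluded
        assert set(map(tuple, per[["window_id", "period_index"]].values)) == {(0, 0)}
        assert set(map(tuple, win[["window_id", "period_index"]].values)) == \
            {(0, 0), (0, 1)}

    def test_unknown_scope_rejected(self):
        sti = pd.DataFrame({"species": ["a"], "sti": [1.0], "n_records": 1})
        with pytest.raises(ValueError):
            compute_cti(pd.DataFrame(assemblage_rows(0, 0, ["a"])), sti,
                        min_species_scope="banana")
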