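"""Period-mean temperature rasters, point extraction and window climate.

Seasonal per-period rasters are arithmetic means over (years in period) x
(months in the taxon's seasonal set).  Occurrence temperatures are read from
the raster of the record's 5-year period, not from yearly fields.  Window
covariates (mean temperature, HII, temperature trend) are unweighted means
over climate cells whose centers fall within the 200-km geodesic radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .geo import haversine_km
from .periods import PeriodDef, median_years


def ensure_celsius(temp: xr.DataArray) -> xr.DataArray:
    """Convert a temperature field to deg C if it arrives in Kelvin.

    Detection is by magnitude (land temperatures in K are ~200-330); applied
    at read time so everything downstream is in deg C.
    """
    if float(temp.mean()) > 150.0:
        return temp - 273.15
    return temp


def build_period_rasters(monthly: xr.DataArray, months, periods: list[PeriodDef],
                         winter: bool = False) -> xr.DataArray:
    """Mean temperature per period over the given month set.

    ``monthly`` has dims (year, month, lat, lon).  With ``winter=True`` the
    month set must be {12, 1} and each period averages the Dec-Jan pairs
    whose January falls inside the period (a December belongs to the
    following January's winter); the December before the first covered year
    is unavailable and simply not part of the mean.
    """
    months = sorted(set(int(m) for m in months))
    avail = set(int(m) for m in monthly.month.values)
    if not set(months) <= avail:
        raise ValueError(f"month set {months} not within available months")

    out = []
    for p in periods:
        if winter:
            if set(months) != {1, 12}:
                raise ValueError("winter convention requires the {12, 1} month set")
            pieces = []
            for jan_year in range(p.start_year, p.end_year + 1):
                if jan_year in monthly.year.values:
                    pieces.append(monthly.sel(year=jan_year, month=1))
                if jan_year - 1 in monthly.year.values:
                    pieces.append(monthly.sel(year=jan_year - 1, month=12))
            out.append(xr.concat(pieces, dim="sample").mean("sample"))
        else:
            sel = monthly.sel(year=slice(p.start_year, p.end_year), month=months)
            out.append(sel.mean(("year", "month")))
    return xr.concat(out, dim=pd.Index([p.index for p in periods], name="period"))


def _grid_index(coord: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Index of the grid cell containing each value; -1 outside the extent."""
    res = coord[1] - coord[0]
    idx = np.floor((values - (coord[0] - res / 2.0)) / res).astype(int)
    idx[(idx < 0) | (idx >= coord.size)] = -1
    return idx


def extract_temperature(records: pd.DataFrame, period_rasters: xr.DataArray,
                        land: xr.DataArray | None = None) -> pd.Series:
    """Temperature at each record's cell from its period's raster.

    NaN where the record falls outside the raster extent or on a cell with
    no value (e.g. ocean, if a land mask is given); such records are meant
    to be excluded from STI computation by the caller.
    """
    lon = records["decimalLongitude"].to_numpy(float)
    lat = records["decimalLatitude"].to_numpy(float)
    per = records["period_index"].to_numpy(int)
    ilon = _grid_index(period_rasters.lon.values, lon)
    ilat = _grid_index(period_rasters.lat.values, lat)
    iper = period_rasters.get_index("period").get_indexer(per)

    vals = np.full(len(records), np.nan)
    ok = (ilon >= 0) & (ilat >= 0) & (iper >= 0)
    data = period_rasters.transpose("period", "lat", "lon").values
    vals[ok] = data[iper[ok], ilat[ok], ilon[ok]]
    if land is not None:
        on_land = np.zeros(len(records), dtype=bool)
        on_land[ok] = land.values[ilat[ok], ilon[ok]]
        vals[~on_land] = np.nan
    return pd.Series(vals, index=records.index, name="temp_C")


def land_lookup_from_raster(land: xr.DataArray):
    """Callable (lon, lat) -> bool for use by coordinate cleaning."""
    def lookup(lon, lat):
        ilon = _grid_index(land.lon.values, np.asarray(lon, float))
        ilat = _grid_index(land.lat.values, np.asarray(lat, float))
        ok = (ilon >= 0) & (ilat >= 0)
        out = np.zeros(np.shape(lon), dtype=bool)
        out[ok] = land.values[ilat[ok], ilon[ok]]
        return out
    return lookup


def window_climate(windows: pd.DataFrame, period_rasters: xr.DataArray,
                   hii: xr.DataArray, periods: list[PeriodDef],
                   land: xr.DataArray | None = None,
                   radius_km: float = 200.0,
                   area_weighted: bool = False) -> pd.DataFrame:
    """Per-window climate covariates and temperature trend.

    Columns: one ``T_p{i}`` per period, ``mean_temp`` (mean of period means),
    ``hii`` and ``temp_trend`` (OLS slope of period means on median years,
    NaN when fewer than two period means exist).  Means are over land cells
    only when a land mask is given; ``area_weighted`` weights cells by
    cos(latitude) instead of the default unweighted mean.
    """
    lon2, lat2 = np.meshgrid(period_rasters.lon.values, period_rasters.lat.values)
    data = period_rasters.transpose("period", "lat", "lon").values
    if land is not None:
        data = np.where(land.values[None, :, :], data, np.nan)
        hvals = np.where(land.values, hii.values, np.nan)
    else:
        hvals = hii.values
    years = median_years(periods)
    cellw = np.cos(np.radians(lat2)) if area_weighted else np.ones_like(lat2)

    def wmean(values, mask):
        v, cw = values[mask], cellw[mask]
        ok = np.isfinite(v)
        return (v[ok] @ cw[ok]) / cw[ok].sum() if ok.any() else np.nan

    rows = []
    for _, w in windows.iterrows():
        inside = haversine_km(w["lon"], w["lat"], lon2, lat2) <= radius_km
        if not inside.any():
            rows.append({"window_id": w["window_id"], "usable": False})
            continue
        tbar = np.array([wmean(data[j], inside) for j in range(len(periods))])
        row = {"window_id": w["window_id"], "usable": np.isfinite(tbar).any()}
        for j, p in enumerate(periods):
            row[f"T_p{p.index}"] = tbar[j]
        row["mean_temp"] = np.nanmean(tbar) if np.isfinite(tbar).any() else np.nan
        row["hii"] = wmean(hvals, inside)
        row["temp_trend"] = window_temp_trend(tbar, years)
        rows.append(row)
    return pd.DataFrame(rows)


def window_temp_trend(period_means, years) -> float:
    """OLS slope of period mean temperatures on period median years.

    NaN (trend undefined) with fewer than two finite period means.
    """
    period_means = np.asarray(period_means, float)
    years = np.asarray(years, float)
    ok = np.isfinite(period_means)
    if ok.sum() < 2:
        return np.nan
    x, y = years[ok], period_means[ok]
    xc = x - x.mean()
    return float((xc @ (y - y.mean())) / (xc @ xc))
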