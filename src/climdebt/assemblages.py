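"""Sliding-window assemblages, species and community temperature indices.

Windows are 200-km-radius buffers around the centroids of a 1-degree lattice;
adjacent windows overlap by construction, so one record typically belongs to
several windows.  The species temperature index (STI) is the mean extracted
temperature over all of a species' cleaned, thinned records, pooled across
continents and periods.  The community temperature index (CTI) of a window x
period is the unweighted mean STI of the distinct species present (presence-
only; no abundance weighting), defined only where at least two species with
an STI are present.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from scipy.spatial import cKDTree

from .geo import chord_length, haversine_km, sphere_xyz


def build_windows(continent: xr.DataArray, region: xr.DataArray,
                  land: xr.DataArray, step: float = 1.0,
                  radius_km: float = 200.0,
                  lat_range: tuple | None = None,
                  lon_range: tuple | None = None) -> pd.DataFrame:
    """Window registry on a ``step``-degree lattice over the study extent.

    The study extent defaults to the full map extent; passing ``lat_range``
    / ``lon_range`` restricts the lattice (e.g. to an interior band of a
    buffered synthetic landscape).  A lattice centroid yields a window when
    at least one land cell center lies within the radius.  Continent is the
    map label at the centroid; ecoregion is the region label with the
    largest land-cell count inside the buffer.
    """
    lon_c, lat_c = land.lon.values, land.lat.values
    res = lon_c[1] - lon_c[0]
    lon0, lat0 = lon_c[0] - res / 2.0, lat_c[0] - res / 2.0
    lon1, lat1 = lon_c[-1] + res / 2.0, lat_c[-1] + res / 2.0
    if lon_range is not None:
        lon0, lon1 = max(lon0, lon_range[0]), min(lon1, lon_range[1])
    if lat_range is not None:
        lat0, lat1 = max(lat0, lat_range[0]), min(lat1, lat_range[1])
    cx = np.arange(np.floor(lon0 / step) * step + step / 2.0, lon1, step)
    cy = np.arange(np.floor(lat0 / step) * step + step / 2.0, lat1, step)
    cx = cx[cx >= lon0]
    cy = cy[cy >= lat0]

    lon2, lat2 = np.meshgrid(lon_c, lat_c)
    land_m = land.values.astype(bool)
    rows = []
    wid = 0
    for y in cy:
        for x in cx:
            inside = haversine_km(x, y, lon2, lat2) <= radius_km
            land_in = inside & land_m
            if not land_in.any():
                continue
            regs, counts = np.unique(region.values[land_in], return_counts=True)
            ilat = int(np.clip(np.searchsorted(lat_c, y), 0, lat_c.size - 1))
            ilon = int(np.clip(np.searchsorted(lon_c, x), 0, lon_c.size - 1))
            rows.append({"window_id": wid, "lon": x, "lat": y,
                         "continent": str(continent.values[ilat, ilon]),
                         "ecoregion": regs[np.argmax(counts)]})
            wid += 1
    return pd.DataFrame(rows)


def assign_occurrences(records: pd.DataFrame, windows: pd.DataFrame,
                       radius_km: float = 200.0) -> pd.DataFrame:
    """Window membership table (window_id, record) -- overlapping by design.

    Membership: record within ``radius_km`` great-circle distance of the
    window centroid.  Uses a KD-tree on unit-sphere coordinates with the
    equivalent chord radius, which is exact for great-circle distance.
    """
    if records.empty or windows.empty:
        return pd.DataFrame({"window_id": [], "record": []}, dtype=int)
    tree = cKDTree(sphere_xyz(records["decimalLongitude"].to_numpy(float),
                              records["decimalLatitude"].to_numpy(float)))
    centers = sphere_xyz(windows["lon"].to_numpy(), windows["lat"].to_numpy())
    hits = tree.query_ball_point(centers, r=chord_length(radius_km))
    wid = np.repeat(windows["window_id"].to_numpy(), [len(h) for h in hits])
    rec = records.index.to_numpy()[np.concatenate([np.asarray(h, int) for h in hits])
                                   if len(hits) else np.array([], int)]
    return pd.DataFrame({"window_id": wid, "record": rec})


def compute_sti(records: pd.DataFrame, temps: pd.Series) -> pd.DataFrame:
    """STI per species: mean extracted temperature over all usable records.

    Records whose extraction is missing are excluded; species with no usable
    record are dropped (their count appears in the returned frame's attrs).
    """
    df = pd.DataFrame({"species": records["species"], "temp": temps})
    ok = df["temp"].notna()
    sti = (df.loc[ok].groupby("species")["temp"]
           .agg(sti="mean", n_records="size").reset_index())
    dropped = set(df.loc[~ok, "species"]) - set(sti["species"])
    sti.attrs["species_dropped"] = sorted(dropped)
    return sti


def build_assemblages(records: pd.DataFrame, members: pd.DataFrame) -> pd.DataFrame:
    """Distinct-species membership per window x period, with record counts.

    Long format: one row per (window_id, period_index, species) with the
    number of thinned records ``n`` behind it.
    """
    joined = members.merge(
        records[["species", "period_index"]], left_on="record", right_index=True)
    return (joined.groupby(["window_id", "period_index", "species"])
            .size().rename("n").reset_index())


def compute_cti(assemblages: pd.DataFrame, sti: pd.DataFrame,
                min_species: int = 2,
                min_species_scope: str = "period") -> pd.DataFrame:
    """CTI records: one row per qualifying window x period.

    CTI is the unweighted mean STI over the distinct species present that
    have an STI.  With ``min_species_scope="period"`` (default) a window x
    period qualifies when it holds at least ``min_species`` such species;
    with ``"window"`` the window qualifies as a whole when its pooled
    species set reaches the threshold, and all its periods with at least
    one STI-carrying species get a CTI.  ``n_occ`` counts all thinned
    occurrences in the window x period (model weight = ln n_occ).
    """
    merged = assemblages.merge(sti[["species", "sti"]], on="species", how="left")
    grp = merged.groupby(["window_id", "period_index"])
    out = grp.agg(
        cti=("sti", "mean"),
        n_species=("sti", lambda s: s.notna().sum()),
        n_occ=("n", "sum"),
    ).reset_index()
    if min_species_scope == "period":
        out = out[out["n_species"] >= min_species]
    elif min_species_scope == "window":
        pooled = (merged.dropna(subset=["sti"])
                  .groupby("window_id")["species"].nunique())
        keep = pooled[pooled >= min_species].index
        out = out[out["window_id"].isin(keep) & (out["n_species"] >= 1)]
    else:
        raise ValueError("min_species_scope must be 'period' or 'window'")
    out = out.reset_index(drop=True)
    out["weight"] = np.log(out["n_occ"].astype(float))
    return out
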