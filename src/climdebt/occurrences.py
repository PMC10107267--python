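"""Cleaning, filtering, period binning and spatial thinning of raw records.

Mirrors the standard hygiene applied to aggregated presence-only archives:
drop coordinate artefacts (zero / equal coordinates, capital and institution
centroids, ocean points), drop excluded species and out-of-season months,
bin records into 5-year periods, and keep a single record per species per
5-km equal-area cell per period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import equal_area_cell, haversine_km
from .periods import PeriodDef, period_of_year

#: canonical column order of a cleaned occurrence table
COLUMNS = ["species", "decimalLongitude", "decimalLatitude", "year", "month", "provider"]


@dataclass(frozen=True)
class TaxonProfile:
    """Taxon-level filtering rules.

    ``months`` is the seasonal month set (e.g. March-September for breeding
    season taxa, December-January for wintering birds, all twelve for the
    rest).  ``winter`` marks the Dec-Jan convention: December is grouped with
    the following January and the pair is binned into the period containing
    that January.
    """

    name: str
    months: frozenset[int] = frozenset(range(1, 13))
    excluded_species: frozenset[str] = frozenset()
    winter: bool = False

    def __post_init__(self):
        if not self.months:
            raise ValueError("seasonal month set must be non-empty")

    @property
    def all_months(self) -> bool:
        return self.months == frozenset(range(1, 13))


ALL_MONTHS = TaxonProfile("generic")
BREEDING = TaxonProfile("breeding", frozenset(range(3, 10)))
WINTER = TaxonProfile("winter", frozenset({12, 1}), winter=True)


def clean_coordinates(records: pd.DataFrame,
                      land_lookup=None,
                      bad_points: np.ndarray | None = None,
                      radius_km: float = 1.0):
    """Remove coordinate artefacts; return (survivors, per-rule counts).

    Rules (order-independent predicates):
      * ``zero_or_equal``: longitude == latitude exactly, or both exactly 0;
      * ``near_listed_point``: within ``radius_km`` of any listed capital /
        country centroid / institution point (``bad_points``: (n, 2) lon, lat);
      * ``non_land``: ``land_lookup(lon, lat)`` is False (ocean or off-grid).
    """
    if land_lookup is None:
        raise ValueError("a land mask lookup is required")
    lon = records["decimalLongitude"].to_numpy(float)
    lat = records["decimalLatitude"].to_numpy(float)

    bad_equal = (lon == lat) | ((lon == 0.0) & (lat == 0.0))
    bad_point = np.zeros(len(records), dtype=bool)
    if bad_points is not None and len(bad_points):
        pts = np.asarray(bad_points, dtype=float)
        for plon, plat in pts:
            bad_point |= haversine_km(lon, lat, plon, plat) <= radius_km
    on_land = np.asarray(land_lookup(lon, lat), dtype=bool)

    removed = {"zero_or_equal": int(bad_equal.sum()),
               "near_listed_point": int(bad_point.sum()),
               "non_land": int((~on_land).sum())}
    keep = ~(bad_equal | bad_point | ~on_land)
    return records.loc[keep].reset_index(drop=True), removed


def filter_taxa(records: pd.DataFrame, profile: TaxonProfile,
                year_min: int = 1990, year_max: int = 2019) -> pd.DataFrame:
    """Drop excluded species, out-of-season months and out-of-range years.

    Records with a missing month are kept for all-month profiles (season
    membership is then irrelevant) and dropped for seasonal profiles.
    """
    keep = ~records["species"].isin(profile.excluded_species)
    keep &= records["year"].between(year_min, year_max)
    if "month" in records.columns:
        month = records["month"]
        if profile.all_months:
            keep &= month.isna() | month.isin(list(profile.months))
        else:
            keep &= month.isin(list(profile.months))
    elif not profile.all_months:
        raise ValueError("seasonal profile requires a month column")
    return records.loc[keep].reset_index(drop=True)


def assign_periods(records: pd.DataFrame, periods: list[PeriodDef],
                   profile: TaxonProfile = ALL_MONTHS) -> pd.DataFrame:
    """Attach ``period_index``; one biological winter spans Dec(y)-Jan(y+1).

    For winter profiles, a December record is binned with the January it
    precedes (effective year = year + 1); Decembers whose following January
    falls outside the study span are dropped.
    """
    out = records.copy()
    eff_year = out["year"].to_numpy(int).copy()
    if profile.winter and "month" in out.columns:
        dec = out["month"].to_numpy() == 12
        eff_year[dec] += 1
        in_span = (eff_year >= periods[0].start_year) & (eff_year <= periods[-1].end_year)
        out = out.loc[in_span].reset_index(drop=True)
        eff_year = eff_year[in_span]
    out["period_index"] = period_of_year(eff_year, periods)
    return out


def spatial_thin(records: pd.DataFrame, cell_km: float = 5.0,
                 seed: int = 0) -> pd.DataFrame:
    """Keep one record per (species, equal-area cell, period), at random.

    Idempotent for a fixed seed: groups of size one are kept unchanged, so a
    second pass removes nothing.
    """
    if records.empty:
        return records.copy()
    ix, iy = equal_area_cell(records["decimalLongitude"].to_numpy(float),
                             records["decimalLatitude"].to_numpy(float), cell_km)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    shuffled = records.iloc[order].copy()
    shuffled["_cx"], shuffled["_cy"] = ix[order], iy[order]
    kept = shuffled.drop_duplicates(subset=["species", "_cx", "_cy", "period_index"],
                                    keep="first")
    return (kept.drop(columns=["_cx", "_cy"])
            .sort_index().reset_index(drop=True))


def summarize_data(records: pd.DataFrame,
                   window_members: pd.DataFrame | None = None,
                   top_n: int = 10):
    """Data-characteristic summaries: effort, coverage and provider mix.

    Returns (per-year occurrence counts, per-year window counts or None,
    provider proportions).  Provider proportions are computed over all
    records, missing entries labelled "unknown", truncated to the ``top_n``
    largest (so they sum to <= 1).
    """
    counts = (records.groupby("year").size()
              .rename("n_occurrences").reset_index())

    win_counts = None
    if window_members is not None:
        merged = window_members.merge(records[["year"]], left_on="record",
                                      right_index=True)
        win_counts = (merged.groupby("year")["window_id"].nunique()
                      .rename("n_windows").reset_index())

    prov = records.get("provider")
    if prov is None:
        prov = pd.Series(pd.NA, index=records.index)
    prov = prov.fillna("unknown").replace("", "unknown")
    prop = (prov.value_counts(normalize=True).head(top_n)
            .rename("proportion").rename_axis("provider").reset_index())
    return counts, win_counts, prop
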