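"""End-to-end driver: synthetic world -> cleaned records -> CTI -> models.

This is the path the analysis scripts, the acceptance checks and the
parameter-recovery tests all share.  Every stage is the public function of
its module; this file only wires them together and carries the intermediate
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assemblages as asm
from . import climate as clim
from . import occurrences as occ
from .synthetic import Landscape, WorldConfig, generate_world
from .trends import CtiTimeFit, DebtFit, fit_cti_time, fit_debt, marginal_slopes


@dataclass
class PipelineResult:
    config: WorldConfig
    landscape: Landscape
    pool: pd.DataFrame
    records: pd.DataFrame          # cleaned, period-binned, thinned
    removal_report: dict
    windows: pd.DataFrame
    window_climate: pd.DataFrame
    sti: pd.DataFrame
    assemblages: pd.DataFrame
    cti: pd.DataFrame
    cti_fit: CtiTimeFit | None = None
    debt: DebtFit | None = None
    meta: dict = field(default_factory=dict)


def prepare_records(landscape: Landscape, raw: pd.DataFrame,
                    profile: occ.TaxonProfile = occ.ALL_MONTHS,
                    thin_seed: int = 0):
    """Clean, filter, period-bin and thin a raw occurrence table."""
    cfg = landscape.config
    land_lookup = clim.land_lookup_from_raster(landscape.land)
    cleaned, removed = occ.clean_coordinates(raw, land_lookup=land_lookup)
    cleaned = occ.filter_taxa(cleaned, profile, cfg.year_start, cfg.year_end)
    cleaned = occ.assign_periods(cleaned, cfg.periods, profile)
    thinned = occ.spatial_thin(cleaned, seed=thin_seed)
    return thinned, removed


def run_pipeline(config: WorldConfig, fit_models: bool = True,
                 profile: occ.TaxonProfile = occ.ALL_MONTHS) -> PipelineResult:
    """Run the whole analysis on one synthetic world."""
    landscape, pool, raw = generate_world(config)
    records, removed = prepare_records(landscape, raw, profile,
                                       thin_seed=config.seed + 13)

    lat_range = None
    if config.window_lat_min is not None or config.window_lat_max is not None:
        lat_range = (config.window_lat_min if config.window_lat_min is not None
                     else config.lat_min,
                     config.window_lat_max if config.window_lat_max is not None
                     else config.lat_max)
    windows = asm.build_windows(landscape.continent, landscape.region,
                                landscape.land, lat_range=lat_range)
    rasters = clim.build_period_rasters(landscape.temp, sorted(profile.months),
                                        config.periods, winter=profile.winter)
    wclim = clim.window_climate(windows, rasters, landscape.hii, config.periods,
                                land=landscape.land)
    windows = windows[windows["window_id"].isin(
        wclim.loc[wclim["usable"], "window_id"])].reset_index(drop=True)

    temps = clim.extract_temperature(records, rasters, land=landscape.land)
    sti = asm.compute_sti(records, temps)
    members = asm.assign_occurrences(records, windows)
    assemblage = asm.build_assemblages(records, members)
    cti = asm.compute_cti(assemblage, sti)

    result = PipelineResult(config=config, landscape=landscape, pool=pool,
                            records=records, removal_report=removed,
                            windows=windows, window_climate=wclim, sti=sti,
                            assemblages=assemblage, cti=cti)
    if fit_models:
        result.cti_fit = fit_cti_time(cti, windows, wclim, config.periods)
        try:
            result.debt = fit_debt(result.cti_fit.local_trends, windows, wclim, cti)
            result.meta["marginal_slopes"] = marginal_slopes(result.debt)
        except ValueError as exc:
            # e.g. spatially constant warming -> temperature trend has no
            # variance and the debt model is unidentifiable
            result.meta["debt_skipped"] = str(exc)
    return result
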