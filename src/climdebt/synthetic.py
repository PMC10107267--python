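"""Synthetic occurrence/climate world with known ground truth.

The generator builds a gridded landscape whose monthly temperatures combine a
south-north baseline gradient, a seasonal cycle and a (possibly spatially
varying) linear warming trend; a pool of virtual species with Gaussian thermal
niches; and presence-only occurrence records sampled under exponentially
growing, spatially biased effort.

The climate-tracking mechanism is controlled by a single parameter, the
tracking fraction lambda: each species responds to a *perceived* temperature
field

    T_perceived(cell, t) = T(cell, t0) + lambda * (T(cell, t) - T(cell, t0)),

so lambda = 1 means ranges adjust instantly and completely to warming,
lambda = 0 means ranges never move, and intermediate values produce a
climatic debt whose expected debt-model slope is exactly lambda.  lambda can
optionally decrease with the human influence index (HII), emulating
anthropization slowing climate tracking.

Occupancy is simulated at the grid-cell level and realized with one
persistent uniform draw per (species, cell): a cell flips occupancy only when
its occupancy probability crosses that draw, which emulates site persistence
and avoids period-to-period white noise that a fresh Bernoulli draw per
period would inject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .periods import PeriodDef, make_periods


class ConfigurationError(ValueError):
    """Raised when a WorldConfig fails its invariants."""


@dataclass
class WorldConfig:
    """Parameters of the synthetic world.

    Geometry is two rectangular "continents" separated by an empty (sea)
    longitudinal band; regions are latitudinal bands within each continent.
    Temperatures are in deg C, rates in deg C / year.
    """

    # grid extent (cell edges) and resolution, decimal degrees
    lon_min: float = -20.0
    lon_max: float = 4.0
    lat_min: float = 20.0
    lat_max: float = 58.0
    resolution: float = 1.0

    # study extent for the window lattice: an interior latitudinal band, so
    # windows sit far (in niche widths) from the landscape's thermal edges
    # and boundary truncation of species pools cannot bias CTI trends
    window_lat_min: float | None = 33.0
    window_lat_max: float | None = 47.0

    year_start: int = 1990
    year_end: int = 2019

    # baseline field: temperature at lat_min, minus gradient * (lat - lat_min)
    base_temp: float = 30.0
    lat_gradient: float = 0.6      # deg C per degree latitude, south warm
    seasonal_amplitude: float = 8.0
    temp_noise_sd: float = 0.0     # iid monthly noise, deg C

    # warming rate: a constant, or (min, max) for spatially heterogeneous
    # rates.  "ramp" varies the rate linearly across longitude (smooth at
    # the window scale, so a window's mean trend is also what its species
    # experience); "blocks" draws a rate per warming_block_deg-degree block
    warming_rate: float | tuple[float, float] = 0.02
    warming_pattern: str = "ramp"
    warming_block_deg: float = 4.0

    # species pool
    n_species: int = 800
    niche_sd: float = 1.0          # deg C, Gaussian niche breadth
    optima_margin_sd: float = 3.0  # extend optima range this many sigma past
                                   # the landscape annual-temperature range
    p_max: float = 0.9             # occupancy probability at the optimum

    # climate tracking
    lam: float = 1.0               # tracking fraction in [0, 1]
    lam_hii_slope: float = 0.0     # lambda(cell) = clip(lam - slope*HII/64, 0, 1)

    # effort model: expected records in the first period, growth per period,
    # and strength of the sinusoidal spatial over/under-sampling pattern
    effort_first_period: float = 60000.0
    effort_growth: float = 1.5
    effort_bias_strength: float = 1.0

    # geography
    sea_band: tuple[float, float] = (-9.0, -7.0)   # lon range with no land
    regions_per_continent: int = 5                 # latitudinal bands

    # data providers; None stands for a missing provider entry
    provider_names: tuple = ("inat", "museum_a", "atlas_b", "soc_c", None)
    provider_probs: tuple = (0.3, 0.2, 0.15, 0.1, 0.25)

    seed: int = 0

    def __post_init__(self):
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be > 0")
        if not (0.0 <= self.lam <= 1.0):
            raise ConfigurationError("tracking fraction lam must be in [0, 1]")
        if self.effort_growth <= 0:
            raise ConfigurationError("effort growth factor must be > 0")
        if self.n_species < 2:
            raise ConfigurationError("need at least 2 species")
        if (self.lon_max - self.lon_min) < 2 * self.resolution or \
           (self.lat_max - self.lat_min) < 2 * self.resolution:
            raise ConfigurationError("extent must span >= 2 cells per axis")
        if abs(sum(self.provider_probs) - 1.0) > 1e-9:
            raise ConfigurationError("provider probabilities must sum to 1")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def periods(self) -> list[PeriodDef]:
        n = (self.year_end - self.year_start + 1) // 5
        return make_periods(self.year_start, n, 5)


@dataclass
class Landscape:
    """Gridded world: monthly temperature plus static covariate maps."""

    config: WorldConfig
    temp: xr.DataArray        # (year, month, lat, lon), deg C
    land: xr.DataArray        # bool
    continent: xr.DataArray   # "west" / "east" labels (defined for all cells)
    region: xr.DataArray      # int labels, >= 2 contiguous latitudinal bands
    hii: xr.DataArray         # human influence index, [0, 64]
    warming: xr.DataArray     # per-cell warming rate, deg C / yr
    lam_cell: xr.DataArray    # per-cell effective tracking fraction

    @property
    def lon(self) -> np.ndarray:
        return self.temp.lon.values

    @property
    def lat(self) -> np.ndarray:
        return self.temp.lat.values

    def annual_mean(self) -> xr.DataArray:
        """(year, lat, lon) mean over the 12 months."""
        return self.temp.mean("month")

    def period_annual_mean(self, period: PeriodDef) -> xr.DataArray:
        """(lat, lon) mean annual temperature over a period's years."""
        am = self.annual_mean()
        return am.sel(year=slice(period.start_year, period.end_year)).mean("year")

    def perceived_period_mean(self, period: PeriodDef) -> xr.DataArray:
        """Per-cell temperature each species perceives in a period.

        Anchored at the first year's annual mean; deviations from the anchor
        are scaled by the cell's tracking fraction.
        """
        anchor = self.annual_mean().sel(year=self.config.year_start)
        actual = self.period_annual_mean(period)
        return anchor + self.lam_cell * (actual - anchor)

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset({
            "temp": self.temp, "land": self.land, "continent": self.continent,
            "region": self.region, "hii": self.hii, "warming": self.warming,
            "lam_cell": self.lam_cell,
        })


def _cell_centers(lo: float, hi: float, res: float) -> np.ndarray:
    n = int(round((hi - lo) / res))
    return lo + res * (np.arange(n) + 0.5)


def generate_landscape(config: WorldConfig) -> Landscape:
    """Build the monthly temperature cube and static covariate maps.

    Per-cell monthly temperature:

        baseline(lat) + seasonal_amplitude * cos(2 pi (month - 7) / 12)
        + warming(lon) * (year - year_start) [+ noise]

    The cosine term sums to zero over the 12 months, so annual means reduce to
    baseline + trend exactly when noise is off.
    """
    cfg = config
    lon = _cell_centers(cfg.lon_min, cfg.lon_max, cfg.resolution)
    lat = _cell_centers(cfg.lat_min, cfg.lat_max, cfg.resolution)
    years = cfg.years
    months = np.arange(1, 13)

    baseline = cfg.base_temp - cfg.lat_gradient * (lat - cfg.lat_min)  # (lat,)
    seasonal = cfg.seasonal_amplitude * np.cos(2 * np.pi * (months - 7) / 12.0)

    if isinstance(cfg.warming_rate, tuple):
        w_lo, w_hi = cfg.warming_rate
        if cfg.warming_pattern == "blocks":
            rng_w = np.random.default_rng(cfg.seed + 211)
            bx = ((lon - cfg.lon_min) // cfg.warming_block_deg).astype(int)
            by = ((lat - cfg.lat_min) // cfg.warming_block_deg).astype(int)
            blocks = rng_w.uniform(w_lo, w_hi, (by.max() + 1, bx.max() + 1))
            warming = blocks[np.ix_(by, bx)]                       # (lat, lon)
        elif cfg.warming_pattern == "ramp":
            # the ramp restarts on each continent, so the warming gradient is
            # orthogonal to the continent contrast (both are functions of
            # longitude) and spans the full range within either continent
            sea_lo, sea_hi = cfg.sea_band
            frac = np.where(
                lon < 0.5 * (sea_lo + sea_hi),
                (lon - cfg.lon_min) / max(sea_lo - cfg.lon_min, 1e-9),
                (lon - sea_hi) / max(cfg.lon_max - sea_hi, 1e-9))
            frac = np.clip(frac, 0.0, 1.0)
            warming = np.broadcast_to(w_lo + (w_hi - w_lo) * frac,
                                      (lat.size, lon.size)).copy()
        else:
            raise ConfigurationError(
                f"unknown warming pattern {cfg.warming_pattern!r}")
    else:
        warming = np.full((lat.size, lon.size), float(cfg.warming_rate))

    t = (baseline[None, None, :, None]
         + seasonal[None, :, None, None]
         + warming[None, None, :, :] * (years - cfg.year_start)[:, None, None, None])
    t = np.broadcast_to(t, (years.size, months.size, lat.size, lon.size)).copy()
    if cfg.temp_noise_sd > 0:
        rng = np.random.default_rng(cfg.seed + 101)
        t += rng.normal(0.0, cfg.temp_noise_sd, t.shape)

    coords2 = {"lat": lat, "lon": lon}
    temp = xr.DataArray(t, coords={"year": years, "month": months, **coords2},
                        dims=("year", "month", "lat", "lon"), name="temp")

    sea_lo, sea_hi = cfg.sea_band
    land = xr.DataArray(~((lon >= sea_lo) & (lon < sea_hi))[None, :].repeat(lat.size, 0),
                        coords=coords2, dims=("lat", "lon"), name="land")

    mid = 0.5 * (sea_lo + sea_hi)
    continent = xr.DataArray(np.where(lon[None, :] < mid, "west", "east").repeat(lat.size, 0)
                             .reshape(lat.size, lon.size),
                             coords=coords2, dims=("lat", "lon"), name="continent")

    # latitudinal bands per continent -> >= 2 contiguous region labels
    nb = cfg.regions_per_continent
    band = np.clip(((lat - cfg.lat_min) / (cfg.lat_max - cfg.lat_min) * nb).astype(int),
                   0, nb - 1)
    region = band[:, None] + nb * (lon[None, :] >= mid).astype(int)
    region = xr.DataArray(region, coords=coords2, dims=("lat", "lon"), name="region")

    # smooth sinusoidal anthropization surface in [0, 64]: wavelengths of a
    # few window diameters give many independent high/low-influence patches
    # while remaining resolvable after 200-km window averaging, and the
    # pattern is uncorrelated with the linear lon (warming) and lat
    # (baseline temperature) gradients
    hii = 32.0 + 30.0 * np.sin(2 * np.pi * lon / 8.0)[None, :] * \
        np.cos(2 * np.pi * lat / 8.0)[:, None]
    hii = xr.DataArray(np.clip(hii, 0.0, 64.0), coords=coords2,
                       dims=("lat", "lon"), name="hii")

    warming_da = xr.DataArray(warming.copy(), coords=coords2,
                              dims=("lat", "lon"), name="warming")
    lam_cell = xr.DataArray(
        np.clip(cfg.lam - cfg.lam_hii_slope * hii.values / 64.0, 0.0, 1.0),
        coords=coords2, dims=("lat", "lon"), name="lam_cell")

    return Landscape(cfg, temp, land, continent, region, hii, warming_da, lam_cell)


def generate_species_pool(config: WorldConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw the species pool: uniform thermal optima, fixed niche breadth.

    Optima span the landscape's annual baseline temperature range extended by
    ``optima_margin_sd`` niche widths on each end, so assemblages near the
    thermal edges of the landscape still see an approximately symmetric pool.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    lat = _cell_centers(cfg.lat_min, cfg.lat_max, cfg.resolution)
    baseline = cfg.base_temp - cfg.lat_gradient * (lat - cfg.lat_min)
    margin = cfg.optima_margin_sd * cfg.niche_sd
    lo, hi = baseline.min() - margin, baseline.max() + margin
    mu = rng.uniform(lo, hi, cfg.n_species)
    continent = rng.choice(["west", "east"], cfg.n_species)
    return pd.DataFrame({
        "species": [f"sp{i:04d}" for i in range(cfg.n_species)],
        "mu": mu,
        "sigma": np.full(cfg.n_species, cfg.niche_sd),
        "continent": continent,
    })


def occupancy_probability(landscape: Landscape, pool: pd.DataFrame,
                          period: PeriodDef) -> np.ndarray:
    """(n_species, n_lat, n_lon) occupancy probability for one period.

    Gaussian in the difference between the cell's perceived temperature and
    the species optimum; zero off-land and off the species' home continent.
    """
    cfg = landscape.config
    tp = landscape.perceived_period_mean(period).values        # (lat, lon)
    mu = pool["mu"].values[:, None, None]
    sig = pool["sigma"].values[:, None, None]
    p = cfg.p_max * np.exp(-0.5 * ((tp[None, :, :] - mu) / sig) ** 2)
    home = (landscape.continent.values[None, :, :]
            == pool["continent"].values[:, None, None])
    return p * home * landscape.land.values[None, :, :]


def effort_weights(landscape: Landscape) -> np.ndarray:
    """Relative spatial sampling-effort weight per cell.

    A smooth sinusoidal over/under-sampling pattern in longitude (well- vs
    poorly-recorded areas), chosen orthogonal to the linear longitudinal
    warming ramp so sampling intensity is uncorrelated with warming.
    """
    cfg = landscape.config
    lonn = (landscape.lon - cfg.lon_min) / (cfg.lon_max - cfg.lon_min)
    w = np.exp(cfg.effort_bias_strength * np.sin(2 * np.pi * 2.0 * lonn))
    return np.broadcast_to(w, (landscape.lat.size, landscape.lon.size))


def sample_occurrences(landscape: Landscape, pool: pd.DataFrame,
                       seed: int | None = None) -> pd.DataFrame:
    """Sample presence-only records for every period.

    Occupancy is realized with a persistent uniform per (species, cell).
    Effort allocates an expected ``effort_first_period * growth**p`` records
    per period over occupied pairs proportionally to the spatial bias; a
    pair yields a record when its persistent detection uniform falls below
    the Poisson detection probability 1 - exp(-mu).  Record coordinates are
    cell centroids jittered uniformly within the cell.
    """
    cfg = landscape.config
    if len(pool) == 0:
        raise ValueError("empty species pool")
    rng = np.random.default_rng(cfg.seed + 7 if seed is None else seed)
    n_lat, n_lon = landscape.lat.size, landscape.lon.size
    u_persist = rng.uniform(size=(len(pool), n_lat, n_lon))
    u_detect = rng.uniform(size=(len(pool), n_lat, n_lon))
    # persistent within-cell jitter: a (species, cell) pair is one locality,
    # re-observed at the same point whenever it is detected again
    half = cfg.resolution / 2.0
    jit_lon = rng.uniform(-half, half, size=(len(pool), n_lat, n_lon))
    jit_lat = rng.uniform(-half, half, size=(len(pool), n_lat, n_lon))
    eff = effort_weights(landscape)

    frames = []
    prov_names = np.array([p if p is not None else "" for p in cfg.provider_names],
                          dtype=object)
    for period in cfg.periods:
        p_occ = occupancy_probability(landscape, pool, period)
        occupied = u_persist < p_occ
        w = occupied * eff[None, :, :]
        total_w = w.sum()
        if total_w == 0:
            continue
        # expected records this period, allocated over occupied pairs in
        # proportion to spatial effort; detection of a pair is Poisson
        # thinning realized against a persistent uniform, so the observed
        # record set also evolves smoothly (revisitation, not resampling)
        n_expected = cfg.effort_first_period * cfg.effort_growth ** period.index
        mu = n_expected * w / total_w
        detected = u_detect < -np.expm1(-mu)
        sp_idx, lat_idx, lon_idx = np.nonzero(detected)
        n = sp_idx.size
        frames.append(pd.DataFrame({
            "species": pool["species"].values[sp_idx],
            "decimalLongitude": landscape.lon[lon_idx] + jit_lon[sp_idx, lat_idx, lon_idx],
            "decimalLatitude": landscape.lat[lat_idx] + jit_lat[sp_idx, lat_idx, lon_idx],
            "year": rng.integers(period.start_year, period.end_year + 1, n),
            "month": rng.integers(1, 13, n),
            "provider": prov_names[rng.choice(len(prov_names), n, p=cfg.provider_probs)],
        }))
    out = pd.concat(frames, ignore_index=True)
    out.loc[out["provider"] == "", "provider"] = pd.NA
    return out


def expected_effort(config: WorldConfig, period_index: int) -> float:
    """Expected record total allocated to a period by the effort model."""
    return config.effort_first_period * config.effort_growth ** period_index


def generate_world(config: WorldConfig):
    """Convenience: landscape, species pool and occurrence table in one call."""
    landscape = generate_landscape(config)
    pool = generate_species_pool(config)
    records = sample_occurrences(landscape, pool)
    return landscape, pool, records


# ---------------------------------------------------------------------------
# ground-truth oracles (used by tests and by the expectation-based checks)

def true_sti(landscape: Landscape, pool: pd.DataFrame) -> pd.Series:
    """Occupancy-weighted mean *actual* temperature per species, all periods.

    This is the generator-truth counterpart of the species temperature index:
    the expected extracted temperature of a random occurrence, ignoring
    effort bias.
    """
    num = np.zeros(len(pool))
    den = np.zeros(len(pool))
    for period in landscape.config.periods:
        p_occ = occupancy_probability(landscape, pool, period)
        actual = landscape.period_annual_mean(period).values
        num += (p_occ * actual[None, :, :]).sum(axis=(1, 2))
        den += p_occ.sum(axis=(1, 2))
    with np.errstate(invalid="ignore"):
        return pd.Series(num / den, index=pool["species"].values, name="true_sti")


def expected_window_cti(landscape: Landscape, pool: pd.DataFrame,
                        window_lon: np.ndarray, window_lat: np.ndarray,
                        radius_km: float = 200.0) -> np.ndarray:
    """Expected CTI per (window, period) from generator truth.

    Window-level presence probability is the union over cells within the
    radius of cell-level occupancy; the expected CTI is the presence-
    probability-weighted mean of the species' true STIs.  Shape
    (n_windows, n_periods).
    """
    from .geo import haversine_km

    cfg = landscape.config
    sti = true_sti(landscape, pool).values
    lon2, lat2 = np.meshgrid(landscape.lon, landscape.lat)
    out = np.full((window_lon.size, len(cfg.periods)), np.nan)
    for j, period in enumerate(cfg.periods):
        p_occ = occupancy_probability(landscape, pool, period)
        for i in range(window_lon.size):
            inside = haversine_km(window_lon[i], window_lat[i], lon2, lat2) <= radius_km
            if not inside.any():
                continue
            p_pres = 1.0 - np.prod(1.0 - p_occ[:, inside], axis=1)
            ok = np.isfinite(sti)
            denom = p_pres[ok].sum()
            if denom > 0:
                out[i, j] = (p_pres[ok] * sti[ok]).sum() / denom
    return out
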