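# Methods

`climdebt` estimates climate-driven restructuring of animal communities from
unstructured presence-only occurrence data, and verifies the whole estimation
chain end to end on a synthetic world with known ground truth. This note
documents the statistical procedure, the generative model behind the
synthetic world, the numerical choices, and what the verification results do
and do not show.

## The estimation chain

**Community temperature index.** Every species receives a species temperature
index (STI): the mean temperature extracted at all of its cleaned, spatially
thinned records, where each record reads the mean seasonal temperature raster
of its 5-year period (six periods covering 1990–2019) at its grid cell.
Assemblages are defined by 200-km-radius sliding windows centred on a 1°
lattice; windows overlap by construction. The community temperature index
(CTI) of a window × period is the unweighted mean STI of the distinct
species present — a presence-only variant; abundance weighting is impossible
with opportunistic archives. A window × period qualifies only with at least
two species carrying an STI.

**Data hygiene.** Before any index is computed, records pass coordinate
cleaning (exactly-zero or equal lat/lon, listed capital/centroid/institution
points within a configurable 1-km buffer, off-land cells), taxon filters
(excluded synanthropic species; seasonal month windows, with December joined
to the following January for wintering taxa), the 1990–2019 window, and
spatial thinning: one record per species per 5 × 5-km equal-area cell per
period, tie-broken uniformly at random under an explicit seed. The 5-km grid
lives in a world cylindrical equal-area projection because "5 km" is a metric
statement; a degree grid would shrink with latitude.

**Trend models.** CTI is modelled per taxon by a weighted linear mixed model
with fixed effects for the period median year (centred at 2004.5), continent
and window mean temperature; random intercept and year slope by window,
crossed with a random intercept by ecoregion; weights are ln(occurrences) per
window × period. The local CTI trend of a window is the fixed year slope
plus that window's random slope (a best linear unbiased predictor, BLUP).
The climatic-debt model then regresses local CTI trends on local temperature
trends (the OLS slope of window period-mean temperatures on period median
years), in interaction with window mean temperature (centred at its observed
mean) and with the human influence index (HII), plus a continent effect,
weighted by ln(total occurrences per window). The *marginal debt slope* at a
given HII — evaluated at average climate — is the headline quantity: 1 means
communities track temperature change completely; values below 1 quantify the
climatic debt. Marginal slopes are reported at the 25th, 50th and 75th
percentiles of observed window HII with Wald CIs from the coefficient
covariance. Taxon-level estimates are pooled by DerSimonian–Laird
random-effects meta-analysis.

**Random-effects structure of the debt model.** The debt model carries a
random intercept *and a random temperature-trend slope* by ecoregion. The
slope component is essential for honest inference: overlapping windows share
species, so their trend deviations are regionally correlated in a way that
scales with the temperature-trend regressor itself (a region's realized
tracking efficiency is one draw, not hundreds of independent ones). With an
intercept-only structure the Wald CI of the debt slope treats every window
as independent and is roughly twice too narrow in our verification worlds;
the random slope restores near-nominal replicate-level coverage.

**Turnover.** For each window and consecutive period pair with valid CTIs,
species gained and lost are scored by the relative STI, rSTI = STI −
CTI(t−1); positive values mark locally warm-adapted species. Means per
status use percentile bootstrap CIs over events (1,000 resamples, seeded)
rather than an analytic formula, because events from overlapping windows are
not independent. CTI change decomposes exactly into the gained and lost
contributions, which the tests assert identically.

**Sensitivity.** The CTI-over-time model is refitted after keeping only
windows with at least {50, 75, 100, 125, 150} total occurrences or at least
{2, 3, 4, 5} periods with a CTI; taxon-level slopes are compared by Pearson
correlation and per-window trends by absolute differences, and a mixed model
of |Δ trend| on taxon × filter levels (window random intercept, ML fits)
tests the three-way interaction by likelihood ratio.

## The synthetic world

The generator is the package's ground truth. A rectangular landscape
(default 24° × 38° at 1° resolution) holds two continents separated by a sea
band; monthly temperature is a south–north baseline gradient (0.6 °C per
degree latitude) plus a seasonal cosine (amplitude 8 °C, which cancels
exactly in annual means) plus a linear warming trend, optionally varying
across space. Regions are latitudinal bands per continent (5 per continent
by default), standing in for ecoregions. The human influence surface is a
smooth sinusoid in [0, 64] with wavelengths of a few window diameters —
enough independent high/low patches to identify an HII interaction, still
resolvable after 200-km window averaging, and uncorrelated with the
latitudinal temperature gradient and the longitudinal warming ramp.

**Species and tracking.** Each of 800 species has a Gaussian thermal niche
(σ = 1 °C) around an optimum drawn uniformly over the landscape's annual
temperature range extended by 3σ at both ends, and lives on one continent.
The tracking fraction λ controls range adjustment through a *perceived*
temperature field: T_perc(c, t) = T(c, t₀) + λ·(T(c, t) − T(c, t₀)). With
λ = 1 ranges follow isotherms instantly; λ = 0 freezes them; intermediate
values produce a climatic debt whose expected debt-model slope is λ. λ may
decline linearly with the cell's HII, emulating anthropization impeding
range shifts.

**Occupancy and sampling.** Occupancy is cell-level Bernoulli with
probability p_max·exp(−(T_perc − μ)²/2σ²), realized against one *persistent*
uniform draw per (species, cell): a cell flips only when its probability
crosses that draw, emulating site persistence — fresh draws per period would
inject white noise that real occupancy does not have. Effort allocates an
expected 60,000 records (growing ×1.5 per period) over occupied pairs
proportionally to a sinusoidal spatial bias; detection of a pair is Poisson
thinning, also realized against a persistent uniform (revisitation, not
resampling), and each detected pair contributes one record at a persistent
within-cell jitter position. Records carry uniform years within the period,
uniform months, and a categorical provider (with a missing-provider mass)
for the data-characteristic summaries.

## Design choices that required care

These were found, diagnosed against the truth oracle (expected window CTI
computed from occupancy probabilities and true STIs, independent of the
fitted models), and fixed during design; each is a property of presence-only
CTI estimation worth knowing about:

1. **Thermal buffering.** Windows are built only on an interior latitudinal
   band (33–47° of a 20–58° landscape). Near the landscape's thermal edges
   the species pool is truncated on one side, which attenuates CTI trends by
   tens of percent; the oracle shows interior windows track 1:1.
2. **Detection saturation.** First-period effort is set so that detection of
   occupied cells is nearly complete from the start. When early detection is
   sparse, the realized presence kernel widens as effort grows, and this
   interacts with range translation to bias per-window trends — entries at
   the warm edge get easier over time while exits do not. Record counts
   still grow through the effort model; species sets are occupancy-driven.
3. **Warming smooth at window scale.** Heterogeneous warming is a linear
   longitudinal ramp restarting on each continent (0–0.04 °C/yr). A ramp
   that runs across both continents is collinear with the continent
   contrast, letting continent-level pool differences destabilize the debt
   slope. Drawing rates in blocks at the window scale (available as
   `warming_pattern="blocks"`) is *biased low*: when warming varies inside a
   window, species persist in slow-warming refuge cells and colonize from
   fast-warming vanguard cells, so community change no longer corresponds to
   the window-mean trend that serves as the regressor. The window-mean
   temperature trend is only the right covariate when warming is smooth at
   the window scale — for real data this is plausibly satisfied because
   climatic trends vary at synoptic scales much larger than 200 km, but it
   is an assumption of the method, not a convenience.
4. **Pool density.** The local-trend extractor is a shrinkage estimator:
   BLUP slopes are pulled toward the fixed slope by the ratio of sampling
   noise to true slope heterogeneity, which attenuates the debt slope
   multiplicatively. Per-window CTI sampling noise scales inversely with the
   number of species per assemblage, so the verification world uses a dense
   pool (800 species, ~10⁵ records per period) to keep shrinkage at the
   percent level. Sparse real datasets will sit lower on this curve — a
   caveat the original analyses share.

## What the verification shows, and what it does not

Under the defaults, twenty seeded replicates of the full pipeline give a
debt slope at median HII of ~0.98 (seed SD ~0.05) for λ = 1, ~0.46 for
λ = 0.5, a CTI trend matching the occupancy oracle's expected drift within a
few percent for uniform warming of 0.02 °C/yr, and a monotonically declining
marginal slope across HII quartiles when λ declines with HII. Residual
attenuation of 2–5% from kernel truncation, realized-presence dynamics and
shrinkage is intrinsic to the estimator at these settings.

The synthetic world deliberately omits: abundance dynamics and
detection/abundance coupling, dispersal limitation (tracking is
instantaneous at fraction λ), taxonomic error, spatially varying seasonal
cycles, interannual climate variability beyond the linear trend (the
temperature noise option exists but defaults to zero), and non-zonal
geography. Passing tests therefore show the *estimation chain* is faithful
and calibrated under the stated generative assumptions; they do not show
that real archives satisfy those assumptions.

## Numerical notes

- The mixed-model fitter profiles fixed effects and the residual variance
  out of the (RE)ML criterion and optimizes relative covariance factors
  (log-Cholesky) by Nelder–Mead; marginal covariance algebra uses the
  Woodbury identity with all O(n) cross-products precomputed, so each
  objective evaluation is cubic only in the number of random-effect columns.
  The search is boxed (|θ| ≤ 12) and a lost-precision guard rejects variance
  ratios where the Woodbury subtraction would cancel catastrophically.
  Fixed effects agree with statsmodels `MixedLM` and with `lme4::lmer`
  (weighted, crossed) to four decimals on test problems.
- Weights enter as residual precisions, so rescaling all weights by a
  constant only rescales σ² — the logarithm base in ln(n_occ) is
  inconsequential, and natural log is used by convention.
- Debt-model marginal slopes use a Student-t quantile with df = (number of
  ecoregions − 2): the slope's effective replication is the number of
  regional random-slope draws, not the number of overlapping windows, and
  normal-quantile Wald intervals are anticonservative in exactly this
  few-levels regime. Other fixed effects (e.g. β_year, whose variance is
  carried by hundreds of window-level slopes) use the normal quantile.
- OLS slopes (temperature trends) are computed by centred cross-products;
  period rasters are exact arithmetic means, so linear-in-time fields give
  machine-precision trend recovery.
- Geodesy: great-circle distances on a sphere (R = 6371.0088 km); window
  membership via a KD-tree on unit-sphere coordinates with the exact chord
  radius. Thinning cells come from the world cylindrical equal-area
  projection.
- Ties and degenerate inputs: thinning tie-breaks are seeded-uniform;
  single-period data refuse a time slope; a spatially constant temperature
  trend makes the debt model unidentifiable and is reported as such
  (the pipeline records the reason and skips the debt stage); a constant
  |Δ| table short-circuits the sensitivity interaction test to χ² = 0.

## Problem sizes

Verification experiments use 336 windows × 6 periods (~2,000 CTI records,
~10⁵–10⁶ occurrence records per world) and 20 replicates per condition;
exact identities (CTI vs brute force, turnover decomposition, thinning
bounds, trend recovery) run on smaller worlds where exhaustive assertion is
feasible. These sizes were chosen so each replicate resolves the debt slope
to a few percent while a full multi-condition verification remains a
minutes-scale computation on one CPU.
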