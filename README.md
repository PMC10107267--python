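# climdebt

Tools for detecting climate-driven restructuring of animal communities from
unstructured presence-only occurrence data — the kind of opportunistic,
effort-biased records that public biodiversity archives aggregate — plus a
synthetic occurrence/climate world with known ground truth on which the whole
estimation chain is verified end to end.

## Who this is for

Ecologists who want to ask, for taxa without systematic monitoring schemes:
*are assemblages becoming composed of more warm-adapted species, does that
compositional change keep pace with local warming, and does human influence
slow it down?* — using nothing but cleaned occurrence tables and a gridded
temperature time series.

## The method

Each species gets a **species temperature index** (STI): the mean
temperature extracted at all of its cleaned, spatially thinned records, read
from the 5-year-period seasonal temperature raster matching each record.
Assemblages are **200-km-radius sliding windows** on a 1° lattice; the
**community temperature index** (CTI) of a window × period is the unweighted
mean STI of the distinct species present (presence-only; ≥ 2 species
required). Records are first cleaned (zero/equal coordinates, listed
centroid and institution points, ocean cells), filtered (species exclusions,
seasonal month sets, 1990–2019), binned into six 5-year periods and thinned
to one record per species per 5 × 5-km equal-area cell per period.

Temporal change is estimated per taxon with a weighted linear mixed model

    CTI ~ year_c + continent + mean_temp + (1 + year_c | window) + (1 | ecoregion)

weighted by ln(occurrences); the fitted year slope β_year is the
thermophilization rate, and each window's local CTI trend is β_year plus its
random slope. The **climatic-debt model** then regresses local CTI trends
on local temperature trends b_T (OLS slope of window period-mean
temperature on period median years), in interaction with mean temperature
and the human influence index (HII), with continent, a random intercept and
random b_T slope by ecoregion, weighted by ln(total occurrences). The
marginal slope ∂(CTI trend)/∂b_T at a given HII is the tracking estimate:
1 = complete adjustment, < 1 = climatic debt. Taxon estimates are pooled by
DerSimonian–Laird random-effects meta-analysis. Species turnover is
decomposed with the relative STI (rSTI = STI − CTI at the interval start),
and robustness to data quantity is probed by refitting under a factorial
grid of minimum-occurrence / minimum-period filters.

The synthetic world drives everything with one parameter, the tracking
fraction λ: species respond to a perceived temperature field that realizes
a fraction λ of actual warming, so the expected debt slope *is* λ. See
`docs/methods.md` for the generative model and its calibration.

## Worked example

The numbered scripts under `analysis/` run the full study on three
simulated taxa that differ only in tracking fraction (λ = 1.0, 0.5, 0.2),
writing tables under `results/`:

```bash
python analysis/01_simulate_world.py --seed 1
python analysis/03_assemblages_cti.py --seed 1
python analysis/04_fit_trends.py --seed 1
```

prints, among other things:

```
trackers: 336 windows, 786 species with STI, 2016 window x period CTIs
trackers (lam=1.0): beta_year=0.0195 debt slope (median HII)=1.010
laggards (lam=0.5): beta_year=0.0108 debt slope (median HII)=0.473
sessile (lam=0.2): beta_year=0.0037 debt slope (median HII)=0.231
meta: beta_year=0.0113 [0.0033, 0.0193], debt=0.555
```

Reading this: with warming averaging 0.02 °C/yr across windows, the
perfectly tracking taxon warms its community composition at
β_year ≈ 0.0195 °C/yr and shows a debt slope of ≈ 1 (no debt); the lagging
taxa recover their true tracking fractions (0.47 vs 0.5, 0.23 vs 0.2) — a
climatic debt. The meta-analytic row pools the three taxa. Turnover
(`analysis/05_turnover.py`) shows the mechanism — species gained between
periods are locally warm-adapted (mean rSTI +1.69 for the tracking taxon,
80% positive), lost species cold-adapted — and
`analysis/06_sensitivity.py` refits everything under the data-quantity
filter grid (taxon-level slopes correlate at r ≥ 0.999 between filtered and
full datasets in this example).

`analysis/02_clean_and_thin.py` exercises the cleaning/thinning stage
explicitly and writes a removal report.

## Layout

- `src/climdebt/` — the library: `synthetic` (world generator and truth
  oracles), `occurrences` (cleaning/filtering/thinning), `climate` (period
  rasters, extraction, window climate), `assemblages` (windows, STI, CTI),
  `lmm` (weighted mixed models with crossed random effects), `trends`
  (CTI-over-time, debt model, meta-analysis), `turnover`, `sensitivity`,
  `pipeline`, `verification`.
- `analysis/` — numbered study drivers (see worked example).
- `tests/` — pytest suite, including end-to-end parameter recovery.
- `docs/methods.md` — model details, assumptions, calibration and limits.
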