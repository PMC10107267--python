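"""Data-quantity sensitivity of the CTI temporal trend.

Re-runs the CTI-over-time model keeping only windows with at least a given
total number of occurrences and at least a given number of periods with a
CTI, over the factorial filter grid; compares taxon-level slopes (Pearson r
across taxa) and per-window local trends (absolute differences), and tests
whether filter effects differ among taxa with a mixed model on |delta|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .lmm import RandomTerm, fit_lmm, lrt
from .trends import CtiTimeFit, fit_cti_time

#: the factorial filter grid explored by the sensitivity analysis
OCC_LEVELS = (0, 50, 75, 100, 125, 150)
PERIOD_LEVELS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class FilterSpec:
    """Minimum total occurrences and minimum periods-with-CTI per window."""

    min_occurrences: int = 0
    min_periods: int = 1

    def __post_init__(self):
        if self.min_occurrences < 0 or self.min_periods < 0:
            raise ValueError("filter thresholds must be nonnegative")

    @property
    def is_baseline(self) -> bool:
        return self.min_occurrences == 0 and self.min_periods <= 1


def filter_windows(cti: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Keep all periods of windows satisfying both filter criteria."""
    per_window = cti.groupby("window_id").agg(total_occ=("n_occ", "sum"),
                                              n_periods=("period_index", "nunique"))
    keep = per_window[(per_window["total_occ"] >= spec.min_occurrences)
                      & (per_window["n_periods"] >= spec.min_periods)].index
    out = cti[cti["window_id"].isin(keep)].reset_index(drop=True)
    if out.empty:
        raise ValueError(f"filter {spec} removed every window")
    return out


@dataclass
class SensitivityResult:
    spec: FilterSpec
    slopes_full: pd.Series       # taxon -> beta_year, unfiltered
    slopes_filtered: pd.Series
    pearson_r: float
    deltas: pd.DataFrame         # taxon, window_id, abs_delta (common windows)
    n_windows_dropped: dict = field(default_factory=dict)


def refit_and_compare(taxa: dict, full_fits: dict[str, CtiTimeFit],
                      spec: FilterSpec) -> SensitivityResult:
    """Refit each taxon under a filter and compare with the full fits.

    ``taxa`` maps taxon name -> dict with keys cti, windows, window_climate,
    periods (the inputs of :func:`fit_cti_time`).
    """
    slopes_full, slopes_filt, deltas, dropped = {}, {}, [], {}
    for name, data in taxa.items():
        full = full_fits[name]
        filt_cti = filter_windows(data["cti"], spec)
        fit = fit_cti_time(filt_cti, data["windows"], data["window_climate"],
                           data["periods"])
        slopes_full[name] = full.beta_year
        slopes_filt[name] = fit.beta_year
        common = full.local_trends.index.intersection(fit.local_trends.index)
        dropped[name] = int(len(full.local_trends) - len(common))
        deltas.append(pd.DataFrame({
            "taxon": name, "window_id": common,
            "abs_delta": (fit.local_trends[common]
                          - full.local_trends[common]).abs().to_numpy(),
        }))
    sf = pd.Series(slopes_full, name="full")
    sg = pd.Series(slopes_filt, name="filtered")
    if len(sf) >= 2 and sf.std(ddof=0) > 0 and sg.std(ddof=0) > 0:
        r = float(pearsonr(sf, sg).statistic)
    else:
        # degenerate across-taxa correlation; identical slopes count as 1
        r = 1.0 if np.allclose(sf, sg) else np.nan
    return SensitivityResult(spec=spec, slopes_full=sf, slopes_filtered=sg,
                             pearson_r=r, deltas=pd.concat(deltas, ignore_index=True),
                             n_windows_dropped=dropped)


def run_grid(taxa: dict, occ_levels=OCC_LEVELS[1:], period_levels=PERIOD_LEVELS[1:]):
    """Run the full filter grid; returns (long results table, |delta| table)."""
    full_fits = {name: fit_cti_time(d["cti"], d["windows"], d["window_climate"],
                                    d["periods"]) for name, d in taxa.items()}
    rows, delta_frames = [], []
    for occ, per in product(occ_levels, period_levels):
        spec = FilterSpec(occ, per)
        res = refit_and_compare(taxa, full_fits, spec)
        for name in taxa:
            rows.append({"min_occurrences": occ, "min_periods": per,
                         "taxon": name,
                         "beta_full": res.slopes_full[name],
                         "beta_filtered": res.slopes_filtered[name],
                         "pearson_r": res.pearson_r,
                         "n_windows_dropped": res.n_windows_dropped[name]})
        d = res.deltas.copy()
        d["min_occurrences"], d["min_periods"] = occ, per
        delta_frames.append(d)
    return pd.DataFrame(rows), pd.concat(delta_frames, ignore_index=True)


def fit_difference_model(deltas: pd.DataFrame):
    """Mixed model of |delta CTI trend| on taxon x min_occ x min_periods.

    Continuous (standardized) filter covariates, taxon as a factor, window
    identity as a random intercept; the three-way interaction is tested by a
    likelihood-ratio chi^2 between ML fits with and without it.  Returns
    (chi2, df, p, full fit).
    """
    df = deltas.copy()
    taxa = sorted(df["taxon"].unique())
    if len(taxa) < 2:
        raise ValueError("difference model needs at least two taxa")
    for col in ("min_occurrences", "min_periods"):
        if df[col].nunique() < 2:
            raise ValueError(f"difference model needs >= 2 levels of {col}")
    if np.isclose(df["abs_delta"].std(ddof=0), 0.0):
        # constant |delta| (e.g. identically zero): nothing for any factor to
        # explain, the interaction statistic is exactly zero
        return 0.0, 3, 1.0, None
    occ = (df["min_occurrences"] - df["min_occurrences"].mean()) / df["min_occurrences"].std()
    per = (df["min_periods"] - df["min_periods"].mean()) / df["min_periods"].std()
    y = df["abs_delta"].to_numpy(float)

    def design(include_three_way: bool):
        cols = [("intercept", np.ones(len(df))), ("occ", occ.to_numpy()),
                ("per", per.to_numpy()), ("occ:per", (occ * per).to_numpy())]
        for t in taxa[1:]:
            ind = (df["taxon"] == t).to_numpy(float)
            cols += [(f"taxon[{t}]", ind), (f"occ:taxon[{t}]", occ * ind),
                     (f"per:taxon[{t}]", per * ind)]
            if include_three_way:
                cols.append((f"occ:per:taxon[{t}]", occ * per * ind))
        return [c[0] for c in cols], np.column_stack([c[1] for c in cols])

    codes, _ = pd.factorize(df["taxon"].astype(str) + "/" + df["window_id"].astype(str))
    term = [RandomTerm("window", codes, np.ones((len(df), 1)))]
    names_f, X_f = design(True)
    names_r, X_r = design(False)
    full = fit_lmm(y, X_f, term, reml=False, beta_names=names_f)
    reduced = fit_lmm(y, X_r, term, reml=False, beta_names=names_r)
    stat, dfree, p = lrt(full, reduced)
    return stat, dfree, p, full
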