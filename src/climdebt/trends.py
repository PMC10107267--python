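"""CTI temporal trends, climatic-debt model and meta-analytic pooling.

Three statistical stages:

1. ``fit_cti_time`` -- weighted linear mixed model of CTI on the period
   median year (centered), continent and window mean temperature, with a
   random intercept + year slope by sliding window crossed with a random
   intercept by ecoregion; weights are ln(occurrences) per window x period.
   The local CTI trend of a window is the fixed year slope plus that
   window's random slope.

2. ``fit_debt`` -- weighted mixed model of local CTI trends on local
   temperature trends in interaction with mean temperature (centered at its
   observed mean) and with the human influence index, plus continent, with
   an ecoregion random intercept; weights are ln(total occurrences per
   window).  The marginal slope dCTItrend/dTtrend evaluated at a given HII
   (and at average climate) is the climate-tracking estimate; 1 means
   perfect adjustment, < 1 a climatic debt.

3. ``meta_analyze`` -- DerSimonian-Laird random-effects pooling of per-taxon
   estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .lmm import LMMResult, RandomTerm, fit_lmm
from .periods import PeriodDef, median_years

YEAR_CENTER = 2004.5  # midpoint of the 1990-2019 span


def _continent_dummies(cont: pd.Series):
    levels = sorted(cont.unique())
    cols = [(f"continent[{c}]", (cont == c).to_numpy(float)) for c in levels[1:]]
    return levels, cols


@dataclass
class CtiTimeFit:
    """CTI-over-time fit: overall trend and per-window local trends."""

    result: LMMResult
    beta_year: float
    ci: tuple
    local_trends: pd.Series      # indexed by window_id: beta_year + random slope
    year_center: float
    meta: dict = field(default_factory=dict)


def fit_cti_time(cti: pd.DataFrame, windows: pd.DataFrame,
                 window_climate: pd.DataFrame, periods: list[PeriodDef],
                 year_center: float = YEAR_CENTER) -> CtiTimeFit:
    """Weighted LMM of CTI on time; returns overall and local trends.

    ``cti`` needs columns window_id, period_index, cti, n_occ, weight;
    ``windows`` needs window_id, continent, ecoregion; ``window_climate``
    needs window_id, mean_temp.
    """
    df = (cti.merge(windows[["window_id", "continent", "ecoregion"]], on="window_id")
          .merge(window_climate[["window_id", "mean_temp"]], on="window_id"))
    if df["period_index"].nunique() < 2:
        raise ValueError("cannot identify a time slope from a single period")
    if df["window_id"].nunique() < 2:
        raise ValueError("need at least two windows")

    years = {p.index: p.median_year for p in periods}
    year_c = df["period_index"].map(years).to_numpy(float) - year_center
    mtemp_c = df["mean_temp"].to_numpy(float)
    mtemp_c = mtemp_c - mtemp_c.mean()

    cols = [("intercept", np.ones(len(df))), ("year", year_c)]
    _, cdum = _continent_dummies(df["continent"])
    cols += cdum
    cols.append(("mean_temp", mtemp_c))
    names = [c[0] for c in cols]
    X = np.column_stack([c[1] for c in cols])

    win_codes, win_ids = pd.factorize(df["window_id"])
    eco_codes, _ = pd.factorize(df["ecoregion"])
    terms = [RandomTerm("window", win_codes,
                        np.column_stack([np.ones(len(df)), year_c]),
                        names=("intercept", "year")),
             RandomTerm("ecoregion", eco_codes, np.ones((len(df), 1)),
                        names=("intercept",))]

    res = fit_lmm(df["cti"].to_numpy(float), X, terms,
                  weights=df["weight"].to_numpy(float), reml=True,
                  beta_names=names)
    beta_year = res.coef("year")
    local = pd.Series(beta_year + res.blups["window"][:, 1], index=win_ids,
                      name="cti_trend").sort_index()
    return CtiTimeFit(result=res, beta_year=beta_year, ci=res.wald_ci("year"),
                      local_trends=local, year_center=year_center,
                      meta={"n_obs": res.n_obs, "converged": res.converged,
                            "weights": "ln(n_occ)"})


@dataclass
class DebtFit:
    """Climatic-debt model fit and the quantities needed for marginal slopes."""

    result: LMMResult
    hii_percentiles: dict        # {"p25": value, "p50": ..., "p75": ...}
    hii_range: tuple
    df_inference: int | None = None   # small-sample t df; None -> normal
    meta: dict = field(default_factory=dict)

    def marginal_slope(self, hii_value: float, level: float = 0.95):
        """Slope of CTI trend on temperature trend at a given HII.

        Evaluated at average climate (the mean-temperature interaction term
        is centered, so it contributes nothing at its mean).  Returns
        (slope, lo, hi) with a Wald CI from the coefficient covariance; the
        quantile is Student-t with ``df_inference`` degrees of freedom when
        set, because the slope's effective replication is the number of
        regional random-slope draws, not the number of (overlapping)
        windows.
        """
        import warnings
        lo_h, hi_h = self.hii_range
        if not (lo_h <= hii_value <= hi_h):
            warnings.warn(f"HII {hii_value} outside observed range {self.hii_range}")
        res = self.result
        a = np.zeros(len(res.beta))
        a[res.beta_names.index("temp_trend")] = 1.0
        a[res.beta_names.index("temp_trend:hii")] = hii_value
        est = float(a @ res.beta)
        se = float(np.sqrt(a @ res.beta_cov @ a))
        if self.df_inference is not None:
            from scipy.stats import t as t_dist
            q = t_dist.ppf(0.5 + level / 2.0, self.df_inference)
        else:
            q = norm.ppf(0.5 + level / 2.0)
        return est, est - q * se, est + q * se


def fit_debt(local_trends: pd.Series, windows: pd.DataFrame,
             window_climate: pd.DataFrame, cti: pd.DataFrame) -> DebtFit:
    """Weighted mixed model of local CTI trends on temperature trends.

    Fixed effects: temperature trend, mean temperature (centered), HII,
    continent, trend x mean-temperature and trend x HII interactions;
    random intercept and random temperature-trend slope by ecoregion;
    weights ln(total occurrences per window).

    The random slope matters for honest inference: realized tracking
    efficiency varies regionally (neighbouring windows share species, so
    their trend deviations are correlated), and without a slope component
    the Wald CI of the debt slope treats windows as independent and is
    overconfident.
    """
    tot_occ = cti.groupby("window_id")["n_occ"].sum().rename("total_occ")
    df = (local_trends.rename("cti_trend").rename_axis("window_id").reset_index()
          .merge(windows[["window_id", "continent", "ecoregion"]], on="window_id")
          .merge(window_climate[["window_id", "temp_trend", "mean_temp", "hii"]],
                 on="window_id")
          .merge(tot_occ, on="window_id"))
    df = df.dropna(subset=["cti_trend", "temp_trend", "mean_temp", "hii"])

    for col in ("temp_trend", "hii"):
        if np.isclose(df[col].std(ddof=0), 0.0):
            raise ValueError(f"degenerate design: '{col}' is constant across windows")

    bt = df["temp_trend"].to_numpy(float)
    mtemp_c = df["mean_temp"].to_numpy(float)
    mtemp_c = mtemp_c - mtemp_c.mean()
    hii = df["hii"].to_numpy(float)

    cols = [("intercept", np.ones(len(df))), ("temp_trend", bt),
            ("mean_temp", mtemp_c), ("hii", hii)]
    _, cdum = _continent_dummies(df["continent"])
    cols += cdum
    cols += [("temp_trend:mean_temp", bt * mtemp_c), ("temp_trend:hii", bt * hii)]
    names = [c[0] for c in cols]
    X = np.column_stack([c[1] for c in cols])

    eco_codes, _ = pd.factorize(df["ecoregion"])
    terms = [RandomTerm("ecoregion", eco_codes,
                        np.column_stack([np.ones(len(df)), bt]),
                        names=("intercept", "temp_trend"))]
    res = fit_lmm(df["cti_trend"].to_numpy(float), X, terms,
                  weights=np.log(df["total_occ"].to_numpy(float)), reml=True,
                  beta_names=names)
    pcts = {f"p{q}": float(np.percentile(hii, q)) for q in (25, 50, 75)}
    n_eco = int(eco_codes.max()) + 1
    return DebtFit(result=res, hii_percentiles=pcts,
                   hii_range=(float(hii.min()), float(hii.max())),
                   df_inference=max(n_eco - 2, 2) if n_eco >= 4 else None,
                   meta={"n_windows": len(df), "n_ecoregions": n_eco,
                         "converged": res.converged,
                         "weights": "ln(total n_occ)"})


def marginal_slopes(debt: DebtFit, hii_values=None, level: float = 0.95) -> pd.DataFrame:
    """Marginal debt slopes with CIs at given HII values (default: quartiles)."""
    if hii_values is None:
        hii_values = debt.hii_percentiles
    if not isinstance(hii_values, dict):
        hii_values = {f"hii={v:g}": float(v) for v in hii_values}
    rows = []
    for label, h in hii_values.items():
        est, lo, hi = debt.marginal_slope(h, level)
        rows.append({"label": label, "hii": h, "slope": est, "lo": lo, "hi": hi})
    return pd.DataFrame(rows)


@dataclass
class MetaEstimate:
    estimate: float
    ci: tuple
    tau2: float
    k: int
    single_study: bool = False


def meta_analyze(estimates, ses, level: float = 0.95) -> MetaEstimate:
    """DerSimonian-Laird random-effects pooling of independent estimates.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with fixed-effect
    weights w = 1/SE^2; pooled mean uses weights 1/(SE^2 + tau^2) and a Wald
    CI.  With a single estimate the input is returned, flagged.
    """
    est = np.asarray(estimates, float)
    se = np.asarray(ses, float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    k = est.size
    z = norm.ppf(0.5 + level / 2.0)
    if k == 1:
        e = float(est[0])
        return MetaEstimate(e, (e - z * se[0], e + z * se[0]), 0.0, 1,
                            single_study=True)
    w = 1.0 / se ** 2
    mu_fe = (w * est).sum() / w.sum()
    Q = float((w * (est - mu_fe) ** 2).sum())
    denom = w.sum() - (w ** 2).sum() / w.sum()
    tau2 = max(0.0, (Q - (k - 1)) / denom)
    w_re = 1.0 / (se ** 2 + tau2)
    mu = float((w_re * est).sum() / w_re.sum())
    se_mu = float(np.sqrt(1.0 / w_re.sum()))
    return MetaEstimate(mu, (mu - z * se_mu, mu + z * se_mu), float(tau2), int(k))
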