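"""Weighted linear mixed models with crossed random effects.

The trend models need a Gaussian mixed model of the form

    y = X beta + sum_r Z_r b_r + e,
    b_r(level) ~ N(0, Sigma_r),    e_i ~ N(0, sigma^2 / w_i),

with possibly *crossed* grouping factors (e.g. random intercept + slope by
sliding window, crossed with a random intercept by ecoregion) and known
residual precision weights w_i (here: log occurrence counts).

Estimation profiles beta and sigma^2 out of the (RE)ML criterion and
optimizes the relative covariance factors Lambda_r (Sigma_r = sigma^2
Lambda_r Lambda_r') by Nelder-Mead on their log-Cholesky parametrization.
Marginal-covariance solves use the Woodbury identity

    V* = W^-1 + Z~ Z~',   V*^-1 = W - W Z~ (I + Z~' W Z~)^-1 Z~' W,

with Z~ = Z (I_L (x) Lambda_r) sparse, so cost is cubic in the total number
of random-effect columns, not in the number of observations.  Multiplying
all weights by a positive constant rescales sigma^2 and leaves the fixed
effects unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import solve_triangular
from scipy.optimize import minimize

__all__ = ["RandomTerm", "LMMResult", "fit_lmm", "lrt"]


@dataclass
class RandomTerm:
    """One random-effects term.

    ``codes``: integer group code per observation (0..n_levels-1);
    ``design``: per-observation design (n_obs, d) -- e.g. [[1, t_i]] for a
    random intercept + slope; ``names`` labels the d components.
    """

    name: str
    codes: np.ndarray
    design: np.ndarray
    names: tuple = ()

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=int)
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        if self.design.shape[0] != self.codes.shape[0]:
            self.design = self.design.T
        if not self.names:
            self.names = tuple(f"c{j}" for j in range(self.dim))

    @property
    def dim(self) -> int:
        return self.design.shape[1]

    @property
    def n_levels(self) -> int:
        return int(self.codes.max()) + 1

    @property
    def n_params(self) -> int:
        d = self.dim
        return d * (d + 1) // 2

    def sparse_z(self) -> sp.csr_matrix:
        """N x (n_levels * d) block design, columns ordered (level, comp)."""
        n, d = self.design.shape
        rows = np.repeat(np.arange(n), d)
        cols = (self.codes[:, None] * d + np.arange(d)[None, :]).ravel()
        return sp.csr_matrix((self.design.ravel(), (rows, cols)),
                             shape=(n, self.n_levels * d))


@dataclass
class LMMResult:
    beta: np.ndarray
    beta_cov: np.ndarray
    beta_names: list
    sigma2: float
    vc: dict                      # term name -> d x d covariance (absolute)
    blups: dict                   # term name -> (n_levels, d) array
    loglik: float                 # maximized criterion (REML or ML), log-lik scale
    method: str
    converged: bool
    n_obs: int
    n_params_vc: int
    meta: dict = field(default_factory=dict)

    def wald_ci(self, name: str, level: float = 0.95):
        from scipy.stats import norm
        i = self.beta_names.index(name)
        se = float(np.sqrt(self.beta_cov[i, i]))
        z = norm.ppf(0.5 + level / 2.0)
        return self.beta[i] - z * se, self.beta[i] + z * se

    def coef(self, name: str) -> float:
        return float(self.beta[self.beta_names.index(name)])


def _unpack_chol(theta_r: np.ndarray, d: int) -> np.ndarray:
    """Lower-triangular factor from packed params (log diagonal)."""
    L = np.zeros((d, d))
    k = 0
    for i in range(d):
        for j in range(i + 1):
            L[i, j] = np.exp(theta_r[k]) if i == j else theta_r[k]
            k += 1
    return L


def fit_lmm(y, X, terms: list[RandomTerm], weights=None, reml: bool = True,
            beta_names=None, maxiter: int = 4000) -> LMMResult:
    """Fit the weighted mixed model; see module docstring for the form.

    ``weights`` are residual precision weights (variance of e_i is
    sigma^2 / w_i); None means 1.  ``reml=False`` gives ML, required for
    likelihood-ratio tests of fixed effects.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if beta_names is None:
        beta_names = [f"x{j}" for j in range(p)]
    if np.linalg.matrix_rank(X) < p:
        bad = _aliased_column(X, beta_names)
        raise np.linalg.LinAlgError(f"rank-deficient fixed-effects design; "
                                    f"aliased term: {bad}")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")

    n_theta = sum(t.n_params for t in terms)
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    # baseline scale for starting values: residual sd of the weighted OLS fit
    beta0, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid0 = yw - Xw @ beta0

    # all O(n) work happens once: cross-products of the untransformed random
    # design; each objective evaluation then only transforms by the current
    # relative Cholesky factors and works in q x q space
    if terms:
        Z_all = sp.hstack([t.sparse_z() for t in terms], format="csr")
        Zw_all = Z_all.multiply(sw[:, None]).tocsr()
        S = (Zw_all.T @ Zw_all).tocsr()          # Z' W Z
        U_X = Zw_all.T @ Xw                      # Z' W X
        U_y = Zw_all.T @ yw                      # Z' W y
    XtWX = Xw.T @ Xw
    XtWy = Xw.T @ yw

    def split(theta):
        out, k = [], 0
        for t in terms:
            out.append(theta[k:k + t.n_params])
            k += t.n_params
        return out

    def transform(theta):
        """Block-diagonal T = diag_r kron(I_levels, L_r)."""
        blocks = [sp.kron(sp.identity(t.n_levels, format="csr"),
                          sp.csr_matrix(_unpack_chol(th, t.dim)), format="csr")
                  for t, th in zip(terms, split(theta))]
        return sp.block_diag(blocks, format="csr")

    def profile(theta):
        """Profiled -2 log-lik (REML or ML) and ingredients at theta."""
        # keep the search inside a numerically safe box; a finite, gently
        # sloped penalty steers the simplex back instead of stranding it
        if np.any(np.abs(theta) > 12.0):
            return 1e8 * (1.0 + np.sum(np.abs(theta))), None
        if terms:
            T = transform(theta)
            M = (T.T @ S @ T).toarray()
            M[np.diag_indices_from(M)] += 1.0
            try:
                M_chol = np.linalg.cholesky(M)
            except np.linalg.LinAlgError:
                return np.inf, None
            logdet_M = 2.0 * np.log(np.diag(M_chol)).sum()
            TtUX = T.T @ U_X
            TtUy = T.T @ U_y
            tmpX = solve_triangular(M_chol, TtUX, lower=True)
            tmpy = solve_triangular(M_chol, TtUy, lower=True)
            XtVX = XtWX - tmpX.T @ tmpX
            Xty = XtWy - tmpX.T @ tmpy
            # subtraction losing > ~10 digits means the variance ratio is
            # absurd and the criterion value would be numerical noise
            if np.any(np.diag(XtVX) < 1e-10 * np.diag(XtWX)):
                return 1e8 * (1.0 + np.sum(np.abs(theta))), None
        else:
            T = M_chol = None
            logdet_M = 0.0
            XtVX, Xty = XtWX, XtWy
        try:
            C = np.linalg.cholesky(XtVX)
        except np.linalg.LinAlgError:
            return np.inf, None
        beta = np.linalg.solve(XtVX, Xty)
        rw = yw - Xw @ beta
        quad = float(rw @ rw)
        if M_chol is not None:
            Ztr = solve_triangular(M_chol, T.T @ (U_y - U_X @ beta), lower=True)
            quad -= float(Ztr @ Ztr)
        dof = n - p if reml else n
        sigma2 = quad / dof
        if sigma2 <= 0:
            return np.inf, None
        # -2 log-lik up to an additive constant; -sum(log w) is constant too
        crit = dof * np.log(sigma2) + logdet_M - np.log(w).sum()
        if reml:
            crit += 2.0 * np.log(np.diag(C)).sum()
        return crit, (beta, sigma2, XtVX, M_chol, T)

    # starting values: each random-effect sd at half the residual scale of a
    # weighted OLS fit, relative to its design column's scale (log-diagonal)
    theta0 = np.zeros(n_theta)
    resid_scale = max(float(np.std(resid0)), 1e-10)
    k = 0
    for t in terms:
        for i in range(t.dim):
            for j in range(i + 1):
                if i == j:
                    col_scale = max(float(np.std(t.design[:, i] * sw)), 1e-10)
                    theta0[k] = np.log(0.5 * resid_scale / col_scale)
                k += 1

    if n_theta:
        res = minimize(lambda th: profile(th)[0], theta0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-9})
        theta_hat, converged = res.x, bool(res.success)
    else:
        theta_hat, converged = theta0, True
    crit, ing = profile(theta_hat)
    if ing is None:
        raise np.linalg.LinAlgError("mixed-model fit failed to produce a "
                                    "positive-definite covariance")
    beta, sigma2, XtVX, M_chol, T = ing

    beta_cov = sigma2 * np.linalg.inv(XtVX)
    vc, blups = {}, {}
    if M_chol is not None:
        rhs = T.T @ (U_y - U_X @ beta)
        u = solve_triangular(M_chol, solve_triangular(M_chol, rhs, lower=True),
                             lower=True, trans='T')
        b_all = T @ u                          # back to natural scale
        offset = 0
        for t, th in zip(terms, split(theta_hat)):
            L = _unpack_chol(th, t.dim)
            vc[t.name] = sigma2 * (L @ L.T)
            q = t.n_levels * t.dim
            blups[t.name] = b_all[offset:offset + q].reshape(t.n_levels, t.dim)
            offset += q
    dof = n - p if reml else n
    loglik = -0.5 * (crit + dof * (np.log(2.0 * np.pi) + 1.0))
    return LMMResult(beta=beta, beta_cov=beta_cov, beta_names=list(beta_names),
                     sigma2=float(sigma2), vc=vc, blups=blups,
                     loglik=float(loglik), method="REML" if reml else "ML",
                     converged=converged, n_obs=n, n_params_vc=n_theta,
                     meta={"theta": theta_hat.tolist()})


def _aliased_column(X: np.ndarray, names) -> str:
    """Name a column linearly dependent on its predecessors (for errors)."""
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, :j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
            return names[j]
    return names[0]


def lrt(full: LMMResult, reduced: LMMResult):
    """Likelihood-ratio chi^2 between nested ML fits; returns (stat, df, p)."""
    from scipy.stats import chi2
    if full.method != "ML" or reduced.method != "ML":
        raise ValueError("likelihood-ratio tests on fixed effects require ML fits")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = (len(full.beta) - len(reduced.beta)) + (full.n_params_vc - reduced.n_params_vc)
    return stat, df, float(chi2.sf(stat, df)) if df > 0 else np.nan
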