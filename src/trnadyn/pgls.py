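"""Phylogenetic generalized least squares with Pagel's lambda.

The response (a continuous trait, or a presence/absence profile treated as
continuous) is modeled as multivariate normal around a linear predictor with
covariance sigma^2 * V(lambda), where V is the Brownian-motion tree
covariance and lambda scales its off-diagonal entries. beta and sigma^2 have
closed-form GLS solutions at fixed lambda; lambda is profiled on [0, 1] by
bounded scalar search over a grid-seeded bracket (unimodality assumed, grid
multistart guards against local optima). Nested models are compared by
likelihood-ratio tests against chi-square(1), and calls across a screen are
controlled by one pooled Benjamini-Hochberg correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .codon_metrics import _mann_whitney
from .phylo import TreeIndex, lambda_transform, read_newick, tree_vcv

_LOG2PI = np.log(2 * np.pi)


class GLSWorkspace:
    """Precomputed spectral data for repeated lambda-profile likelihood
    evaluations on one tree covariance.

    When the tree is ultrametric (constant diagonal of V), V(lambda) shares
    V's eigenvectors, so each lambda evaluation costs O(n p) after one
    eigendecomposition. Otherwise a Cholesky factorization per evaluation is
    used.
    """

    def __init__(self, V: np.ndarray):
        self.V = np.asarray(V, dtype=float)
        d = np.diag(self.V)
        self.n = self.V.shape[0]
        self.ultrametric = np.allclose(d, d[0], rtol=1e-8, atol=1e-12)
        if self.ultrametric:
            self.d0 = float(d[0])
            w, U = np.linalg.eigh(self.V)
            self.eigvals = w
            self.U = U

    def rotate(self, A: np.ndarray) -> np.ndarray:
        return self.U.T @ A

    def lam_eigvals(self, lam: float) -> np.ndarray:
        return lam * self.eigvals + (1 - lam) * self.d0


def _gls_at_lambda(ws: GLSWorkspace, Xd, y, Xr, yr, lam):
    """GLS estimates and ML log-likelihood at fixed lambda.

    Returns (beta, sigma2_ml, loglik, xtwx_inv, rwr). ``Xr``/``yr`` are the
    eigenrotated design/response (fast path) or None.
    """
    n, p = Xd.shape
    if ws.ultrametric:
        w = ws.lam_eigvals(lam)
        if np.any(w <= 0):
            return None
        iw = 1.0 / w
        xtwx = (Xr * iw[:, None]).T @ Xr
        xtwy = (Xr * iw[:, None]).T @ yr
        try:
            beta = np.linalg.solve(xtwx, xtwy)
            xtwx_inv = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular design matrix") from exc
        r = yr - Xr @ beta
        rwr = float((r * r * iw).sum())
        logdet = float(np.log(w).sum())
    else:
        W = lambda_transform(ws.V, lam)
        try:
            c, low = cho_factor(W, lower=True)
        except np.linalg.LinAlgError:
            return None
        Wi_X = cho_solve((c, low), Xd)
        Wi_y = cho_solve((c, low), y)
        xtwx = Xd.T @ Wi_X
        try:
            beta = np.linalg.solve(xtwx, Xd.T @ Wi_y)
            xtwx_inv = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular design matrix") from exc
        r = y - Xd @ beta
        rwr = float(r @ cho_solve((c, low), r))
        logdet = 2 * float(np.log(np.diag(c)).sum())
    if rwr <= 0:
        rwr = np.finfo(float).tiny
    sigma2 = rwr / n
    loglik = -0.5 * (n * (_LOG2PI + np.log(sigma2) + 1) + logdet)
    return beta, sigma2, loglik, xtwx_inv, rwr


class PhylogeneticGLS(BaseEstimator):
    """Maximum-likelihood PGLS regression with Pagel's lambda.

    Parameters
    ----------
    optimize_lambda : bool
        Profile lambda over [0, 1]; when False, ``lam`` is held fixed.
    lam : float
        Fixed lambda used when ``optimize_lambda`` is False.
    fit_intercept : bool
        Include an intercept column.

    Fitted attributes (trailing underscore): ``coef_``, ``intercept_``,
    ``sigma2_``, ``lambda_``, ``loglik_``, ``r2_``, ``se_``, ``nobs_``.
    """

    def __init__(self, optimize_lambda: bool = True, lam: float = 1.0,
                 fit_intercept: bool = True):
        self.optimize_lambda = optimize_lambda
        self.lam = lam
        self.fit_intercept = fit_intercept

    # grid seeds for the bounded lambda search; dense enough that the profile
    # refinement never misses the global optimum between knots
    _GRID = tuple(np.round(np.linspace(0, 1, 21), 3))

    def fit(self, X, y, tree=None, V=None, workspace: GLSWorkspace | None = None):
        """Fit with predictors ``X`` (n x p, p may be 0), response ``y`` and a
        phylogeny given as a tree, a covariance matrix ``V`` or a
        precomputed :class:`GLSWorkspace`."""
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        X = np.empty((n, 0)) if X is None else np.asarray(X, dtype=float).reshape(n, -1)
        if workspace is None:
            if V is None:
                if tree is None:
                    raise ValueError("provide tree, V or workspace")
                _, V = tree_vcv(read_newick(tree) if not isinstance(tree, TreeIndex) else tree)
            workspace = GLSWorkspace(V)
        if n != workspace.n:
            raise ValueError("response length does not match covariance dimension")
        if n < X.shape[1] + 3:
            raise ValueError("need at least n_predictors + 3 observations")
        if np.ptp(y) == 0:
            raise ValueError("response has zero variance")
        Xd = np.column_stack([np.ones(n), X]) if self.fit_intercept else X
        if Xd.shape[1] == 0:
            raise ValueError("empty design (no intercept, no predictors)")
        if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
            raise ValueError("singular design matrix")
        Xr = workspace.rotate(Xd) if workspace.ultrametric else None
        yr = workspace.rotate(y) if workspace.ultrametric else None

        def neg_ll(lam):
            res = _gls_at_lambda(workspace, Xd, y, Xr, yr, lam)
            return np.inf if res is None else -res[2]

        if self.optimize_lambda:
            grid_vals = [(neg_ll(g), g) for g in self._GRID]
            grid_vals.sort()
            best_val, best_lam = grid_vals[0]
            k = self._GRID.index(best_lam)
            lo = self._GRID[max(0, k - 1)]
            hi = self._GRID[min(len(self._GRID) - 1, k + 1)]
            if hi > lo:
                opt = minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                                      options={"xatol": 1e-6})
                if opt.fun < best_val:
                    best_val, best_lam = float(opt.fun), float(opt.x)
            lam_hat = best_lam
        else:
            lam_hat = float(self.lam)
        res = _gls_at_lambda(workspace, Xd, y, Xr, yr, lam_hat)
        if res is None or not np.isfinite(res[2]):
            raise ValueError("non-finite likelihood at the optimum "
                             f"(lambda={lam_hat}, n={n})")
        beta, sigma2, loglik, xtwx_inv, rwr = res
        self.lambda_ = float(lam_hat)
        self.sigma2_ = float(sigma2)
        self.loglik_ = float(loglik)
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self.nobs_ = n
        df_resid = n - Xd.shape[1]
        sigma2_unbiased = rwr / df_resid if df_resid > 0 else np.nan
        se = np.sqrt(np.diag(xtwx_inv) * sigma2_unbiased)
        self.se_ = se[1:] if self.fit_intercept else se
        self.se_intercept_ = se[0] if self.fit_intercept else 0.0
        self.df_resid_ = df_resid
        fitted = Xd @ beta
        self.fitted_ = fitted
        if np.ptp(fitted) == 0:
            self.r2_ = 0.0
        else:
            self.r2_ = float(np.corrcoef(fitted, y)[0, 1] ** 2)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, len(self.coef_)) if len(self.coef_) else X.reshape(-1, 0)
        return self.intercept_ + (X @ self.coef_ if len(self.coef_) else 0.0)


def fit_ml(y, X, tree=None, V=None, workspace=None, optimize_lambda=True) -> PhylogeneticGLS:
    """Functional wrapper: fit a :class:`PhylogeneticGLS` and return it."""
    return PhylogeneticGLS(optimize_lambda=optimize_lambda).fit(
        X, y, tree=tree, V=V, workspace=workspace)


@dataclass
class LRTResult:
    statistic: float
    df: int
    pvalue: float


def lrt(full, restricted, df: int = 1, tol: float = 1e-4) -> LRTResult:
    """Likelihood-ratio test of nested PGLS fits: 2 (lnL_full - lnL_restr)
    against chi-square with ``df`` degrees of freedom."""
    l_full = full.loglik_ if hasattr(full, "loglik_") else float(full)
    l_res = restricted.loglik_ if hasattr(restricted, "loglik_") else float(restricted)
    stat = 2 * (l_full - l_res)
    if stat < -tol:
        raise ValueError(f"negative LRT statistic {stat:.3g}: optimization failure in the full model")
    stat = max(stat, 0.0)
    return LRTResult(stat, df, float(chi2.sf(stat, df)))


def bh_fdr(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up. Returns (reject boolean array, threshold),
    the threshold being the largest rejected p-value (0.0 when none)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return reject, threshold


def trait_correlation(x, y, tree=None, V=None, workspace=None):
    """Phylogenetically controlled correlation of two continuous traits.

    Fits y ~ x by PGLS with profiled lambda; R is the signed square root of
    the fit's R^2 and the p-value comes from the LRT against the
    intercept-only model (chi-square, 1 df).
    """
    x = np.asarray(x, dtype=float)
    full = fit_ml(y, x.reshape(-1, 1), tree=tree, V=V, workspace=workspace)
    null = fit_ml(y, None, tree=tree, V=V, workspace=workspace)
    test = lrt(full, null)
    r = float(np.sign(full.coef_[0]) * np.sqrt(full.r2_))
    return r, test.pvalue


def association_screen(matrix, traits: pd.DataFrame, tree, q: float = 0.05,
                       trait_cols=("genome_size_z", "gc_content_z", "enc_diff_z"),
                       min_discordant: int = 4):
    """Screen every tRNA species for independent trait associations.

    For each species with at least ``min_discordant`` organisms discordant
    from the majority, fits PGLS models with each single trait and each trait
    pair plus the intercept-only model, and records the LRTs of each trait
    against the null and of each trait added over each other single trait.
    All p-values are pooled into one Benjamini-Hochberg correction at level
    ``q``; trait X is called significant-and-independent for a species when
    every "X over Y" test survives. Returns ``(tests, calls, threshold)``:
    the per-test table, the per-(species, trait) call table with coefficient
    signs, and the data-dependent BH threshold.
    """
    organisms = matrix.organisms
    missing = [o for o in organisms if o not in traits.index]
    if missing:
        raise ValueError(f"organisms without traits: {missing[:5]}")
    T = traits.loc[organisms, list(trait_cols)].to_numpy(dtype=float)
    _, V = tree_vcv(read_newick(tree) if not isinstance(tree, TreeIndex) else tree,
                    tip_order=organisms)
    ws = GLSWorkspace(V)
    records = []
    fits_cache = {}
    for s_idx, species in enumerate(matrix.species):
        y = matrix.values[:, s_idx].astype(float)
        discordant = int(min(y.sum(), len(y) - y.sum()))
        if discordant <= min_discordant - 1:
            continue
        null = fit_ml(y, None, workspace=ws)
        singles = {}
        for t_idx, tname in enumerate(trait_cols):
            m = fit_ml(y, T[:, [t_idx]], workspace=ws)
            singles[tname] = m
            records.append(dict(species=species, trait=tname, over="(null)",
                                beta=float(m.coef_[0]), lam=m.lambda_, r2=m.r2_,
                                loglik=m.loglik_, p=lrt(m, null).pvalue))
        for (i, tx), (j, ty) in itertools.permutations(enumerate(trait_cols), 2):
            key = tuple(sorted((i, j)))
            if key not in fits_cache:
                fits_cache[key] = fit_ml(y, T[:, list(key)], workspace=ws)
            pair = fits_cache[key]
            bx = pair.coef_[list(key).index(i)]
            records.append(dict(species=species, trait=tx, over=ty,
                                beta=float(bx), lam=pair.lambda_, r2=pair.r2_,
                                loglik=pair.loglik_, p=lrt(pair, singles[ty]).pvalue))
        fits_cache.clear()
    tests = pd.DataFrame.from_records(records)
    if tests.empty:
        return tests, pd.DataFrame(columns=["species", "trait", "called", "sign"]), 0.0
    reject, threshold = bh_fdr(tests["p"].to_numpy(), q)
    tests["rejected"] = reject
    calls = []
    for (species, tname), grp in tests.groupby(["species", "trait"]):
        over = grp[grp["over"] != "(null)"]
        called = bool(len(over) and over["rejected"].all())
        single = grp[grp["over"] == "(null)"]
        sign = int(np.sign(single["beta"].iloc[0])) if len(single) else 0
        calls.append(dict(species=species, trait=tname, called=called, sign=sign))
    return tests, pd.DataFrame(calls), threshold


def variability_vs_association(var_associated, var_other):
    """Two-sided Mann-Whitney comparison of the variability measures of
    trait-associated vs non-associated species; None when a group is empty."""
    a = np.asarray(var_associated, dtype=float)
    b = np.asarray(var_other, dtype=float)
    if a.size == 0 or b.size == 0:
        return None
    return _mann_whitney(a, b)
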