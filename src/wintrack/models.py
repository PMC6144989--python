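"""Shared statistical machinery for the behavioral and selection models.

Covariate standardization, collinearity screening, mixed-effects model
fitting with a single random intercept (animal id), small-sample AIC
ranking, marginal r-squared, stratified k-fold cross-validated AUC, and
residual diagnostics.

Gaussian mixed models are fitted by maximum likelihood through
``statsmodels`` MixedLM.  Binomial (logistic) mixed models are fitted
here directly: the random intercept is integrated out with Gauss-
Hermite quadrature and the marginal likelihood maximized with BFGS.
This supports multiplicative observation weights on the log-likelihood,
which the used-available designs need to balance the 1:2 class ratio
(available-point weight = n_used/n_available, so both classes carry
equal total weight).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.numdiff import approx_hess


class Standardizer(TransformerMixin, BaseEstimator):
    """Column-wise z-scoring with stored means/SDs for later prediction.

    Errors on constant columns (naming them), since a zero-SD covariate
    cannot be standardized.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        self.means_ = X.mean()
        self.sds_ = X.std(ddof=1)
        bad = self.sds_[self.sds_ == 0]
        if len(bad):
            raise ValueError(f"zero-SD column(s): {list(bad.index)}")
        self.columns_ = list(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        return (X[self.columns_] - self.means_) / self.sds_

    def inverse_transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        Z = pd.DataFrame(Z)
        return Z[self.columns_] * self.sds_ + self.means_


def standardize(data: pd.DataFrame, columns: list[str]) -> tuple[pd.DataFrame, Standardizer]:
    """Z-score the named columns in place (copy); returns the fitted
    transformer for use on prediction data."""
    sc = Standardizer().fit(data[columns])
    out = data.copy()
    out[columns] = sc.transform(data[columns])
    return out, sc


def collinearity_screen(
    X: pd.DataFrame, r_threshold: float = 0.60, vif_threshold: float = 2.0
) -> dict:
    """Pairwise |r| and variance inflation factors for a design.

    Returns the correlation matrix, per-column VIF = 1/(1-R^2) from
    regressing each column on the others, and flags for any pair with
    |r| >= ``r_threshold`` or column with VIF >= ``vif_threshold``.
    """
    X = pd.DataFrame(X).astype(float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 columns to screen")
    corr = X.corr()
    Xc = X - X.mean()
    vifs = {}
    for col in X.columns:
        others = Xc.drop(columns=col).to_numpy()
        target = Xc[col].to_numpy()
        beta, res, rank, _ = np.linalg.lstsq(others, target, rcond=None)
        if rank < others.shape[1]:
            raise ValueError("singular design: perfectly collinear columns")
        rss = float(((target - others @ beta) ** 2).sum())
        tss = float((target**2).sum())
        if rss <= 1e-12 * max(tss, 1.0):
            vifs[col] = np.inf
        else:
            vifs[col] = tss / rss  # 1 / (1 - R^2)
    vifs = pd.Series(vifs)
    tri = corr.where(~np.eye(len(corr), dtype=bool)).abs()
    flagged_pairs = [
        (a, b)
        for a in corr.columns
        for b in corr.columns
        if a < b and tri.loc[a, b] >= r_threshold
    ]
    return {
        "correlations": corr,
        "vif": vifs,
        "flagged_pairs": flagged_pairs,
        "flagged_vif": list(vifs[vifs >= vif_threshold].index),
        "ok": not flagged_pairs and not (vifs >= vif_threshold).any(),
    }


@dataclass
class ModelSpec:
    """Declarative mixed-model specification.

    ``terms`` are patsy-style fixed-effect terms ("canopy",
    "intensity:area", "C(area_period)"); the random part is a single
    intercept grouped by ``group``.
    """

    response: str
    terms: list[str]
    group: str
    family: str = "gaussian"  # or "binomial"
    weights: str | None = None
    label: str | None = None

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{self.response} ~ {rhs}"

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError("family must be 'gaussian' or 'binomial'")


@dataclass
class FitResult:
    """A fitted mixed model, with everything AICc ranking and
    cross-validation need."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame  # columns lower, upper
    loglik: float
    k: int
    n: int
    random_var: float
    resid_var: float | None
    converged: bool
    design_info: object = field(repr=False, default=None)
    fitted_fixed: np.ndarray | None = field(repr=False, default=None)
    endog: np.ndarray | None = field(repr=False, default=None)
    response_checksum: float = 0.0

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)

    @property
    def random_sd(self) -> float:
        return float(np.sqrt(self.random_var))

    def design(self, data: pd.DataFrame) -> np.ndarray:
        (X,) = patsy.build_design_matrices([self.design_info], data)
        return np.asarray(X)

    def predict_fixed(self, data: pd.DataFrame) -> np.ndarray:
        """Population-level (fixed-effects-only) prediction: the mean
        for gaussian models, the probability for binomial models."""
        eta = self.design(data) @ self.params.to_numpy()
        return expit(eta) if self.spec.family == "binomial" else eta


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# binomial GLMM via Gauss-Hermite quadrature


def _node_pieces(theta, X, y, codes, n_groups, weights, nodes):
    """Per-node linear predictors and per-group complete-data logliks,
    vectorized over the quadrature nodes (rows of the returned arrays)."""
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    eta = (X @ beta)[None, :] + (np.sqrt(2.0) * sigma * nodes)[:, None]
    ll_i = weights[None, :] * (y[None, :] * eta - np.logaddexp(0.0, eta))
    K = len(nodes)
    group_ll = np.empty((K, n_groups))
    for k in range(K):
        group_ll[k] = np.bincount(codes, ll_i[k], minlength=n_groups)
    return sigma, eta, group_ll


def _binomial_loglik(theta, X, y, codes, n_groups, weights, nodes, lognorm):
    _, _, group_ll = _node_pieces(theta, X, y, codes, n_groups, weights, nodes)
    return float(logsumexp(group_ll + lognorm[:, None], axis=0).sum())


def _binomial_loglik_grad(theta, X, y, codes, n_groups, weights, nodes, lognorm):
    """Marginal log-likelihood and its analytic gradient in (beta, log sigma).

    d/d theta of log sum_k exp(A_gk) is the softmax-weighted sum of the
    per-node complete-data score contributions.
    """
    sigma, eta, group_ll = _node_pieces(theta, X, y, codes, n_groups, weights, nodes)
    A = group_ll + lognorm[:, None]
    Amax = A.max(axis=0)
    soft = np.exp(A - Amax)
    norm = soft.sum(axis=0)
    soft /= norm  # (K, G) node responsibilities per group
    ll = float((Amax + np.log(norm)).sum())
    # observation-level mixture weight = its group's responsibility
    resid = weights[None, :] * (y[None, :] - expit(eta))
    wk = soft[:, codes] * resid  # (K, n)
    wsum = wk.sum(axis=0)
    grad_beta = X.T @ wsum
    grad_ls = np.sqrt(2.0) * sigma * (nodes @ wk.sum(axis=1))
    return ll, np.append(grad_beta, grad_ls)


def _binomial_group_scores(theta, X, y, codes, n_groups, weights, nodes, lognorm):
    """Per-group score vectors d log L_g / d theta at theta (for the
    cluster-robust sandwich)."""
    sigma, eta, group_ll = _node_pieces(theta, X, y, codes, n_groups, weights, nodes)
    A = group_ll + lognorm[:, None]
    soft = np.exp(A - A.max(axis=0))
    soft /= soft.sum(axis=0)
    p = X.shape[1]
    resid = weights[None, :] * (y[None, :] - expit(eta))
    wk = soft[:, codes] * resid  # (K, n)
    wsum = wk.sum(axis=0)
    scores = np.zeros((n_groups, p + 1))
    for j in range(p):
        scores[:, j] = np.bincount(codes, wsum * X[:, j], minlength=n_groups)
    scores[:, p] = np.sqrt(2.0) * sigma * np.array(
        [np.bincount(codes, wk[k], minlength=n_groups) for k in range(len(nodes))]
    ).T @ nodes
    return scores


def fit_binomial_glmm(
    X: np.ndarray,
    y: np.ndarray,
    groups,
    weights: np.ndarray | None = None,
    n_quad: int = 25,
    cluster_robust: bool = False,
) -> dict:
    """ML fit of a random-intercept logistic model.

    logit P(y=1) = X beta + b_g, b_g ~ N(0, sigma^2); the marginal
    likelihood integrates b_g with ``n_quad``-node Gauss-Hermite
    quadrature.  ``weights`` multiply each observation's log-likelihood
    term.  Returns coefficient estimates, Wald standard errors from the
    numerical Hessian, sigma^2 and the maximized log-likelihood.

    ``cluster_robust`` replaces the model-based standard errors with an
    estimator clustered on the grouping factor: ``"sandwich"`` (or
    True) for the score sandwich with a G/(G-1) factor, ``"jackknife"``
    for the delete-one-cluster jackknife (less downward-biased when G
    is small).  Use these when observations within a group are serially
    dependent beyond the shared intercept -- e.g. autocorrelated GPS
    fixes of one animal -- where model-based SEs are badly
    anticonservative.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial response must be 0/1")
    if y.min() == y.max():
        raise ValueError("degenerate response: only one class present")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    codes, uniques = pd.factorize(np.asarray(groups))
    n_groups = len(uniques)
    nodes, quad_w = np.polynomial.hermite.hermgauss(n_quad)
    lognorm = np.log(quad_w) - 0.5 * np.log(np.pi)

    # start from the independence (GLM) fit
    p = X.shape[1]
    try:
        import statsmodels.api as sm

        glm = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit()
        beta0 = np.asarray(glm.params)
    except Exception:
        beta0 = np.zeros(p)
    x0 = np.append(beta0, np.log(0.3))

    def neg(theta):
        ll, grad = _binomial_loglik_grad(theta, X, y, codes, n_groups, w, nodes, lognorm)
        return -ll, -grad

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            neg, x0, jac=True, method="BFGS", options={"gtol": 1e-6, "maxiter": 500}
        )
    theta = res.x
    H = approx_hess(
        theta, lambda th: -_binomial_loglik(th, X, y, codes, n_groups, w, nodes, lognorm)
    )
    try:
        cov = np.linalg.inv(H)
        if cluster_robust == "jackknife":
            jk = np.empty((n_groups, p))
            for g in range(n_groups):
                keep = codes != g
                kcodes = pd.factorize(codes[keep])[0]

                def neg_g(th, keep=keep, kcodes=kcodes):
                    ll, grad = _binomial_loglik_grad(
                        th, X[keep], y[keep], kcodes, n_groups - 1, w[keep], nodes, lognorm
                    )
                    return -ll, -grad

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rg = optimize.minimize(
                        neg_g, theta, jac=True, method="BFGS",
                        options={"gtol": 1e-4, "maxiter": 100},
                    )
                jk[g] = rg.x[:p]
            dev = jk - jk.mean(axis=0)
            cov_beta = (dev.T @ dev) * (n_groups - 1) / n_groups
            cov = cov.copy()
            cov[:p, :p] = cov_beta
        elif cluster_robust:
            S = _binomial_group_scores(theta, X, y, codes, n_groups, w, nodes, lognorm)
            B = (S.T @ S) * n_groups / max(n_groups - 1, 1)
            cov = cov @ B @ cov
        bse = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
        cov_ok = np.isfinite(bse).all()
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)
        cov_ok = False
    return {
        "beta": theta[:p],
        "bse": bse,
        "sigma2": float(np.exp(theta[-1]) ** 2),
        "loglik": float(-res.fun),
        "converged": bool(res.success or (np.linalg.norm(res.jac) < 1e-2)) and cov_ok,
        "n_groups": n_groups,
        "ci_df": (n_groups - 1) if cluster_robust else None,
    }


# ---------------------------------------------------------------------------
# unified fitting front-end


def fit_mixed(
    spec: ModelSpec,
    data: pd.DataFrame,
    n_quad: int = 25,
    cluster_robust: bool = False,
) -> FitResult:
    """Fit a mixed model per ``spec``.

    Gaussian: ML (not REML) linear mixed model via statsmodels; the
    parameter count k = fixed effects + random-intercept variance +
    residual variance.  Binomial: Gauss-Hermite ML logistic GLMM
    (k = fixed effects + random-intercept variance), with optional
    observation weights and optionally cluster-robust (by group)
    standard errors whose Wald CIs then use a t(G-1) critical value.
    A non-convergent fit is returned flagged; :func:`rank_aicc`
    excludes it with a warning.
    """
    if spec.group not in data.columns:
        raise ValueError(f"grouping column {spec.group!r} not in data")
    y_df, X_df = patsy.dmatrices(spec.formula, data, return_type="dataframe")
    y = np.asarray(y_df).ravel()
    X = np.asarray(X_df)
    names = list(X_df.columns)
    n = len(y)
    groups = data[spec.group].loc[X_df.index]

    ci_df = None
    if spec.family == "gaussian":
        if spec.weights is not None:
            raise ValueError("observation weights are only supported for binomial fits")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = MixedLM(y, X, groups=np.asarray(groups)).fit(reml=False)
        beta = np.asarray(fit.fe_params)
        bse = np.asarray(fit.bse_fe)
        random_var = float(np.asarray(fit.cov_re)[0, 0])
        resid_var = float(fit.scale)
        loglik = float(fit.llf)
        if not (np.isfinite(loglik) and np.isfinite(beta).all()):
            # variance boundary (random SD ~ 0): the ML solution is the
            # ordinary regression; statsmodels returns llf = inf there
            import statsmodels.api as sm

            ols = sm.OLS(y, X).fit()
            beta = np.asarray(ols.params)
            bse = np.asarray(ols.bse)
            random_var = 0.0
            resid_var = float(ols.ssr / n)
            loglik = float(ols.llf)
        k = X.shape[1] + 2
        converged = bool(np.isfinite(beta).all() and np.isfinite(loglik))
    else:
        w = None if spec.weights is None else data[spec.weights].loc[X_df.index].to_numpy()
        res = fit_binomial_glmm(
            X, y, np.asarray(groups), w, n_quad=n_quad, cluster_robust=cluster_robust
        )
        beta, bse = res["beta"], res["bse"]
        random_var = res["sigma2"]
        resid_var = None
        loglik = res["loglik"]
        k = X.shape[1] + 1
        converged = res["converged"]
        ci_df = res["ci_df"]

    z = stats.norm.ppf(0.975) if ci_df is None else stats.t.ppf(0.975, ci_df)
    params = pd.Series(beta, index=names)
    bse_s = pd.Series(bse, index=names)
    ci = pd.DataFrame(
        {"lower": params - z * bse_s, "upper": params + z * bse_s}, index=names
    )
    return FitResult(
        spec=spec,
        params=params,
        bse=bse_s,
        conf_int=ci,
        loglik=loglik,
        k=k,
        n=n,
        random_var=random_var,
        resid_var=resid_var,
        converged=converged,
        design_info=X_df.design_info,
        fitted_fixed=X @ beta,
        endog=y,
        response_checksum=float(np.sum(y) + 0.001 * n),
    )


def rank_aicc(fits: list[FitResult]) -> pd.DataFrame:
    """AICc ranking table (ascending) with delta-AICc to the best model.

    All fits must be on identical data rows (checked via n and a
    response checksum); non-converged fits are dropped with a warning.
    """
    if not fits:
        raise ValueError("no fits to rank")
    ref = fits[0]
    for f in fits[1:]:
        if f.n != ref.n or f.response_checksum != ref.response_checksum:
            raise ValueError("fits are not on identical data rows")
    usable = []
    for f in fits:
        if f.converged:
            usable.append(f)
        else:
            warnings.warn(f"dropping non-converged fit {f.spec.label or f.spec.formula!r}")
    if not usable:
        raise ValueError("no converged fits to rank")
    rows = pd.DataFrame(
        {
            "label": [f.spec.label or f.spec.formula for f in usable],
            "k": [f.k for f in usable],
            "loglik": [f.loglik for f in usable],
            "aicc": [f.aicc for f in usable],
        }
    ).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    rows["delta_aicc"] = rows["aicc"] - rows["aicc"].iloc[0]
    order = np.argsort([f.aicc for f in usable], kind="stable")
    rows["fit"] = [usable[i] for i in order]
    return rows


def marginal_r2(fit: FitResult) -> float:
    """Fixed-effects variance share of a gaussian mixed model:
    var(X beta) / (var(X beta) + random var + residual var)."""
    if fit.spec.family != "gaussian":
        raise ValueError("marginal r2 is defined here for gaussian fits only")
    vf = float(np.var(fit.fitted_fixed))
    denom = vf + fit.random_var + (fit.resid_var or 0.0)
    return 0.0 if denom == 0 else vf / denom


def auc_rank(y_true, scores) -> float:
    """AUC as the Wilcoxon rank-sum probability: the chance a random
    positive outscores a random negative (ties count 1/2)."""
    return float(roc_auc_score(np.asarray(y_true), np.asarray(scores)))


def cv_auc(
    spec: ModelSpec, data: pd.DataFrame, k: int = 5, seed: int = 0, n_quad: int = 25
) -> dict:
    """Stratified k-fold cross-validated AUC for a binomial spec.

    Refits the model on k-1 folds, scores the held-out fold with
    fixed-effects predictions, and reports per-fold AUC with mean/SD.
    A fold with a single class triggers a reshuffle with a new seed.
    """
    if spec.family != "binomial":
        raise ValueError("cv_auc requires a binomial spec")
    y = data[spec.response].to_numpy()
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        aucs = []
        ok = True
        for train, test in skf.split(np.zeros(len(y)), y):
            if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
                ok = False
                break
            fit = fit_mixed(spec, data.iloc[train], n_quad=n_quad)
            scores = fit.predict_fixed(data.iloc[test])
            aucs.append(auc_rank(y[test], scores))
        if ok:
            break
        warnings.warn("single-class fold; refolding with a new seed")
    return {
        "fold_auc": np.asarray(aucs),
        "mean": float(np.mean(aucs)),
        "sd": float(np.std(aucs, ddof=1)),
    }


def diagnostics(fit: FitResult) -> dict:
    """Residual diagnostics for a gaussian fit: residuals against
    fixed-effect fitted values, normal Q-Q correlation, and a
    Shapiro-Wilk statistic for reporting."""
    if fit.spec.family != "gaussian":
        raise ValueError("diagnostics are for gaussian fits")
    resid = fit.endog - fit.fitted_fixed
    n = len(resid)
    srt = np.sort((resid - resid.mean()) / (resid.std() or 1.0))
    qq_theor = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    qq_corr = float(np.corrcoef(srt, qq_theor)[0, 1]) if n > 2 else np.nan
    sub = resid if n <= 4999 else np.random.default_rng(0).choice(resid, 4999, replace=False)
    sw_stat, sw_p = (stats.shapiro(sub) if n >= 3 else (np.nan, np.nan))
    return {
        "residuals": resid,
        "fitted": fit.fitted_fixed,
        "qq_correlation": qq_corr,
        "shapiro_stat": float(sw_stat),
        "shapiro_p": float(sw_p),
    }
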