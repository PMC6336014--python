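"""Seed-coat and seed-morphology statistics across dormancy categories.

Kruskal-Wallis on testa thickness, proportional-odds ordinal logistic
regression of the dormancy category (ordered D < R < N, increasing
germination propensity) on seed morphology with AIC model ranking, and
AN(C)OVA of the soluble/insoluble proanthocyanidin ratio with total PA as
covariate, including the custom D+R vs N contrast on least-squares means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.miscmodels.ordinal_model import OrderedModel

__all__ = [
    "kruskal_wallis",
    "median_ci",
    "ProportionalOddsModel",
    "ordinal_logistic",
    "ancova_ratio",
    "AncovaResult",
    "CATEGORY_ORDER",
]

CATEGORY_ORDER = ("D", "R", "N")  # increasing germination propensity


@dataclass
class KruskalResult:
    h: float
    df: int
    p: float


def kruskal_wallis(values, groups) -> KruskalResult:
    """Rank-based Kruskal-Wallis H with tie correction, chi-square p."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(values) == 0:
        return KruskalResult(0.0, len(samples) - 1, 1.0)
    h, p = stats.kruskal(*samples)
    return KruskalResult(float(h), len(samples) - 1, float(p))


def median_ci(x, confidence=0.95):
    """Distribution-free CI of the median from binomial order statistics."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    med = float(np.median(x))
    if n < 6:
        return med, (x[0], x[-1])
    lo = stats.binom.ppf((1 - confidence) / 2, n, 0.5)
    hi = stats.binom.isf((1 - confidence) / 2, n, 0.5)
    lo_i = int(np.clip(lo, 0, n - 1))
    hi_i = int(np.clip(hi, 0, n - 1))
    return med, (float(x[lo_i]), float(x[hi_i]))


class ProportionalOddsModel(BaseEstimator):
    """Proportional-odds ordinal logistic regression (ML via statsmodels).

    ``fit(X, y)`` takes covariates X and an ordered categorical / integer
    response y.  Attributes: ``coef_`` (covariate effects), ``thresholds_``,
    ``se_``, ``pvalues_``, ``aic_``, ``llf_``, ``converged_``.  With a binary
    response the model collapses to ordinary logistic regression.
    """

    def __init__(self, categories=None):
        self.categories = categories

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if not np.all(np.isfinite(X)):
            raise ValueError("missing covariate values")
        cats = list(self.categories) if self.categories is not None else None
        if cats is None:
            y_arr = np.asarray(y)
            cats = sorted(pd.unique(y_arr).tolist())
        y_ord = pd.Categorical(np.asarray(y), categories=cats, ordered=True)
        if y_ord.isna().any():
            raise ValueError("response contains values outside the category set")
        model = OrderedModel(y_ord.codes.astype(int), X, distr="logit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="bfgs", maxiter=500, disp=False)
        self.converged_ = bool(res.mle_retvals.get("converged", True))
        if not self.converged_:
            warnings.warn(
                "ordinal logistic fit did not converge (possible complete "
                "separation); estimates unreliable",
                UserWarning,
                stacklevel=2,
            )
        k = X.shape[1]
        self.coef_ = np.asarray(res.params[:k])
        self.thresholds_ = np.asarray(model.transform_threshold_params(res.params)[1:-1])
        self.se_ = np.asarray(res.bse[:k])
        self.pvalues_ = np.asarray(res.pvalues[:k])
        self.llf_ = float(res.llf)
        self.aic_ = float(res.aic)
        self.n_params_ = len(res.params)
        self.categories_ = cats
        self._res = res
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self._res.model.predict(self._res.params, exog=X)


def ordinal_logistic(response, covariates: pd.DataFrame, models=None,
                     categories=CATEGORY_ORDER) -> pd.DataFrame:
    """Fit one proportional-odds model per covariate set and rank by AIC.

    ``models`` is a dict name -> list of covariate columns; default is one
    simple model per covariate plus the full multiple model.  Returns a
    DataFrame sorted by AIC with per-covariate coefficients and Wald p.
    """
    if models is None:
        models = {c: [c] for c in covariates.columns}
        if len(covariates.columns) > 1:
            models["multiple"] = list(covariates.columns)
    rows = []
    for name, cols in models.items():
        fit = ProportionalOddsModel(categories=categories).fit(
            covariates[cols].to_numpy(), response
        )
        for c, beta, se, p in zip(cols, fit.coef_, fit.se_, fit.pvalues_):
            rows.append({"model": name, "covariate": c, "beta": beta,
                         "se": se, "p": p, "aic": fit.aic_,
                         "loglik": fit.llf_, "converged": fit.converged_})
    return pd.DataFrame(rows).sort_values(["aic", "model"]).reset_index(drop=True)


@dataclass
class AncovaResult:
    f_category: float
    p_category: float
    f_covariate: float
    p_covariate: float
    ls_means: pd.DataFrame
    contrast_f: float
    contrast_p: float
    anova_f_category: float  # covariate-free model
    anova_p_category: float


def ancova_ratio(ratio, category, covariate, contrast=None,
                 confidence=0.95) -> AncovaResult:
    """AN(C)OVA of the sPA/inPA ratio across dormancy categories.

    Fits ``ratio ~ category + covariate`` with type-III F tests, computes
    least-squares means (predictions at the covariate grand mean) with CIs,
    and tests an optional contrast on the LS means (dict category -> weight,
    e.g. ``{"D": .5, "R": .5, "N": -1}`` for D+R vs N) via the Wald F of the
    corresponding linear combination.  Also reports the covariate-free ANOVA.
    """
    import statsmodels.api as sm

    ratio = np.asarray(ratio, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariate must be finite")
    cat = pd.Categorical(np.asarray(category))
    levels = list(cat.categories)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 categories")
    counts = pd.Series(category).value_counts()
    if (counts < 2).any():
        warnings.warn("category with a single observation; CIs suppressed",
                      UserWarning, stacklevel=2)
    # cell-means coding: one column per category + centered covariate; the
    # category F is then the type-III test of equal adjusted means
    Dmat = np.zeros((len(ratio), k))
    Dmat[np.arange(len(ratio)), cat.codes] = 1.0
    covc = cov - cov.mean()
    X = np.column_stack([Dmat, covc])
    fit = sm.OLS(ratio, X).fit()
    # H0: all category means equal -> (k-1) contrasts
    Rc = np.zeros((k - 1, k + 1))
    for i in range(k - 1):
        Rc[i, i], Rc[i, i + 1] = 1.0, -1.0
    ftest = fit.f_test(Rc)
    f_cat, p_cat = float(ftest.fvalue), float(ftest.pvalue)
    Rcov = np.zeros((1, k + 1))
    Rcov[0, k] = 1.0
    fcov = fit.f_test(Rcov)

    # LS means: category coefficient = prediction at covariate grand mean
    tcrit = stats.t.ppf(0.5 + confidence / 2, fit.df_resid)
    cov_params = fit.cov_params()
    ls_rows = []
    for i, lev in enumerate(levels):
        est = fit.params[i]
        se = np.sqrt(cov_params[i, i])
        ls_rows.append({"category": lev, "ls_mean": est,
                        "ci_low": est - tcrit * se, "ci_high": est + tcrit * se})
    ls_means = pd.DataFrame(ls_rows)

    contrast_f = contrast_p = np.nan
    if contrast is not None:
        w = np.zeros(k + 1)
        for lev, wt in contrast.items():
            w[levels.index(lev)] = wt
        ct = fit.f_test(w[None, :])
        contrast_f, contrast_p = float(ct.fvalue), float(ct.pvalue)

    fit0 = sm.OLS(ratio, Dmat).fit()
    ft0 = fit0.f_test(Rc[:, :k])
    return AncovaResult(
        f_category=f_cat,
        p_category=p_cat,
        f_covariate=float(fcov.fvalue),
        p_covariate=float(fcov.pvalue),
        ls_means=ls_means,
        contrast_f=contrast_f,
        contrast_p=contrast_p,
        anova_f_category=float(ft0.fvalue),
        anova_p_category=float(ft0.pvalue),
    )
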