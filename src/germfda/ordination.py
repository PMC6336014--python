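"""Ordination of the germination descriptor matrix.

Unstandardized (covariance) PCA of the B-spline coefficient matrix, whose
first axis orders accessions along a dormant -> non-dormant gradient
("germination responsivity"); spatially corrected correlations of
environmental variables with the axes; redundancy analysis (RDA) with
Ezekiel-adjusted R2, Monte Carlo permutation tests, forward selection with
double stopping, Benjamini-Hochberg FDR, and pure/shared variance
partitioning between an environmental and a spatial (PCNM) predictor set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .spatial import dutilleul_modified_t

__all__ = [
    "collinearity_prune",
    "UnstandardizedPCA",
    "pca_unstandardized",
    "axis_env_correlations",
    "RDA",
    "rda_adjusted_r2",
    "permutation_test",
    "forward_select",
    "fdr_bh",
    "variance_partition",
    "PartitionResult",
]


def collinearity_prune(env: pd.DataFrame, threshold=0.90):
    """Greedily drop variables until no pairwise |Pearson r| >= threshold.

    At each step the worst-correlated pair is found and its member with the
    larger mean absolute correlation to all remaining variables is removed.
    Constant columns are removed first (their correlations are undefined).
    Returns (pruned DataFrame, removal log as list of dicts).
    """
    env = env.copy()
    if env.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    log = []
    for col in list(env.columns):
        if env[col].nunique() <= 1:
            warnings.warn(f"constant variable {col!r} removed", UserWarning, stacklevel=2)
            log.append({"removed": col, "reason": "constant", "pair": None, "r": np.nan})
            env = env.drop(columns=col)
    while env.shape[1] >= 2:
        C = env.corr().to_numpy()
        np.fill_diagonal(C, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(C)), C.shape)
        r = C[i, j]
        if abs(r) < threshold:
            break
        mean_abs = np.abs(env.corr().to_numpy() - np.eye(env.shape[1])).mean(axis=0)
        drop = i if mean_abs[i] >= mean_abs[j] else j
        a, b = env.columns[i], env.columns[j]
        removed = env.columns[drop]
        log.append({"removed": removed, "reason": "collinear",
                    "pair": (a, b), "r": float(r)})
        env = env.drop(columns=removed)
    return env, log


class UnstandardizedPCA(BaseEstimator, TransformerMixin):
    """Covariance-based PCA (column-centered, not scaled).

    Deterministic sign convention: each axis is oriented so that its
    largest-magnitude loading is positive.

    Attributes: ``components_`` (axes x variables loadings), ``scores_``,
    ``eigenvalues_``, ``explained_variance_ratio_``, ``mean_``.
    """

    def __init__(self, n_components=None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("need a 2-D matrix with >= 2 rows and columns")
        if not np.all(np.isfinite(X)):
            raise ValueError("missing values in PCA input")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        if s[0] == 0:
            raise ValueError("rank-0 matrix")
        eig = s**2 / (X.shape[0] - 1)
        k = self.n_components or len(s)
        # sign convention: largest-|loading| positive per axis
        for j in range(Vt.shape[0]):
            i = np.argmax(np.abs(Vt[j]))
            if Vt[j, i] < 0:
                Vt[j] = -Vt[j]
                U[:, j] = -U[:, j]
        self.components_ = Vt[:k]
        self.eigenvalues_ = eig[:k]
        self.explained_variance_ratio_ = (eig / eig.sum())[:k]
        self.scores_ = (U * s)[:, :k]
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_.T

    def fit_transform(self, X, y=None):
        return self.fit(X).scores_


def pca_unstandardized(matrix, n_components=None) -> UnstandardizedPCA:
    return UnstandardizedPCA(n_components=n_components).fit(matrix)


def axis_env_correlations(scores, env: pd.DataFrame, coords, axes=(0, 1),
                          classes=None) -> pd.DataFrame:
    """Correlate ordination axes with supplementary environmental variables.

    For every variable x axis: Pearson r, classical t-test p, and the
    Dutilleul spatially corrected p (with its effective sample size).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if len(env) != scores.shape[0]:
        raise ValueError(
            f"mismatched accession sets: {len(env)} env rows vs {scores.shape[0]} scores"
        )
    rows = []
    for var in env.columns:
        x = env[var].to_numpy(dtype=float)
        for ax in axes:
            res = dutilleul_modified_t(x, scores[:, ax], coords=coords, classes=classes)
            rows.append({
                "variable": var,
                "axis": f"PC{ax + 1}",
                "r": res.r,
                "p_classical": res.p_classical,
                "p_corrected": res.p_corrected,
                "effective_n": res.effective_n,
            })
    return pd.DataFrame(rows)


def _drop_aliased(X: np.ndarray):
    """QR-based removal of linearly dependent columns; returns kept indices."""
    if X.shape[1] == 0:
        return X, np.array([], dtype=int)
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return X, np.arange(X.shape[1])
    keep = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    warnings.warn(
        f"dropped {X.shape[1] - len(keep)} aliased predictor column(s)",
        UserWarning,
        stacklevel=3,
    )
    return X[:, keep], np.array(keep, dtype=int)


def _hat_fit(Y, X):
    """Fitted values of each Y column on X (with intercept via centering)."""
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return X @ coef


class RDA(BaseEstimator):
    """Redundancy analysis: multivariate regression followed by PCA of fits.

    ``fit(X, Y)`` centers Y and the predictors; with ``covariates`` both Y
    and X are first residualized on the covariates (partial RDA).  R2 is the
    fraction of the (residual) total sum of squares captured by the fitted
    values, adjusted by Ezekiel's formula ``1 - (1 - R2)(n - 1)/(n - p - 1)``.

    Attributes: ``r2_``, ``adjusted_r2_``, ``f_``, ``n_``, ``p_``,
    ``canonical_axes_`` (site scores on constrained axes), ``kept_columns_``.
    """

    def __init__(self, covariates=None):
        self.covariates = covariates

    def fit(self, X, Y):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = Y.shape[0]
        Yc = Y - Y.mean(axis=0)
        Xc = X - X.mean(axis=0)
        q = 0
        if self.covariates is not None:
            Z = np.asarray(self.covariates, dtype=float)
            if Z.ndim == 1:
                Z = Z[:, None]
            Zc = Z - Z.mean(axis=0)
            Zc, _ = _drop_aliased(Zc)
            q = Zc.shape[1]
            Yc = Yc - _hat_fit(Yc, Zc)
            Xc = Xc - _hat_fit(Xc, Zc)
        Xc, keep = _drop_aliased(Xc)
        p = Xc.shape[1]
        fitted = _hat_fit(Yc, Xc) if p else np.zeros_like(Yc)
        ss_tot = float(np.sum(Yc**2))
        ss_fit = float(np.sum(fitted**2))
        r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0
        df_res = n - p - q - 1
        if df_res < 1:
            warnings.warn("too few residual df for adjusted R2", UserWarning, stacklevel=2)
            adj = np.nan
        else:
            adj = 1.0 - (1.0 - r2) * (n - q - 1) / df_res
        self.n_, self.p_, self.q_ = n, p, q
        self.r2_ = r2
        self.adjusted_r2_ = float(adj)
        denom_df = max(df_res, 1)
        self.f_ = (r2 / max(p, 1)) / max((1 - r2) / denom_df, 1e-300)
        U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
        self.canonical_axes_ = U * s
        self.canonical_eigenvalues_ = s**2 / max(n - 1, 1)
        self.kept_columns_ = keep
        self._Yc, self._Xc = Yc, Xc
        return self


def rda_adjusted_r2(Y, X, covariates=None) -> RDA:
    return RDA(covariates=covariates).fit(X, Y)


def _f_stat(Y, X, n, q=0):
    p = X.shape[1]
    fitted = _hat_fit(Y, X)
    ss_tot = float(np.sum(Y**2))
    ss_fit = float(np.sum(fitted**2))
    r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0
    df_res = max(n - p - q - 1, 1)
    return (r2 / max(p, 1)) / max((1 - r2) / df_res, 1e-300), r2


def permutation_test(fit: RDA, n_permutations=999, seed=None) -> float:
    """Monte Carlo permutation p-value for an RDA fit.

    Rows of (residualized) Y are permuted — Freedman-Lane style under a
    partial model, where the permuted quantity is already the reduced-model
    residual; p = (1 + #{F* >= F}) / (1 + n_permutations).
    """
    rng = np.random.default_rng(seed)
    Y, X = fit._Yc, fit._Xc
    n = fit.n_
    f_obs, _ = _f_stat(Y, X, n, fit.q_)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        f_p, _ = _f_stat(Y[perm], X, n, fit.q_)
        if f_p >= f_obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_permutations)


def forward_select(Y, candidates: pd.DataFrame, alpha=0.05, n_permutations=999,
                   seed=None, r2_cap=True):
    """Forward selection of RDA predictors with double stopping.

    At each step the candidate raising R2 the most is tested by permutation
    (conditional on the already-selected set); selection stops when its p
    exceeds ``alpha`` or when the cumulative adjusted R2 would exceed the
    adjusted R2 of the model with all candidates (the double-stopping
    criterion).  Returns a DataFrame of the ordered selections with their
    p-values and cumulative adjusted R2.
    """
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    names = list(candidates.columns)
    if not names:
        raise ValueError("need at least one candidate")
    X_all = candidates.to_numpy(dtype=float)
    full_adj = rda_adjusted_r2(Y, X_all).adjusted_r2_
    selected: list[int] = []
    rows = []
    while len(selected) < len(names):
        remaining = [j for j in range(len(names)) if j not in selected]
        best_j, best_r2 = None, -np.inf
        for j in remaining:
            r2 = rda_adjusted_r2(Y, X_all[:, selected + [j]]).r2_
            if r2 > best_r2:
                best_j, best_r2 = j, r2
        cov = X_all[:, selected] if selected else None
        fit = rda_adjusted_r2(Y, X_all[:, [best_j]], covariates=cov)
        p = permutation_test(fit, n_permutations, seed=rng.integers(2**31 - 1))
        cum_adj = rda_adjusted_r2(Y, X_all[:, selected + [best_j]]).adjusted_r2_
        if p > alpha:
            break
        selected.append(best_j)
        rows.append({"variable": names[best_j], "p": p,
                     "cumulative_r2": best_r2, "cumulative_adjusted_r2": cum_adj})
        # double stopping: a significant variable is kept, but once the
        # cumulative adjusted R2 reaches the full-candidate-model level any
        # further addition would only chase noise
        if r2_cap and cum_adj > full_adj + 1e-12:
            break
    return pd.DataFrame(rows, columns=["variable", "p", "cumulative_r2",
                                       "cumulative_adjusted_r2"])


def fdr_bh(p_values):
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PartitionResult:
    """Pure/shared adjusted-R2 decomposition of two predictor sets."""

    adj_x1: float
    adj_x2: float
    adj_combined: float
    pure_x1: float
    pure_x2: float
    shared: float
    unexplained: float
    p_pure_x1: float = field(default=np.nan)
    p_pure_x2: float = field(default=np.nan)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("pure X1 (env)", self.pure_x1, self.p_pure_x1),
                ("pure X2 (space)", self.pure_x2, self.p_pure_x2),
                ("shared", self.shared, np.nan),
                ("unexplained", self.unexplained, np.nan),
            ],
            columns=["fraction", "adjusted_r2", "p"],
        )


def variance_partition(Y, X1, X2, n_permutations=999, seed=None) -> PartitionResult:
    """Partition adjusted explained variation between two predictor sets.

    pure(X1) = adj(X1 u X2) - adj(X2); shared = adj(X1) + adj(X2) -
    adj(X1 u X2); the pure fractions are tested by partial-RDA permutation
    (the shared fraction has no permutation test).
    """
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    if X1.ndim == 1:
        X1 = X1[:, None]
    if X2.ndim == 1:
        X2 = X2[:, None]
    if X1.shape[1] and X2.shape[1]:
        joined = {tuple(np.round(c, 12)) for c in X1.T}
        if any(tuple(np.round(c, 12)) in joined for c in X2.T):
            warnings.warn("X1 and X2 share identical columns", UserWarning, stacklevel=2)
    if X2.shape[1] == 0:
        a1 = rda_adjusted_r2(Y, X1).adjusted_r2_
        return PartitionResult(a1, 0.0, a1, a1, 0.0, 0.0, 1 - a1)
    if X1.shape[1] == 0:
        a2 = rda_adjusted_r2(Y, X2).adjusted_r2_
        return PartitionResult(0.0, a2, a2, 0.0, a2, 0.0, 1 - a2)
    a1 = rda_adjusted_r2(Y, X1).adjusted_r2_
    a2 = rda_adjusted_r2(Y, X2).adjusted_r2_
    a12 = rda_adjusted_r2(Y, np.hstack([X1, X2])).adjusted_r2_
    pure1, pure2 = a12 - a2, a12 - a1
    shared = a1 + a2 - a12
    f1 = rda_adjusted_r2(Y, X1, covariates=X2)
    f2 = rda_adjusted_r2(Y, X2, covariates=X1)
    p1 = permutation_test(f1, n_permutations, seed=rng.integers(2**31 - 1))
    p2 = permutation_test(f2, n_permutations, seed=rng.integers(2**31 - 1))
    return PartitionResult(a1, a2, a12, pure1, pure2, shared, 1 - a12, p1, p2)
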