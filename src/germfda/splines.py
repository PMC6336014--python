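"""Penalized B-spline smoothing engine.

The germination curve of an accession is modelled as a spline
``s(t) = sum_j c_j B_j(t)`` on a clamped B-spline basis, fitted by
penalized least squares::

    min_c  sum_i (y_i - s(t_i))^2  +  lam * int_a^b (s^(m)(t))^2 dt

with ``m`` the penalty derivative order (1 for germination curves, where
roughness of the cumulative count itself is penalized; 2 for scatterplot
smoothing, where curvature is penalized).  The penalty integral is computed
exactly by Gauss-Legendre quadrature on each knot interval, so the solve is
a plain symmetric linear system.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "build_knots",
    "design_matrix",
    "derivative_penalty",
    "PenalizedBSpline",
]


def build_knots(domain, degree, interior=None, spacing=None, n_interior=None):
    """Clamped knot vector on ``domain = (a, b)``.

    Exactly one of ``interior`` (explicit interior knots), ``spacing``
    (equal spacing in domain units) or ``n_interior`` may be given; the
    basis dimension is ``len(interior) + degree + 1``.
    """
    a, b = map(float, domain)
    if not b > a:
        raise ValueError("domain must satisfy a < b")
    if interior is not None:
        interior = np.asarray(interior, dtype=float)
    elif spacing is not None:
        interior = np.arange(a + spacing, b - 1e-9, spacing, dtype=float)
    elif n_interior is not None:
        interior = np.linspace(a, b, n_interior + 2)[1:-1]
    else:
        raise ValueError("give one of interior, spacing, n_interior")
    if np.any(interior <= a) or np.any(interior >= b):
        raise ValueError("interior knots must lie strictly inside the domain")
    return np.concatenate(
        [np.full(degree + 1, a), np.sort(interior), np.full(degree + 1, b)]
    )


def n_basis(knots, degree):
    return len(knots) - degree - 1


_BASIS_CACHE: dict = {}


def design_matrix(x, knots, degree, deriv=0):
    """Dense matrix ``B[i, j] = B_j^{(deriv)}(x_i)`` for the clamped basis.

    Results are memoized on (x, knots, degree, deriv): germination studies
    evaluate the same basis on the same daily grid for every accession.
    """
    x = np.asarray(x, dtype=float)
    key = (x.tobytes(), np.asarray(knots).tobytes(), degree, deriv)
    cached = _BASIS_CACHE.get(key)
    if cached is not None:
        return cached
    k = n_basis(knots, degree)
    # evaluate each basis function via a unit coefficient vector; the basis
    # dimension here is ~20 so the column loop is cheap and avoids sparse
    # design_matrix version quirks at the right endpoint
    B = np.empty((x.size, k))
    eye = np.eye(k)
    for j in range(k):
        spl = BSpline(knots, eye[j], degree, extrapolate=False)
        if deriv:
            spl = spl.derivative(deriv)
        col = spl(np.clip(x, knots[0], knots[-1]))
        B[:, j] = np.nan_to_num(col)
    if len(_BASIS_CACHE) > 256:
        _BASIS_CACHE.clear()
    _BASIS_CACHE[key] = B
    return B


def derivative_penalty(knots, degree, order=1):
    """Exact Gram matrix ``P[j,k] = int B_j^{(order)} B_k^{(order)} dt``.

    Gauss-Legendre with ``degree + 1`` nodes per knot span is exact because
    the integrand is piecewise polynomial of degree ``2*(degree - order)``.
    """
    if order >= degree:
        raise ValueError("penalty order must be below the spline degree")
    key = ("penalty", np.asarray(knots).tobytes(), degree, order)
    cached = _BASIS_CACHE.get(key)
    if cached is not None:
        return cached
    nodes, weights = leggauss(degree + 1)
    spans = np.unique(knots)
    k = n_basis(knots, degree)
    P = np.zeros((k, k))
    for lo, hi in zip(spans[:-1], spans[1:]):
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        x = mid + half * nodes
        D = design_matrix(x, knots, degree, deriv=order)
        P += half * (D.T * weights) @ D
    _BASIS_CACHE[key] = P
    return P


class PenalizedBSpline(BaseEstimator, RegressorMixin):
    """Penalized B-spline smoother with GCV-selected smoothing parameter.

    Parameters
    ----------
    degree : int
        Polynomial degree of the basis (default 4).
    knot_spacing : float or None
        Interior-knot spacing in x units; ignored if ``knots`` given.
    n_interior : int or None
        Alternative knot specification: number of equispaced interior knots.
    knots : array or None
        Full clamped knot vector; overrides the other knot options.
    domain : (float, float) or None
        Fit domain; defaults to the data range.
    lam : float or "gcv"
        Smoothing parameter, or ``"gcv"`` to minimize generalized
        cross-validation over ``lam_grid``.
    lam_grid : array
        Candidate lambdas for GCV.
    penalty_order : int
        Derivative order in the roughness penalty.

    Attributes
    ----------
    coef_ : (k,) array of B-spline coefficients.
    knots_ : fitted knot vector.
    lam_ : smoothing parameter actually used.
    edf_ : effective degrees of freedom, trace of the hat matrix.
    rss_ : residual sum of squares at the fit.
    """

    def __init__(
        self,
        degree=4,
        knot_spacing=2.0,
        n_interior=None,
        knots=None,
        domain=None,
        lam="gcv",
        lam_grid=None,
        penalty_order=1,
    ):
        self.degree = degree
        self.knot_spacing = knot_spacing
        self.n_interior = n_interior
        self.knots = knots
        self.domain = domain
        self.lam = lam
        self.lam_grid = lam_grid
        self.penalty_order = penalty_order

    def _resolve_knots(self, x):
        if self.knots is not None:
            return np.asarray(self.knots, dtype=float)
        domain = self.domain if self.domain is not None else (x.min(), x.max())
        if self.n_interior is not None:
            return build_knots(domain, self.degree, n_interior=self.n_interior)
        return build_knots(domain, self.degree, spacing=self.knot_spacing)

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("X and y lengths differ")
        if np.unique(x).size < 2:
            raise ValueError("need at least 2 distinct observation points")
        knots = self._resolve_knots(x)
        B = design_matrix(x, knots, self.degree)
        P = derivative_penalty(knots, self.degree, self.penalty_order)
        BtB, Bty = B.T @ B, B.T @ y

        def solve(lam):
            A = BtB + lam * P
            try:
                c = np.linalg.solve(A, Bty)
                # one step of iterative refinement: the normal equations can
                # be ill-conditioned near lam = 0
                c += np.linalg.solve(A, Bty - A @ c)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    "singular normal system (rank deficiency); increase lam "
                    "above 0 or reduce the number of knots"
                ) from err
            return c, A

        if self.lam == "gcv":
            grid = (
                np.logspace(-4, 4, 33)
                if self.lam_grid is None
                else np.asarray(self.lam_grid, dtype=float)
            )
            best = None
            n = x.size
            for lam in grid:
                c, A = solve(lam)
                edf = np.trace(np.linalg.solve(A, BtB))
                rss = float(np.sum((y - B @ c) ** 2))
                denom = max(n - edf, 1e-8)
                gcv = n * rss / denom**2
                if best is None or gcv < best[0]:
                    best = (gcv, lam, c, edf, rss)
            _, lam, c, edf, rss = best
        else:
            lam = float(self.lam)
            if lam < 0:
                raise ValueError("lam must be non-negative")
            c, A = solve(lam)
            edf = np.trace(np.linalg.solve(A, BtB))
            rss = float(np.sum((y - B @ c) ** 2))

        self.knots_ = knots
        self.coef_ = c
        self.lam_ = lam
        self.edf_ = float(edf)
        self.rss_ = rss
        self.n_obs_ = x.size
        return self

    def _check_domain(self, x):
        lo, hi = self.knots_[0], self.knots_[-1]
        if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
            raise ValueError(
                f"evaluation point outside fitted domain [{lo}, {hi}]"
            )

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        self._check_domain(x)
        return design_matrix(x, self.knots_, self.degree) @ self.coef_

    def derivative(self, X, order=1):
        x = np.asarray(X, dtype=float).reshape(-1)
        self._check_domain(x)
        return design_matrix(x, self.knots_, self.degree, deriv=order) @ self.coef_
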