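"""Absolute germination distribution functions (AGDFs) and scalar descriptors.

A germination test records, for one accession under one alternating
temperature regime, the cumulative number of imbibed seeds on each of 28
daily scores.  The AGDF is a degree-4 penalized B-spline fitted to those
counts (with a (0, 0) anchor: seeds start ungerminated), whose B-spline
coefficient vector serves as a multivariate descriptor of the germination
pattern; the area under the AGDF aggregates final germination and speed.
Classical single-number indices (final %, LT50, MGT, CV, AUC) are provided
for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .splines import PenalizedBSpline, design_matrix

__all__ = [
    "GerminationRecord",
    "AGDF",
    "GerminationIndices",
    "SplineConfig",
    "fit_agdf",
    "evaluate_agdf",
    "agdf_area",
    "classical_indices",
    "smooth_regression",
]

TREATMENTS = ("T25_15", "T35_15")


@dataclass(frozen=True)
class GerminationRecord:
    """Daily cumulative imbibed-seed counts for one accession x treatment x replicate."""

    accession_id: str
    treatment: str
    replicate: int
    seeds_total: int
    days: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        days = np.asarray(self.days, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "counts", counts)
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.seeds_total <= 0:
            raise ValueError("seeds_total must be positive")
        if days.size != counts.size:
            raise ValueError("days and counts lengths differ")
        if days.size and (np.any(np.diff(days) <= 0) or days[0] <= 0):
            raise ValueError("days must be strictly increasing and positive")
        if np.any(np.diff(counts) < 0):
            raise ValueError(
                f"cumulative counts decrease ({self.accession_id}, {self.treatment})"
            )
        if np.any(counts < 0) or np.any(counts > self.seeds_total):
            raise ValueError("counts must lie in [0, seeds_total]")

    @property
    def horizon(self) -> float:
        return float(self.days[-1])

    def summed_with(self, other: "GerminationRecord") -> "GerminationRecord":
        """Pool two replicates into one series (counts add, totals add)."""
        if (self.accession_id, self.treatment) != (other.accession_id, other.treatment):
            raise ValueError("can only sum replicates of the same accession x treatment")
        if not np.array_equal(self.days, other.days):
            raise ValueError("replicates observed on different days")
        return GerminationRecord(
            self.accession_id,
            self.treatment,
            0,
            self.seeds_total + other.seeds_total,
            self.days,
            self.counts + other.counts,
        )


@dataclass
class SplineConfig:
    degree: int = 4
    knot_spacing: float = 2.0
    lam: object = "gcv"
    lam_grid: object = None
    anchor: bool = True
    monotone_tol: float = 0.02  # warn if s' < -tol * seeds_total anywhere


@dataclass
class AGDF:
    """Fitted absolute germination distribution function."""

    degree: int
    knots: np.ndarray
    coefficients: np.ndarray
    domain: tuple
    smoothing_parameter: float
    accession_id: str = ""
    treatment: str = ""
    seeds_total: int = 0
    edf: float = field(default=np.nan)

    def __call__(self, times):
        return evaluate_agdf(self, times)

    def derivative(self, times, order=1):
        t = np.asarray(times, dtype=float).reshape(-1)
        _check_domain(self, t)
        return design_matrix(t, self.knots, self.degree, deriv=order) @ self.coefficients


@dataclass
class GerminationIndices:
    """Classical single-number germination descriptors.

    LT50, MGT and CV are ``nan`` (undefined) when no seed germinated.
    """

    final_proportion: float
    auc: float
    lt50: float
    mgt: float
    cv: float


def _check_domain(agdf: AGDF, t: np.ndarray):
    lo, hi = agdf.domain
    if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
        raise ValueError(f"time outside AGDF domain [{lo}, {hi}]; no extrapolation")


def fit_agdf(record: GerminationRecord, config: SplineConfig | None = None) -> AGDF:
    """Fit the penalized-spline AGDF to one count series.

    The objective is ``sum_i (y_i - s(t_i))^2 + lam * int (s'(t))^2 dt`` over
    degree-``config.degree`` splines on equispaced knots; a (0, 0) anchor is
    prepended by default so the AUC domain is [0, horizon] for every
    accession.
    """
    config = config or SplineConfig()
    if record.days.size < 2:
        raise ValueError("need at least 2 observations to fit an AGDF")
    t, y = record.days, record.counts
    if config.anchor:
        t = np.concatenate([[0.0], t])
        y = np.concatenate([[0.0], y])
    domain = (0.0 if config.anchor else float(t[0]), record.horizon)
    smoother = PenalizedBSpline(
        degree=config.degree,
        knot_spacing=config.knot_spacing,
        domain=domain,
        lam=config.lam,
        lam_grid=config.lam_grid,
        penalty_order=1,
    ).fit(t, y)
    agdf = AGDF(
        degree=config.degree,
        knots=smoother.knots_,
        coefficients=smoother.coef_,
        domain=domain,
        smoothing_parameter=smoother.lam_,
        accession_id=record.accession_id,
        treatment=record.treatment,
        seeds_total=record.seeds_total,
        edf=smoother.edf_,
    )
    grid = np.arange(domain[0], domain[1] + 1e-9, 0.1)
    if agdf.derivative(grid).min() < -config.monotone_tol * record.seeds_total:
        warnings.warn(
            f"AGDF for {record.accession_id}/{record.treatment} dips below the "
            "monotonicity tolerance; consider larger lam or monotone projection",
            UserWarning,
            stacklevel=2,
        )
    return agdf


def evaluate_agdf(agdf: AGDF, times) -> np.ndarray:
    """Evaluate the fitted spline; linear in the coefficients, no extrapolation."""
    t = np.asarray(times, dtype=float).reshape(-1)
    _check_domain(agdf, t)
    return design_matrix(t, agdf.knots, agdf.degree) @ agdf.coefficients


def agdf_area(values_or_agdf, grid=None, monotone=False) -> float:
    """Area under the AGDF by the composite trapezoidal rule.

    Accepts either a fitted :class:`AGDF` (evaluated on ``grid``, default a
    0.1-day grid over its domain) or raw values sampled on ``grid`` — for raw
    counts this integrates the piecewise-linear interpolant.  With
    ``monotone=True`` evaluations are isotonically adjusted (running maximum)
    before integration.
    """
    if isinstance(values_or_agdf, AGDF):
        agdf = values_or_agdf
        if grid is None:
            grid = np.arange(agdf.domain[0], agdf.domain[1] + 1e-9, 0.1)
        grid = np.asarray(grid, dtype=float)
        values = evaluate_agdf(agdf, grid)
    else:
        values = np.asarray(values_or_agdf, dtype=float)
        grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty evaluation grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if monotone:
        values = np.maximum.accumulate(values)
    return float(np.trapezoid(values, grid))


def classical_indices(record: GerminationRecord) -> GerminationIndices:
    """Final %, AUC, LT50, MGT and CV for one count series.

    LT50 is the linearly interpolated first time the cumulative count reaches
    half the final count; MGT is the increment-weighted mean of germination
    days; CV = 100 / MGT.  All three are ``nan`` when nothing germinated.
    """
    t, y = record.days, record.counts
    final = float(y[-1])
    auc = agdf_area(np.concatenate([[0.0], y]), np.concatenate([[0.0], t]))
    if final == 0:
        return GerminationIndices(0.0, auc, np.nan, np.nan, np.nan)
    half = 0.5 * final
    t0 = np.concatenate([[0.0], t])
    y0 = np.concatenate([[0.0], y])
    idx = int(np.argmax(y0 >= half))  # first crossing
    if y0[idx] == half or idx == 0:
        lt50 = float(t0[idx])
    else:
        ta, tb = t0[idx - 1], t0[idx]
        ya, yb = y0[idx - 1], y0[idx]
        lt50 = float(ta + (half - ya) / (yb - ya) * (tb - ta))
    g = np.diff(y0)
    mgt = float(np.sum(g * t) / np.sum(g))
    return GerminationIndices(final / record.seeds_total, auc, lt50, mgt, 100.0 / mgt)


@dataclass
class SmoothFit:
    """Penalized-spline scatterplot smooth with a test against the flat model."""

    smoother: PenalizedBSpline
    residual_deviance: float
    null_deviance: float
    f_statistic: float
    p_value: float
    edf: float

    def predict(self, x):
        return self.smoother.predict(x)


def smooth_regression(x, y, degree=4, n_interior=8, lam="gcv", lam_grid=None) -> SmoothFit:
    """GAM-style penalized-spline regression of y on x.

    Same engine as :func:`fit_agdf` but applied to scattered data, without the
    (0,0) anchor or monotonicity diagnostics, and with a curvature
    (second-derivative) penalty so the infinite-smoothing limit is the
    least-squares line.  Returns the smooth plus an approximate F-test against
    the intercept-only model using the hat-trace effective df.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size != y.size or x.size < 5:
        raise ValueError("need matched x, y with at least 5 points")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    smoother = PenalizedBSpline(
        degree=degree,
        n_interior=n_interior,
        knot_spacing=None,
        domain=(x.min(), x.max()),
        lam=lam,
        lam_grid=lam_grid,
        penalty_order=2,
    ).fit(x, y)
    n = x.size
    rss = smoother.rss_
    tss = float(np.sum((y - y.mean()) ** 2))
    edf = smoother.edf_
    # reference df inflated by one over the naive edf - 1: compensates the
    # anti-conservativeness of testing at a data-selected smoothing level
    df1 = max(edf, 1.0)
    df2 = max(n - edf, 1e-8)
    f = ((tss - rss) / df1) / (rss / df2) if rss > 0 else np.inf
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return SmoothFit(smoother, rss, tss, float(f), p, edf)
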