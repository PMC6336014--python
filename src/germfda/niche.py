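"""Niche overlap between dormancy groups on gridded suitability surfaces.

Suitability surfaces (from any niche model; a climate-envelope baseline is
built in) are normalized to probability surfaces over a background area and
compared with Schoener's D and the Hellinger-based I.  The niche equivalency
test pools the two groups' occurrences, repartitions them at random
preserving group sizes, refits the model and recomputes the indices; a low
observed overlap relative to that null signals non-equivalent niches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .raster import Grid
from .spatial import cross_haversine

__all__ = [
    "OccurrenceSet",
    "normalize_surface",
    "overlap_indices",
    "background_buffer_mask",
    "ClimateEnvelopeModel",
    "envelope_model",
    "OverlapResult",
    "equivalency_test",
]


@dataclass
class OccurrenceSet:
    """Labelled occurrence points for one dormancy group."""

    label: str
    coords: np.ndarray  # (n, 2) lon/lat
    buffer_km: float = 300.0

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        if c.shape[0] < 3:
            raise ValueError(f"group {self.label!r}: need >= 3 occurrence points")
        self.coords = c


def background_buffer_mask(grid: Grid, coords, buffer_km=300.0) -> np.ndarray:
    """Boolean mask of cells whose centers lie within buffer_km of any point."""
    lons, lats = grid.cell_centers()
    cells = np.column_stack([lons.ravel(), lats.ravel()])
    pts = np.asarray(coords, dtype=float).reshape(-1, 2)
    d = cross_haversine(pts, cells)
    return (d.min(axis=0) <= buffer_km).reshape(grid.shape)


def normalize_surface(grid: Grid, background=None) -> Grid:
    """Normalize a non-negative suitability grid to sum to 1 over the background."""
    v = grid.values.astype(float)
    mask = np.ma.getmaskarray(v).copy()
    if background is not None:
        mask |= ~np.asarray(background, dtype=bool)
    vals = np.ma.masked_array(np.ma.getdata(v), mask)
    total = float(vals.sum())
    if not total > 0:
        raise ValueError("all-zero (or fully masked) suitability surface")
    return grid.copy_with(vals / total)


def overlap_indices(p1: Grid, p2: Grid):
    """Schoener's D and Hellinger-based I between two probability surfaces.

    D = 1 - 0.5 * sum |p1 - p2|; I = 1 - 0.5 * sum (sqrt(p1) - sqrt(p2))^2,
    summing over cells unmasked in both grids (missing-in-one cells count as
    zero probability there).  Both are 1 for identical surfaces and 0 for
    disjoint supports.
    """
    if not p1.same_geometry(p2):
        raise ValueError("probability surfaces must share grid geometry")
    a = p1.values.filled(0.0)
    b = p2.values.filled(0.0)
    d = 1.0 - 0.5 * float(np.abs(a - b).sum())
    h2 = float(((np.sqrt(a) - np.sqrt(b)) ** 2).sum())
    i = 1.0 - 0.5 * h2
    return float(np.clip(d, 0, 1)), float(np.clip(i, 0, 1))


class ClimateEnvelopeModel(BaseEstimator):
    """Baseline suitability model from per-variable percentile envelopes.

    For each environmental raster, suitability is 1 inside the central
    percentile envelope (default 5th-95th) of the values observed at the
    occurrence points, tapering linearly to 0 at the observed minimum and
    maximum; the cell suitability is the product across variables, restricted
    to the background buffer.  This is a deliberately simple, transparent
    stand-in behind the same interface that externally produced suitability
    rasters (e.g. from a maximum-entropy model) can be plugged into.
    """

    def __init__(self, percentiles=(5.0, 95.0), buffer_km=300.0):
        self.percentiles = percentiles
        self.buffer_km = buffer_km

    def fit(self, occurrences: OccurrenceSet, env_grids: list[Grid]):
        if not env_grids:
            raise ValueError("need at least one environmental raster")
        kept, dropped = [], 0
        for lon, lat in occurrences.coords:
            try:
                vals = [g.value_at(lon, lat) for g in env_grids]
            except ValueError:
                dropped += 1
                continue
            if any(v is None for v in vals):
                dropped += 1
                continue
            kept.append((lon, lat, vals))
        if dropped:
            warnings.warn(f"{dropped} occurrence(s) outside rasters dropped",
                          UserWarning, stacklevel=2)
        if len(kept) < 3:
            raise ValueError("fewer than 3 usable occurrences after dropping")
        self.coords_ = np.array([(lon, lat) for lon, lat, _ in kept])
        V = np.array([vals for *_, vals in kept])  # (n_occ, n_var)
        lo_p, hi_p = self.percentiles
        self.env_min_ = V.min(axis=0)
        self.env_max_ = V.max(axis=0)
        self.env_lo_ = np.percentile(V, lo_p, axis=0)
        self.env_hi_ = np.percentile(V, hi_p, axis=0)
        self.env_grids_ = env_grids
        return self

    def _taper(self, x, j):
        lo, hi = self.env_lo_[j], self.env_hi_[j]
        mn, mx = self.env_min_[j], self.env_max_[j]
        s = np.ones_like(x)
        left = x < lo
        if lo > mn:
            s[left] = np.clip((x[left] - mn) / (lo - mn), 0, 1)
        else:
            s[left] = (x[left] >= mn).astype(float)
        right = x > hi
        if mx > hi:
            s[right] = np.clip((mx - x[right]) / (mx - hi), 0, 1)
        else:
            s[right] = (x[right] <= mx).astype(float)
        s[(x < mn) | (x > mx)] = 0.0
        return s

    def predict_surface(self) -> Grid:
        base = self.env_grids_[0]
        suit = np.ones(base.shape)
        mask = np.zeros(base.shape, dtype=bool)
        for j, g in enumerate(self.env_grids_):
            x = g.values.filled(np.nan)
            mask |= np.ma.getmaskarray(g.values)
            suit *= self._taper(np.nan_to_num(x), j)
        bg = background_buffer_mask(base, self.coords_, self.buffer_km)
        out = np.ma.masked_array(suit, mask | ~bg)
        return base.copy_with(out)


def envelope_model(occurrences: OccurrenceSet, env_grids, **kwargs) -> Grid:
    """Fit the climate-envelope baseline and return its suitability surface."""
    return ClimateEnvelopeModel(**kwargs).fit(occurrences, list(env_grids)).predict_surface()


@dataclass
class OverlapResult:
    d: float
    i: float
    null_d: np.ndarray = field(default_factory=lambda: np.array([]))
    null_i: np.ndarray = field(default_factory=lambda: np.array([]))
    p_d: float = np.nan
    p_i: float = np.nan


def _group_overlap(occ1, occ2, env_grids, model_factory):
    s1 = model_factory().fit(occ1, env_grids).predict_surface()
    s2 = model_factory().fit(occ2, env_grids).predict_surface()
    try:
        p1, p2 = normalize_surface(s1), normalize_surface(s2)
    except ValueError:
        # a group whose envelope admits no cell has an empty predicted
        # niche: overlap with anything is zero
        return 0.0, 0.0
    return overlap_indices(p1, p2)


def equivalency_test(occ1: OccurrenceSet, occ2: OccurrenceSet, env_grids,
                     model_factory=None, n_reps=100, seed=None) -> OverlapResult:
    """Warren-style niche equivalency permutation test.

    Occurrences are pooled and randomly repartitioned preserving group sizes;
    models are refitted and D, I recomputed per replicate.  One-sided
    p = (1 + #{null <= observed}) / (1 + n_reps): an observed overlap lower
    than the null indicates non-equivalent niches.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if model_factory is None:
        model_factory = ClimateEnvelopeModel
    rng = np.random.default_rng(seed)
    env_grids = list(env_grids)
    d_obs, i_obs = _group_overlap(occ1, occ2, env_grids, model_factory)
    pool = np.vstack([occ1.coords, occ2.coords])
    n1 = len(occ1.coords)
    null_d, null_i = np.empty(n_reps), np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(len(pool))
        o1 = OccurrenceSet(occ1.label, pool[perm[:n1]], occ1.buffer_km)
        o2 = OccurrenceSet(occ2.label, pool[perm[n1:]], occ2.buffer_km)
        null_d[r], null_i[r] = _group_overlap(o1, o2, env_grids, model_factory)
    p_d = (1 + np.sum(null_d <= d_obs + 1e-12)) / (1 + n_reps)
    p_i = (1 + np.sum(null_i <= i_obs + 1e-12)) / (1 + n_reps)
    return OverlapResult(d_obs, i_obs, null_d, null_i, float(p_d), float(p_i))
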