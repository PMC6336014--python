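"""Dormancy classification by UPGMA clustering of germination descriptors.

Accessions are clustered on the Euclidean distances between their B-spline
coefficient vectors (per temperature treatment) or between their (AUC at
25/15, AUC at 35/15) pairs (combined treatments), and the resulting clusters
are labelled non-dormant (N), temperature-responsive (R) or dormant (D) from
their mean final germination under the two regimes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "pairwise_euclidean",
    "Dendrogram",
    "upgma",
    "UPGMAClusterer",
    "DormancyAssignment",
    "LabelThresholds",
    "cut_and_label",
]


def pairwise_euclidean(matrix, labels=None) -> np.ndarray:
    """Symmetric Euclidean distance matrix between rows; rejects NaN rows by name."""
    X = np.asarray(matrix, dtype=float)
    bad = np.where(~np.isfinite(X).all(axis=1))[0]
    if bad.size:
        names = [labels[i] if labels is not None else str(i) for i in bad]
        raise ValueError(f"non-finite descriptor values for: {', '.join(names)}")
    return squareform(pdist(X, metric="euclidean"))


@dataclass
class Dendrogram:
    """UPGMA tree: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: list

    @property
    def merges(self):
        """List of (cluster_a, cluster_b, height) in agglomeration order."""
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage]

    def cophenetic_matrix(self) -> np.ndarray:
        return squareform(hierarchy.cophenet(self.linkage))

    def cut(self, k: int) -> np.ndarray:
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def upgma(dist: np.ndarray, labels=None) -> Dendrogram:
    """Average-linkage agglomeration of a symmetric distance matrix.

    Cophenetic distance between two leaves equals the height at which their
    clusters merged; UPGMA heights are non-decreasing (ultrametric tree).
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if D.shape[0] < 2:
        raise ValueError("need at least 2 leaves")
    if labels is None:
        labels = [str(i) for i in range(D.shape[0])]
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    return Dendrogram(Z, list(labels))


class UPGMAClusterer(BaseEstimator, ClusterMixin):
    """sklearn-style wrapper: UPGMA on Euclidean distances of feature rows.

    Attributes after fit: ``dendrogram_``, ``labels_`` (cluster ids 0..k-1).
    """

    def __init__(self, n_clusters=3):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.dendrogram_ = upgma(pairwise_euclidean(X))
        self.labels_ = self.dendrogram_.cut(self.n_clusters) - 1
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class DormancyAssignment:
    accession_id: str
    category: str  # N / R / D
    subgroup: str
    mean_final_25: float
    mean_final_35: float


@dataclass
class LabelThresholds:
    """Cluster-labelling cutoffs on mean final germination (fractions).

    A cluster is dormant when its 35/15 mean stays below ``dormant_max``,
    non-dormant when both means exceed ``nondormant_min``; anything with low
    25/15 but elevated 35/15 germination is responsive.  The dormant cutoff
    sits mid-gap between the dormant response level (~0.2: dormant groups
    germinate below 20-28% at 35/15) and the released level (~0.6-0.8 for
    responsive groups): a boundary placed at 0.2 itself would bisect the
    dormant class.
    """

    nondormant_min: float = 0.80
    dormant_max: float = 0.40


def _cluster_category(m25, m35, thr: LabelThresholds) -> str:
    if m25 >= thr.nondormant_min and m35 >= thr.nondormant_min:
        return "N"
    if m35 < thr.dormant_max:
        return "D"
    return "R"


def cut_and_label(
    dendrogram: Dendrogram,
    k: int,
    final_25,
    final_35,
    thresholds: LabelThresholds | None = None,
    subgroup_k: int = 0,
) -> list[DormancyAssignment]:
    """Cut the UPGMA tree into ``k`` clusters and label each N / R / D.

    ``final_25`` / ``final_35`` are per-accession mean final germination
    fractions (ordered as the dendrogram leaves).  Clusters are labelled from
    their mean final germination: high at both regimes -> N, low at 35/15 ->
    D, low at 25/15 but released at 35/15 -> R.  Ties in labelling inputs are
    broken deterministically by cluster size then leaf order, with a warning.
    Optional ``subgroup_k`` produces a finer cut whose cluster ids are
    appended as subgroup labels (N1, N2, ...).
    """
    thresholds = thresholds or LabelThresholds()
    n = len(dendrogram.labels)
    if not 2 <= k <= n:
        raise ValueError("k must be between 2 and the number of leaves")
    f25 = np.asarray(final_25, dtype=float)
    f35 = np.asarray(final_35, dtype=float)
    clusters = dendrogram.cut(k)
    means = {}
    for c in np.unique(clusters):
        mask = clusters == c
        means[c] = (float(f25[mask].mean()), float(f35[mask].mean()))
    cats = {c: _cluster_category(m25, m35, thresholds) for c, (m25, m35) in means.items()}
    pairs = list(means.values())
    if len(set(pairs)) < len(pairs):
        warnings.warn(
            "tied cluster germination means; labels broken by cluster size then id",
            UserWarning,
            stacklevel=2,
        )

    sub = {}
    if subgroup_k:
        fine = dendrogram.cut(subgroup_k)
        # number subgroups within each category by leaf order
        for cat in ("N", "R", "D"):
            seen = {}
            for i in range(n):
                if cats[clusters[i]] != cat:
                    continue
                fid = fine[i]
                seen.setdefault(fid, len(seen) + 1)
                sub[i] = f"{cat}{seen[fid]}"

    return [
        DormancyAssignment(
            accession_id=dendrogram.labels[i],
            category=cats[clusters[i]],
            subgroup=sub.get(i, ""),
            mean_final_25=float(f25[i]),
            mean_final_35=float(f35[i]),
        )
        for i in range(n)
    ]
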