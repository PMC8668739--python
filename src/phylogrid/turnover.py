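"""Compositional turnover, bioregionalization and composition color maps.

Pairwise turnover between occupied cells is measured by Simpson
dissimilarity, beta_sim = min(b, c) / (min(b, c) + a) with a the shared and
b, c the unique species counts, and by its branch-length analogue
PhyloSor_turn, which substitutes shared and unique spanning-path lengths.
Both ignore nestedness: a cell whose assemblage is a subset of another's is
at distance 0.

Cells are grouped into bioregions by average-linkage (UPGMA) clustering of
either matrix, cut to k clusters, and visualized by classical scaling
(PCoA) of the dissimilarity matrix with the first three axes mapped to RGB
so that compositionally similar cells share similar colors.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .diversity import _PhyloIndexEngine
from .rasterops import PresenceAbsenceMatrix

__all__ = [
    "simpson_dissimilarity",
    "phylosor_turnover",
    "UPGMABioregions",
    "PCoARGB",
    "upgma_cluster",
    "pcoa_rgb",
    "linkage_to_newick",
]


def _pairwise_turnover(shared: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """min(b,c)/(min(b,c)+a) from a shared-quantity matrix and per-cell totals."""
    b = totals[:, None] - shared
    c = totals[None, :] - shared
    m = np.minimum(b, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = m / (m + shared)
    beta[np.isnan(beta)] = 0.0  # both cells empty of the measured quantity
    np.fill_diagonal(beta, 0.0)
    return np.clip(beta, 0.0, 1.0)


def simpson_dissimilarity(pam: PresenceAbsenceMatrix) -> np.ndarray:
    """Pairwise Simpson (turnover-only) dissimilarity between occupied cells.

    Returns a symmetric (n_occupied, n_occupied) matrix ordered as the
    occupied cells appear in the PAM; use ``pam.richness > 0`` to align.
    """
    M = pam.matrix[pam.richness > 0].astype(float)
    if M.shape[0] < 2:
        raise ValueError("need at least two occupied cells")
    shared = M @ M.T
    return _pairwise_turnover(shared, M.sum(axis=1))


def phylosor_turnover(tree: dendropy.Tree, pam: PresenceAbsenceMatrix) -> np.ndarray:
    """Pairwise PhyloSor turnover between occupied cells.

    Shared quantity is the branch length common to both cells' minimum
    spanning paths; unique quantities are each path's remainder.
    """
    occ = pam.richness > 0
    M = pam.matrix[occ]
    if M.shape[0] < 2:
        raise ValueError("need at least two occupied cells")
    eng = _PhyloIndexEngine(tree, pam.species)
    P = eng.branch_presence(M).astype(float)  # cells x branches
    shared = (P * eng.L) @ P.T
    totals = P @ eng.L
    return _pairwise_turnover(shared, totals)


class UPGMABioregions(ClusterMixin, BaseEstimator):
    """Bioregions by UPGMA (average-linkage) clustering of a dissimilarity.

    Parameters
    ----------
    n_clusters : int
        Number of bioregions to cut the dendrogram into (default 4).

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster label (1..k) per cell, relabeled so that cluster 1 contains
        the lowest cell index (deterministic under input permutation).
    linkage_ : ndarray
        scipy linkage matrix of the full agglomeration.
    """

    def __init__(self, n_clusters: int = 4):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        D = np.asarray(X, dtype=float)
        n = D.shape[0]
        if D.shape != (n, n):
            raise ValueError("X must be a square dissimilarity matrix")
        if self.n_clusters > n:
            raise ValueError(f"cannot cut {n} cells into {self.n_clusters} clusters")
        self.linkage_ = hierarchy.linkage(squareform(D, checks=False), method="average")
        raw = hierarchy.fcluster(self.linkage_, t=self.n_clusters, criterion="maxclust")
        # canonical labels: order of first appearance
        order = {}
        for lab in raw:
            if lab not in order:
                order[lab] = len(order) + 1
        self.labels_ = np.array([order[lab] for lab in raw])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def to_newick(self, leaf_names=None) -> str:
        check_is_fitted(self, "linkage_")
        return linkage_to_newick(self.linkage_, leaf_names)


class PCoARGB(TransformerMixin, BaseEstimator):
    """Classical scaling of a dissimilarity matrix mapped to RGB.

    The squared dissimilarities are double-centered and eigendecomposed
    (principal coordinates analysis); the first three positive axes are each
    rescaled to [0, 255].  If fewer than three positive axes exist, the
    remaining channels are set to the midpoint 128 with a warning.
    """

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        from skbio.stats.ordination import pcoa
        from skbio import DistanceMatrix

        D = np.asarray(X, dtype=float)
        if D.shape[0] < 4:
            raise ValueError("PCoA->RGB needs at least 4 cells")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # skbio warns on negative eigenvalues
            ord_res = pcoa(DistanceMatrix(D), number_of_dimensions=min(D.shape[0] - 1, 10))
        eig = ord_res.eigvals.to_numpy()
        coords = ord_res.samples.to_numpy()
        pos = eig > 1e-12 * max(eig.max(), 1.0)
        coords = coords[:, pos]
        rgb = np.full((D.shape[0], 3), 128.0)
        n_axes = min(3, coords.shape[1])
        if n_axes < 3:
            warnings.warn(
                f"dissimilarity matrix has only {n_axes} positive PCoA axes; "
                "remaining RGB channels set to 128"
            )
        for ax in range(n_axes):
            v = coords[:, ax]
            span = v.max() - v.min()
            rgb[:, ax] = 128.0 if span == 0 else (v - v.min()) / span * 255.0
        self.eigenvalues_ = eig
        self.coordinates_ = coords
        self.rgb_ = rgb
        return rgb


def upgma_cluster(dissim: np.ndarray, k: int = 4) -> np.ndarray:
    """Cell -> bioregion labels (1..k) from UPGMA at the k-cluster cut."""
    return UPGMABioregions(n_clusters=k).fit_predict(dissim)


def pcoa_rgb(dissim: np.ndarray) -> np.ndarray:
    """Per-cell RGB triple in [0, 255] from the first three PCoA axes."""
    return PCoARGB().fit_transform(dissim)


def linkage_to_newick(Z: np.ndarray, leaf_names=None) -> str:
    """Export a scipy linkage matrix as a newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)
    n = tree.get_count()
    if leaf_names is None:
        leaf_names = [f"cell{i}" for i in range(n)]

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.10g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return rec(tree, tree.dist) + ";"
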