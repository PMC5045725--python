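"""Composite-angle distances between normalised P'(r') vectors and
hierarchical shape clustering.

Per sampled bin the shared mass min(a_i, b_i) and unique mass
max(a_i, b_i) - min(a_i, b_i) are accumulated into a 2-vector (X, Y);
the distance is the angle of that vector with the shared axis, scaled to
[0, 1].  Identical vectors give 0; disjoint supports give 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .pr_metrics import NormalizedPr

LINKAGES = ("complete", "average")


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if d.min() < 0 or d.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")


@dataclass(frozen=True)
class ClusterResult:
    """Agglomerative merge tree plus a flat cut at k clusters."""

    labels: tuple
    linkage_matrix: np.ndarray
    assignment: np.ndarray  # cluster ids 1..k, renumbered by first appearance
    k: int


def _padded(a: np.ndarray, n: int) -> np.ndarray:
    if len(a) == n:
        return a
    out = np.zeros(n)
    out[:len(a)] = a
    return out


def composite_angle_distance(a: NormalizedPr, b: NormalizedPr) -> float:
    """Composite-angle distance between two unit-sum P'(r') vectors.

    Grids of unequal length are zero-padded; padding contributes only
    unique mass, penalising differing dmax/Rg extents.
    """
    n = max(len(a), len(b))
    pa = _padded(a.p_prime, n)
    pb = _padded(b.p_prime, n)
    shared = np.minimum(pa, pb).sum()
    unique = (np.maximum(pa, pb) - np.minimum(pa, pb)).sum()
    if shared == 0 and unique == 0:
        return 0.0
    return float(np.arctan2(unique, shared) / (np.pi / 2))


def distance_matrix(prs: Sequence[NormalizedPr]) -> DistanceMatrix:
    """All pairwise composite-angle distances, labelled by input order."""
    n = len(prs)
    if n < 2:
        raise ValueError("need at least 2 P'(r') functions")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = composite_angle_distance(prs[i], prs[j])
    labels = tuple(p.label or f"curve_{i}" for i, p in enumerate(prs))
    return DistanceMatrix(labels=labels, d=np.clip(d, 0.0, 1.0))


def cluster_shapes(dm: DistanceMatrix, k: int,
                   linkage: str = "complete") -> ClusterResult:
    """Hierarchical agglomerative clustering of a distance matrix.

    Complete linkage by default; the flat assignment cuts the tree at k
    clusters, with cluster ids renumbered in order of first appearance so
    that results are deterministic given input order.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    n = len(dm.labels)
    if not (2 <= k <= n):
        raise ValueError(f"k must be in [2, {n}]")
    z = hierarchy.linkage(squareform(dm.d, checks=False), method=linkage)
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    remap: dict = {}
    assignment = np.empty_like(raw)
    for i, c in enumerate(raw):
        if c not in remap:
            remap[c] = len(remap) + 1
        assignment[i] = remap[c]
    return ClusterResult(labels=dm.labels, linkage_matrix=z,
                         assignment=assignment, k=int(assignment.max()))


def to_newick(result: ClusterResult) -> str:
    """Render the merge tree as a newick string with branch lengths."""
    tree = hierarchy.to_tree(result.linkage_matrix)

    def _walk(node, parent_dist):
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{result.labels[node.id]}:{length:.6g}"
        left = _walk(node.left, node.dist)
        right = _walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _walk(tree, tree.dist) + ";"
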