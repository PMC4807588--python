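"""Ligand-ligand distances and hierarchical clustering.

Two ligands are compared through their binding-site statistics under
three Euclidean metrics:

* CED — over the 20-entry residue composition vectors (RC);
* PED — over the 20-entry residue propensity vectors (RP, percent scale);
* PCED — over the 8-entry physicochemical-class composition vectors (PC).

A symmetric distance matrix over a set of ligands feeds agglomerative
hierarchical clustering (complete linkage by default); the resulting tree
can be cut into k groups or serialized as Newick with merge heights as
branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .site_statistics import (
    CompositionVector,
    PropensityTable,
    PropertyCompositionVector,
)

METRICS = ("composition", "propensity", "property")
LINKAGES = ("complete", "average", "single")


def _vector(profile, expected_dim: int) -> np.ndarray:
    if isinstance(profile, (CompositionVector, PropensityTable, PropertyCompositionVector)):
        arr = np.asarray(profile.values, dtype=float)
    else:
        arr = np.asarray(profile, dtype=float)
    if arr.ndim != 1 or arr.shape[0] != expected_dim:
        raise ValueError(f"expected a {expected_dim}-entry vector, got shape {arr.shape}")
    return arr


def _euclidean(p, q, dim: int) -> float:
    a, b = _vector(p, dim), _vector(q, dim)
    return float(np.sqrt(((a - b) ** 2).sum()))


def composition_distance(p, q) -> float:
    """CED: Euclidean distance between two 20-entry RC vectors."""
    return _euclidean(p, q, 20)


def propensity_distance(p, q) -> float:
    """PED: Euclidean distance between two 20-entry RP vectors
    (percent scale, not the 0-9 normalized track)."""
    return _euclidean(p, q, 20)


def property_distance(p, q) -> float:
    """PCED: Euclidean distance between two 8-entry PC vectors."""
    return _euclidean(p, q, 8)


_METRIC_FUNCS = {
    "composition": (composition_distance, 20),
    "propensity": (propensity_distance, 20),
    "property": (property_distance, 8),
}


@dataclass
class LigandDistanceMatrix:
    ligand_ids: list[str]
    metric: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ligand_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ligand count")

    def distance(self, p: str, q: str) -> float:
        return float(self.values[self.ligand_ids.index(p), self.ligand_ids.index(q)])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ligand_ids, columns=self.ligand_ids)


@dataclass
class ClusterTree:
    """Agglomerative merge tree over ligand leaves.

    ``leaves`` are in the (lexicographic) order used for linkage;
    ``linkage_matrix`` is the scipy format (each row: left, right, height,
    size)."""

    leaves: list[str]
    linkage_matrix: np.ndarray
    method: str

    def cut(self, k: int) -> dict[str, int]:
        """Partition leaves into k flat clusters (labels 1..k)."""
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.leaves, (int(x) for x in labels)))

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def to_newick(self) -> str:
        """Newick text; branch length = parent height - child height."""
        root = hierarchy.to_tree(self.linkage_matrix)

        def fmt(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaves[node.id]}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        if root.is_leaf():
            return f"{self.leaves[root.id]}:0;"
        left = fmt(root.left, root.dist)
        right = fmt(root.right, root.dist)
        return f"({left},{right});"


def distance_matrix(profiles: Mapping[str, object], metric: str = "composition") -> LigandDistanceMatrix:
    """All pairwise distances between ligand profiles under one metric.

    ``profiles`` maps ligand id -> vector (or the corresponding statistics
    object).  Requires >= 2 ligands.
    """
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    ids = list(profiles)
    if len(ids) < 2:
        raise ValueError("need at least 2 ligands")
    func, dim = _METRIC_FUNCS[metric]
    vecs = [_vector(profiles[i], dim) for i in ids]
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = func(vecs[i], vecs[j])
            values[i, j] = values[j, i] = d
    return LigandDistanceMatrix(ligand_ids=ids, metric=metric, values=values)


def hierarchical_cluster(matrix: LigandDistanceMatrix, linkage: str = "complete") -> ClusterTree:
    """Agglomerative clustering of a ligand distance matrix.

    Ligands are reordered lexicographically before linkage so that ties
    are broken deterministically by ligand id and the tree is invariant to
    the input ordering.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    v = matrix.values
    if not np.allclose(v, v.T, atol=1e-9) or not np.allclose(np.diag(v), 0, atol=1e-12):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    order = np.argsort(matrix.ligand_ids)
    leaves = [matrix.ligand_ids[i] for i in order]
    reordered = v[np.ix_(order, order)]
    condensed = squareform(reordered, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(leaves=leaves, linkage_matrix=Z, method=linkage)


def leaf_order(tree: ClusterTree) -> list[str]:
    """Dendrogram leaf order (the order a heatmap would use)."""
    return [tree.leaves[i] for i in hierarchy.leaves_list(tree.linkage_matrix)]
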