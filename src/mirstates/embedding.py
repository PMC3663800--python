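"""Numeric embedding of interaction states: substitution into real values,
city-block sample distances, Ward clustering and PCA of the distance matrix.

The substitution maps each interaction state to a signed strength of the
repression reading: +1 for full repression (HL), -1 for fully released
repression (LH), +/-0.5 for the half-defined states and 0 for the undefined
ones. Samples are then compared by the city-block distance over all
interactions, clustered with Ward's method, and embedded by a principal
component analysis that treats the N x N distance matrix as N
N-dimensional observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

#: Substitution of interaction states into real values.
STATE_SUBSTITUTION: dict[str, float] = {
    "LH": -1.0,
    "MH": -0.5,
    "LM": -0.5,
    "LL": 0.0,
    "MM": 0.0,
    "HH": 0.0,
    "HM": 0.5,
    "ML": 0.5,
    "HL": 1.0,
}


def substitute_states(table: pd.DataFrame) -> pd.DataFrame:
    """Elementwise mapping of a 9-state interaction table to real values."""
    arr = table.to_numpy()
    unknown = set(np.unique(arr)) - set(STATE_SUBSTITUTION)
    if unknown:
        raise ValueError(f"unknown interaction states: {sorted(unknown)}")
    numeric = np.vectorize(STATE_SUBSTITUTION.__getitem__, otypes=[float])(arr)
    return pd.DataFrame(numeric, index=table.index, columns=table.columns)


def sample_distance_matrix(numeric: pd.DataFrame) -> pd.DataFrame:
    """Symmetric city-block distances between sample columns."""
    if numeric.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = numeric.to_numpy().T  # samples x interactions
    d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    return pd.DataFrame(d, index=numeric.columns, columns=numeric.columns)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over samples."""

    linkage: np.ndarray  # scipy linkage matrix, (n-1) x 4
    labels: list[str]

    def to_newick(self) -> str:
        """Newick string with merge heights converted to branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> tuple[str, float]:
            if node.is_leaf():
                return self.labels[node.id], node.dist
            left, lh = walk(node.left)
            right, rh = walk(node.right)
            lb = max(node.dist - lh, 0.0)
            rb = max(node.dist - rh, 0.0)
            return "(" + ",".join([f"{left}:{lb:g}", f"{right}:{rb:g}"]) + ")", node.dist

        newick, _ = walk(tree)
        return newick + ";"

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]


def ward_clustering(distances: pd.DataFrame) -> Dendrogram:
    """Ward hierarchical clustering of the given city-block distance matrix.

    Ward's method classically assumes Euclidean distances; it is applied to
    the city-block dissimilarities on purpose, for fidelity to the analysis
    this package mirrors, not orthodoxy.
    """
    condensed = squareform(distances.to_numpy(), checks=True)
    linkage = hierarchy.linkage(condensed, method="ward")
    return Dendrogram(linkage=linkage, labels=list(distances.index))


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x components
    explained_variance_fraction: np.ndarray  # sums to 1 over all components


def pca_of_distance_matrix(distances: pd.DataFrame) -> PCAResult:
    """PCA of the distance matrix treated as N observations of N features.

    Columns are centered before decomposition; components are ordered by
    decreasing variance and signed so the largest-magnitude loading is
    positive.
    """
    x = distances.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # sign convention: per component, the loading of largest magnitude is positive
    for k in range(len(s)):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    coords = u * s
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    cols = [f"PC{k + 1}" for k in range(len(s))]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=distances.index, columns=cols),
        explained_variance_fraction=frac,
    )
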