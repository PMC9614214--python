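"""Ordination of codon-usage profiles: average-linkage clustering and PCA.

Entities (species or subgenomes) are rows of a feature matrix over the 59
SCs (frequencies or RSCU). Clustering is UPGMA over Euclidean distances
with merge heights re-expressed as percent similarity, 100 * (1 - d/d_max).
PCA eigendecomposes the correlation matrix by default (scale-free, the
safer stand-in for proprietary software defaults); factor score
coefficients are eigenvectors scaled by 1/sqrt(eigenvalue), so that entity
scores come out standardized. A deterministic sign convention (the
largest-magnitude loading of each component is positive) makes outputs
comparable across linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist


@dataclass
class ClusterTree:
    labels: list[str]
    linkage_matrix: np.ndarray  # scipy linkage format
    newick: str
    merge_order: list[tuple[frozenset, frozenset, float]]

    def similarity(self, height: float) -> float:
        d_max = float(self.linkage_matrix[:, 2].max())
        if d_max == 0:
            return 100.0
        return 100.0 * (1.0 - height / d_max)


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    proportions: np.ndarray  # variance proportions, sum to 1
    loadings: np.ndarray  # columns = components; eigenvectors * sqrt(eigenvalue)
    factor_score_coefficients: np.ndarray  # eigenvectors / sqrt(eigenvalue)
    scores: np.ndarray  # entity scores (rows) on the components (columns)
    labels: list[str]


def _newick(node, labels: list[str], parent_height: float) -> str:
    length = parent_height / 2.0 - node.dist / 2.0
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.6g}"
    left = _newick(node.get_left(), labels, node.dist)
    right = _newick(node.get_right(), labels, node.dist)
    return f"({left},{right}):{length:.6g}"


def hierarchical_cluster(
    matrix: np.ndarray, labels: list[str] | None = None
) -> ClusterTree:
    """UPGMA (average linkage) over Euclidean distances.

    The Newick string carries ultrametric branch lengths (half the merge
    distance); ``merge_order`` lists each merge as (left leaf set, right
    leaf set, distance) for direct assertions about join order.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    if labels is None:
        labels = [f"row{i + 1}" for i in range(arr.shape[0])]
    labels = list(labels)
    z = linkage(pdist(arr, metric="euclidean"), method="average")
    n = arr.shape[0]
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    merge_order: list[tuple[frozenset, frozenset, float]] = []
    for i, (a, b, dist, _cnt) in enumerate(z):
        sa, sb = members[int(a)], members[int(b)]
        merge_order.append((sa, sb, float(dist)))
        members[n + i] = sa | sb
    root = to_tree(z)
    newick = _newick(root, labels, root.dist) + ";"
    return ClusterTree(
        labels=labels, linkage_matrix=z, newick=newick, merge_order=merge_order
    )


def pca(
    matrix: np.ndarray,
    labels: list[str] | None = None,
    standardize: bool = True,
    n_components: int = 3,
) -> PcaResult:
    """PCA via eigendecomposition of the correlation (or covariance) matrix.

    With ``standardize`` (default) columns are z-scored; a constant column
    is an error naming the column. Components with eigenvalue below 1e-12
    are dropped from the factor-score scaling to avoid division blow-ups.
    """
    arr = np.asarray(matrix, dtype=float)
    n, p = arr.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if labels is None:
        labels = [f"row{i + 1}" for i in range(n)]
    centered = arr - arr.mean(axis=0)
    if standardize:
        sd = arr.std(axis=0, ddof=1)
        constant = np.flatnonzero(sd == 0)
        if constant.size:
            raise ValueError(
                f"constant column(s) {constant.tolist()} cannot be standardized"
            )
        z = centered / sd
    else:
        z = centered
    cov = z.T @ z / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-|loading| entry of each component positive
    for j in range(eigvecs.shape[1]):
        k = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] *= -1
    total = eigvals.sum()
    proportions = eigvals / total if total > 0 else np.zeros_like(eigvals)
    k = min(n_components, p)
    vals = eigvals[:k]
    vecs = eigvecs[:, :k]
    safe = np.where(vals > 1e-12, np.sqrt(vals), np.nan)
    loadings = vecs * safe
    fsc = vecs / safe
    scores = z @ vecs
    return PcaResult(
        eigenvalues=eigvals,
        proportions=proportions,
        loadings=loadings,
        factor_score_coefficients=fsc,
        scores=scores,
        labels=labels,
    )
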