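"""Partitioning cells from a similarity matrix or embedding.

Default method is bottom-up agglomerative clustering with average linkage on
the distance transform D = 1 - M of a [0, 1] similarity matrix. K-means and
normalized-cut spectral clustering are provided as variants, and the number
of clusters can be estimated by a silhouette sweep when unknown.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans, SpectralClustering
from sklearn.metrics import silhouette_score

from .io import ClusteringResult, ValidationError
from .kernel import KernelMatrix

SYMMETRY_TOL = 1e-8


def _similarity_values(M) -> tuple[np.ndarray, list[str] | None]:
    """Extract a [0, 1] similarity array from M (kernel matrices rescaled)."""
    ids = None
    if isinstance(M, KernelMatrix):
        vals = M.rescaled()
        ids = list(M.cell_ids)
    elif hasattr(M, "values") and hasattr(M, "cell_ids"):  # LearnedSimilarity
        vals = np.asarray(M.values, dtype=float)
        ids = list(M.cell_ids)
    else:
        vals = np.asarray(M, dtype=float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValidationError("similarity matrix must be square")
    if not np.allclose(vals, vals.T, atol=SYMMETRY_TOL):
        raise ValidationError("similarity matrix not symmetric within tolerance")
    return vals, ids


def similarity_to_distance(M) -> np.ndarray:
    """D = 1 - M with an exactly zero diagonal, clipped into [0, 1]."""
    vals, _ = _similarity_values(M)
    D = 1.0 - np.clip(vals, 0.0, 1.0)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def dendrogram_from_similarity(M) -> np.ndarray:
    """Average-linkage merge tree (scipy linkage array) on D = 1 - M."""
    D = similarity_to_distance(M)
    return linkage(squareform(D, checks=False), method="average")


def cut_dendrogram(Z: np.ndarray, k: int) -> np.ndarray:
    """Cut a linkage tree into k clusters; labels renumbered 0..k-1 by first
    appearance so equal partitions compare equal."""
    raw = fcluster(Z, t=k, criterion="maxclust")
    _, labels = np.unique(raw, return_inverse=True)
    order = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        out[i] = order[lab]
    return out


def agglomerative_from_similarity(M, k: int, linkage_method: str = "average") -> ClusteringResult:
    """Hierarchical agglomeration on D = 1 - M, cut at k clusters.

    Deterministic given M. ``linkage_method`` may be average (default),
    complete, or single.
    """
    vals, ids = _similarity_values(M)
    n = vals.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    D = similarity_to_distance(vals)
    Z = linkage(squareform(D, checks=False), method=linkage_method)
    labels = cut_dendrogram(Z, k)
    k_actual = len(set(labels.tolist()))
    return ClusteringResult(labels=labels, k=k_actual, method="AG", cell_ids=ids)


def agglomerative_from_embedding(E: np.ndarray, k: int) -> ClusteringResult:
    """Ward-linkage agglomeration of per-cell embedding rows (Euclidean)."""
    E = np.asarray(E, dtype=float)
    n = E.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    Z = linkage(E, method="ward")
    labels = cut_dendrogram(Z, k)
    return ClusteringResult(labels=labels, k=len(set(labels.tolist())), method="AG")


def cluster_variants(E, k: int, method: str, seed: int = 0) -> ClusteringResult:
    """K-means (rows of E as points) or spectral clustering (E as affinity).

    E may be an n x n similarity matrix or an n x d per-cell embedding
    (k-means only).
    """
    if method == "AG":
        return agglomerative_from_similarity(E, k)
    if hasattr(E, "values"):
        vals = np.asarray(E.values, dtype=float)
        ids = list(getattr(E, "cell_ids", [])) or None
        if isinstance(E, KernelMatrix):
            vals = E.rescaled()
    else:
        vals = np.asarray(E, dtype=float)
        ids = None
    n = vals.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells {n}")
    if method == "KM":
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
        labels = km.fit_predict(vals)
    elif method == "SC":
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValidationError("spectral clustering requires a square affinity")
        sc = SpectralClustering(
            n_clusters=k,
            affinity="precomputed",
            assign_labels="kmeans",
            random_state=seed,
        )
        labels = sc.fit_predict(np.clip(vals, 0.0, None))
    else:
        raise ValueError(f"unknown method {method!r}; expected AG, KM, or SC")
    k_actual = len(set(labels.tolist()))
    return ClusteringResult(
        labels=np.asarray(labels), k=k_actual, method=method, seed=seed, cell_ids=ids
    )


def estimate_num_clusters(M, k_min: int = 2, k_max: int | None = None) -> int:
    """Pick k maximizing the mean silhouette of the agglomerative partition.

    Sweeps k in [k_min, k_max] on distance 1 - M, ties broken toward the
    smaller k. Default k_max is min(15, n - 1).
    """
    vals, _ = _similarity_values(M)
    n = vals.shape[0]
    if n < 4:
        raise ValueError("k estimation needs n >= 4 cells")
    if k_max is None:
        k_max = min(15, n - 1)
    if not 2 <= k_min < k_max <= n - 1:
        raise ValueError(f"need 2 <= k_min < k_max <= n-1, got [{k_min}, {k_max}]")
    D = similarity_to_distance(vals)
    Z = linkage(squareform(D, checks=False), method="average")
    best_k, best_score = k_min, -np.inf
    for k in range(k_min, k_max + 1):
        labels = cut_dendrogram(Z, k)
        if len(set(labels.tolist())) < 2:
            continue
        score = silhouette_score(D, labels, metric="precomputed")
        if score > best_score + 1e-12:  # strict improvement: ties stay small
            best_k, best_score = k, score
    return int(best_k)
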