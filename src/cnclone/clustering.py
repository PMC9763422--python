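"""Clonal decomposition of single-cell copy-number profiles.

Cells are embedded with t-SNE and partitioned with spectral clustering into
clusters of closely related copy-number profiles (putative clones). When the
number of clusters is not given, it is chosen with the eigengap heuristic on
the normalized Laplacian of a scale-adapted RBF affinity. Cluster
profiles are the per-bin means over member cells, integerized half-up into
the character states used by the phylogeny. An agglomerative clustering of
the cluster profiles under the Canberra distance is provided as an
independent cross-check of the tree's groupings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.sparse.csgraph import laplacian as csgraph_laplacian
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import SpectralClustering
from sklearn.manifold import TSNE
from sklearn.metrics.pairwise import rbf_kernel

from .cnmatrix import (
    CellCnMatrix,
    ClusterProfile,
    average_profile,
    estimate_chromosome_number,
    round_half_up,
)

__all__ = [
    "ClusterSet",
    "LinkageResult",
    "CloneClusterer",
    "embed_tsne",
    "spectral_cluster",
    "make_cluster_profiles",
    "hierarchical_check",
]


@dataclass
class ClusterSet:
    """A partition of cells into clusters 1..k with its t-SNE embedding."""

    assignments: np.ndarray  # per-cell integer label in 1..k
    k: int
    embedding: np.ndarray | None = None
    seed: int = 0
    matrix_ref: str = ""

    def __post_init__(self):
        self.assignments = np.asarray(self.assignments, dtype=np.int64)
        observed = np.unique(self.assignments)
        if self.k < 1 or not np.array_equal(observed, np.arange(1, self.k + 1)):
            raise ValueError(
                f"labels must be contiguous 1..k, got {observed.tolist()} for k={self.k}"
            )
        if self.embedding is not None:
            self.embedding = np.asarray(self.embedding, dtype=float)
            if len(self.embedding) != len(self.assignments):
                raise ValueError("embedding and assignments disagree on cell count")

    @property
    def n_cells(self) -> int:
        return len(self.assignments)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == cluster_id)


@dataclass
class LinkageResult:
    """Agglomerative clustering of cluster profiles.

    ``merge_history`` is a scipy linkage matrix: each row merges two
    clusters (indices) at a given height (Canberra distance under the
    configured linkage).
    """

    labels: list
    merge_history: np.ndarray
    distance_metric: str = "canberra"
    linkage_method: str = "complete"
    distances: np.ndarray = field(default=None, repr=False)  # condensed


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, CellCnMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=float)


def embed_tsne(matrix, perplexity: float = 30.0, seed: int = 42) -> np.ndarray:
    """2-D t-SNE embedding of per-cell CN profiles; deterministic per seed."""
    X = _as_array(matrix)
    n = X.shape[0]
    if n < 3 * perplexity:
        raise ValueError(
            f"{n} cells is too few for perplexity {perplexity}; need at least "
            f"{int(np.ceil(3 * perplexity))} cells or a smaller perplexity"
        )
    # PCA init is deterministic, but degenerates when the profiles carry
    # (almost) no variance; fall back to the seeded random init there.
    init = "pca" if np.ptp(X, axis=0).max() > 0 else "random"
    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        init=init,
        random_state=seed,
        metric="euclidean",
    ).fit_transform(X)
    if not np.all(np.isfinite(emb)):
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return emb


def _scaled_gamma(X: np.ndarray, gamma: float | None) -> float:
    """RBF width adapted to the data scale (1 / total variance)."""
    if gamma is not None:
        return gamma
    v = float(X.var())
    return 1.0 / v if v > 0 else 1.0


def _eigengap_k(X: np.ndarray, k_range: tuple, gamma: float | None) -> int:
    """Pick k maximizing the eigengap of the normalized Laplacian.

    The affinity is a scale-adapted RBF kernel, the same one used for the
    spectral partition, so the selected k matches what the clustering sees.
    """
    n = X.shape[0]
    W = rbf_kernel(X, gamma=_scaled_gamma(X, gamma))
    np.fill_diagonal(W, 0.0)
    L = csgraph_laplacian(W, normed=True)
    vals = np.sort(np.linalg.eigvalsh(L))
    lo, hi = k_range
    hi = min(hi, n - 1)
    gaps = {k: vals[k] - vals[k - 1] for k in range(max(lo, 2), hi + 1)}
    return max(gaps, key=lambda k: (gaps[k], -k))


class CloneClusterer(ClusterMixin, BaseEstimator):
    """t-SNE embedding followed by spectral clustering of single cells.

    Parameters
    ----------
    n_clusters : int or None
        Number of clusters; ``None`` selects k by the eigengap heuristic
        over ``k_range``.
    k_range : (int, int)
        Inclusive candidate range for automatic k selection.
    perplexity : float
        t-SNE perplexity; requires at least ``3 * perplexity`` cells.
    cluster_on : {"embedding", "matrix"}
        Run spectral clustering on the 2-D embedding (default) or on the
        raw CN matrix.
    gamma : float or None
        RBF affinity width; ``None`` adapts it to the data scale
        (1 / total variance).
    random_state : int
        Seed for both t-SNE and spectral clustering.

    Attributes
    ----------
    labels_ : per-cell cluster labels in 1..k
    embedding_ : per-cell t-SNE coordinates, shape (n_cells, 2)
    n_clusters_ : the number of clusters used
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        k_range: tuple = (2, 12),
        perplexity: float = 30.0,
        cluster_on: str = "embedding",
        gamma: float | None = None,
        random_state: int = 42,
    ):
        self.n_clusters = n_clusters
        self.k_range = k_range
        self.perplexity = perplexity
        self.cluster_on = cluster_on
        self.gamma = gamma
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _as_array(X)
        n = X.shape[0]
        if self.cluster_on not in ("embedding", "matrix"):
            raise ValueError("cluster_on must be 'embedding' or 'matrix'")
        self.embedding_ = embed_tsne(
            X, perplexity=self.perplexity, seed=self.random_state
        )
        target = self.embedding_ if self.cluster_on == "embedding" else X
        k = self.n_clusters
        if k is None:
            k = _eigengap_k(target, self.k_range, self.gamma)
        if not 1 <= k <= n:
            raise ValueError(f"n_clusters={k} outside 1..{n} cells")
        if k == 1:
            raw = np.zeros(n, dtype=int)
        else:
            raw = SpectralClustering(
                n_clusters=k,
                affinity="rbf",
                gamma=_scaled_gamma(target, self.gamma),
                assign_labels="kmeans",
                random_state=self.random_state,
            ).fit_predict(target)
        # relabel 1..k in order of first appearance (stable, deterministic)
        _, first = np.unique(raw, return_index=True)
        order = {raw[i]: r + 1 for r, i in enumerate(sorted(first))}
        self.labels_ = np.array([order[v] for v in raw], dtype=np.int64)
        self.n_clusters_ = k
        return self

    def to_cluster_set(self, matrix_ref: str = "") -> ClusterSet:
        return ClusterSet(
            assignments=self.labels_,
            k=self.n_clusters_,
            embedding=self.embedding_,
            seed=self.random_state,
            matrix_ref=matrix_ref,
        )


def spectral_cluster(
    matrix,
    k: int | None = None,
    seed: int = 42,
    embedding: np.ndarray | None = None,
    **kwargs,
) -> ClusterSet:
    """Functional wrapper over :class:`CloneClusterer`.

    If ``embedding`` is given, clustering runs on it directly and the t-SNE
    step is skipped.
    """
    if embedding is not None:
        est = CloneClusterer(n_clusters=k, random_state=seed, **kwargs)
        X = np.asarray(embedding, dtype=float)
        n = X.shape[0]
        kk = k if k is not None else _eigengap_k(X, est.k_range, est.gamma)
        if not 1 <= kk <= n:
            raise ValueError(f"k={kk} outside 1..{n} cells")
        if kk == 1:
            raw = np.zeros(n, dtype=int)
        else:
            raw = SpectralClustering(
                n_clusters=kk,
                affinity="rbf",
                gamma=_scaled_gamma(X, est.gamma),
                random_state=seed,
            ).fit_predict(X)
        _, first = np.unique(raw, return_index=True)
        order = {raw[i]: r + 1 for r, i in enumerate(sorted(first))}
        labels = np.array([order[v] for v in raw], dtype=np.int64)
        return ClusterSet(assignments=labels, k=kk, embedding=X, seed=seed)
    est = CloneClusterer(n_clusters=k, random_state=seed, **kwargs).fit(matrix)
    return est.to_cluster_set()


def make_cluster_profiles(matrix: CellCnMatrix, clusters: ClusterSet) -> list:
    """Average member cells of each cluster into a :class:`ClusterProfile`.

    Integer states are the half-up rounding of the mean profile; the
    chromosome estimate is computed from the mean profile.
    """
    if clusters.n_cells != matrix.n_cells:
        raise ValueError("cluster set and matrix disagree on cell count")
    profiles = []
    for cid in range(1, clusters.k + 1):
        rows = clusters.members(cid)
        subset = [matrix.cell_ids[i] for i in rows]
        mean_cn = average_profile(matrix, subset)
        profiles.append(
            ClusterProfile(
                cluster_id=cid,
                cell_count=len(rows),
                mean_cn=mean_cn,
                state_cn=round_half_up(mean_cn),
                chromosome_estimate=estimate_chromosome_number(mean_cn, matrix.genome),
                passage_label=matrix.passage_label,
                genome=matrix.genome,
            )
        )
    return profiles


def hierarchical_check(profiles, method: str = "complete") -> LinkageResult:
    """Agglomerate cluster profiles under the Canberra distance.

    Canberra: d(x, y) = sum_i |x_i - y_i| / (|x_i| + |y_i|), terms with both
    coordinates zero contributing 0. Used as an independent check that the
    groupings of the parsimony tree are not an artefact of the tree method.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to cluster")
    X = np.vstack([p.mean_cn for p in profiles])
    d = pdist(X, metric="canberra")
    Z = linkage(d, method=method)
    return LinkageResult(
        labels=[p.label for p in profiles],
        merge_history=Z,
        distance_metric="canberra",
        linkage_method=method,
        distances=d,
    )
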