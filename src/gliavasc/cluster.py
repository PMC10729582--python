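"""Morphology clustering: z-scoring, Ward-linkage trees, UMAP embeddings.

Single-cell morphology vectors are standardized per feature, clustered by
hierarchical agglomerative clustering with Ward's minimum-variance linkage
on Euclidean distances, and embedded in 2D with UMAP for visualization.
The default cut is k = 4 clusters, but the full linkage tree and per-k
silhouette scores are always available since the morphological transition
between states is continuous and no single k is canonical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusterResult",
    "standardize_features",
    "ward_cluster",
    "umap_embed",
    "cluster_frequencies",
    "cluster_morphologies",
]


@dataclass
class ClusterResult:
    linkage: np.ndarray
    k: int
    labels: np.ndarray                      # 1..k
    embedding: np.ndarray | None = None     # (n, 2) UMAP coordinates
    silhouette: dict = field(default_factory=dict)
    frequency_tables: dict = field(default_factory=dict)


def standardize_features(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Column-wise z-scores (mean 0, population sd 1).

    Constant columns carry no morphology information and make the z-score
    undefined, so they raise, naming the offending feature.
    """
    df = pd.DataFrame(matrix)
    if len(df) < 2:
        raise ValueError("need at least 2 rows to standardize")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("feature matrix contains missing values")
    sd = values.std(axis=0, ddof=0)
    for col, s in zip(df.columns, sd):
        if s == 0:
            raise ValueError(f"feature {col!r} is constant and cannot be standardized")
    z = (values - values.mean(axis=0)) / sd
    return pd.DataFrame(z, index=df.index, columns=df.columns)


def ward_cluster(matrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Ward-linkage agglomerative clustering cut at k clusters.

    Returns ``(labels, linkage_matrix)`` with labels in 1..k.  Expects a
    standardized feature matrix; Ward's criterion operates on Euclidean
    distances.
    """
    X = np.asarray(pd.DataFrame(matrix), dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n} cells")
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return labels, Z


def umap_embed(
    matrix,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 42,
) -> np.ndarray:
    """Deterministic 2D UMAP embedding of the standardized feature matrix."""
    import umap  # deferred: numba compilation makes this import expensive

    X = np.asarray(pd.DataFrame(matrix), dtype=float)
    if X.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} rows, got {X.shape[0]}"
        )
    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    return np.asarray(reducer.fit_transform(X), dtype=float)


def cluster_frequencies(
    labels, metadata: pd.DataFrame, by: str
) -> pd.DataFrame:
    """Relative frequency of each cluster within each stratum of ``by``.

    Rows are strata (groups / regions / stages), columns are cluster
    labels; each row sums to 1.  Strata with no cells are simply absent.
    """
    labels = np.asarray(labels)
    if len(labels) != len(metadata):
        raise ValueError("labels and metadata are not aligned")
    table = pd.crosstab(metadata[by], pd.Series(labels, name="cluster"), normalize="index")
    return table


def cluster_morphologies(
    features: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    k: int = 4,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 42,
    embed: bool = True,
    max_silhouette_k: int = 8,
) -> ClusterResult:
    """standardize -> Ward(k) -> UMAP -> frequency tables, in one call."""
    z = standardize_features(features)
    labels, Z = ward_cluster(z, k)
    sil = {}
    for kk in range(2, min(max_silhouette_k, len(z) - 1) + 1):
        lk = fcluster(Z, t=kk, criterion="maxclust")
        if len(np.unique(lk)) > 1:
            sil[kk] = float(silhouette_score(z, lk))
    embedding = None
    if embed and len(z) >= n_neighbors + 1:
        embedding = umap_embed(z, n_neighbors=n_neighbors, min_dist=min_dist, seed=seed)
    tables = {}
    if metadata is not None:
        for col in metadata.columns:
            tables[col] = cluster_frequencies(labels, metadata, by=col)
    return ClusterResult(
        linkage=Z,
        k=k,
        labels=labels,
        embedding=embedding,
        silhouette=sil,
        frequency_tables=tables,
    )


def plot_embedding(result: ClusterResult, path=None, ax=None):
    """Scatter the UMAP embedding colored by cluster label.

    Returns the matplotlib Axes; writes to ``path`` when given.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if result.embedding is None:
        raise ValueError("cluster result has no embedding (run with embed=True)")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for lab in np.unique(result.labels):
        sel = result.labels == lab
        ax.scatter(
            result.embedding[sel, 0], result.embedding[sel, 1],
            s=12, label=f"cluster {lab}",
        )
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
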