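"""LDA embedding, k-means clustering and completeness of multilayer metrics.

Each (recording, class) pair yields one sample whose feature vector is the
concatenation of all multilayer electrode metrics (4 metrics x 22
electrodes = 88 dimensions at the reference montage).  Linear discriminant
analysis projects the samples to 3 dimensions (four classes admit at most
classes - 1 = 3 discriminants), k-means with k = 4 clusters the projection,
and the completeness score

    completeness = 1 - H(K | C) / H(K)

measures whether every motor-imagery class C ends up inside a single
cluster K (1 when the clustering is class-pure; by convention 1 when
H(K) = 0, i.e. a single cluster).  The LDA is fit on the same samples it
projects; the unsupervised step is the clustering, not the embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import completeness_score as _sk_completeness

__all__ = [
    "EmbeddingResult",
    "feature_matrix",
    "lda_project",
    "kmeans_cluster",
    "completeness_score",
    "embed_and_cluster",
]


@dataclass
class EmbeddingResult:
    """3-D LDA coordinates with cluster labels and the completeness score."""

    coords: np.ndarray  # (samples, 3)
    cluster_labels: np.ndarray
    true_labels: np.ndarray
    completeness: float
    threshold_method: str | None = None
    sample_index: pd.MultiIndex | None = None

    def confusion(self) -> pd.DataFrame:
        """Class x cluster contingency table."""
        return pd.crosstab(
            pd.Series(self.true_labels, name="class"),
            pd.Series(self.cluster_labels, name="cluster"),
        )


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, pd.MultiIndex]:
    """Concatenate all (metric, electrode) values per (recording, class) sample."""
    wide = table.pivot_table(
        index=["recording_id", "class_label"],
        columns=["metric", "electrode"],
        values="value",
        sort=False,
    )
    if wide.isna().any().any():
        raise ValueError("metric table has missing (metric, electrode) cells")
    labels = wide.index.get_level_values("class_label").to_numpy()
    return wide.to_numpy(dtype=float), labels, wide.index


def lda_project(
    features: np.ndarray, labels: np.ndarray, n_components: int = 3
) -> np.ndarray:
    """Fisher discriminant projection of the samples to ``n_components`` axes."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n_classes = len(np.unique(labels))
    if n_components > n_classes - 1:
        raise ValueError(
            f"LDA yields at most classes-1 = {n_classes - 1} components"
        )
    if features.shape[1] < n_components:
        raise ValueError("need at least n_components feature dimensions")
    try:
        lda = LinearDiscriminantAnalysis(solver="svd", n_components=n_components)
        return lda.fit_transform(features, labels)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular within-class scatter; falling back to shrinkage LDA"
        )
        lda = LinearDiscriminantAnalysis(
            solver="eigen", shrinkage="auto", n_components=n_components
        )
        return lda.fit_transform(features, labels)


def kmeans_cluster(
    coords: np.ndarray, k: int = 4, seed: int = 0, n_restarts: int = 10
) -> np.ndarray:
    """Seeded k-means with multi-restart; the best-inertia partition is kept."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < k:
        raise ValueError(f"need at least k={k} samples, got {coords.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(coords)


def completeness_score(true_labels, cluster_labels) -> float:
    """Completeness 1 - H(K|C)/H(K); 1.0 when H(K) = 0 (single cluster)."""
    true_labels = np.asarray(true_labels)
    cluster_labels = np.asarray(cluster_labels)
    if true_labels.shape != cluster_labels.shape:
        raise ValueError("label vectors must have equal length")
    return float(_sk_completeness(true_labels, cluster_labels))


def embed_and_cluster(
    table: pd.DataFrame,
    seed: int = 0,
    threshold_method: str | None = None,
    k: int = 4,
) -> EmbeddingResult:
    """Full chain: feature concatenation -> 3-D LDA -> k-means -> completeness."""
    X, labels, index = feature_matrix(table)
    coords = lda_project(X, labels, n_components=min(3, len(np.unique(labels)) - 1))
    clusters = kmeans_cluster(coords, k=k, seed=seed)
    score = completeness_score(labels, clusters)
    return EmbeddingResult(
        coords=coords,
        cluster_labels=clusters,
        true_labels=labels,
        completeness=score,
        threshold_method=threshold_method,
        sample_index=index,
    )
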