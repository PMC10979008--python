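"""Relative abundance, PCA and k-means trajectory clustering.

Proteins are normalized to relative abundance (each protein's
intensities divided by its across-sample mean, so every row averages
to 1), samples are ordinated by PCA, and per-protein stage-mean
trajectories are clustered with k-means.  The number of clusters is
chosen by majority vote of five cluster-validity indices (silhouette,
Calinski-Harabasz, Davies-Bouldin, within-SS elbow, gap statistic) --
a fixed, deterministic panel standing in for index-voting packages.
Clusters are re-labelled by the slope of their centroid so Cluster 1 is
the most-decreasing trajectory and the last cluster the most-increasing.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .quant import QuantTable

VALIDITY_INDICES = ("silhouette", "calinski_harabasz", "davies_bouldin", "elbow", "gap")


@dataclass
class RelativeAbundanceMatrix:
    """Mean-normalized intensities plus per-stage means of those values."""

    values: pd.DataFrame       # proteins x samples, row mean == 1
    stage_means: pd.DataFrame  # proteins x stages


@dataclass
class ClusterResult:
    chosen_k: int
    labels: pd.Series          # protein -> 1-based cluster id (1 = most decreasing)
    centroids: pd.DataFrame    # cluster x stage
    inertia: float
    index_votes: pd.DataFrame | None = None


def relative_abundance(table: QuantTable) -> RelativeAbundanceMatrix:
    """Divide each protein by its across-sample mean intensity."""
    mat = table.intensities
    row_means = mat.mean(axis=1)
    if (row_means <= 0).any():
        raise ValueError("zero row mean; filter the table first")
    values = mat.div(row_means, axis=0)
    stage_means = pd.DataFrame(
        {s: values[table.stage_samples(s)].mean(axis=1) for s in table.stage_order}
    )
    return RelativeAbundanceMatrix(values=values, stage_means=stage_means)


def pca_samples(matrix: RelativeAbundanceMatrix, n_components: int | None = None):
    """PCA of samples with proteins as variables.

    Returns ``(scores, explained_variance_ratio)`` where ``scores`` is a
    samples x components frame.  Ratios over all components sum to 1.
    """
    X = matrix.values.to_numpy().T  # samples x proteins
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X - X.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    frame = pd.DataFrame(scores, index=matrix.values.columns, columns=cols)
    return frame, pca.explained_variance_ratio_


def _wss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def _fit_kmeans(X: np.ndarray, k: int, restarts: int, seed: int) -> KMeans:
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    km.fit(X)
    return km


def _gap_statistic(
    X: np.ndarray, ks: list[int], restarts: int, seed: int, n_refs: int = 10
):
    """Gap statistic against uniform reference data in the feature box."""
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_w = {k: np.log(_fit_kmeans(X, k, restarts, seed).inertia_) for k in ks}
    gaps, sks = {}, {}
    for k in ks:
        ref_logs = []
        for _ in range(n_refs):
            ref = rng.uniform(lo, hi, size=X.shape)
            ref_logs.append(np.log(_fit_kmeans(ref, k, max(restarts // 5, 1), seed).inertia_))
        ref_logs = np.asarray(ref_logs)
        gaps[k] = float(ref_logs.mean() - log_w[k])
        sks[k] = float(ref_logs.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_refs))
    # Tibshirani rule: smallest k with gap(k) >= gap(k+1) - s(k+1)
    for k in ks[:-1]:
        if gaps[k] >= gaps[k + 1] - sks[k + 1]:
            return k, gaps, sks
    return ks[-1], gaps, sks


def select_k(
    stage_means: pd.DataFrame,
    k_min: int = 2,
    k_max: int = 8,
    restarts: int = 10,
    seed: int = 0,
):
    """Choose the cluster count by majority vote of five validity indices.

    Each index nominates one k in ``[k_min, k_max]``; the winner is the
    k with most votes, ties broken toward smaller k.  A warning is
    emitted when no strict majority exists (weak cluster structure) and
    when the data are degenerate (all trajectories identical, in which
    case ``chosen_k`` is 1).

    Returns ``(chosen_k, votes)`` where ``votes`` tabulates each
    index's nomination.
    """
    X = stage_means.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        warnings.warn("degenerate data: all trajectories identical; k set to 1")
        return 1, pd.DataFrame({"index": list(VALIDITY_INDICES), "best_k": 1})
    ks = list(range(k_min, min(k_max, len(X) - 1) + 1))
    if len(ks) < 2:
        raise ValueError("need at least two candidate cluster counts")

    labels = {k: _fit_kmeans(X, k, restarts, seed).labels_ for k in ks}
    sil = {k: silhouette_score(X, labels[k]) for k in ks}
    ch = {k: calinski_harabasz_score(X, labels[k]) for k in ks}
    db = {k: davies_bouldin_score(X, labels[k]) for k in ks}
    # elbow: maximum discrete curvature of the within-SS curve over
    # k_min-1 .. k_max+1 (WSS at k=1 is the total sum of squares)
    wss_ks = [max(ks[0] - 1, 1)] + ks + [ks[-1] + 1]
    wss_ks = sorted(set(k for k in wss_ks if k <= len(X)))
    wss = {
        k: (_wss(X, np.zeros(len(X), dtype=int)) if k == 1
            else _fit_kmeans(X, k, restarts, seed).inertia_)
        for k in wss_ks
    }
    curvature = {
        k: wss[k - 1] - 2.0 * wss[k] + wss[k + 1]
        for k in ks
        if (k - 1 in wss) and (k + 1 in wss)
    }
    gap_k, _, _ = _gap_statistic(X, ks, restarts, seed)

    best = {
        "silhouette": max(ks, key=lambda k: sil[k]),
        "calinski_harabasz": max(ks, key=lambda k: ch[k]),
        "davies_bouldin": min(ks, key=lambda k: db[k]),
        "elbow": max(curvature, key=lambda k: curvature[k]) if curvature else ks[0],
        "gap": gap_k,
    }
    counts = Counter(best.values())
    top = max(counts.values())
    chosen = min(k for k, c in counts.items() if c == top)
    if top <= len(best) // 2:
        warnings.warn(
            f"no index majority for the cluster count (votes: {dict(counts)}); "
            f"adopting k={chosen}"
        )
    if sil[chosen] < 0.25:
        warnings.warn(
            f"weak cluster structure (silhouette {sil[chosen]:.2f} at k={chosen}); "
            "the data may be a single cluster"
        )
    votes = pd.DataFrame(
        {"index": list(best.keys()), "best_k": list(best.values())}
    )
    return chosen, votes


def kmeans_trajectories(
    stage_means: pd.DataFrame,
    k: int,
    restarts: int = 50,
    seed: int = 0,
) -> ClusterResult:
    """K-means on per-protein stage-mean trajectories, trend-ordered.

    Best of ``restarts`` k-means++ initializations by within-cluster SS.
    Output cluster ids are re-labelled by the slope of each centroid
    against stage index, ascending: Cluster 1 has the most negative
    (decreasing) centroid slope, cluster ``k`` the most positive.
    """
    if k < 1:
        raise ValueError("k must be positive")
    X = stage_means.to_numpy(dtype=float)
    if k > len(X):
        raise ValueError("more clusters than proteins")
    km = _fit_kmeans(X, k, restarts, seed)
    centroids = km.cluster_centers_
    t = np.arange(centroids.shape[1], dtype=float)
    slopes = np.polyfit(t, centroids.T, 1)[0]
    order = np.argsort(slopes)  # most decreasing first
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = pd.Series(
        relabel[km.labels_], index=stage_means.index, name="cluster"
    )
    centroid_frame = pd.DataFrame(
        centroids[order], index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=stage_means.columns,
    )
    return ClusterResult(
        chosen_k=k,
        labels=labels,
        centroids=centroid_frame,
        inertia=float(km.inertia_),
    )
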