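"""FPKM expression processing: filtering, transforms, family means and
k-means clustering under Pearson-correlation distance.

The workflow mirrors common practice for RNA-seq survey papers: genes
whose FPKM stays below 10 in every sample are set aside as lowly
expressed, the rest are log2(FPKM + 1) transformed, and profiles are
clustered with k-means where the distance between a profile x and a
centroid c is 1 - r(x, c) (Pearson).  Centroids are arithmetic means of
member profiles; the best of ``n_restarts`` random initialisations by
the summed within-cluster distance is kept.  Family-level expression is
the arithmetic mean of member FPKM per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "filter_low_expression",
    "log_transform",
    "family_mean_expression",
    "kmeans_pearson",
    "DEFAULT_FPKM_THRESHOLD",
    "DEFAULT_K",
]

DEFAULT_FPKM_THRESHOLD = 10.0
DEFAULT_K = 10


@dataclass
class ClusterAssignment:
    """Result of one Pearson-distance k-means run (best restart)."""

    labels: pd.Series  # gene -> cluster id, 1..k
    centroids: pd.DataFrame  # cluster id x samples, mean member profile
    objective: float  # sum of within-cluster Pearson distances
    n_iter: int
    dropped_zero_variance: list[str]


def filter_low_expression(
    matrix: pd.DataFrame, threshold: float = DEFAULT_FPKM_THRESHOLD
) -> tuple[pd.DataFrame, list[str]]:
    """Partition genes into retained and lowly-expressed sets.

    A gene is filtered iff *every* sample value is strictly below
    ``threshold`` (a single sample at exactly the threshold retains the
    gene).  Returns the retained matrix and the filtered gene ids.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    low = (matrix < threshold).all(axis=1)
    return matrix.loc[~low], list(matrix.index[low])


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(FPKM + 1); rejects negative input."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative expression values")
    return np.log2(matrix + 1.0)


def family_mean_expression(
    matrix: pd.DataFrame, gene_to_family: Mapping[str, str]
) -> pd.DataFrame:
    """Average member expression per family and sample.

    Genes absent from the mapping are ignored; families with no member
    in the matrix are omitted.
    """
    families = pd.Series(
        {g: gene_to_family[g] for g in matrix.index if g in gene_to_family},
        name="family",
    )
    if families.empty:
        return pd.DataFrame(columns=matrix.columns)
    grouped = matrix.loc[families.index].groupby(families).mean()
    grouped.index.name = "family"
    return grouped.sort_index()


def _pearson_distance_to_centroids(z_rows: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Distance matrix 1 - r between z-scored rows and raw centroids.

    A zero-variance centroid has undefined correlation; its distance is
    pinned to 2 (the maximum) so iterations stay total.
    """
    m = z_rows.shape[1]
    c_mean = centroids.mean(axis=1, keepdims=True)
    c_centered = centroids - c_mean
    c_norm = np.linalg.norm(c_centered, axis=1)
    dist = np.full((z_rows.shape[0], centroids.shape[0]), 2.0)
    ok = c_norm > 0
    if ok.any():
        zc = c_centered[ok] / c_norm[ok, None]
        corr = z_rows @ zc.T  # rows are unit-normalised, so this is r
        dist[:, ok] = 1.0 - corr
    return dist


def kmeans_pearson(
    matrix: pd.DataFrame,
    k: int = DEFAULT_K,
    n_restarts: int = 50,
    seed: int = 0,
    max_iter: int = 300,
) -> ClusterAssignment:
    """k-means with Pearson-correlation distance, best of ``n_restarts``.

    Zero-variance profiles cannot be correlated and are dropped first
    (reported in the result).  Empty clusters are re-seeded from the
    point farthest from its centroid.  Deterministic for a given seed.
    """
    variances = matrix.var(axis=1, ddof=0)
    dropped = list(matrix.index[variances == 0])
    if dropped:
        logger.warning("dropping %d zero-variance profiles", len(dropped))
        matrix = matrix.loc[variances > 0]
    n, m = matrix.shape
    if k <= 0 or k > n:
        raise ValueError(f"k={k} out of range for {n} profiles")

    x = matrix.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    z = centered / np.linalg.norm(centered, axis=1, keepdims=True)

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    for _ in range(max(1, n_restarts)):
        centroid_idx = rng.choice(n, size=k, replace=False)
        centroids = x[centroid_idx].copy()
        labels = np.zeros(n, dtype=int)
        for iteration in range(1, max_iter + 1):
            dist = _pearson_distance_to_centroids(z, centroids)
            labels = dist.argmin(axis=1)
            new_centroids = centroids.copy()
            for c in range(k):
                members = labels == c
                if members.any():
                    new_centroids[c] = x[members].mean(axis=0)
                else:
                    worst = dist[np.arange(n), labels].argmax()
                    new_centroids[c] = x[worst]
                    labels[worst] = c
            if np.allclose(new_centroids, centroids):
                centroids = new_centroids
                break
            centroids = new_centroids
        dist = _pearson_distance_to_centroids(z, centroids)
        labels = dist.argmin(axis=1)
        objective = float(dist[np.arange(n), labels].sum())
        if best is None or objective < best[0]:
            best = (objective, labels.copy(), centroids.copy(), iteration)

    objective, labels, centroids, n_iter = best
    # honour the contract that reported centroids are member-profile means
    for c in range(k):
        members = labels == c
        if members.any():
            centroids[c] = x[members].mean(axis=0)
    label_series = pd.Series(labels + 1, index=matrix.index, name="cluster")
    centroid_df = pd.DataFrame(
        centroids, index=pd.RangeIndex(1, k + 1, name="cluster"), columns=matrix.columns
    )
    return ClusterAssignment(
        labels=label_series,
        centroids=centroid_df,
        objective=objective,
        n_iter=n_iter,
        dropped_zero_variance=dropped,
    )
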