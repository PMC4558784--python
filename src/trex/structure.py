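"""Global structure analyses of the normalized expression data.

Covers the sample-level views (Pearson correlation matrix of
experiments, classical 2-D multidimensional scaling on leading
log-fold-change distances) and the gene-level clustering (k-means with
an automatically chosen k via mean silhouette, and average-linkage
hierarchical clustering on a correlation distance). Clustering runs on
two feature spaces: "signal" (mean log2-CPM per condition) and "ratio"
(logFC per contrast), with rows restricted to the TopHits genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

logger = logging.getLogger("trex")

__all__ = [
    "CorrelationMatrix",
    "MDSCoordinates",
    "KMeansResult",
    "HClustTree",
    "experiment_correlation",
    "mds_coordinates",
    "auto_k",
    "kmeans_cluster",
    "AutoKMeans",
    "hclust",
    "signal_space",
    "ratio_space",
]


# ---------------------------------------------------------------------------
# feature spaces
# ---------------------------------------------------------------------------


def signal_space(signal: pd.DataFrame, conditions: pd.Series) -> pd.DataFrame:
    """Mean log2-CPM per condition level (one column per condition)."""
    cond = conditions.reindex(signal.columns)
    return signal.T.groupby(cond, sort=False).mean().T


def ratio_space(results) -> pd.DataFrame:
    """logFC per contrast (one column per contrast)."""
    return pd.DataFrame({name: res.table["logFC"] for name, res in results.items()})


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    matrix: pd.DataFrame  # symmetric, unit diagonal, ordered by clustering
    leaf_order: list[str]


def _pearson_with_degenerate(X: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation; zero-variance columns get r=0."""
    sd = X.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d zero-variance column(s) in correlation; r set to 0", int(degenerate.sum())
        )
    Xs = (X - X.mean(axis=0)) / np.where(degenerate, 1.0, sd)
    r = Xs.T @ Xs / X.shape[0]
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def experiment_correlation(signal: pd.DataFrame) -> CorrelationMatrix:
    """Pearson correlation between sample columns, rows/columns ordered by
    average-linkage clustering of the 1-r distance."""
    if signal.shape[1] < 2 or signal.shape[0] < 3:
        raise ValueError("need >=2 samples and >=3 genes for a correlation matrix")
    r = _pearson_with_degenerate(signal.to_numpy(dtype=float))
    r = (r + r.T) / 2.0
    labels = list(signal.columns)
    if len(labels) > 2:
        d = np.clip(1.0 - r, 0.0, None)
        np.fill_diagonal(d, 0.0)
        Z = hierarchy.linkage(squareform(d, checks=False), method="average")
        order = hierarchy.leaves_list(Z)
    else:
        order = np.arange(len(labels))
    ordered = [labels[i] for i in order]
    df = pd.DataFrame(r, index=labels, columns=labels).loc[ordered, ordered]
    return CorrelationMatrix(df, ordered)


# ---------------------------------------------------------------------------
# MDS
# ---------------------------------------------------------------------------


@dataclass
class MDSCoordinates:
    coords: pd.DataFrame    # samples x (x, y), centered at the origin
    distances: pd.DataFrame


def leading_logfc_distance(signal: pd.DataFrame, top_n: int = 500) -> pd.DataFrame:
    """Pairwise sample distance: RMS of the top_n largest absolute
    per-gene signal differences (leading log-fold-change convention)."""
    X = signal.to_numpy(dtype=float)
    n = X.shape[1]
    top = min(top_n, X.shape[0])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(X[:, i] - X[:, j])
            sel = np.partition(diff, len(diff) - top)[len(diff) - top:]
            d[i, j] = d[j, i] = float(np.sqrt(np.mean(sel**2)))
    return pd.DataFrame(d, index=signal.columns, columns=signal.columns)


def classical_mds(d: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson scaling: double-center -squared-distances/2, eigendecompose."""
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_components]
    vals_top = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(vals_top)[None, :]
    return coords - coords.mean(axis=0)


def mds_coordinates(signal: pd.DataFrame, top_n: int = 500) -> MDSCoordinates:
    """2-D classical MDS of samples on the leading log-fold-change distance."""
    if signal.shape[1] < 3:
        raise ValueError("MDS needs at least 3 samples")
    dist = leading_logfc_distance(signal, top_n)
    coords = classical_mds(dist.to_numpy())
    return MDSCoordinates(
        pd.DataFrame(coords, index=signal.columns, columns=["x", "y"]), dist
    )


# ---------------------------------------------------------------------------
# k-means with automatic k
# ---------------------------------------------------------------------------


@dataclass
class KMeansResult:
    k: int
    assignment: pd.Series    # gene -> cluster id (0-based)
    centroids: np.ndarray    # k x features
    inertia: float
    silhouette: float
    seed: int


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = X[rng.integers(n)]
            continue
        centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((X - centers[j]) ** 2, axis=1))
    return centers


def _lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int = 300, rtol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, float]:
    prev_inertia = np.inf
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        inertia = float(d2[np.arange(len(X)), labels].sum())
        assert inertia <= prev_inertia + 1e-9, "k-means inertia increased"
        for j in range(centers.shape[0]):
            members = labels == j
            if members.any():
                centers[j] = X[members].mean(axis=0)
            else:
                # re-seed an emptied cluster at the farthest point
                far = int(np.argmax(d2[np.arange(len(X)), labels]))
                centers[j] = X[far]
                logger.info("k-means: empty cluster re-seeded at farthest point")
        if np.isfinite(prev_inertia) and prev_inertia - inertia <= rtol * max(
            prev_inertia, 1e-12
        ):
            break
        prev_inertia = inertia
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    inertia = float(d2[np.arange(len(X)), labels].sum())
    return labels, centers, inertia


def kmeans_cluster(
    matrix: pd.DataFrame, k: int, seed: int = 20150903, n_init: int = 10
) -> KMeansResult:
    """Best-of-n_init Lloyd k-means with k-means++ initialization.

    Deterministic given the seed; Lloyd iterations stop at a relative
    inertia change below 1e-6 or 300 iterations, and the inertia is
    asserted non-increasing across iterations.
    """
    X = matrix.to_numpy(dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds {X.shape[0]} rows")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_init):
        centers = _kmeans_pp_init(X, k, rng)
        labels, centers, inertia = _lloyd(X, centers.copy())
        if best is None or inertia < best[0]:
            best = (inertia, labels, centers)
    inertia, labels, centers = best
    if k >= 2 and len(np.unique(labels)) >= 2:
        sil = float(silhouette_score(X, labels))
    else:
        sil = float("nan")
    return KMeansResult(
        k=k,
        assignment=pd.Series(labels, index=matrix.index, name="cluster"),
        centroids=centers,
        inertia=inertia,
        silhouette=sil,
        seed=seed,
    )


def auto_k(
    matrix: pd.DataFrame,
    k_range: range = range(2, 13),
    seed: int = 20150903,
    n_init: int = 10,
) -> int:
    """Number of clusters maximizing the mean silhouette; ties -> smallest k.

    The candidate range is truncated so k <= rows - 1; with fewer than 4
    rows the rule degenerates to k = 2 (warned).
    """
    n = matrix.shape[0]
    if n < 4:
        logger.warning("auto_k: fewer than 4 rows; returning k=2")
        return 2
    k_max = min(max(k_range), n - 1)
    best_k, best_sil = None, -np.inf
    for k in range(min(k_range), k_max + 1):
        res = kmeans_cluster(matrix, k, seed=seed, n_init=n_init)
        if np.isnan(res.silhouette):
            continue
        if res.silhouette > best_sil + 1e-12:
            best_k, best_sil = k, res.silhouette
    return best_k if best_k is not None else 2


class AutoKMeans(BaseEstimator, ClusterMixin):
    """k-means clusterer that picks k automatically by mean silhouette.

    sklearn-style: ``fit(X)`` sets ``k_``, ``labels_``, ``centroids_``,
    ``inertia_`` and ``silhouette_``. ``k`` may be fixed to skip the
    silhouette scan.
    """

    def __init__(
        self,
        k: int | None = None,
        k_min: int = 2,
        k_max: int = 12,
        n_init: int = 10,
        seed: int = 20150903,
    ):
        self.k = k
        self.k_min = k_min
        self.k_max = k_max
        self.n_init = n_init
        self.seed = seed

    def fit(self, X, y=None) -> "AutoKMeans":
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        k = self.k or auto_k(
            df, range(self.k_min, self.k_max + 1), seed=self.seed, n_init=self.n_init
        )
        res = kmeans_cluster(df, k, seed=self.seed, n_init=self.n_init)
        self.k_ = res.k
        self.labels_ = res.assignment.to_numpy()
        self.assignment_ = res.assignment
        self.centroids_ = res.centroids
        self.inertia_ = res.inertia
        self.silhouette_ = res.silhouette
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class HClustTree:
    linkage: np.ndarray      # scipy linkage matrix (merge sequence + heights)
    leaf_order: list[str]
    labels: list[str]


def correlation_distance(matrix: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Pearson distance between rows (constant rows -> r=0)."""
    r = _pearson_with_degenerate(matrix.to_numpy(dtype=float).T)
    d = np.clip(1.0 - r, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return squareform((d + d.T) / 2.0, checks=False)


def hclust(
    matrix: pd.DataFrame, linkage: str = "average", metric: str = "correlation"
) -> HClustTree:
    """Agglomerative clustering of rows; default average linkage on 1-r."""
    if matrix.shape[0] < 2:
        raise ValueError("hierarchical clustering needs at least 2 rows")
    if metric == "correlation":
        cond = correlation_distance(matrix)
    elif metric == "euclidean":
        from scipy.spatial.distance import pdist

        cond = pdist(matrix.to_numpy(dtype=float))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    Z = hierarchy.linkage(cond, method=linkage)
    order = hierarchy.leaves_list(Z)
    labels = list(matrix.index)
    return HClustTree(Z, [labels[i] for i in order], labels)
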