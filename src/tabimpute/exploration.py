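"""Plot-ready backends for data exploration.

Everything here returns coordinate/label/merge tables rather than figures,
so any plotting layer (or the CLI's CSV artifacts) can render them:
pairwise feature correlation, missingness-pattern matrices with a feature
dendrogram, PCA/t-SNE embeddings, k-means clustering, and elbow-based
selection of the cluster count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage

from .imputation import CompletedDataset
from .tabular_io import CONTINUOUS, Dataset


@dataclass
class CorrelationView:
    feature_a: str
    feature_b: str
    r: float
    points: np.ndarray  # (n, 2) scatter coordinates
    flagged: bool = False


@dataclass
class PatternView:
    """Binary missingness matrix in display order plus the feature tree."""

    matrix: np.ndarray  # 1 = missing, rows/cols permuted to display order
    row_order: np.ndarray
    col_order: np.ndarray
    merges: list[tuple[int, int, float]] | None = None  # (node_a, node_b, height)


@dataclass
class ClusterView:
    embedding: np.ndarray  # (n, 2)
    method: str
    params: dict
    labels: np.ndarray
    k: int
    wcss_by_k: dict[int, float] = field(default_factory=dict)
    suggested_k: int | None = None


def _completed_matrix(c) -> np.ndarray:
    if isinstance(c, CompletedDataset):
        return c.dataset.values
    if isinstance(c, Dataset):
        if c.mask.any():
            raise ValueError("dataset still has missing cells; impute first")
        return c.values
    return np.asarray(c, dtype=float)


def pairwise_correlation(c, feature_a: str, feature_b: str) -> CorrelationView:
    """Pearson correlation of two continuous features plus scatter points."""
    d = c.dataset if isinstance(c, CompletedDataset) else c
    ja, jb = d.column_index(feature_a), d.column_index(feature_b)
    for j in (ja, jb):
        if d.col_types[j] != CONTINUOUS:
            raise ValueError(f"column {d.col_names[j]!r} is not continuous")
    x, y = d.values[:, ja], d.values[:, jb]
    if x.size < 3:
        raise ValueError("need at least 3 paired points")
    points = np.column_stack([x, y])
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationView(feature_a, feature_b, float("nan"), points, flagged=True)
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationView(feature_a, feature_b, r, points)


def missingness_pattern(d: Dataset, cluster_features: bool = False) -> PatternView:
    """The 0/1 missingness image of ``d``.

    With ``cluster_features`` the features are hierarchically clustered
    (average linkage on Euclidean distances between the binary indicator
    columns) and reordered by the dendrogram's leaf order; the merge list
    ``(node_a, node_b, height)`` uses scipy's node numbering (leaves
    ``0..m-1``, internal nodes from ``m``).
    """
    M = d.mask.astype(int)
    row_order = np.arange(d.n_samples)
    col_order = np.arange(d.n_features)
    merges = None
    if cluster_features and d.n_features >= 2:
        Z = linkage(M.T.astype(float), method="average", metric="euclidean")
        col_order = np.asarray(leaves_list(Z))
        merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    return PatternView(M[np.ix_(row_order, col_order)], row_order, col_order, merges)


def embed(c, method: str = "pca", params: dict | None = None, seed: int = 0) -> np.ndarray:
    """2-D embedding of a completed table's z-standardised features.

    PCA is deterministic with the component sign fixed so that each
    component's largest-magnitude loading is positive.  t-SNE honours
    perplexity (default 30), learning rate (200) and n_iter (1000), seeded.
    """
    X = _completed_matrix(c)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to embed")
    params = dict(params or {})
    sd = X.std(axis=0)
    Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    if method == "pca":
        from sklearn.decomposition import PCA

        n_comp = min(2, min(Xs.shape))
        pca = PCA(n_components=n_comp, svd_solver="full")
        coords = pca.fit_transform(Xs)
        for i in range(n_comp):
            load = pca.components_[i]
            if load[np.argmax(np.abs(load))] < 0:
                coords[:, i] = -coords[:, i]
        if n_comp == 1:
            coords = np.column_stack([coords, np.zeros(Xs.shape[0])])
        return coords
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = params.pop("perplexity", 30.0)
        if perplexity >= X.shape[0]:
            raise ValueError("perplexity must be smaller than the sample count")
        tsne = TSNE(
            n_components=2,
            perplexity=perplexity,
            learning_rate=params.pop("learning_rate", 200.0),
            max_iter=params.pop("n_iter", 1000),
            random_state=seed,
            init="pca",
            **params,
        )
        return tsne.fit_transform(Xs)
    raise ValueError(f"unknown embedding method {method!r}")


def kmeans_cluster(
    points: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, float]:
    """Best-of-``n_init`` k-means; returns labels and the final within-cluster
    sum of squares."""
    from sklearn.cluster import KMeans

    points = np.asarray(points, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > points.shape[0]:
        raise ValueError(f"k={k} exceeds the sample count {points.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(points)
    return labels, float(km.inertia_)


def elbow_suggest_k(
    points: np.ndarray,
    k_min: int = 1,
    k_max: int = 9,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[int, dict[int, float]]:
    """Suggest a cluster count by the elbow rule.

    Runs k-means for every k in ``[k_min, k_max]`` and picks the interior k
    maximising the second difference of the within-cluster sum of squares
    (the sharpest knee); ties resolve to the smallest k.  The WCSS curve
    must be non-increasing — a violation (possible only through unlucky
    restarts) is retried with more initialisations and raised as a
    diagnostic if it persists.
    """
    points = np.asarray(points, dtype=float)
    ks = list(range(k_min, k_max + 1))
    if len(ks) < 3:
        raise ValueError("need at least 3 k values for an interior elbow point")
    if k_max > points.shape[0]:
        raise ValueError("k_max exceeds the sample count")
    wcss: dict[int, float] = {}
    for k in ks:
        _, inertia = kmeans_cluster(points, k, seed, n_init)
        if wcss and inertia > wcss[k - 1] + 1e-9:
            _, inertia = kmeans_cluster(points, k, seed, n_init * 5)
            if inertia > wcss[k - 1] + 1e-9:
                raise RuntimeError(
                    f"WCSS increased from k={k - 1} to k={k}; clustering restarts "
                    "failed to find a better optimum"
                )
        wcss[k] = inertia
    return suggest_k_from_wcss(wcss), wcss


def suggest_k_from_wcss(wcss: dict[int, float]) -> int:
    """The elbow rule: the interior k maximising the second difference
    ``(wcss[k-1] - wcss[k]) - (wcss[k] - wcss[k+1])``; ties resolve to the
    smallest k."""
    ks = sorted(wcss)
    if len(ks) < 3:
        raise ValueError("need at least 3 k values for an interior elbow point")
    best_k, best_gain = None, -np.inf
    for k in ks[1:-1]:
        gain = (wcss[k - 1] - wcss[k]) - (wcss[k] - wcss[k + 1])
        if gain > best_gain + 1e-12:
            best_k, best_gain = k, gain
    return int(best_k)


def cluster_view(
    c,
    method: str = "pca",
    k: int | None = None,
    k_min: int = 1,
    k_max: int = 9,
    params: dict | None = None,
    seed: int = 0,
) -> ClusterView:
    """Embed, pick k by the elbow rule when not given, and cluster."""
    coords = embed(c, method, params, seed)
    suggested, wcss = elbow_suggest_k(coords, k_min, k_max, seed)
    k = k or suggested
    labels, _ = kmeans_cluster(coords, k, seed)
    n_found = len(np.unique(labels))
    if n_found < k:
        warnings.warn(f"k-means produced {n_found} non-empty clusters for k={k}")
    return ClusterView(coords, method, dict(params or {}), labels, k, wcss, suggested)
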