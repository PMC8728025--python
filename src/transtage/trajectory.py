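"""Hidden layer -> PCA -> 3-D UMAP -> principal-curve trajectory -> severity.

The hidden representation of the whole cohort is reduced to 50 principal
components (mean-centering only), embedded in three dimensions by UMAP
(cosine metric, 15 neighbours, min_dist 0.1), and summarized by a single
lineage: a minimum spanning tree over cluster centroids gives an initial
polyline which is refined into a principal curve.  The severity index (SI)
of a sample is its arc-length position along the curve measured from the
control-dominated origin end, so SI = 0 at the healthy terminus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA


# ---------------------------------------------------------------- PCA

@dataclass
class PCAModel:
    center: np.ndarray
    rotation: np.ndarray            # n_features x k, orthonormal columns
    explained_variance: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.center) @ self.rotation


def fit_pca(X: np.ndarray, k: int = 50) -> Tuple[PCAModel, np.ndarray]:
    """Truncated PCA with mean-centering only (no variance scaling).

    Sign convention: each component's largest-magnitude loading is positive,
    which makes the rotation deterministic across SVD backends.
    """
    X = np.asarray(X, dtype=float)
    max_k = min(X.shape[0] - 1, X.shape[1])
    if np.allclose(X, X[0]):
        raise ValueError("constant matrix has no principal components")
    if k > max_k:
        warnings.warn(f"k reduced from {k} to {max_k}")
        k = max_k
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    rotation = pca.components_.T.copy()
    for j in range(rotation.shape[1]):
        i = np.argmax(np.abs(rotation[:, j]))
        if rotation[i, j] < 0:
            rotation[:, j] *= -1
            scores[:, j] *= -1
    model = PCAModel(pca.mean_.copy(), rotation,
                     pca.explained_variance_.copy())
    return model, scores


def apply_pca(model: PCAModel, X: np.ndarray) -> np.ndarray:
    return model.transform(X)


# ---------------------------------------------------------------- UMAP

@dataclass
class UMAPConfig:
    n_components: int = 3
    n_neighbors: int = 15
    metric: str = "cosine"
    min_dist: float = 0.1
    seed: int = 2016


class UMAPModel:
    """Frozen UMAP embedding supporting out-of-sample transform."""

    def __init__(self, config: UMAPConfig):
        self.config = config
        self._reducer = None
        self.embedding: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> np.ndarray:
        import umap

        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.config.n_neighbors + 1:
            raise ValueError("need at least n_neighbors + 1 samples")
        self._reducer = umap.UMAP(
            n_components=self.config.n_components,
            n_neighbors=self.config.n_neighbors,
            metric=self.config.metric,
            min_dist=self.config.min_dist,
            random_state=self.config.seed,
        )
        self.embedding = np.asarray(self._reducer.fit_transform(X),
                                    dtype=float)
        return self.embedding

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self._reducer is None:
            raise RuntimeError("transform before fit")
        return np.asarray(self._reducer.transform(np.asarray(X, dtype=float)),
                          dtype=float)


def fit_umap(scores: np.ndarray,
             config: UMAPConfig = UMAPConfig()) -> Tuple[UMAPModel, np.ndarray]:
    model = UMAPModel(config)
    embedding = model.fit(scores)
    return model, embedding


def transform_umap(model: UMAPModel, scores: np.ndarray) -> np.ndarray:
    return model.transform(scores)


# ---------------------------------------------------------------- trajectory

@dataclass
class TrajectoryModel:
    """Single-lineage principal curve through the 3-D embedding."""

    polyline: np.ndarray          # m x 3 ordered vertices, origin end first
    origin_cluster: int
    cluster_labels: np.ndarray
    centroids: np.ndarray
    mst_edges: list

    @property
    def arc_length(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.polyline, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])


def _dedupe_polyline(poly: np.ndarray) -> np.ndarray:
    keep = [0]
    for i in range(1, len(poly)):
        if np.linalg.norm(poly[i] - poly[keep[-1]]) > 1e-12:
            keep.append(i)
    return poly[keep]


def _project_to_polyline(poly: np.ndarray, points: np.ndarray):
    """Nearest-point projection of each point onto the polyline.

    Returns (arc-length position, squared distance) per point.
    """
    a = poly[:-1]                       # m-1 x 3 segment starts
    d = poly[1:] - a                    # segment vectors
    seg_len2 = (d ** 2).sum(axis=1)
    seg_len = np.sqrt(seg_len2)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    diff = points[:, None, :] - a[None, :, :]          # n x m-1 x 3
    t = np.einsum("nmd,md->nm", diff, d) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * d[None, :, :]
    dist2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    best = np.argmin(dist2, axis=1)
    rows = np.arange(len(points))
    si = cum[best] + t[rows, best] * seg_len[best]
    return si, dist2[rows, best]


def _longest_path_from(adj: dict, start: int) -> list:
    """Longest (by summed edge length) simple path from ``start`` in a tree."""
    best_path = [start]
    best_len = 0.0
    stack = [(start, -1, 0.0, [start])]
    while stack:
        node, parent, length, path = stack.pop()
        if length > best_len:
            best_len, best_path = length, path
        for nbr, w in adj[node]:
            if nbr != parent:
                stack.append((nbr, node, length + w, path + [nbr]))
    return best_path


def fit_trajectory(embedding: np.ndarray, cluster_labels: np.ndarray,
                   diagnosis: Optional[pd.Series] = None,
                   classifier_prob: Optional[np.ndarray] = None,
                   n_bins: Optional[int] = None, max_iter: int = 10,
                   tol: float = 1e-3) -> TrajectoryModel:
    """Fit the single-lineage principal curve.

    Cluster centroids are joined by a Euclidean MST; the longest path
    starting at the origin cluster (the one with the largest fraction of CN
    samples, or the lowest mean classifier probability if diagnosis labels
    are absent) seeds the polyline, which is then refined by projecting
    samples onto the curve, averaging coordinates within arc-length bins and
    lightly smoothing, until sample positions stabilize.
    """
    embedding = np.asarray(embedding, dtype=float)
    labels = np.asarray(cluster_labels).copy()
    n = len(embedding)

    # merge tiny clusters into the nearest one
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters for lineage inference")
    big = uniq[counts >= 3]
    if len(big) < 2:
        raise ValueError("fewer than two clusters with >= 3 points")
    if len(big) < len(uniq):
        warnings.warn("clusters with < 3 points merged into the nearest")
        cent_big = np.array([embedding[labels == u].mean(axis=0) for u in big])
        for u in uniq[counts < 3]:
            for i in np.where(labels == u)[0]:
                labels[i] = big[np.argmin(
                    np.linalg.norm(cent_big - embedding[i], axis=1))]
    uniq = np.unique(labels)
    centroids = np.array([embedding[labels == u].mean(axis=0) for u in uniq])
    k = len(uniq)

    # origin cluster
    if diagnosis is not None:
        diagnosis = np.asarray(diagnosis)
        cn_frac = np.array([
            np.mean(diagnosis[labels == u] == "CN") if (labels == u).any()
            else 0.0 for u in uniq])
        origin_idx = int(np.argmax(cn_frac))
    elif classifier_prob is not None:
        prob = np.asarray(classifier_prob)
        origin_idx = int(np.argmin(
            [prob[labels == u].mean() for u in uniq]))
    else:
        raise ValueError("need diagnosis labels or classifier probabilities "
                         "to locate the origin")

    # Euclidean MST over centroids
    dist = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=2)
    mst = minimum_spanning_tree(dist).toarray()
    adj = {i: [] for i in range(k)}
    edges = []
    for i in range(k):
        for j in range(k):
            if mst[i, j] > 0:
                adj[i].append((j, mst[i, j]))
                adj[j].append((i, mst[i, j]))
                edges.append((int(uniq[i]), int(uniq[j])))
    path = _longest_path_from(adj, origin_idx)
    poly = _dedupe_polyline(centroids[path])

    origin_points = embedding[labels == uniq[origin_idx]]
    if n_bins is None:
        n_bins = max(20, n // 25)

    si_prev = None
    for _ in range(max_iter):
        si, _d2 = _project_to_polyline(poly, embedding)
        edges_bins = np.linspace(0.0, si.max() + 1e-12, n_bins + 1)
        which = np.clip(np.digitize(si, edges_bins) - 1, 0, n_bins - 1)
        verts = [embedding[which == b].mean(axis=0)
                 for b in range(n_bins) if (which == b).any()]
        new_poly = np.asarray(verts)
        if len(new_poly) >= 3:   # light smoothing, endpoints fixed
            sm = new_poly.copy()
            sm[1:-1] = (new_poly[:-2] + new_poly[1:-1] + new_poly[2:]) / 3.0
            new_poly = sm
        new_poly = _dedupe_polyline(new_poly)
        if len(new_poly) < 2:
            break
        # keep the origin end first
        o = origin_points.mean(axis=0)
        if (np.linalg.norm(new_poly[-1] - o)
                < np.linalg.norm(new_poly[0] - o)):
            new_poly = new_poly[::-1]
        poly = new_poly
        si_new, _ = _project_to_polyline(poly, embedding)
        if si_prev is not None and np.mean(np.abs(si_new - si_prev)) < tol:
            si_prev = si_new
            break
        si_prev = si_new

    return TrajectoryModel(polyline=poly,
                           origin_cluster=int(uniq[origin_idx]),
                           cluster_labels=labels, centroids=centroids,
                           mst_edges=edges)


def compute_si(traj: TrajectoryModel, embedding: np.ndarray,
               sample_ids: Optional[Sequence[str]] = None) -> pd.Series:
    """Arc-length severity index from the origin end of the curve."""
    si, _ = _project_to_polyline(traj.polyline,
                                 np.asarray(embedding, dtype=float))
    index = list(sample_ids) if sample_ids is not None else range(len(si))
    return pd.Series(si, index=index, name="si")


def cluster_embedding(embedding: np.ndarray, k: int = 2,
                      seed: int = 0) -> np.ndarray:
    """Default lineage clusters: k-means on the 3-D embedding."""
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(np.asarray(embedding, dtype=float))
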