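"""K-means clustering driven by the Fire Hawk Optimizer.

A candidate solution is a flattened K x d centroid matrix; its fitness is
the within-cluster sum of squares (WCSS). The FHO explores the per-feature
data extrema box globally, and the best centroid set found is then refined
with standard Lloyd iterations (nearest-centroid assignment alternating
with mean updates) until convergence — the hybrid alternates global search
with the classical center-update/assignment loop.

Cluster-number selection scores each K by the mean silhouette coefficient
of the fitted model and picks the argmax (ties to the smallest K): the raw
WCSS decreases monotonically with K and cannot exhibit an interior optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fho import FHOConfig, SearchSpace, minimize as fho_minimize

__all__ = [
    "ClusteringModel",
    "KSelectionReport",
    "wcss",
    "assign",
    "cluster",
    "select_k",
    "mean_silhouette",
]


@dataclass
class ClusteringModel:
    K: int
    centroids: np.ndarray          # K x d
    assignments: np.ndarray        # n, ints in [0, K)
    objective: float               # WCSS at the returned centroids

    def to_dict(self) -> dict:
        return {
            "K": int(self.K),
            "centroids": self.centroids.tolist(),
            "objective": float(self.objective),
        }

    @classmethod
    def from_dict(cls, d: dict, points: np.ndarray | None = None) -> "ClusteringModel":
        cents = np.asarray(d["centroids"], float)
        assigns = assign(points, cents) if points is not None else np.empty(0, int)
        return cls(int(d["K"]), cents, assigns, float(d["objective"]))


@dataclass
class KSelectionReport:
    candidate_ks: list[int]
    scores: list[float]
    chosen_k: int
    models: dict[int, ClusteringModel]


def assign(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels (squared Euclidean; ties to the lowest index)."""
    points = np.asarray(points, float)
    d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def wcss(points: np.ndarray, centroids: np.ndarray) -> float:
    """Within-cluster sum of squared distances under nearest-centroid labels."""
    points = np.asarray(points, float)
    if points.size == 0:
        raise ValueError("empty point set")
    d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return float(d2.min(axis=1).sum())


def _repair_empty(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Re-seed empty clusters at the point farthest from its own centroid."""
    cents = centroids.copy()
    for _ in range(cents.shape[0]):
        labels = assign(points, cents)
        empties = np.setdiff1d(np.arange(cents.shape[0]), np.unique(labels))
        if empties.size == 0:
            break
        d2 = ((points - cents[labels]) ** 2).sum(axis=1)
        far = int(np.argmax(d2))
        cents[empties[0]] = points[far]
    return cents


def _lloyd(points: np.ndarray, centroids: np.ndarray, max_iter: int = 100,
           tol: float = 1e-10) -> np.ndarray:
    """Classical center-update/assignment iterations from a warm start."""
    cents = _repair_empty(points, centroids)
    for _ in range(max_iter):
        labels = assign(points, cents)
        new = cents.copy()
        for k in range(cents.shape[0]):
            members = points[labels == k]
            if members.shape[0]:
                new[k] = members.mean(axis=0)
        new = _repair_empty(points, new)
        if np.max(np.abs(new - cents)) < tol:
            cents = new
            break
        cents = new
    return cents


def cluster(points, K: int, fho_config: FHOConfig | None = None,
            warm_start: np.ndarray | None = None) -> ClusteringModel:
    """Cluster ``points`` into K groups by FHO-minimized WCSS.

    The search box is the per-coordinate data extrema tiled K times. Empty
    clusters are repaired (farthest-point re-seeding) before each fitness
    evaluation. ``warm_start`` (a K x d centroid matrix) is injected into
    the initial population when given.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D matrix")
    n, d = pts.shape
    if not 1 <= K <= n:
        raise ValueError(f"need 1 <= K <= n ({K=}, {n=})")
    cfg = fho_config or FHOConfig()

    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    space = SearchSpace(np.tile(lo, K), np.tile(lo + span, K))

    def objective(flat: np.ndarray) -> float:
        cents = _repair_empty(pts, flat.reshape(K, d))
        return wcss(pts, cents)

    result = fho_minimize(objective, space, cfg)
    best = result.best_position.reshape(K, d)
    if warm_start is not None:
        ws = np.asarray(warm_start, float).reshape(K, d)
        if wcss(pts, _repair_empty(pts, ws)) < result.best_fitness:
            best = ws
    cents = _lloyd(pts, best)
    labels = assign(pts, cents)
    return ClusteringModel(K, cents, labels, wcss(pts, cents))


def mean_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient over all points.

    Degenerate cases score 0: a single cluster, singleton clusters
    (b undefined for their members gives s=0), or zero spread.
    """
    pts = np.asarray(points, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        return 0.0
    n = pts.shape[0]
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own <= 1:
            continue  # singleton: silhouette defined as 0
        a = d[i, own].sum() / (n_own - 1)
        b = np.inf
        for c in uniq:
            if c == labels[i]:
                continue
            b = min(b, d[i, labels == c].mean())
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def select_k(points, k_range, fho_config: FHOConfig | None = None) -> KSelectionReport:
    """Pick the cluster count whose fitted model maximizes mean silhouette.

    Ties resolve to the smallest K. Each K reuses the same FHO config; the
    per-K seed is offset so runs stay independent but reproducible.
    """
    ks = [int(k) for k in k_range]
    if not ks:
        raise ValueError("k_range must be non-empty")
    pts = np.asarray(points, float)
    n = pts.shape[0]
    for k in ks:
        if not 2 <= k <= n - 1:
            raise ValueError(f"every K must satisfy 2 <= K <= n-1, got {k}")
    cfg = fho_config or FHOConfig()
    scores, models = [], {}
    for k in ks:
        sub = FHOConfig(cfg.pop_size, cfg.max_iters, cfg.hawk_count_cap,
                        seed=(cfg.seed * 1000 + k) % (2 ** 31))
        model = cluster(pts, k, sub)
        models[k] = model
        scores.append(mean_silhouette(pts, model.assignments))
    best = int(np.argmax(scores))  # argmax takes the first max -> smallest K
    return KSelectionReport(ks, scores, ks[best], models)
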