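"""Cluster-derived fatigue grading.

Implements Lloyd's K-means with seeded multi-start, silhouette-based
selection of the cluster count, per-cluster threshold extraction on the
two normalized indicators (reaction time y1, Borg y2), weighted
combination of those thresholds into bands of the composite index F,
and consolidation of overlapping bands into a small number of grades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .entropy import EntropyWeights

__all__ = [
    "ClusterModel",
    "GradeThresholds",
    "euclidean",
    "kmeans",
    "silhouette",
    "select_k",
    "cluster_thresholds",
    "weighted_thresholds",
    "consolidate_levels",
]

MAX_ITER = 100


def euclidean(p, q) -> float:
    """Euclidean distance between two equal-length vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"dimension mismatch: {p.shape} vs {q.shape}")
    return float(np.sqrt(np.sum((p - q) ** 2)))


@dataclass(frozen=True)
class ClusterModel:
    """Result of a multi-start K-means run."""

    K: int
    centroids: np.ndarray  # (K, d)
    labels: np.ndarray  # (n,)
    within_ss: float
    replicates: int
    seed: int | None = None


def _assign(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # squared distances; argmin breaks ties toward the lowest centroid index
    d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _within_ss(points: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    return float(((points - centroids[labels]) ** 2).sum())


def _lloyd(
    points: np.ndarray, K: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    n = points.shape[0]
    centroids = points[rng.choice(n, size=K, replace=False)].copy()
    labels = _assign(points, centroids)
    prev_ss = _within_ss(points, centroids, labels)
    for _ in range(MAX_ITER):
        for k in range(K):
            members = labels == k
            if members.any():
                centroids[k] = points[members].mean(axis=0)
            else:
                # empty-cluster repair: reseed at the point farthest from
                # its currently assigned centroid (keeps K fixed)
                dist = ((points - centroids[labels]) ** 2).sum(axis=1)
                centroids[k] = points[int(dist.argmax())]
        new_labels = _assign(points, centroids)
        ss = _within_ss(points, centroids, new_labels)
        assert ss <= prev_ss + 1e-8, "Lloyd iteration increased within-SS"
        if np.array_equal(new_labels, labels):
            labels = new_labels
            prev_ss = ss
            break
        labels = new_labels
        prev_ss = ss
    return centroids, labels, prev_ss


def kmeans(
    points: np.ndarray,
    K: int,
    replicates: int = 10,
    seed: int | np.random.Generator | None = 0,
) -> ClusterModel:
    """Best-of-`replicates` Lloyd K-means, initial centroids drawn from the data.

    Each replicate starts from K distinct data points sampled without
    replacement from its own seeded stream; the model with the smallest
    within-cluster sum of squares is returned.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be an (n, d) array")
    n = points.shape[0]
    if not np.isfinite(points).all():
        raise ValueError("points must be finite")
    if not 1 <= K <= n:
        raise ValueError(f"K={K} must lie in [1, n={n}]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(replicates):
        cent, lab, ss = _lloyd(points, K, rng)
        if best is None or ss < best[2]:
            best = (cent, lab, ss)
    cent, lab, ss = best
    return ClusterModel(
        K=K,
        centroids=cent,
        labels=lab,
        within_ss=ss,
        replicates=replicates,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def silhouette(points: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-sample silhouette values and their mean.

    s_i = (b_i - a_i) / max(a_i, b_i), with a_i the mean distance of
    sample i to the other members of its own cluster and b_i the
    smallest mean distance to any other cluster.  Members of singleton
    clusters score 0.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = points.shape[0]
    dist = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = dist[i, own].sum() / (n_own - 1)
        b = min(
            dist[i, labels == c].mean() for c in clusters if c != labels[i]
        )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


def select_k(
    points: np.ndarray,
    k_range: range | list[int] = range(2, 11),
    replicates: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Mean silhouette of the best K-means replicate for each candidate K.

    Returns the (K, mean_silhouette) table and the argmax K.  For each
    K the clustering is repeated `replicates` times and the silhouette
    of the lowest-within-SS model is scored.
    """
    points = np.asarray(points, dtype=float)
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range must be non-empty")
    if max(ks) > points.shape[0]:
        raise ValueError("max(k_range) exceeds the number of points")
    rows = []
    root = np.random.SeedSequence(seed)
    for k, ss in zip(ks, root.spawn(len(ks))):
        model = kmeans(points, k, replicates=replicates, seed=np.random.default_rng(ss))
        _, mean_s = silhouette(points, model.labels)
        rows.append({"K": k, "mean_silhouette": mean_s})
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["mean_silhouette"].idxmax(), "K"])
    return table, best_k


@dataclass(frozen=True)
class GradeThresholds:
    """Per-level per-indicator intervals, with optional F bands and map."""

    levels: list[dict[str, tuple[float, float]]]  # ordered by severity
    f_intervals: list[tuple[float, float]] | None = None
    consolidation: dict[int, int] | None = None
    feature_names: tuple[str, ...] = field(default=("rt", "borg"))

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def cluster_thresholds(
    points: np.ndarray,
    labels: np.ndarray,
    feature_names: tuple[str, ...] = ("rt", "borg"),
) -> GradeThresholds:
    """Per-cluster [min, max] interval of each indicator, ordered by severity.

    *points* are the normalized (y1, y2) pairs in [0, 1]; clusters are
    ordered by the mean of their centroid coordinates, so level 1 is the
    least-fatigued cluster.  Adjacent intervals may overlap.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if points.min() < -1e-9 or points.max() > 1 + 1e-9:
        raise ValueError("points must be normalized to [0, 1]")
    clusters = np.unique(labels)
    centroids = np.array([points[labels == c].mean(axis=0) for c in clusters])
    order = np.argsort(centroids.mean(axis=1))
    levels = []
    for idx in order:
        members = points[labels == clusters[idx]]
        if members.size == 0:
            raise ValueError("empty cluster")
        levels.append(
            {
                name: (float(members[:, j].min()), float(members[:, j].max()))
                for j, name in enumerate(feature_names)
            }
        )
    return GradeThresholds(levels=levels, feature_names=tuple(feature_names))


def weighted_thresholds(
    thresholds: GradeThresholds, weights: EntropyWeights | dict[str, float]
) -> list[tuple[float, float]]:
    """Combine per-indicator intervals into F intervals, level by level.

    Each bound is the weight-combination of the indicator bounds:
    F_lo = sum_j w_j * lo_j, F_hi = sum_j w_j * hi_j.
    """
    w = weights.w.to_dict() if isinstance(weights, EntropyWeights) else dict(weights)
    names = thresholds.feature_names
    missing = set(names) - set(w)
    if missing:
        raise ValueError(f"weights missing for features {sorted(missing)}")
    if abs(sum(w[n] for n in names) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1 over the threshold features")
    out = []
    for level in thresholds.levels:
        lo = sum(w[n] * level[n][0] for n in names)
        hi = sum(w[n] * level[n][1] for n in names)
        out.append((lo, hi))
    return out


def _overlap_fraction(a: tuple[float, float], b: tuple[float, float]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    narrower = min(a[1] - a[0], b[1] - b[0])
    if narrower <= 0:
        return 1.0  # a degenerate interval inside the other
    # containment counts as full overlap
    if (a[0] >= b[0] and a[1] <= b[1]) or (b[0] >= a[0] and b[1] <= a[1]):
        return 1.0
    return inter / narrower


def consolidate_levels(
    f_intervals: list[tuple[float, float]],
    min_overlap: float = 0.5,
    target_levels: int = 3,
) -> tuple[list[tuple[float, float]], dict[int, int]]:
    """Merge overlapping adjacent F bands into a coarser grading.

    Two rules, applied repeatedly until neither fires:

    * adjacent bands whose intersection covers at least ``min_overlap``
      of the narrower band, or where one band contains the other, are
      always merged;
    * while more than ``target_levels`` bands remain, the adjacent pair
      with the largest (positive) overlap fraction is merged, ties going
      to the lower pair.

    A merged band spans the union.  Pairwise-disjoint bands are returned
    unchanged.  Returns the merged bands and the order-preserving map
    from original 1-based levels to consolidated 1-based levels.
    """
    bands = [tuple(map(float, iv)) for iv in f_intervals]
    if any(iv[0] > iv[1] for iv in bands):
        raise ValueError("each interval must satisfy lo <= hi")
    groups: list[list[int]] = [[i] for i in range(len(bands))]

    while len(bands) > 1:
        fracs = [
            _overlap_fraction(bands[i], bands[i + 1]) for i in range(len(bands) - 1)
        ]
        candidates = [i for i, f in enumerate(fracs) if f >= min_overlap]
        if not candidates and len(bands) > target_levels:
            positive = [i for i, f in enumerate(fracs) if f > 0]
            if positive:
                best = max(max(fracs[i] for i in positive), 0.0)
                candidates = [i for i in positive if fracs[i] == best]
        if not candidates:
            break
        i = candidates[0] if len(candidates) == 1 else max(
            candidates, key=lambda j: (fracs[j], -j)
        )
        merged = (min(bands[i][0], bands[i + 1][0]), max(bands[i][1], bands[i + 1][1]))
        bands[i : i + 2] = [merged]
        groups[i : i + 2] = [groups[i] + groups[i + 1]]

    mapping = {
        orig + 1: lvl + 1 for lvl, group in enumerate(groups) for orig in group
    }
    return bands, mapping
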