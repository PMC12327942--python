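"""Spatial clustering of channel coordinates with silhouette model selection.

k-means (Euclidean distance on 3-D millimetre coordinates) is run for each
candidate number of clusters (2-10 by default); the mean silhouette score
selects the best k. Clustering *consistency* between two channel sets (e.g.
channels significant in the task-vs-rest contrast vs channels significant in
the brain-behaviour correlation) is compared by the silhouette-score
difference with a permutation test that re-assigns points between the two
sets while preserving their sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


@dataclass
class ClusterResult:
    k_range: tuple[int, ...]
    silhouette: np.ndarray  # one mean score per k
    best_k: int
    labels: np.ndarray  # labels at best_k
    input_set: str = ""


def _silhouette_for_k(coords: np.ndarray, k: int, seed: int, n_init: int) -> tuple[float, np.ndarray]:
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(coords)
    if len(np.unique(labels)) < 2:
        return -1.0, labels
    return float(silhouette_score(coords, labels)), labels


def _lloyd(x: np.ndarray, k: int, rng: np.random.Generator, n_init: int, n_iter: int = 30):
    """Small vectorised Lloyd k-means (k-means++ seeding, best inertia kept).

    Used inside the permutation loop, where the per-fit overhead of the
    scikit-learn estimator dominates; point sets there are tiny.
    """
    n = len(x)
    best_inertia = np.inf
    best_labels = None
    for _ in range(n_init):
        centers = np.empty((k, x.shape[1]))
        centers[0] = x[rng.integers(n)]
        d2 = ((x - centers[0]) ** 2).sum(axis=1)
        for j in range(1, k):
            p = d2 / d2.sum() if d2.sum() > 0 else None
            centers[j] = x[rng.choice(n, p=p)]
            d2 = np.minimum(d2, ((x - centers[j]) ** 2).sum(axis=1))
        labels = None
        for _ in range(n_iter):
            dist = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            new_labels = dist.argmin(axis=1)
            if labels is not None and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                sel = labels == j
                if sel.any():
                    centers[j] = x[sel].mean(axis=0)
        inertia = ((x - centers[labels]) ** 2).sum()
        if inertia < best_inertia:
            best_inertia = inertia
            best_labels = labels
    return best_labels


def _silhouette_from_dist(dist: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette from a precomputed pairwise distance matrix."""
    n = len(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        return -1.0
    sil = np.zeros(n)
    means = np.stack([dist[:, labels == c].sum(axis=1) for c in uniq], axis=1)
    counts = np.array([(labels == c).sum() for c in uniq])
    for i in range(n):
        ci = np.flatnonzero(uniq == labels[i])[0]
        if counts[ci] <= 1:
            sil[i] = 0.0
            continue
        a = means[i, ci] / (counts[ci] - 1)
        other = [means[i, cj] / counts[cj] for cj in range(len(uniq)) if cj != ci]
        b = min(other)
        sil[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(sil.mean())


def _fast_silhouette(x: np.ndarray, k: int, rng: np.random.Generator, n_init: int) -> float:
    labels = _lloyd(x, k, rng, n_init)
    diff = x[:, None, :] - x[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    return _silhouette_from_dist(dist, labels)


def kmeans_silhouette(
    coords,
    k_range=range(2, 11),
    seed: int = 0,
    n_init: int = 50,
    input_set: str = "",
) -> ClusterResult:
    """Silhouette-selected k-means clustering of channel coordinates.

    For each k, k-means runs with ``n_init`` restarts (best inertia kept,
    fixed seed, deterministic); best_k maximises the mean silhouette.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2:
        raise ValueError("coords must be n x d")
    ks = tuple(int(k) for k in k_range)
    if len(x) < max(ks) + 1:
        raise ValueError(f"need at least {max(ks) + 1} points for k up to {max(ks)}")
    if len(np.unique(x, axis=0)) <= max(ks):
        raise ValueError("too many duplicate points for the requested k range")
    scores = np.empty(len(ks))
    all_labels = []
    for i, k in enumerate(ks):
        scores[i], lab = _silhouette_for_k(x, k, seed, n_init)
        all_labels.append(lab)
    best = int(np.argmax(scores))
    return ClusterResult(ks, scores, ks[best], all_labels[best], input_set)


@dataclass
class ClusterabilityComparison:
    k_range: tuple[int, ...]
    observed_diff: np.ndarray  # silhouette(set_b) - silhouette(set_a) per k
    p_values: np.ndarray  # one-sided (b more clusterable) per k
    best_k_diff: float
    best_k_p: float
    n_perm: int


def compare_clusterability(
    set_a,
    set_b,
    k_range=range(2, 11),
    n_perm: int = 1000,
    seed: int = 0,
    n_init_obs: int = 50,
    n_init_null: int = 5,
) -> ClusterabilityComparison:
    """Permutation comparison of silhouette scores between two channel sets.

    Observed statistic: silhouette(set_b) - silhouette(set_a) at each k (and
    at set_b's best k). Null: points are pooled and randomly re-assigned to
    the two sets preserving sizes (N = n_perm). One-sided p (set_b more
    consistently clustered), +1-corrected. Both the observed statistic and
    the permuted replicates run through the same internal k-means/silhouette
    path (``n_init_null`` restarts) so the test is exchangeable; the reported
    per-k silhouettes use the full estimator with ``n_init_obs`` restarts.
    """
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if len(a) < 6 or len(b) < 6:
        raise ValueError("both channel sets need at least 6 points")
    ks = tuple(int(k) for k in k_range)
    ks = tuple(k for k in ks if k < min(len(a), len(b)))
    sil_a = np.array([_silhouette_for_k(a, k, seed, n_init_obs)[0] for k in ks])
    sil_b = np.array([_silhouette_for_k(b, k, seed, n_init_obs)[0] for k in ks])
    best_i = int(np.argmax(sil_b))

    rng = np.random.default_rng(seed)
    obs = np.array(
        [
            _fast_silhouette(b, k, rng, n_init_null) - _fast_silhouette(a, k, rng, n_init_null)
            for k in ks
        ]
    )
    pooled = np.vstack([a, b])
    n_a = len(a)
    count = np.zeros(len(ks))
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        pa = pooled[perm[:n_a]]
        pb = pooled[perm[n_a:]]
        for i, k in enumerate(ks):
            d = _fast_silhouette(pb, k, rng, n_init_null) - _fast_silhouette(pa, k, rng, n_init_null)
            count[i] += d >= obs[i]
    p = (1.0 + count) / (1.0 + n_perm)
    return ClusterabilityComparison(
        k_range=ks,
        observed_diff=obs,
        p_values=p,
        best_k_diff=float(obs[best_i]),
        best_k_p=float(p[best_i]),
        n_perm=n_perm,
    )
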