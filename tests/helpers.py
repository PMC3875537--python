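"""Independent oracles used by the test suite.

Everything here is coded from textbook definitions only and must stay free
of imports from the package under test, so that agreement between the two
routes is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import itertools

import numpy as np


def nipals_pls1(X: np.ndarray, y: np.ndarray):
    """One-component textbook PLS1 on centered X, centered y.

    w = X'y / ||X'y||;  t = X w;  p = X't / t't;  b = t'y / t't.
    Returns (t, w, p, b, r2y).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = X.T @ y
    w = w / np.linalg.norm(w)
    t = X @ w
    p = X.T @ t / (t @ t)
    b = float(t @ y) / float(t @ t)
    resid = y - b * t
    r2y = 1.0 - float(resid @ resid) / float(y @ y)
    return t, w, p, b, r2y


def splot_direct(t: np.ndarray, X: np.ndarray):
    """Direct per-gene evaluation of cov(t, X) and corr(t, X).

    cov_g = sum_i t_i * X_ig / (N - 1);  corr_g = cov_g / (s_t * s_Xg),
    with s the N-1 sample standard deviations.
    """
    t = np.asarray(t, dtype=float)
    X = np.asarray(X, dtype=float)
    n = t.size
    cov = np.array([float(np.sum(t * X[:, g])) / (n - 1) for g in range(X.shape[1])])
    s_t = float(np.sqrt(np.sum((t - t.mean()) ** 2) / (n - 1)))
    s_x = np.array([
        float(np.sqrt(np.sum((X[:, g] - X[:, g].mean()) ** 2) / (n - 1)))
        for g in range(X.shape[1])
    ])
    corr = cov / (s_t * s_x)
    return cov, corr


def naive_agglomerate(points: np.ndarray, linkage: str):
    """O(n^3) agglomerative clustering recomputing cluster distances from scratch.

    Returns the sorted list of merge heights.  Cluster distances:
    average = mean pairwise point distance, complete = max pairwise,
    ward = sqrt(2 |A||B| / (|A|+|B|)) * ||centroid_A - centroid_B||.
    """
    points = np.asarray(points, dtype=float)
    clusters: list[list[int]] = [[i] for i in range(len(points))]
    heights: list[float] = []

    def dist(a: list[int], b: list[int]) -> float:
        if linkage == "average":
            return float(np.mean([
                np.linalg.norm(points[i] - points[j]) for i in a for j in b
            ]))
        if linkage == "complete":
            return float(max(
                np.linalg.norm(points[i] - points[j]) for i in a for j in b
            ))
        if linkage == "ward":
            ca, cb = points[a].mean(axis=0), points[b].mean(axis=0)
            return float(np.sqrt(2.0 * len(a) * len(b) / (len(a) + len(b)))
                         * np.linalg.norm(ca - cb))
        raise ValueError(linkage)

    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = dist(clusters[i], clusters[j])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return sorted(heights)


def brute_force_misclassified(flat_clusters, labels):
    """Minimum misclassification over all injective cluster -> class mappings."""
    clusters = sorted(set(flat_clusters))
    classes = sorted(set(labels))
    assert len(clusters) <= len(classes), "brute force assumes k <= n_classes"
    best = None
    for perm in itertools.permutations(classes, len(clusters)):
        mapping = dict(zip(clusters, perm))
        mis = sum(1 for c, lab in zip(flat_clusters, labels) if mapping[c] != lab)
        if best is None or mis < best:
            best = mis
    return best
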