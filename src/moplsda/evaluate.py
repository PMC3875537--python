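"""Panel validation: PCA score plots and hierarchical cluster analysis.

A selected gene panel is judged by whether unsupervised structure recovers
the known classes: PCA should separate them in the leading score
components, and an agglomerative dendrogram cut at k = number of classes
should reproduce the class partition.  Misclassification is made a scalar
by choosing the injective cluster -> class mapping that minimizes the
number of samples landing in a cluster mapped to a different class.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy as sch
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist

from .matrix import ExpressionMatrix

DISTANCES = ("euclidean", "pearson")
LINKAGES = ("ward", "average", "complete")


@dataclass
class PcaResult:
    """Truncated SVD decomposition X ~ T P' of a centered sample x gene matrix."""

    scores: np.ndarray              # samples x components (T)
    loadings: np.ndarray            # genes x components (P)
    explained_fraction: np.ndarray  # per component, of total X sum of squares
    residual_fraction: float
    residual_norm: float            # ||X - T P'||_F  (the E block)
    sample_ids: list[str] = field(default_factory=list)


@dataclass
class LinkageTree:
    """Agglomerative merge sequence over samples (scipy linkage encoding)."""

    Z: np.ndarray
    sample_ids: list[str]
    distance: str
    linkage: str


@dataclass
class ClusterEvaluation:
    tree: LinkageTree
    k_clusters: int
    assignment: dict[str, int]      # sample -> cluster id (1-based)
    mapping: dict[int, str]         # cluster id -> class
    misclassified: list[str]
    n_misclassified: int


def pca(m: ExpressionMatrix, n_components: int) -> PcaResult:
    """Principal components of the centered sample x gene matrix, via SVD.

    Scores are left singular vectors scaled by the singular values; each
    component's sign is fixed so its largest-magnitude loading is positive.
    ``n_components`` beyond the matrix rank is truncated with a warning.
    """
    m.require_state("centered")
    X = m.values.T  # samples x genes
    if n_components < 1 or n_components > min(X.shape):
        raise ValueError(
            f"n_components must be in [1, {min(X.shape)}], got {n_components}"
        )
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s ** 2))
    rank = int(np.sum(s > s[0] * max(X.shape) * np.finfo(float).eps)) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating",
            stacklevel=2,
        )
        n_components = max(rank, 1)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    loadings = Vt.T
    scores = U * s
    # deterministic orientation: largest-|loading| entry positive per component
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    explained = (s ** 2) / total if total > 0 else np.zeros_like(s)
    residual = X - scores @ loadings.T
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_fraction=explained,
        residual_fraction=float(1.0 - explained.sum()),
        residual_norm=float(np.linalg.norm(residual)),
        sample_ids=list(m.sample_ids),
    )


def hcluster(m: ExpressionMatrix, distance: str = "euclidean",
             linkage: str = "average") -> LinkageTree:
    """Agglomerative clustering of samples.

    Pearson distance is 1 - Pearson correlation between sample expression
    profiles (so it ignores per-sample scale and offset); Euclidean is the
    plain L2 distance between profiles.
    """
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if m.n_samples < 2:
        raise ValueError("clustering needs at least 2 samples")
    X = m.values.T  # samples x genes
    if distance == "pearson":
        sd = X.std(axis=1)
        if np.any(sd <= 0):
            bad = [m.sample_ids[i] for i in np.nonzero(sd <= 0)[0]]
            raise ValueError(
                f"pearson distance undefined for zero-variance samples: {bad[:10]}"
            )
        d = pdist(X, metric="correlation")
        d = np.clip(d, 0.0, None)  # tiny negatives from rounding
    else:
        d = pdist(X, metric="euclidean")
    Z = sch.linkage(d, method=linkage)
    return LinkageTree(Z=Z, sample_ids=list(m.sample_ids),
                       distance=distance, linkage=linkage)


def _best_injective_mapping(confusion: np.ndarray, clusters: list[int],
                            classes: list[str]) -> dict[int, str]:
    """Injective cluster -> class map maximizing correctly placed samples.

    Solved exactly as a rectangular assignment problem (Hungarian method);
    for <= 5 classes this matches brute-force enumeration over all
    injective mappings.
    """
    row, col = linear_sum_assignment(-confusion)
    return {clusters[r]: classes[c] for r, c in zip(row, col)}


def count_misclassified(tree: LinkageTree, labels: dict[str, str],
                        k_clusters: int | None = None) -> ClusterEvaluation:
    """Cut the dendrogram and count samples placed with the wrong class.

    The tree is cut into ``k_clusters`` flat clusters (default: the number
    of distinct classes), each cluster is mapped to a class by the optimal
    injective assignment, and samples whose own class differs from their
    cluster's mapped class are reported as misclassified.
    """
    missing = [s for s in tree.sample_ids if s not in labels]
    if missing:
        raise KeyError(f"samples without labels: {missing[:10]}")
    y = [labels[s] for s in tree.sample_ids]
    classes = sorted(set(y))
    if k_clusters is None:
        k_clusters = len(classes)
    if k_clusters < 1:
        raise ValueError("k_clusters must be >= 1")
    if k_clusters > len(tree.sample_ids):
        raise ValueError("k_clusters exceeds the number of samples")

    flat = sch.fcluster(tree.Z, t=k_clusters, criterion="maxclust")
    clusters = sorted(set(int(c) for c in flat))
    confusion = np.zeros((len(clusters), len(classes)), dtype=int)
    cl_index = {c: i for i, c in enumerate(clusters)}
    cls_index = {c: i for i, c in enumerate(classes)}
    for c, lab in zip(flat, y):
        confusion[cl_index[int(c)], cls_index[lab]] += 1

    if len(clusters) <= len(classes):
        mapping = _best_injective_mapping(confusion, clusters, classes)
    else:
        # more clusters than classes: each cluster takes its majority class
        mapping = {c: classes[int(np.argmax(confusion[cl_index[c]]))]
                   for c in clusters}

    mis = [s for s, c, lab in zip(tree.sample_ids, flat, y)
           if mapping.get(int(c)) != lab]
    return ClusterEvaluation(
        tree=tree,
        k_clusters=k_clusters,
        assignment={s: int(c) for s, c in zip(tree.sample_ids, flat)},
        mapping=mapping,
        misclassified=mis,
        n_misclassified=len(mis),
    )


def to_newick(tree: LinkageTree) -> str:
    """Serialize the dendrogram as a Newick string with height-difference branch lengths."""
    root = sch.to_tree(tree.Z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{tree.sample_ids[node.id]}:{length:.10g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return walk(root, root.dist) + ";"
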