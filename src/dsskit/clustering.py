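"""Drug-response profile clustering and external cluster-index evaluation.

Drugs are clustered by Ward's hierarchical algorithm on a Spearman
rank-correlation dissimilarity of their differential response profiles,
partitioned with an adaptive (dynamic) branch cut, and the partition is
scored against mechanism-of-action classes with pair-counting indices
(Rand, adjusted Rand, Jaccard, Fowlkes-Mallows).  Index differences between
two response metrics are tested against a label-shuffling permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "Partition",
    "Dendrogram",
    "spearman_distance_matrix",
    "ward_linkage",
    "dynamic_cut",
    "partition_indices",
    "index_difference_permutation_test",
    "ResponseProfileClustering",
]

INDEX_NAMES = ("rand", "adjusted_rand", "jaccard", "fowlkes_mallows")


@dataclass(frozen=True)
class Partition:
    """Assignment of items (drugs) to cluster labels."""

    item_ids: tuple
    labels: np.ndarray  # integer cluster codes aligned with item_ids

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != (len(self.item_ids),):
            raise ValueError("labels must align with item_ids")
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "Partition":
        items = tuple(mapping)
        _, codes = np.unique([mapping[i] for i in items], return_inverse=True)
        return cls(items, codes)

    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)

    def aligned_labels(self, item_ids: Sequence) -> np.ndarray:
        lookup = {item: lab for item, lab in zip(self.item_ids, self.labels)}
        missing = [i for i in item_ids if i not in lookup]
        if missing:
            raise ValueError(f"items missing from partition: {missing[:5]}")
        return np.array([lookup[i] for i in item_ids])


@dataclass(frozen=True)
class Dendrogram:
    """Ward merge tree: scipy linkage matrix plus the leaf item ids."""

    item_ids: tuple
    linkage: np.ndarray

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = max(parent_height - node.dist, 0.0) if parent_height is not None else 0.0
            if node.is_leaf():
                return f"{self.item_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, None) + ";"


def spearman_distance_matrix(profiles: pd.DataFrame, min_overlap: int = 3) -> pd.DataFrame:
    """1 - Spearman correlation distance between drug profiles.

    ``profiles`` is drugs x samples.  Missing values are handled with
    pairwise-complete ranks; pairs overlapping in fewer than ``min_overlap``
    samples get the maximum observed distance (conservative separation).
    Distances lie in [0, 2], zero on the diagonal.
    """
    if profiles.shape[0] < 2 or profiles.shape[1] < 3:
        raise ValueError("need >= 2 drugs and >= 3 samples")
    X = profiles.to_numpy(dtype=float)
    n = X.shape[0]
    for i, drug in enumerate(profiles.index):
        row = X[i][np.isfinite(X[i])]
        if row.size >= 2 and np.ptp(row) == 0:
            raise ValueError(f"constant profile for drug {drug!r}: Spearman undefined")
    dist = np.zeros((n, n))
    sparse = []
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.isfinite(X[i]) & np.isfinite(X[j])
            if mask.sum() < min_overlap:
                sparse.append((i, j))
                continue
            rho = sps.spearmanr(X[i][mask], X[j][mask]).statistic
            if not np.isfinite(rho):  # constant on the overlap
                rho = 0.0
            dist[i, j] = dist[j, i] = 1.0 - rho
    if sparse:
        dmax = dist.max() if dist.max() > 0 else 2.0
        for i, j in sparse:
            dist[i, j] = dist[j, i] = dmax
    return pd.DataFrame(dist, index=profiles.index, columns=profiles.index)


def ward_linkage(distance: pd.DataFrame) -> Dendrogram:
    """Ward linkage applied directly to the supplied dissimilarities.

    This is the classic un-squared Ward dialect (hclust ``ward.D``): the
    Lance-Williams recurrence runs on the distances as given, which is the
    appropriate reading for a rank-based dissimilarity with no Euclidean
    embedding.  Implemented by feeding sqrt(d) to the squared-dialect solver
    and squaring the merge heights (an exact algebraic identity).
    """
    D = distance.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    condensed = D[np.triu_indices_from(D, k=1)]
    Z = hierarchy.linkage(np.sqrt(np.maximum(condensed, 0.0)), method="ward")
    Z = Z.copy()
    Z[:, 2] = Z[:, 2] ** 2
    return Dendrogram(tuple(distance.index), Z)


def dynamic_cut(dendrogram: Dendrogram, min_cluster_size: int = 3,
                gap: float = 0.5) -> Partition:
    """Adaptive branch cut of a Ward dendrogram.

    Walking down from the root, a merge is split into two clusters when both
    branches hold at least ``min_cluster_size`` items and the branches are
    internally tight relative to the join: every child's own merge height
    must fall below ``(1 - gap)`` times the parent's.  Structureless trees
    (children nearly as high as their parent) and undersized branches stay
    merged, so leftover items are absorbed into their nearest (sibling)
    cluster and every cluster meets the minimum size.
    """
    Z = dendrogram.linkage
    n = len(dendrogram.item_ids)
    if n < max(2, min_cluster_size + 1):
        return Partition(dendrogram.item_ids, np.zeros(n, dtype=int))
    tree = hierarchy.to_tree(Z)

    labels = np.zeros(n, dtype=int)
    next_label = [0]

    def assign(node, label):
        if node.is_leaf():
            labels[node.id] = label
        else:
            assign(node.left, label)
            assign(node.right, label)

    def split(node):
        if node.is_leaf():
            labels[node.id] = next_label[0]
            next_label[0] += 1
            return
        left, right = node.left, node.right
        child_h = max(left.dist, right.dist)
        ok_size = (left.get_count() >= min_cluster_size
                   and right.get_count() >= min_cluster_size)
        ok_gap = node.dist > 0 and child_h < (1.0 - gap) * node.dist
        if ok_size and ok_gap:
            split(left)
            split(right)
        else:
            assign(node, next_label[0])
            next_label[0] += 1

    split(tree)
    # relabel to consecutive codes in leaf order for determinism
    _, codes = np.unique(labels, return_inverse=True)
    return Partition(dendrogram.item_ids, codes)


def _encode(labels: np.ndarray) -> tuple[np.ndarray, int]:
    uniq, inv = np.unique(labels, return_inverse=True)
    return inv, int(uniq.size)


def _pair_counts_coded(ai, ka, bi, kb) -> tuple[float, float, float, float]:
    """(S11, S10, S01, S00) pair counts via the contingency table."""
    n = ai.size
    cont = np.bincount(ai * kb + bi, minlength=ka * kb).astype(float)
    cont = cont.reshape(ka, kb)
    sum_sq = (cont ** 2).sum()
    row_sq = (cont.sum(axis=1) ** 2).sum()
    col_sq = (cont.sum(axis=0) ** 2).sum()
    total = n * (n - 1) / 2.0
    s11 = (sum_sq - n) / 2.0
    s10 = (row_sq - sum_sq) / 2.0
    s01 = (col_sq - sum_sq) / 2.0
    s00 = total - s11 - s10 - s01
    return s11, s10, s01, s00


def _indices_from_codes(ai, ka, bi, kb) -> dict[str, float]:
    s11, s10, s01, s00 = _pair_counts_coded(ai, ka, bi, kb)
    total = s11 + s10 + s01 + s00
    rand = (s11 + s00) / total
    jacc = s11 / (s11 + s10 + s01) if (s11 + s10 + s01) > 0 else 1.0
    fm_den = np.sqrt((s11 + s10) * (s11 + s01))
    fm = s11 / fm_den if fm_den > 0 else 0.0
    # Hubert-Arabie chance correction
    exp = (s11 + s10) * (s11 + s01) / total
    max_index = 0.5 * ((s11 + s10) + (s11 + s01))
    ari = (s11 - exp) / (max_index - exp) if max_index != exp else 1.0
    return {"rand": float(rand), "adjusted_rand": float(ari),
            "jaccard": float(jacc), "fowlkes_mallows": float(fm)}


def _indices_from_labels(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    ai, ka = _encode(np.asarray(a))
    bi, kb = _encode(np.asarray(b))
    return _indices_from_codes(ai, ka, bi, kb)


def partition_indices(p1: Partition, p2: Partition) -> dict[str, float]:
    """Pair-counting agreement indices between two partitions of one item set.

    Rand, Hubert-Arabie adjusted Rand, Jaccard and Fowlkes-Mallows; all equal
    1 for identical partitions.
    """
    if set(p1.item_ids) != set(p2.item_ids):
        raise ValueError("partitions must cover the same item set")
    a = p1.labels
    b = p2.aligned_labels(p1.item_ids)
    return _indices_from_labels(a, b)


def index_difference_permutation_test(partition_a: Partition, partition_b: Partition,
                                      reference: Partition, n_perm: int = 10000,
                                      seed: int | None = None,
                                      min_class_size: int = 3) -> pd.DataFrame:
    """Permutation test of the per-index gain of partition_a over partition_b.

    Both partitions are scored against the reference (MoA) classes; reference
    classes with fewer than ``min_class_size`` items are dropped first.  The
    null shuffles item labels within each observed partition independently
    (cluster sizes preserved) and takes the paired difference of the two
    shuffled index values; the empirical p is the fraction of null
    differences at least as large as the observed one.  Deterministic under
    a fixed seed.
    """
    if seed is None:
        raise ValueError("a seed is required for the permutation null")
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives a very coarse p-value", stacklevel=2)

    keep_classes = [c for c in np.unique(reference.labels)
                    if np.sum(reference.labels == c) >= min_class_size]
    if len(keep_classes) < 2:
        raise ValueError("reference must retain >= 2 classes of sufficient size")
    keep_items = [i for i, lab in zip(reference.item_ids, reference.labels)
                  if lab in keep_classes]

    ref = reference.aligned_labels(keep_items)
    a = partition_a.aligned_labels(keep_items)
    b = partition_b.aligned_labels(keep_items)

    obs_a = _indices_from_labels(a, ref)
    obs_b = _indices_from_labels(b, ref)
    obs = {k: obs_a[k] - obs_b[k] for k in INDEX_NAMES}

    rng = np.random.default_rng(seed)
    ref_i, ref_k = _encode(ref)
    a_i, a_k = _encode(a)
    b_i, b_k = _encode(b)
    counts = {k: 0 for k in INDEX_NAMES}
    for _ in range(n_perm):
        ia = _indices_from_codes(rng.permutation(a_i), a_k, ref_i, ref_k)
        ib = _indices_from_codes(rng.permutation(b_i), b_k, ref_i, ref_k)
        for k in INDEX_NAMES:
            if ia[k] - ib[k] >= obs[k]:
                counts[k] += 1
    rows = [{"index": k, "observed_a": obs_a[k], "observed_b": obs_b[k],
             "difference": obs[k], "p_value": counts[k] / n_perm}
            for k in INDEX_NAMES]
    return pd.DataFrame(rows)


class ResponseProfileClustering(ClusterMixin, BaseEstimator):
    """sklearn-style clusterer: drug profiles -> Ward/Spearman partition.

    Parameters
    ----------
    min_cluster_size : int
        Minimum branch size retained as its own cluster by the dynamic cut.
    gap : float
        Relative height gap a split must exhibit (see :func:`dynamic_cut`).
    min_overlap : int
        Minimum pairwise-complete sample overlap for the Spearman distance.

    Attributes
    ----------
    labels_ : ndarray of cluster codes aligned with the input rows
    partition_ : Partition
    dendrogram_ : Dendrogram
    distance_ : DataFrame of Spearman distances
    """

    def __init__(self, min_cluster_size: int = 3, gap: float = 0.5,
                 min_overlap: int = 3):
        self.min_cluster_size = min_cluster_size
        self.gap = gap
        self.min_overlap = min_overlap

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        self.distance_ = spearman_distance_matrix(X, min_overlap=self.min_overlap)
        self.dendrogram_ = ward_linkage(self.distance_)
        self.partition_ = dynamic_cut(self.dendrogram_, self.min_cluster_size, self.gap)
        self.labels_ = self.partition_.labels
        return self
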