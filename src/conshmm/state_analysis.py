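"""State clustering and model diagnostics.

States are clustered on the concatenation of their per-species align
probabilities f and joint align-and-match probabilities f*g, using
1 - Pearson correlation as the distance, complete linkage, and exact
optimal leaf ordering (adjacent-leaf distance minimised over all orders
consistent with the dendrogram).  Enrichment matrices are clustered after a
log2 transform and row z-normalisation so that each state's relative
preferences across samples drive the grouping rather than its absolute
enrichment level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .hmm import ConsHMMModel, PosteriorMatrix, StatePath

LOG2_FOLD_FLOOR = 0.01  # folds of 0 are floored here before log2


@dataclass
class StateDendrogram:
    """Agglomerative merge tree over states with leaf order and a group cut."""

    linkage: np.ndarray        # scipy linkage matrix
    leaf_order: np.ndarray     # 1-based state labels in optimal leaf order
    groups: np.ndarray         # 1-based group label per state (index = state-1)

    @property
    def n_groups(self) -> int:
        return int(self.groups.max())

    def to_newick(self, labels: list[str] | None = None) -> str:
        tree = hierarchy.to_tree(self.linkage)
        labels = labels or [f"S{i + 1}" for i in range(self.linkage.shape[0] + 1)]

        def rec(node) -> str:
            if node.is_leaf():
                return labels[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:g}"

        return rec(tree) + ";"


def state_feature_vectors(model: ConsHMMModel) -> np.ndarray:
    """Per-state clustering features: [f_k,., (f*g)_k,.], shape (K, 2(N-1))."""
    return np.hstack([model.f, model.f * model.g])


def _correlation_distance(vectors: np.ndarray, what: str = "state") -> np.ndarray:
    sd = vectors.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"correlation undefined: constant feature vector for {what}(s) {', '.join(str(i + 1) for i in bad)}"
        )
    d = 1.0 - np.corrcoef(vectors)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return d


def optimal_leaf_order(Z: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Exact optimal leaf ordering of a dendrogram.

    Dynamic program over (subtree, leftmost leaf, rightmost leaf) triples
    that minimises the summed distance between adjacent leaves over all
    2^(n-1) orders consistent with the tree.  O(n^3) time, exact for any n.
    Returns 0-based leaf indices.
    """
    n = dist.shape[0]
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    M: dict[int, np.ndarray] = {i: np.zeros((1, 1)) for i in range(n)}
    choice: dict[int, tuple[int, int, np.ndarray, np.ndarray]] = {}
    for t, row in enumerate(Z):
        l, r = int(row[0]), int(row[1])
        v = n + t
        SL, SR = leaves[l], leaves[r]
        ML, MR = M[l], M[r]
        D_lr = dist[np.ix_(SL, SR)]
        # min-plus products: best cost with left end i (in SL) and right end j (in SR)
        A = ML[:, :, None] + D_lr[None, :, :]          # (i, k, m)
        k_idx = A.argmin(axis=1)                       # (i, m) -> k
        tmp = A.min(axis=1)
        C = tmp[:, :, None] + MR[None, :, :]           # (i, m, j)
        m_idx = C.argmin(axis=1)                       # (i, j) -> m
        M_lr = C.min(axis=1)
        nl, nr = len(SL), len(SR)
        full = np.full((nl + nr, nl + nr), np.inf)
        full[:nl, nl:] = M_lr
        full[nl:, :nl] = M_lr.T                        # a reversed order has the same cost
        leaves[v] = SL + SR
        M[v] = full
        choice[v] = (l, r, k_idx, m_idx)

    def backtrack(v: int, i: int, j: int) -> list[int]:
        """Optimal order of subtree ``v`` as positions into ``leaves[v]``,
        with endpoint positions ``i`` (left) and ``j`` (right)."""
        if v < n:
            return [0]
        l, r, k_idx, m_idx = choice[v]
        nl = len(leaves[l])
        if i >= nl:  # endpoints in the mirrored half: reverse the (j, i) solution
            return backtrack(v, j, i)[::-1]
        jr = j - nl
        m = int(m_idx[i, jr])
        k = int(k_idx[i, m])
        left = backtrack(l, i, k)
        right = [p + nl for p in backtrack(r, m, jr)]
        return left + right

    root = n + Z.shape[0] - 1
    flat = int(np.argmin(M[root]))
    i, j = divmod(flat, M[root].shape[1])
    order = backtrack(root, i, j)
    return np.asarray([leaves[root][p] for p in order], dtype=np.int64)


def cluster_states(vectors: np.ndarray, n_groups: int = 8) -> StateDendrogram:
    """Hierarchically cluster state feature vectors.

    Complete linkage on 1 - Pearson correlation; leaves are reordered by the
    exact optimal-leaf-ordering dynamic program, and the tree is cut into
    ``n_groups`` groups.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    K = vectors.shape[0]
    if K < 2:
        raise ValueError("at least two states are required")
    dist = _correlation_distance(vectors)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    order = optimal_leaf_order(Z, dist) + 1
    groups = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
    return StateDendrogram(linkage=Z, leaf_order=order, groups=groups)


def leaf_order_cost(dist: np.ndarray, order: np.ndarray) -> float:
    """Sum of distances between adjacent leaves of an ordering (0-based)."""
    return float(sum(dist[order[i], order[i + 1]] for i in range(len(order) - 1)))


@dataclass
class ClusteredEnrichment:
    """Row-normalised, bi-clustered enrichment matrix."""

    matrix: pd.DataFrame       # z-scored log2 folds, reordered
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    kept_states: list[int]     # states passing the min_fold filter, original labels


def cluster_enrichment_matrix(folds: pd.DataFrame, min_fold: float = 2.0) -> ClusteredEnrichment:
    """Normalise and bi-cluster a states x samples fold-enrichment matrix.

    Keeps states with at least ``min_fold`` enrichment in some sample,
    log2-transforms (flooring folds at 0.01), z-scores each row, then
    clusters rows and columns by correlation distance with complete linkage
    and optimal leaf ordering.
    """
    keep = folds.index[folds.max(axis=1) >= min_fold]
    if len(keep) < 2:
        raise ValueError("fewer than two states pass the min_fold filter")
    if folds.shape[1] < 2:
        raise ValueError("row z-scores are undefined with a single sample column")
    sub = folds.loc[keep]
    logm = np.log2(np.maximum(sub.to_numpy(dtype=np.float64), LOG2_FOLD_FLOOR))
    mean = logm.mean(axis=1, keepdims=True)
    sd = logm.std(axis=1, keepdims=True)
    bad = np.flatnonzero(sd[:, 0] == 0)
    if bad.size:
        raise ValueError(f"constant log-enrichment row for state(s) {[int(keep[i]) for i in bad]}")
    z = (logm - mean) / sd

    def _cluster(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dist = _correlation_distance(mat, what="row")
        Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
        return Z, optimal_leaf_order(Z, dist)

    row_Z, row_order = _cluster(z)
    col_Z, col_order = _cluster(z.T)
    out = pd.DataFrame(z, index=keep, columns=sub.columns).iloc[row_order, col_order]
    return ClusteredEnrichment(matrix=out, row_linkage=row_Z, col_linkage=col_Z,
                               kept_states=[int(s) for s in keep])


def posterior_confidence(posteriors: list[PosteriorMatrix], paths: list[StatePath], n_states: int) -> np.ndarray:
    """Mean posterior of the assigned state, per state.

    A per-state internal confidence diagnostic: for each state, the average
    of that state's posterior over all bases assigned to it.  NaN for states
    never assigned.
    """
    sums = np.zeros(n_states)
    counts = np.zeros(n_states, dtype=np.int64)
    for post, path in zip(posteriors, paths):
        if (post.chrom, post.start, post.end) != (path.chrom, path.start, path.end):
            raise ValueError("posterior/path slice mismatch")
        assigned = path.states - 1
        sums += np.bincount(assigned, weights=post.values[np.arange(len(assigned)), assigned], minlength=n_states)
        counts += np.bincount(assigned, minlength=n_states)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out
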