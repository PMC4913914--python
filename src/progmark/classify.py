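"""Signature-based patient classification by hierarchical clustering.

Samples are clustered on the z-scored expression of a signature gene set
(Euclidean distance, average linkage / UPGMA), the tree is cut into k
clusters, clusters are mapped to clinical progression labels by majority
vote, and per-group correct counts are reported — the clustering-based
"classification" read off a two-group heatmap dendrogram.

The UPGMA implementation is deliberately explicit (O(n^3), Lance-Williams
average update) with a documented tie-break: on equal merge heights the
lexicographically smallest pair of cluster ids merges first.  Cohorts here
are tens of samples, where the naive algorithm is instant and its merge
order fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LinkageTree", "ClassificationReport", "zscore_rows",
           "hclust_samples", "classify_by_cut"]


@dataclass(frozen=True)
class LinkageTree:
    """Merge history of an agglomerative clustering.

    ``merges`` has one row per merge: (node_a, node_b, height, size); leaf
    nodes are 0..n-1 in ``leaf_ids`` order, internal node i is created by
    merge row i - n (scipy linkage convention).
    """

    merges: np.ndarray          # (n-1, 4) float
    leaf_ids: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()

    def cut(self, k: int) -> pd.Series:
        """Cluster membership after cutting into ``k`` clusters.

        Replays the first ``n - k`` merges (i.e. cuts above the
        (n-k)-th merge height) and renumbers clusters 0..k-1 in order of
        their smallest leaf index.
        """
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        parent = {i: i for i in range(n)}
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for i, (a, b, _, _) in enumerate(self.merges[: n - k]):
            node = n + i
            members[node] = members.pop(int(a)) + members.pop(int(b))
        labels = np.empty(n, dtype=int)
        roots = sorted(members.values(), key=min)
        for new_id, leaves in enumerate(roots):
            labels[leaves] = new_id
        return pd.Series(labels, index=list(self.leaf_ids), name="cluster")


@dataclass(frozen=True)
class ClassificationReport:
    """Outcome of cluster-vs-label classification."""

    correct: dict[str, int]
    totals: dict[str, int]
    cluster_labels: dict[int, str]
    misclassified: tuple[str, ...]

    @property
    def accuracy(self) -> float:
        return sum(self.correct.values()) / sum(self.totals.values())


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene row to mean 0, SD 1 (sample SD, n-1).

    Constant rows carry no contrast and are dropped with a warning; an
    all-constant matrix is an error.
    """
    sd = matrix.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.all():
        raise ValueError("all gene rows are constant; nothing to standardize")
    if constant.any():
        import warnings

        warnings.warn(
            f"dropping {int(constant.sum())} constant gene rows before z-scoring",
            UserWarning,
            stacklevel=2,
        )
        matrix = matrix.loc[~constant]
        sd = sd.loc[~constant]
    return matrix.sub(matrix.mean(axis=1), axis=0).div(sd, axis=0)


def hclust_samples(
    matrix: pd.DataFrame, signature_genes: list[str] | None = None
) -> LinkageTree:
    """UPGMA clustering of samples over a z-scored signature.

    Distances are Euclidean over the z-scored rows of ``signature_genes``
    (all genes if None).  Average linkage: the distance between two
    clusters is the mean pairwise distance, maintained by the
    Lance-Williams update d(a+b, c) = (n_a d(a,c) + n_b d(b,c)) / (n_a+n_b).
    Ties in merge height are broken toward the lexicographically smallest
    (node_a, node_b) pair, so the merge history is deterministic.
    """
    if signature_genes is not None:
        if len(signature_genes) == 0:
            raise ValueError("signature gene list is empty")
        missing = [g for g in signature_genes if g not in matrix.index]
        if missing:
            raise ValueError(f"signature genes absent from matrix: {missing[:5]}")
        matrix = matrix.loc[signature_genes]
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    Z = zscore_rows(matrix).to_numpy()
    S = Z.T  # samples x genes
    n = S.shape[0]
    diff = S[:, None, :] - S[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))

    # active cluster bookkeeping: node id -> (row in D, size)
    dist = D.copy()
    np.fill_diagonal(dist, np.inf)
    node_of_row = list(range(n))
    size = {i: 1 for i in range(n)}
    active = [True] * n
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = (np.inf, None, None)  # (height, node_a, node_b) with a < b
        rows = [r for r in range(n) if active[r]]
        for ii, r1 in enumerate(rows):
            for r2 in rows[ii + 1:]:
                h = dist[r1, r2]
                a, b = sorted((node_of_row[r1], node_of_row[r2]))
                if h < best[0] or (h == best[0] and (a, b) < (best[1], best[2])):
                    best = (h, a, b)
        h, a, b = best
        ra = node_of_row.index(a)
        rb = node_of_row.index(b)
        na, nb = size[a], size[b]
        new_node = n + step
        merges[step] = (a, b, h, na + nb)
        # Lance-Williams average-linkage update into row ra
        for r in range(n):
            if active[r] and r not in (ra, rb):
                dist[ra, r] = dist[r, ra] = (
                    na * dist[ra, r] + nb * dist[rb, r]
                ) / (na + nb)
        active[rb] = False
        node_of_row[ra] = new_node
        size[new_node] = na + nb
    return LinkageTree(merges=merges, leaf_ids=tuple(matrix.columns))


def classify_by_cut(
    tree: LinkageTree, labels: pd.Series, k: int = 2
) -> ClassificationReport:
    """Cut the tree into ``k`` clusters and score against clinical labels.

    Each cluster is mapped to a label by majority vote among its members;
    a tie is resolved toward the assignment maximizing the total number of
    correct samples, then lexicographically by label.  The report carries
    per-label correct/total counts and the misclassified sample ids.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > tree.n_leaves:
        raise ValueError("k exceeds the number of samples")
    labels = pd.Series(labels).reindex(list(tree.leaf_ids))
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise ValueError(f"no label for samples: {missing[:5]}")
    clusters = tree.cut(k)
    mapping: dict[int, str] = {}
    for c in range(k):
        members = labels[clusters == c]
        counts = members.value_counts()
        top = counts[counts == counts.max()].index.tolist()
        # majority; ties toward the label maximizing global correct counts
        # reduces to the more frequent overall label, then lexicographic
        if len(top) == 1:
            mapping[c] = top[0]
        else:
            overall = labels.value_counts()
            top.sort(key=lambda lab: (-overall.get(lab, 0), lab))
            mapping[c] = top[0]
    predicted = clusters.map(mapping)
    correct_mask = predicted == labels
    totals = labels.value_counts().to_dict()
    correct = {
        lab: int((correct_mask & (labels == lab)).sum()) for lab in totals
    }
    return ClassificationReport(
        correct=correct,
        totals={k_: int(v) for k_, v in totals.items()},
        cluster_labels=mapping,
        misclassified=tuple(labels.index[~correct_mask]),
    )
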