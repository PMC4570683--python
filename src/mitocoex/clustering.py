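"""Hierarchical clustering of expression profiles.

The similarity between two normalized profiles is the uncentered Pearson
correlation (cosine similarity — no mean subtraction), which for
median-centered profiles rewards agreement in the *pattern of deviation
around 1.0*, not just correlated fluctuations.  Genes are agglomerated
with average (UPGMA) linkage on the distance d = 1 − similarity
(range [0, 2]: anti-correlated profiles are maximally dissimilar).

The agglomerator is written here rather than delegated so the merge order
is fully specified: at every step the pair of clusters at minimal average
distance is merged, ties broken by the lexicographically smallest pair of
cluster ids (leaves 0..n−1 in input order, then creation order).  Average
linkage is reducible, so merge heights are non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import ExpressionMatrix


class ClusteringError(ValueError):
    pass


def uncentered_pearson(x, y) -> float:
    """Cosine similarity Σxᵢyᵢ / sqrt(Σxᵢ² · Σyᵢ²); no mean subtraction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("inputs must be equal-length 1-D vectors of length ≥ 2")
    nx, ny = np.sqrt(np.dot(x, x)), np.sqrt(np.dot(y, y))
    if nx == 0 or ny == 0:
        raise ClusteringError("uncentered correlation undefined for an all-zero vector")
    return float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))


def uncentered_distance_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise d = 1 − uncentered Pearson between rows."""
    values = np.asarray(values, dtype=float)
    norms = np.linalg.norm(values, axis=1)
    if (norms == 0).any():
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ClusteringError(f"all-zero profile at row {bad}")
    unit = values / norms[:, None]
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class Dendrogram:
    """Merge history in scipy linkage convention.

    ``merges`` rows are (id_a, id_b, height, size): leaves are clusters
    0..n−1 in input order, the k-th merge creates cluster n+k.
    """

    merges: np.ndarray  # (n-1, 4)
    leaf_labels: list[str]
    linkage: str = "average"
    metric: str = "uncentered-pearson"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def to_linkage(self) -> np.ndarray:
        """scipy-compatible linkage matrix (float copy)."""
        return self.merges.astype(float).copy()

    def _children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {
            n + k: (int(a), int(b))
            for k, (a, b, _, _) in enumerate(self.merges[:, :4].tolist())
        }

    def _leaves_under(self, node: int, children: dict) -> list[int]:
        if node < self.n_leaves:
            return [node]
        a, b = children[node]
        return self._leaves_under(a, children) + self._leaves_under(b, children)

    def to_newick(self) -> str:
        """Ultrametric Newick string (branch length = half merge-height gap)."""
        children = self._children()
        heights = {i: 0.0 for i in range(self.n_leaves)}
        for k, row in enumerate(self.merges):
            heights[self.n_leaves + k] = float(row[2])

        def render(node: int) -> str:
            if node < self.n_leaves:
                return self.leaf_labels[node]
            a, b = children[node]
            la = (heights[node] - heights[a]) / 2.0
            lb = (heights[node] - heights[b]) / 2.0
            return f"({render(a)}:{la:g},{render(b)}:{lb:g})"

        root = self.n_leaves + len(self.merges) - 1 if len(self.merges) else 0
        return render(root) + ";"


def hier_cluster(matrix: ExpressionMatrix) -> Dendrogram:
    """Average-linkage agglomeration on 1 − uncentered Pearson distance."""
    if matrix.state != "centered":
        raise ClusteringError("clustering expects the median-centered state")
    values = matrix.values()
    if values.shape[0] < 2:
        raise ClusteringError("need at least 2 genes to cluster")
    if not np.isfinite(values).all():
        raise ClusteringError("non-finite expression values")
    merges = _agglomerate_average(uncentered_distance_matrix(values))
    return Dendrogram(merges, matrix.gene_ids)


def _agglomerate_average(dist: np.ndarray) -> np.ndarray:
    """Greedy UPGMA with Lance–Williams updates and a lexicographic tie rule."""
    n = dist.shape[0]
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active = np.ones(n, dtype=bool)
    slot_id = np.arange(n)  # cluster id currently held by each matrix slot
    sizes = np.ones(n, dtype=int)
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        sub = np.where(active)[0]
        block = d[np.ix_(sub, sub)]
        m = block.min()
        # candidates at the minimum; pick the lexicographically smallest id pair
        ii, jj = np.where(block == m)
        best = None
        for a, b in zip(sub[ii], sub[jj]):
            if a == b:
                continue
            ids = tuple(sorted((int(slot_id[a]), int(slot_id[b]))))
            if best is None or ids < best[0]:
                best = (ids, (a, b) if slot_id[a] < slot_id[b] else (b, a))
        (id_a, id_b), (sa, sb) = best
        na, nb = sizes[sa], sizes[sb]
        merges[step] = (id_a, id_b, m, na + nb)
        # Lance–Williams average update into slot sa
        others = active.copy()
        others[[sa, sb]] = False
        d[sa, others] = d[others, sa] = (na * d[sa, others] + nb * d[sb, others]) / (na + nb)
        active[sb] = False
        d[sb, :] = d[:, sb] = np.inf
        d[sa, sa] = np.inf
        slot_id[sa] = n + step
        sizes[sa] = na + nb
    return merges


def cut_tree(dend: Dendrogram, k: int | None = None,
             height: float | None = None) -> dict[str, int]:
    """Partition the leaves by cluster count ``k`` or merge ``height``.

    Exactly one of the two must be given.  A height cut applies every merge
    with height ≤ the threshold.  Returns leaf label → cluster index
    (0-based, ordered by first appearance in input order).
    """
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k and height")
    n = dend.n_leaves
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        n_merges = n - k
    else:
        n_merges = int(np.sum(dend.merges[:, 2] <= height))

    parent = list(range(n + n_merges))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n_merges):
        a, b = int(dend.merges[step, 0]), int(dend.merges[step, 1])
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new

    labels: dict[str, int] = {}
    root_index: dict[int, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in root_index:
            root_index[root] = len(root_index)
        labels[dend.leaf_labels[leaf]] = root_index[root]
    return labels


def cluster_enrichment(
    cluster: set[str],
    annotation: set[str],
    universe: set[str],
    alternative: str = "greater",
) -> tuple[tuple[int, int, int, int], float]:
    """Fisher's exact over-representation of an annotation in a cluster.

    Contingency table: (in-cluster ∩ annotated, in-cluster ∖ annotated,
    out-cluster ∩ annotated, out-cluster ∖ annotated).  One-sided (greater)
    by default, matching an enrichment question.
    """
    cluster, annotation, universe = set(cluster), set(annotation), set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not cluster <= universe or not annotation <= universe:
        raise ValueError("cluster and annotation must be subsets of the universe")
    a = len(cluster & annotation)
    b = len(cluster - annotation)
    c = len(annotation - cluster)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return (a, b, c, d), float(p)
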