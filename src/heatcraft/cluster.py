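"""Hierarchical and k-means clustering with dendrogram extraction.

Hierarchical clustering is naive agglomeration straight from the set
definitions of the three linkage criteria:

* ``average`` (default) — mean of all cross-pair distances (UPGMA),
* ``minimum`` — closest cross pair (single linkage),
* ``maximum`` — farthest cross pair (complete linkage).

At each step the pair of active clusters with the smallest linkage distance
merges; ties are broken by the lexicographically smallest pair of minimum
original leaf indices, making results fully deterministic.  All three
criteria are reducible, so merge heights are non-decreasing.  The O(n^3)
direct computation is transparent and fast enough for heatmap-scale inputs
(up to a few thousand rows).

k-means accepts any of the seven distance metrics for the assignment step;
centroids are always arithmetic means, so convergence is only guaranteed
under squared Euclidean distance and every run is bounded by ``max_iter``.
Initial centroids are k distinct rows sampled with the caller's seed; an
emptied cluster is repaired by seizing the point currently farthest from its
assigned centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import metrics as _metrics
from .errors import DomainError, ValidationError
from .metrics import DistanceMatrix

LINKAGE_NAMES = ("average", "minimum", "maximum")

DEFAULT_LINKAGE = "average"


@dataclass
class Dendrogram:
    """Binary merge tree: leaves are 0..n-1, merge i creates node n+i.

    ``merges`` lists (left_node, right_node, height) with the left child the
    one whose minimum original leaf index is smaller.  ``leaf_order`` is the
    left-to-right leaf sequence of a depth-first traversal under that same
    rule; it drives heatmap row/column permutation.
    """

    merges: list[tuple[int, int, float]]
    n_leaves: int

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValidationError(
                f"a tree over {self.n_leaves} leaves needs {self.n_leaves - 1} "
                f"merges, got {len(self.merges)}"
            )
        seen: set[int] = set()
        for left, right, _h in self.merges:
            for node in (left, right):
                if node in seen:
                    raise ValidationError(f"node {node} consumed twice")
                seen.add(node)

    @property
    def root(self) -> int:
        return self.n_leaves + len(self.merges) - 1

    def children(self, node: int) -> tuple[int, int]:
        left, right, _ = self.merges[node - self.n_leaves]
        return left, right

    def height(self, node: int) -> float:
        return self.merges[node - self.n_leaves][2] if node >= self.n_leaves else 0.0


def hierarchical(d: DistanceMatrix, linkage: str = DEFAULT_LINKAGE) -> Dendrogram:
    """Agglomerate a distance matrix under one of the three linkage criteria."""
    if linkage not in LINKAGE_NAMES:
        raise ValidationError(
            f"unknown linkage {linkage!r}; expected one of {', '.join(LINKAGE_NAMES)}"
        )
    n = d.n
    if n < 2:
        raise ValidationError(f"hierarchical clustering needs >= 2 items, got {n}")
    dm = d.d
    # active: node id -> set of original leaf indices
    active: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None  # (D, min_leaf_a, min_leaf_b, id_a, id_b)
        ids = sorted(active)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                cross = dm[np.ix_(sorted(active[a]), sorted(active[b]))]
                if linkage == "average":
                    # exactly rounded sum: the mean is independent of the
                    # order cross pairs are visited, so exact ties stay ties
                    dist = math.fsum(cross.ravel()) / cross.size
                elif linkage == "minimum":
                    dist = float(cross.min())
                else:
                    dist = float(cross.max())
                la, lb = min(active[a]), min(active[b])
                key = (dist, min(la, lb), max(la, lb))
                if best is None or key < best[0]:
                    best = (key, a, b, la, lb)
        (dist, _, _), a, b, la, lb = best
        left, right = (a, b) if la < lb else (b, a)
        merges.append((left, right, dist))
        active[next_id] = active.pop(a) | active.pop(b)
        next_id += 1
    return Dendrogram(merges=merges, n_leaves=n)


def leaf_order(tree: Dendrogram) -> list[int]:
    """Left-to-right leaf sequence: depth-first, smaller-min-leaf child first."""
    # Children always carry smaller ids than the merge node that consumes
    # them, so minimum leaf indices can be filled in one forward pass.
    min_leaf = list(range(tree.n_leaves)) + [0] * len(tree.merges)
    for i, (left, right, _h) in enumerate(tree.merges):
        min_leaf[tree.n_leaves + i] = min(min_leaf[left], min_leaf[right])

    order: list[int] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if node < tree.n_leaves:
            order.append(node)
            continue
        left, right = tree.children(node)
        if min_leaf[left] > min_leaf[right]:
            left, right = right, left
        stack.append(right)
        stack.append(left)
    return order


def cut_tree(tree: Dendrogram, k: int) -> list[int]:
    """Labels from undoing the last k-1 merges; components numbered 0..k-1 in
    order of first appearance along the leaf order."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k must lie in 1..{n}, got {k}")
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # Union the first n-k merges; each merge i creates node n+i.
    for i, (left, right, _h) in enumerate(tree.merges[: n - k]):
        node = n + i
        parent[find(left)] = node
        parent[find(right)] = node

    labels_by_root: dict[int, int] = {}
    labels = [0] * n
    for leaf in leaf_order(tree):
        root = find(leaf)
        if root not in labels_by_root:
            labels_by_root[root] = len(labels_by_root)
        labels[leaf] = labels_by_root[root]
    return labels


@dataclass
class KMeansResult:
    """Assignments, centroids and the per-iteration cost trace of one run."""

    labels: np.ndarray
    centroids: np.ndarray
    cost: float
    n_iter: int
    seed: int
    cost_history: list[float] = field(default_factory=list)


def kmeans(
    matrix: np.ndarray,
    k: int,
    metric: str = "squared_euclidean",
    seed: int = 0,
    max_iter: int = 100,
) -> KMeansResult:
    """Lloyd-style k-means with a pluggable assignment metric.

    The cost is the sum over points of the metric distance to the assigned
    centroid, recorded after every assignment step.  Under correlation
    metrics a constant centroid makes the distance undefined and aborts the
    run with advice to use a geometric metric.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k must lie in 1..{n}, got {k}")
    rng = np.random.default_rng(seed)
    centroids = matrix[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1, dtype=int)
    cost_history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # Assignment: nearest centroid, ties to the lowest centroid index.
        dists = np.empty((n, k), dtype=float)
        for i in range(n):
            for c in range(k):
                try:
                    dists[i, c] = _metrics.distance(matrix[i], centroids[c], metric)
                except DomainError as exc:
                    raise DomainError(
                        f"{exc} (centroid {c} became constant; use a geometric "
                        f"metric such as euclidean for k-means)"
                    ) from exc
        new_labels = dists.argmin(axis=1)
        # Repair empty clusters by seizing the worst-fitted point.
        for c in range(k):
            if not np.any(new_labels == c):
                worst = int(np.argmax(dists[np.arange(n), new_labels]))
                new_labels[worst] = c
        cost_history.append(float(dists[np.arange(n), new_labels].sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = matrix[labels == c].mean(axis=0)
    return KMeansResult(
        labels=labels,
        centroids=centroids,
        cost=cost_history[-1],
        n_iter=n_iter,
        seed=seed,
        cost_history=cost_history,
    )
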