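"""The seven clustering distances and pairwise distance matrices.

Geometric metrics: Euclidean, squared Euclidean, Manhattan (city-block) and
maximum (Chebyshev).  Correlation metrics: Pearson, Spearman and Kendall
distances, each defined as one minus the corresponding coefficient, so they
lie in [0, 2] with 0 for perfect positive correlation and 2 for perfect
anticorrelation.  Spearman uses average ranks for ties; Kendall is the
tie-corrected tau-b, computed by direct O(n^2) pair counting (vector lengths
in heatmap work are small).  Correlation of a constant vector is undefined
and raises a :class:`~heatcraft.errors.DomainError` suggesting the flat
row/column be removed.

The coefficients are computed here from first principles; established
statistical libraries serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError

METRIC_NAMES = (
    "euclidean",
    "squared_euclidean",
    "manhattan",
    "maximum",
    "pearson",
    "spearman",
    "kendall",
)

DEFAULT_METRIC = "pearson"


def average_ranks(x: np.ndarray) -> np.ndarray:
    """Rank values from 1, assigning tied values the mean of their positions."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0.0:
        raise DomainError(
            "correlation is undefined for a constant vector; remove or jitter "
            "the flat row/column, or use a geometric metric"
        )
    return float((xd * yd).sum() / denom)


def _kendall_tau_b(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    concordant = discordant = 0
    ties_x = ties_y = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif (dx > 0) == (dy > 0):
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    denom = np.sqrt(
        float(concordant + discordant + ties_x) * (concordant + discordant + ties_y)
    )
    if denom == 0.0:
        raise DomainError(
            "Kendall correlation is undefined for a constant vector; remove or "
            "jitter the flat row/column, or use a geometric metric"
        )
    return (concordant - discordant) / denom


def distance(x: np.ndarray, y: np.ndarray, metric: str = DEFAULT_METRIC) -> float:
    """Distance between two equal-length vectors under a named metric.

    Correlation distances are 1 - coefficient.  All results are clamped at a
    floor of exactly 0 to absorb floating-point round-off near perfect
    correlation.
    """
    if metric not in METRIC_NAMES:
        raise ValidationError(
            f"unknown metric {metric!r}; expected one of {', '.join(METRIC_NAMES)}"
        )
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(
            f"vectors must be 1-D with equal length, got shapes {x.shape} and {y.shape}"
        )
    if len(x) < 2:
        raise ValidationError(f"vectors must have length >= 2, got {len(x)}")
    if metric == "euclidean":
        d = float(np.sqrt(((x - y) ** 2).sum()))
    elif metric == "squared_euclidean":
        d = float(((x - y) ** 2).sum())
    elif metric == "manhattan":
        d = float(np.abs(x - y).sum())
    elif metric == "maximum":
        d = float(np.abs(x - y).max())
    elif metric == "pearson":
        d = 1.0 - _pearson_r(x, y)
    elif metric == "spearman":
        d = 1.0 - _pearson_r(average_ranks(x), average_ranks(y))
    else:  # kendall
        d = 1.0 - _kendall_tau_b(x, y)
    return max(d, 0.0)


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal pairwise distances under one named metric."""

    d: np.ndarray
    metric: str
    item_labels: list[str]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = self.d.shape[0]
        if self.d.shape != (n, n):
            raise ValidationError(f"distance matrix must be square, got {self.d.shape}")
        if len(self.item_labels) != n:
            raise ValidationError("item label count must match matrix size")

    @property
    def n(self) -> int:
        return self.d.shape[0]


def pairwise(
    matrix: np.ndarray,
    metric: str = DEFAULT_METRIC,
    axis: str = "rows",
    item_labels: list[str] | None = None,
) -> DistanceMatrix:
    """All-pairs distances between the rows or columns of a matrix."""
    if axis not in ("rows", "cols"):
        raise ValidationError(f"axis must be 'rows' or 'cols', got {axis!r}")
    matrix = np.asarray(matrix, dtype=float)
    items = matrix if axis == "rows" else matrix.T
    n = items.shape[0]
    if n < 2:
        raise ValidationError(f"need at least 2 items along {axis}, got {n}")
    if item_labels is None:
        item_labels = [str(i) for i in range(n)]
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = distance(items[i], items[j], metric)
            except DomainError as exc:
                raise DomainError(
                    f"{exc} (items {item_labels[i]!r} and {item_labels[j]!r})"
                ) from exc
    return DistanceMatrix(d=d, metric=metric, item_labels=list(item_labels))
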