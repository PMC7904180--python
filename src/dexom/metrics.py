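"""Diversity metrics over sets of 0/1 activity vectors.

Two summaries of a solution set: the average pairwise (normalized) Hamming
distance δ̄h, which measures how different solutions are on average, and the
average nearest-neighbour distance δ̄hnn, which measures how *spread* they are
(a set of two tight clusters far apart has large δ̄h but small δ̄hnn).
Distances are normalized by the total number of reactions, so both lie in
[0, 1] and are comparable across partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import DimensionError, UndefinedMetricError

__all__ = [
    "hamming",
    "avg_pairwise_distance",
    "avg_nn_distance",
    "diversity_trace",
    "DiversityReport",
]


def _as_matrix(solution_set) -> np.ndarray:
    if hasattr(solution_set, "activity_matrix"):
        return np.asarray(solution_set.activity_matrix(), dtype=float)
    return np.asarray(solution_set, dtype=float)


def hamming(x, y) -> float:
    """Normalized Hamming distance (1/n) Σ |x_i − y_i|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise DimensionError(
            f"hamming needs two equal-length non-empty vectors, got {x.shape} and {y.shape}"
        )
    return float(np.abs(x - y).mean())


def avg_pairwise_distance(solution_set) -> float:
    """Mean Hamming distance over all unordered pairs (δ̄h)."""
    X = _as_matrix(solution_set)
    if X.shape[0] < 2:
        raise UndefinedMetricError("average pairwise distance needs >= 2 solutions")
    return float(pdist(X, metric="hamming").mean())


def avg_nn_distance(solution_set) -> float:
    """Mean distance from each solution to its nearest neighbour (δ̄hnn)."""
    X = _as_matrix(solution_set)
    if X.shape[0] < 2:
        raise UndefinedMetricError("average nearest-neighbour distance needs >= 2 solutions")
    D = squareform(pdist(X, metric="hamming"))
    np.fill_diagonal(D, np.inf)
    return float(D.min(axis=1).mean())


@dataclass
class DiversityReport:
    avg_pairwise: float  # δ̄h of the full set
    avg_nearest_neighbor: float  # δ̄hnn of the full set
    trace: list[tuple[int, float, float]]  # (prefix length, δ̄h, δ̄hnn)


def diversity_trace(solution_set) -> DiversityReport:
    """Evolution of both metrics over growing prefixes of an ordered set.

    For each prefix length k = 2..K the pairwise and nearest-neighbour
    averages are computed, tracking how diversity evolves as the enumeration
    progresses.
    """
    X = _as_matrix(solution_set)
    K = X.shape[0]
    if K < 2:
        raise UndefinedMetricError("diversity trace needs >= 2 solutions")
    D = squareform(pdist(X, metric="hamming"))
    trace: list[tuple[int, float, float]] = []
    # running sums over the upper triangle and running per-row minima
    pair_sum = 0.0
    nn = np.full(K, np.inf)
    for k in range(1, K):
        new = D[:k, k]
        pair_sum += float(new.sum())
        nn[:k] = np.minimum(nn[:k], new)
        nn[k] = float(new.min())
        m = k + 1
        trace.append((m, pair_sum / (m * (m - 1) / 2), float(nn[:m].mean())))
    last = trace[-1]
    return DiversityReport(avg_pairwise=last[1], avg_nearest_neighbor=last[2], trace=trace)
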