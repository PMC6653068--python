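"""Pairwise patient distances.

Two metrics are offered for comparing patients:

* magnitude-based: plain Euclidean distance between fixed-length per-patient
  summary vectors;
* time-aware: multivariate dynamic time warping (DTW) over the full visit
  series, which non-linearly distorts the visit axis to align patients whose
  trajectories evolve similarly but at different tempo.

The DTW local cost between visit m of patient x and visit n of patient y is
the squared Euclidean distance across all 17 z-scored parameters; the DTW
distance is the minimal cumulative local cost over monotone alignment paths
with steps (1,0), (0,1), (1,1), unweighted and unwindowed. Both paths start
at the two first visits. With ``open_end=True`` the alignment may terminate
before the last visit of either series (the minimum is taken over the last
row and last column of the dynamic-programming grid), accommodating unequal
follow-up lengths. The reported distance is the raw minimized sum — no square
root and no path-length normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .core import Cohort, CohortError, PatientSeries
from .preprocess import SummaryVector


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise patient distances."""

    ids: list[str]
    d: np.ndarray
    metric: str  # "euclidean_summary" | "dtw"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.d < 0) or np.any(np.diag(self.d) != 0):
            raise ValueError("distances must be nonnegative with zero diagonal")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass(frozen=True)
class AlignmentPath:
    """One optimal DTW alignment: 0-based (m, n) visit-index pairs and cost."""

    pairs: tuple[tuple[int, int], ...]
    cost: float


def euclidean_distance_matrix(summaries: list[SummaryVector]) -> DistanceMatrix:
    """Pairwise Euclidean distances between patient summary vectors."""
    if len(summaries) < 2:
        raise ValueError("need at least 2 summary vectors")
    lengths = {s.values.shape for s in summaries}
    if len(lengths) != 1:
        raise ValueError(f"summary vectors have mismatched lengths: {lengths}")
    X = np.vstack([s.values for s in summaries])
    d = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(ids=[s.patient_id for s in summaries], d=d,
                          metric="euclidean_summary")


def _accumulate(cost: np.ndarray) -> np.ndarray:
    """Cumulative DTW cost grid for steps (1,0), (0,1), (1,1)."""
    n, m = cost.shape
    acc = np.empty_like(cost)
    acc[0, 0] = cost[0, 0]
    acc[0, 1:] = np.cumsum(cost[0, 1:]) + cost[0, 0]
    acc[1:, 0] = np.cumsum(cost[1:, 0]) + cost[0, 0]
    for i in range(1, n):
        for j in range(1, m):
            acc[i, j] = cost[i, j] + min(
                acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]
            )
    return acc


def _backtrack(acc: np.ndarray, end: tuple[int, int]) -> tuple[tuple[int, int], ...]:
    """Trace one optimal path from ``end`` to (0, 0).

    Equal-cost predecessors are resolved preferring the diagonal step, then
    advancing the first series, then the second, so the path is deterministic.
    """
    i, j = end
    path = [(i, j)]
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            candidates = (
                (acc[i - 1, j - 1], (i - 1, j - 1)),
                (acc[i - 1, j], (i - 1, j)),
                (acc[i, j - 1], (i, j - 1)),
            )
            best = min(c[0] for c in candidates)
            for value, pred in candidates:
                if value == best:
                    i, j = pred
                    break
            else:  # pragma: no cover
                raise AssertionError("unreachable")
            path.append((i, j))
            continue
        path.append((i, j))
    return tuple(reversed(path))


def dtw_distance(
    x: PatientSeries, y: PatientSeries, open_end: bool = True
) -> tuple[float, AlignmentPath]:
    """Open-end multivariate DTW distance between two patients.

    Returns the minimized cumulative squared-Euclidean cost and one optimal
    alignment path. With ``open_end``, either series (but not the alignment
    start) may terminate early; ties between equally cheap end cells prefer
    the longest alignment, then the full corner.
    """
    if x.n_visits == 0 or y.n_visits == 0:
        raise ValueError("DTW requires at least one visit in each series")
    if x.values.shape[1] != y.values.shape[1]:
        raise ValueError("parameter panels of the two series do not match")
    cost = cdist(x.values, y.values, metric="sqeuclidean")
    acc = _accumulate(cost)
    n, m = cost.shape
    if open_end:
        ends = [(i, m - 1) for i in range(n)] + [(n - 1, j) for j in range(m - 1)]
        # prefer longer alignments, then later x-index, among equal costs
        end = min(ends, key=lambda e: (acc[e], -(e[0] + e[1]), -e[0]))
    else:
        end = (n - 1, m - 1)
    return float(acc[end]), AlignmentPath(pairs=_backtrack(acc, end),
                                          cost=float(acc[end]))


def dtw_distance_matrix(cohort: Cohort, open_end: bool = True) -> DistanceMatrix:
    """Symmetric matrix of pairwise DTW distances over a normalized cohort.

    Open-end DTW is symmetric here because the cumulative grid of (y, x) is
    the transpose of the grid of (x, y) and the open-end candidate set (last
    row and last column) maps onto itself under transposition; the matrix
    entry equals min(cost(x, y), cost(y, x)) computed once.
    """
    if not cohort.normalized:
        raise CohortError("DTW distances are defined on a z-normalized cohort")
    n = cohort.n_patients
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c, _ = dtw_distance(cohort.patients[i], cohort.patients[j],
                                open_end=open_end)
            d[i, j] = d[j, i] = c
    return DistanceMatrix(ids=cohort.patient_ids, d=d, metric="dtw")
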