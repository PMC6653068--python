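"""Hierarchical clustering, dendrogram cuts, validity indices, 2-D embeddings.

Patient groups are produced by agglomerative hierarchical clustering of a
pairwise distance matrix (complete linkage by default) and a flat cut of the
dendrogram at a fraction of its total height (0.9 by default — the cut the
registry analysis used). Internal quality is scored by two complementary
indices:

* connectivity — penalizes nearest neighbours assigned to different
  clusters: c = sum_i sum_{j=1..L} x_ij with x_ij = 0 when i's j-th nearest
  neighbour shares i's cluster and 1/j otherwise; lower is better;
* Dunn index — minimal inter-cluster distance over maximal intra-cluster
  diameter; higher is better.

Two-dimensional embeddings for visualisation: classical (metric) MDS via
double-centred eigendecomposition, and isotonic (nonmetric) MDS minimizing
Kruskal stress-1 by SMACOF with isotonic regression on the distance ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import silhouette_score

from .distances import DistanceMatrix

logger = logging.getLogger(__name__)

LINKAGES = ("complete", "single", "average")


@dataclass
class Dendrogram:
    """Agglomerative merge tree: scipy-format merges over patient leaves."""

    ids: list[str]
    merges: np.ndarray  # scipy linkage matrix, shape (n-1, 4)
    linkage: str

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def max_height(self) -> float:
        return float(self.merges[:, 2].max())


@dataclass
class ClusterLabels:
    """Flat group assignment: integer labels 1..k, every cluster nonempty."""

    ids: list[str]
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = set(self.labels.tolist())
        if present != set(range(1, self.k + 1)):
            raise ValueError(f"labels must cover 1..{self.k}, got {sorted(present)}")

    def members(self, label: int) -> list[str]:
        return [pid for pid, l in zip(self.ids, self.labels) if l == label]

    def sizes(self) -> dict[int, int]:
        return {l: int(np.sum(self.labels == l)) for l in range(1, self.k + 1)}


@dataclass
class Embedding2D:
    """Low-dimensional patient coordinates; stress reported for isotonic MDS."""

    ids: list[str]
    coords: np.ndarray
    method: str  # "classical" | "isotonic"
    stress: float | None = None
    converged: bool = True
    stress_trace: tuple[float, ...] = ()


def agglomerative_cluster(dist: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative hierarchical clustering of a distance matrix.

    Repeatedly merges the two closest clusters under the linkage rule
    (complete = maximal pairwise distance between members; single, average
    also offered) and records merge heights.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if dist.n < 2:
        raise ValueError("clustering needs at least 2 patients")
    Z = scipy_linkage(dist.condensed(), method=linkage)
    return Dendrogram(ids=list(dist.ids), merges=Z, linkage=linkage)


def _components(dend: Dendrogram, apply_merge) -> np.ndarray:
    """Union-find over the merge list; ``apply_merge(idx, height)`` decides."""
    n = dend.n_leaves
    parent = list(range(2 * n - 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for idx, (a, b, h, _size) in enumerate(dend.merges):
        if apply_merge(idx, float(h)):
            node = n + idx
            parent[find(int(a))] = node
            parent[find(int(b))] = node
    roots = [find(i) for i in range(n)]
    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for i, r in enumerate(roots):
        if r not in seen:
            seen[r] = len(seen) + 1
        labels[i] = seen[r]
    return labels


def cut_at_height_fraction(dend: Dendrogram, fraction: float = 0.9) -> ClusterLabels:
    """Cut the dendrogram at ``fraction`` x its total (maximal merge) height.

    Clusters are the connected components formed by the merges at or below
    the cut height (so ``fraction=1.0`` yields a single cluster); the number
    of groups k emerges from the cut.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    cut = fraction * dend.max_height
    labels = _components(dend, lambda idx, h: h <= cut)
    return ClusterLabels(ids=list(dend.ids), labels=labels, k=int(labels.max()))


def cut_at_k(dend: Dendrogram, k: int) -> ClusterLabels:
    """Flat cut with exactly k clusters (first n-k merges applied)."""
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    labels = _components(dend, lambda idx, h: idx < n - k)
    if labels.max() != k:  # tied heights cannot break scipy's ordering
        raise RuntimeError("could not realise the requested number of clusters")
    return ClusterLabels(ids=list(dend.ids), labels=labels, k=k)


def connectivity(dist: DistanceMatrix, labels: ClusterLabels,
                 neighbors: int = 10) -> float:
    """Connectivity validity index (lower is better).

    For each observation i and each of its ``neighbors`` nearest neighbours
    (by the supplied distances, self excluded, ties broken by patient order),
    add 1/j when the j-th neighbour lies outside i's cluster.
    """
    n = dist.n
    if not 1 <= neighbors < n:
        raise ValueError(f"neighbors must be in 1..{n - 1}, got {neighbors}")
    if list(dist.ids) != list(labels.ids):
        raise ValueError("distance matrix and labels refer to different patients")
    c = 0.0
    order_idx = np.arange(n)
    for i in range(n):
        others = order_idx[order_idx != i]
        # stable sort on distance keeps patient order among ties
        nn = others[np.argsort(dist.d[i, others], kind="stable")][:neighbors]
        for j, m in enumerate(nn, start=1):
            if labels.labels[m] != labels.labels[i]:
                c += 1.0 / j
    return c


def dunn_index(dist: DistanceMatrix, labels: ClusterLabels) -> float:
    """Dunn validity index: min inter-cluster distance / max cluster diameter."""
    if labels.k < 2:
        raise ValueError("Dunn index requires at least 2 clusters")
    if list(dist.ids) != list(labels.ids):
        raise ValueError("distance matrix and labels refer to different patients")
    lab = labels.labels
    diameters = []
    for g in range(1, labels.k + 1):
        idx = np.flatnonzero(lab == g)
        if len(idx) > 1:
            diameters.append(dist.d[np.ix_(idx, idx)].max())
    if not diameters:
        raise ValueError("Dunn index undefined: all clusters are singletons")
    max_diam = max(diameters)
    if max_diam == 0:
        raise ValueError("Dunn index undefined: zero maximal diameter")
    min_inter = np.inf
    for g in range(1, labels.k + 1):
        for h in range(g + 1, labels.k + 1):
            ig, ih = np.flatnonzero(lab == g), np.flatnonzero(lab == h)
            min_inter = min(min_inter, dist.d[np.ix_(ig, ih)].min())
    return float(min_inter / max_diam)


def classical_mds(dist: DistanceMatrix, dims: int = 2) -> Embedding2D:
    """Classical (metric) MDS: double-centre the squared distances and embed
    on the top positive eigenpairs."""
    n = dist.n
    if n <= dims:
        raise ValueError(f"need more than {dims} patients, got {n}")
    D2 = dist.d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:dims]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(1e-12, 1e-12 * abs(eigval[0]))
    if positive.sum() < dims:
        logger.warning(
            "only %d positive eigenvalue(s); embedding has reduced rank",
            int(positive.sum()),
        )
    coords = np.zeros((n, dims))
    coords[:, positive] = eigvec[:, positive] * np.sqrt(eigval[positive])
    return Embedding2D(ids=list(dist.ids), coords=coords, method="classical")


def isotonic_mds(
    dist: DistanceMatrix,
    dims: int = 2,
    max_iter: int = 300,
    tol: float = 1e-9,
    seed: int | None = None,
) -> Embedding2D:
    """Nonmetric (isotonic) MDS minimizing Kruskal stress-1.

    SMACOF iterations alternate an isotonic regression of the configuration
    distances on the rank order of the input dissimilarities with a Guttman
    coordinate update. Initialised from the classical MDS solution, so the
    result is deterministic; ``seed`` only perturbs a degenerate
    (all-coincident) start. Returns the best configuration seen, flagging
    non-convergence within ``max_iter``.
    """
    n = dist.n
    X = classical_mds(dist, dims=dims).coords.copy()
    if not np.any(X):
        rng = np.random.default_rng(0 if seed is None else seed)
        X = rng.standard_normal((n, dims)) * 1e-6
    iu = np.triu_indices(n, k=1)
    dvec = dist.d[iu]
    order = np.argsort(dvec, kind="stable")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    ranks = np.arange(len(dvec), dtype=float)

    def config_dist(X: np.ndarray) -> np.ndarray:
        return pdist(X)

    best_stress, best_X = np.inf, X.copy()
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        d = config_dist(X)
        dhat = np.empty_like(d)
        dhat[order] = iso.fit_transform(ranks, d[order])
        denom = float(np.sum(d ** 2))
        stress = float(np.sqrt(np.sum((d - dhat) ** 2) / denom)) if denom else 0.0
        if trace and stress > trace[-1]:
            # the normalized stress stopped improving; keep the best seen
            converged = True
            break
        trace.append(stress)
        if stress < best_stress:
            best_stress, best_X = stress, X.copy()
        if len(trace) > 1 and trace[-2] - stress < tol:
            converged = True
            break
        # Guttman transform with target disparities dhat
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        B = np.zeros((n, n))
        B[iu] = -ratio
        B += B.T
        np.fill_diagonal(B, -B.sum(axis=1))
        X = B @ X / n
    if not converged:
        logger.warning("isotonic MDS did not converge in %d iterations", max_iter)
    return Embedding2D(ids=list(dist.ids), coords=best_X, method="isotonic",
                       stress=best_stress, converged=converged,
                       stress_trace=tuple(trace))


def suggest_k(dist: DistanceMatrix, k_range, linkage: str = "complete",
              neighbors: int = 10) -> list[dict]:
    """Tabulate silhouette, connectivity and Dunn across candidate k.

    A scan used to gauge how many groups the distance structure supports;
    degenerate inputs (all-identical points) yield NaN rows with a warning.
    """
    dend = agglomerative_cluster(dist, linkage=linkage)
    rows = []
    degenerate = dist.d.max() == 0
    if degenerate:
        logger.warning("all pairwise distances are zero; indices are undefined")
    for k in k_range:
        if not 2 <= k <= dist.n - 1:
            raise ValueError(f"k={k} outside 2..{dist.n - 1}")
        labels = cut_at_k(dend, k)
        if degenerate:
            rows.append({"k": k, "silhouette": float("nan"),
                         "connectivity": float("nan"), "dunn": float("nan")})
            continue
        sil = float(silhouette_score(dist.d, labels.labels, metric="precomputed"))
        conn = connectivity(dist, labels, neighbors=min(neighbors, dist.n - 1))
        try:
            dunn = dunn_index(dist, labels)
        except ValueError:
            dunn = float("nan")
        rows.append({"k": k, "silhouette": sil, "connectivity": conn, "dunn": dunn})
    return rows
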