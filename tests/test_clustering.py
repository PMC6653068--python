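"""Hierarchical clustering, dendrogram cuts, validity indices, MDS."""

import numpy as np
import pytest
from oracles import connectivity_bruteforce, dunn_bruteforce, naive_linkage_cut
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from sletraj.clustering import (
    ClusterLabels,
    agglomerative_cluster,
    classical_mds,
    connectivity,
    cut_at_height_fraction,
    cut_at_k,
    dunn_index,
    isotonic_mds,
    suggest_k,
)
from sletraj.distances import DistanceMatrix


def dist_from_points(points, metric="euclidean"):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] == 1 or points.ndim == 1:
        points = points.reshape(len(points), -1)
    d = squareform(pdist(points, metric=metric))
    return DistanceMatrix(ids=[f"P{i}" for i in range(len(points))], d=d,
                          metric="euclidean_summary")


def dist_from_matrix(d):
    return DistanceMatrix(ids=[f"P{i}" for i in range(len(d))],
                          d=np.asarray(d, float), metric="euclidean_summary")


THREE_POINT = dist_from_matrix([[0, 1, 10], [1, 0, 10], [10, 10, 0]])


# ------------------------------------------------------------- linkage -----

def test_three_point_forced_merge_order():
    dend = agglomerative_cluster(THREE_POINT, linkage="complete")
    assert list(dend.heights) == [1.0, 10.0]
    assert dend.max_height == 10.0


def test_two_point_single_merge():
    d = dist_from_matrix([[0, 7.0], [7.0, 0]])
    dend = agglomerative_cluster(d)
    assert list(dend.heights) == [7.0]


@pytest.mark.parametrize("linkage", ["complete", "single", "average"])
def test_linkage_matches_naive_reference(rng, linkage):
    for _ in range(15):
        n = int(rng.integers(4, 13))
        points = rng.normal(size=(n, 3))
        dist = dist_from_points(points)
        dend = agglomerative_cluster(dist, linkage=linkage)
        for k in range(2, n):
            ours = cut_at_k(dend, k).labels
            ref = naive_linkage_cut(dist.d, k, linkage)
            assert adjusted_rand_score(ours, ref) == pytest.approx(1.0)


def test_unknown_linkage_rejected():
    with pytest.raises(ValueError, match="linkage"):
        agglomerative_cluster(THREE_POINT, linkage="ward")


# ---------------------------------------------------------------- cuts -----

def test_cut_fraction_one_gives_single_cluster():
    dend = agglomerative_cluster(THREE_POINT)
    labels = cut_at_height_fraction(dend, fraction=1.0)
    assert labels.k == 1


def test_cut_three_point_example_at_half():
    dend = agglomerative_cluster(THREE_POINT)
    labels = cut_at_height_fraction(dend, fraction=0.5)  # cut at height 5
    assert labels.k == 2
    assert set(map(frozenset, [labels.members(1), labels.members(2)])) == {
        frozenset({"P0", "P1"}), frozenset({"P2"})}


def test_cut_fraction_bounds():
    dend = agglomerative_cluster(THREE_POINT)
    for bad in (0.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            cut_at_height_fraction(dend, fraction=bad)


def test_cut_labels_invariant_to_patient_permutation(rng):
    points = rng.normal(size=(10, 2))
    base = cut_at_height_fraction(agglomerative_cluster(dist_from_points(points)))
    perm = rng.permutation(10)
    d = dist_from_points(points[perm])
    permuted = cut_at_height_fraction(agglomerative_cluster(d))
    by_id_base = {f"P{i}" for i in range(10)}
    assert by_id_base == set(base.ids)
    # same partition of the underlying points
    lab_base = {i: base.labels[i] for i in range(10)}
    lab_perm = {perm[i]: permuted.labels[i] for i in range(10)}
    assert adjusted_rand_score([lab_base[i] for i in range(10)],
                               [lab_perm[i] for i in range(10)]) == pytest.approx(1.0)


def test_cut_at_k_range_checks():
    dend = agglomerative_cluster(THREE_POINT)
    assert cut_at_k(dend, 1).k == 1
    assert cut_at_k(dend, 3).k == 3
    with pytest.raises(ValueError):
        cut_at_k(dend, 4)


# ---------------------------------------------------------- connectivity ---

def test_connectivity_separated_tight_clusters_zero():
    points = np.array([0.0, 0.1, 0.2, 100.0, 100.1, 100.2]).reshape(-1, 1)
    d = dist_from_points(points)
    labels = ClusterLabels(ids=d.ids, labels=[1, 1, 1, 2, 2, 2], k=2)
    assert connectivity(d, labels, neighbors=2) == 0.0


def test_connectivity_line_example_follows_formula():
    # A,B,C,D at 0,1,2,3 with clusters {A,B},{C,D}, neighbors=2. Per the
    # formula with patient-order tie-breaks: A's 2nd neighbour C -> 1/2;
    # B's 2nd neighbour C -> 1/2; C's 1st neighbour B -> 1; D's 2nd
    # neighbour B -> 1/2. Total 2.5.
    d = dist_from_points(np.array([0.0, 1.0, 2.0, 3.0]).reshape(-1, 1))
    labels = ClusterLabels(ids=d.ids, labels=[1, 1, 2, 2], k=2)
    assert connectivity(d, labels, neighbors=2) == pytest.approx(2.5)


def test_connectivity_matches_bruteforce(rng):
    for _ in range(40):
        n = int(rng.integers(4, 16))
        d = dist_from_points(rng.normal(size=(n, 3)))
        k = int(rng.integers(2, 4))
        lab = rng.integers(1, k + 1, size=n)
        lab[:k] = np.arange(1, k + 1)  # every cluster nonempty
        labels = ClusterLabels(ids=d.ids, labels=lab, k=k)
        nb = int(rng.integers(1, n))
        assert connectivity(d, labels, neighbors=nb) == pytest.approx(
            connectivity_bruteforce(d.d, lab, nb))


def test_connectivity_random_worse_than_compact(rng):
    wins = 0
    for _ in range(100):
        points = np.concatenate([rng.normal(0, 1, (8, 2)),
                                 rng.normal(12, 1, (8, 2))])
        d = dist_from_points(points)
        compact = ClusterLabels(ids=d.ids, labels=[1] * 8 + [2] * 8, k=2)
        lab = rng.permutation([1] * 8 + [2] * 8)
        rand = ClusterLabels(ids=d.ids, labels=lab, k=2)
        if connectivity(d, rand, 5) > connectivity(d, compact, 5):
            wins += 1
    assert wins >= 95


def test_connectivity_argument_errors():
    d = dist_from_points(np.arange(4.0).reshape(-1, 1))
    labels = ClusterLabels(ids=d.ids, labels=[1, 1, 2, 2], k=2)
    for bad in (0, 4, 7):
        with pytest.raises(ValueError):
            connectivity(d, labels, neighbors=bad)


# ------------------------------------------------------------------ Dunn ---

def test_dunn_line_example_9():
    d = dist_from_points(np.array([0.0, 1.0, 10.0, 11.0]).reshape(-1, 1))
    labels = ClusterLabels(ids=d.ids, labels=[1, 1, 2, 2], k=2)
    assert dunn_index(d, labels) == pytest.approx(9.0)


def test_dunn_overlapping_example_0_2():
    d = dist_from_points(np.array([0.0, 5.0, 4.0, 9.0]).reshape(-1, 1))
    labels = ClusterLabels(ids=d.ids, labels=[1, 1, 2, 2], k=2)
    assert dunn_index(d, labels) == pytest.approx(0.2)


def test_dunn_matches_bruteforce(rng):
    for _ in range(40):
        n = int(rng.integers(4, 16))
        d = dist_from_points(rng.normal(size=(n, 3)))
        k = int(rng.integers(2, 4))
        lab = rng.integers(1, k + 1, size=n)
        lab[:k] = np.arange(1, k + 1)
        labels = ClusterLabels(ids=d.ids, labels=lab, k=k)
        if np.all(np.bincount(lab)[1:] == 1):
            continue  # all singletons: undefined, covered below
        assert dunn_index(d, labels) == pytest.approx(dunn_bruteforce(d.d, lab))


def test_dunn_all_singletons_undefined():
    d = dist_from_points(np.arange(3.0).reshape(-1, 1))
    labels = ClusterLabels(ids=d.ids, labels=[1, 2, 3], k=3)
    with pytest.raises(ValueError, match="singleton"):
        dunn_index(d, labels)


# ------------------------------------------------------------------- MDS ---

def test_classical_mds_recovers_planar_configuration(rng):
    points = rng.normal(size=(5, 2))
    d = dist_from_points(points)
    emb = classical_mds(d)
    assert np.max(np.abs(pdist(emb.coords) - pdist(points))) < 1e-8


def test_classical_mds_equilateral_triangle():
    d = dist_from_matrix(1.0 - np.eye(3))
    emb = classical_mds(d)
    assert np.allclose(pdist(emb.coords), 1.0, atol=1e-8)


def test_classical_mds_residual_equals_eigenvalue_tail(rng):
    points = rng.normal(size=(6, 4))  # genuinely 4-dimensional
    d = dist_from_points(points)
    n = d.n
    D2 = d.d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval = np.sort(np.linalg.eigvalsh(B))[::-1]
    emb = classical_mds(d, dims=2)
    gram = emb.coords @ emb.coords.T
    tail = np.sqrt(np.sum(eigval[2:] ** 2))
    assert np.linalg.norm(B - gram) == pytest.approx(tail, abs=1e-8)


def test_classical_mds_needs_enough_points():
    d = dist_from_matrix(1.0 - np.eye(2))
    with pytest.raises(ValueError):
        classical_mds(d, dims=2)


def test_isotonic_mds_realizable_low_stress(rng):
    d = dist_from_points(rng.normal(size=(8, 2)))
    emb = isotonic_mds(d)
    assert emb.method == "isotonic"
    assert emb.stress < 1e-6


def test_isotonic_mds_monotone_transform_invariance(rng):
    points = rng.normal(size=(8, 2))
    d0 = dist_from_points(points).d
    d = DistanceMatrix(ids=[f"P{i}" for i in range(8)], d=d0 ** 2,
                       metric="euclidean_summary")
    emb = isotonic_mds(d)
    assert emb.stress < 1e-3


def test_isotonic_mds_stress_trace_nonincreasing(rng):
    d = dist_from_points(rng.normal(size=(10, 4)))
    emb = isotonic_mds(d)
    trace = np.array(emb.stress_trace)
    assert len(trace) >= 1
    assert np.all(np.diff(trace) <= 1e-12)
    assert emb.stress == pytest.approx(trace.min())


# ------------------------------------------------------------- suggest_k ---

def test_suggest_k_silhouette_peaks_at_two_planted_clusters(rng):
    points = np.concatenate([rng.normal(0, 0.5, (10, 2)),
                             rng.normal(10, 0.5, (10, 2))])
    rows = suggest_k(dist_from_points(points), k_range=[2, 3, 4])
    assert len(rows) == 3
    best = max(rows, key=lambda r: r["silhouette"])
    assert best["k"] == 2


def test_suggest_k_degenerate_all_identical_warns(caplog):
    d = dist_from_matrix(np.zeros((5, 5)))
    with caplog.at_level("WARNING"):
        rows = suggest_k(d, k_range=[2, 3])
    assert any("zero" in r.message for r in caplog.records)
    assert all(np.isnan(row["silhouette"]) for row in rows)


def test_suggest_k_out_of_range_rejected():
    d = dist_from_points(np.arange(4.0).reshape(-1, 1))
    with pytest.raises(ValueError):
        suggest_k(d, k_range=[4])
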