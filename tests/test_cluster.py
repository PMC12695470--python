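"""Graph construction, modularity, marker AUC and resolution selection."""

import igraph as ig
import numpy as np
import pytest
from scipy import sparse
from sklearn.metrics import adjusted_rand_score

from conftest import make_norm
from cotransmit.cluster import (
    NeighborGraph,
    ResolutionSweep,
    build_knn_graph,
    cluster_similarity,
    cluster_sweep,
    marker_stats,
    modularity_q,
    select_resolution,
)
from cotransmit.errors import CotransmitError
from cotransmit.io_qc import Embedding


def _embedding(points):
    pts = np.asarray(points, dtype=float)
    return Embedding(pts, np.ones(pts.shape[1]), np.arange(len(pts)), pts.shape[1])


def _clique_graph(sizes):
    """Disjoint unweighted cliques as a NeighborGraph."""
    n = sum(sizes)
    A = np.zeros((n, n))
    start = 0
    for s in sizes:
        A[start : start + s, start : start + s] = 1.0
        start += s
    np.fill_diagonal(A, 0.0)
    return NeighborGraph(sparse.csr_matrix(A), k=max(sizes) - 1)


def brute_force_modularity(A: np.ndarray, labels) -> float:
    two_w = A.sum()
    deg = A.sum(axis=1)
    q = 0.0
    for i in range(len(labels)):
        for j in range(len(labels)):
            if labels[i] == labels[j]:
                q += A[i, j] - deg[i] * deg[j] / two_w
    return q / two_w


# ---------------------------------------------------------------------------
# kNN graph


def test_knn_graph_matches_bruteforce_neighbors():
    pts = np.array([[0.0], [1.0], [2.2], [5.0], [5.5], [9.0]])
    k = 2
    graph = build_knn_graph(_embedding(pts), k=k)
    # exhaustive neighbor enumeration
    d = np.abs(pts - pts.T)
    np.fill_diagonal(d, np.inf)
    expected = set()
    for i in range(6):
        for j in np.argsort(d[i])[:k]:
            expected.add((min(i, j), max(i, j)))
    coo = sparse.triu(graph.adjacency, k=1).tocoo()
    got = set(zip(coo.row.tolist(), coo.col.tolist()))
    assert got == expected
    assert (coo.data > 0).all() and (coo.data <= 1).all()


def test_knn_graph_two_blobs_two_components(rng):
    pts = np.r_[rng.normal(0, 0.1, (30, 2)), rng.normal(10, 0.1, (30, 2))]
    graph = build_knn_graph(_embedding(pts), k=5)
    assert graph.n_components == 2


def test_knn_graph_complete_when_k_is_n_minus_1(rng):
    pts = rng.normal(size=(8, 3))
    graph = build_knn_graph(_embedding(pts), k=7)
    assert graph.adjacency.nnz == 8 * 7


def test_knn_graph_k_too_large(rng):
    with pytest.raises(CotransmitError, match="k="):
        build_knn_graph(_embedding(rng.normal(size=(5, 2))), k=5)


# ---------------------------------------------------------------------------
# Modularity


def test_modularity_single_community_is_zero(rng):
    A = rng.random((20, 20))
    A = np.triu(A, 1) + np.triu(A, 1).T
    g = NeighborGraph(sparse.csr_matrix(A), k=5)
    assert modularity_q(g, np.zeros(20, dtype=int)) == pytest.approx(0.0, abs=1e-12)


def test_modularity_two_cliques_is_half():
    g = _clique_graph([5, 5])
    labels = np.r_[np.zeros(5, dtype=int), np.ones(5, dtype=int)]
    assert modularity_q(g, labels) == pytest.approx(0.5, abs=1e-12)


def test_modularity_matches_bruteforce_and_igraph(rng):
    for _ in range(10):
        n = int(rng.integers(5, 50))
        A = rng.random((n, n)) * (rng.random((n, n)) < 0.3)
        A = np.triu(A, 1) + np.triu(A, 1).T
        if A.sum() == 0:
            continue
        labels = rng.integers(0, 4, n)
        g = NeighborGraph(sparse.csr_matrix(A), k=3)
        mine = modularity_q(g, labels)
        assert mine == pytest.approx(brute_force_modularity(A, labels), abs=1e-12)
        coo = sparse.triu(g.adjacency, k=1).tocoo()
        gig = ig.Graph(n=n, edges=list(zip(coo.row, coo.col)))
        ref = gig.modularity(labels.tolist(), weights=coo.data.tolist())
        assert mine == pytest.approx(ref, abs=1e-9)


def test_modularity_random_labels_mean_matches_permutation_expectation(rng):
    # under iid uniform labels over k groups, E[Q] = -(1 - 1/k) sum d_i^2/(2W)^2
    n, k = 60, 5
    A = (rng.random((n, n)) < 0.2).astype(float)
    A = np.triu(A, 1) + np.triu(A, 1).T
    g = NeighborGraph(sparse.csr_matrix(A), k=3)
    qs = [modularity_q(g, rng.integers(0, k, n)) for _ in range(100)]
    deg = A.sum(axis=1)
    expected = -(1 - 1 / k) * (deg**2).sum() / A.sum() ** 2
    se = np.std(qs, ddof=1) / np.sqrt(len(qs))
    assert np.mean(qs) == pytest.approx(expected, abs=3 * se + 1e-3)


def test_modularity_label_coverage_error():
    g = _clique_graph([4])
    with pytest.raises(CotransmitError, match="labels"):
        modularity_q(g, np.zeros(3, dtype=int))


# ---------------------------------------------------------------------------
# Sweep


def test_sweep_two_cliques_low_resolution():
    g = _clique_graph([8, 8])
    sweep = cluster_sweep(g, resolutions=[0.1, 0.5], seed=0)
    assert sweep.n_clusters[0.1] == 2
    ari = adjusted_rand_score(np.r_[np.zeros(8), np.ones(8)], sweep.labels[0.1])
    assert ari == 1.0


def test_sweep_recovers_planted_blobs(rng):
    truth = np.repeat(np.arange(4), 50)
    centers = rng.normal(0, 8, size=(4, 5))
    pts = centers[truth] + rng.normal(0, 0.5, size=(200, 5))
    graph = build_knn_graph(_embedding(pts), k=10)
    sweep = cluster_sweep(graph, resolutions=[0.1], seed=0)
    assert adjusted_rand_score(truth, sweep.labels[0.1]) > 0.95


def test_sweep_deterministic(rng):
    pts = rng.normal(size=(80, 4))
    graph = build_knn_graph(_embedding(pts), k=8)
    s1 = cluster_sweep(graph, seed=3)
    s2 = cluster_sweep(graph, seed=3)
    for r in s1.resolutions:
        assert (s1.labels[r] == s2.labels[r]).all()
        assert s1.modularity[r] == s2.modularity[r]


# ---------------------------------------------------------------------------
# Marker statistics


def test_marker_identical_distribution_auc_half(rng):
    half = rng.random((2, 15))
    vals = np.concatenate([half, half], axis=1)  # in/out groups share values
    norm = make_norm(vals)
    labels = np.r_[np.zeros(15, dtype=int), np.ones(15, dtype=int)]
    ms = marker_stats(norm, labels, 0, min_pct=0.0, logfc_min=0.0)
    assert ms["auc"].to_numpy() == pytest.approx(0.5, abs=1e-12)
    assert (ms["p_value"] > 0.9).all()


def test_marker_perfect_separation():
    vals = np.zeros((1, 20))
    vals[0, :10] = 2.0
    norm = make_norm(vals)
    labels = np.r_[np.zeros(10, dtype=int), np.ones(10, dtype=int)]
    ms = marker_stats(norm, labels, 0, min_pct=0.0, logfc_min=0.0)
    assert ms.loc[0, "auc"] == 1.0
    assert ms.loc[0, "p_value"] < 1e-3


def test_marker_auc_matches_pair_counting_with_ties():
    vals = np.array([[0.0, 1.0, 1.0, 2.0, 0.0, 1.0, 3.0, 2.0]])
    labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    norm = make_norm(vals)
    ms = marker_stats(norm, labels, 0, min_pct=0.0, logfc_min=0.0)
    x_in, x_out = vals[0, :4], vals[0, 4:]
    pairs = sum(
        1.0 if a > b else 0.5 if a == b else 0.0 for a in x_in for b in x_out
    )
    assert ms.loc[0, "auc"] == pytest.approx(pairs / 16, abs=1e-12)


def test_marker_complement_auc_sums_to_one(rng):
    vals = rng.poisson(1.0, size=(5, 40)).astype(float)
    labels = (np.arange(40) < 15).astype(int)
    a = marker_stats(make_norm(vals), labels, 1, min_pct=0.0, logfc_min=0.0).set_index("gene")["auc"]
    b = marker_stats(make_norm(vals), labels, 0, min_pct=0.0, logfc_min=0.0).set_index("gene")["auc"]
    for g in a.index:
        assert a[g] + b[g] == pytest.approx(1.0, abs=1e-12)


def test_marker_prefilters_and_bonferroni(rng):
    vals = np.zeros((3, 40))
    vals[0, :20] = 3.0  # strong marker
    vals[1] = rng.random(40) * 0.01  # tiny log-fc -> filtered
    labels = (np.arange(40) < 20).astype(int)
    ms = marker_stats(make_norm(vals), labels, 1)
    assert list(ms["gene"]) == ["g0"]
    assert ms.attrs["bonferroni_multiplier"] == 1
    assert (ms["p_adj"] >= ms["p_value"]).all()


def test_marker_small_cluster_errors():
    norm = make_norm(np.ones((2, 5)))
    with pytest.raises(CotransmitError, match=">=3"):
        marker_stats(norm, np.array([0, 0, 1, 1, 1]), 0)


# ---------------------------------------------------------------------------
# Resolution selection


def _separated_norm(rng, n_per=40):
    """Two well-separated expression groups over 12 genes."""
    vals = rng.poisson(0.2, size=(12, 2 * n_per)).astype(float)
    vals[:4, :n_per] += 4.0
    vals[4:8, n_per:] += 4.0
    return make_norm(vals), np.r_[np.zeros(n_per, dtype=int), np.ones(n_per, dtype=int)]


def _fake_sweep(resolutions, labels_per_res, modularity):
    return ResolutionSweep(
        resolutions=np.asarray(resolutions),
        labels={r: np.asarray(l) for r, l in zip(resolutions, labels_per_res)},
        n_clusters={r: int(np.max(l)) + 1 for r, l in zip(resolutions, labels_per_res)},
        modularity=dict(zip(resolutions, modularity)),
        seed=0,
    )


def test_select_resolution_caps_oversplitting(rng):
    norm, true_labels = _separated_norm(rng)
    n = len(true_labels)
    random_split = rng.integers(0, 4, n)
    sweep = _fake_sweep(
        [0.1, 0.2, 0.3],
        [np.zeros(n, dtype=int), true_labels, random_split],
        [0.0, 0.4, 0.41],
    )
    choice = select_resolution(sweep, norm)
    assert choice.max_valid_resolution == 0.2
    assert choice.chosen_resolution == 0.2
    assert choice.validity == {0.1: True, 0.2: True, 0.3: False}


def test_select_resolution_no_plateau_uses_last(rng):
    norm, true_labels = _separated_norm(rng)
    n = len(true_labels)
    sweep = _fake_sweep(
        [0.1, 0.2, 0.3],
        [np.zeros(n, dtype=int), true_labels, true_labels],
        [0.1, 0.2, 0.3],  # strictly linear growth: no plateau step
    )
    choice = select_resolution(sweep, norm)
    assert choice.plateau_candidate == 0.3
    assert choice.chosen_resolution == 0.3


def test_select_resolution_homogeneous_picks_lowest(rng):
    vals = rng.poisson(1.0, size=(10, 60)).astype(float)
    norm = make_norm(vals)
    n = 60
    sweep = _fake_sweep(
        [0.1, 0.2],
        [np.zeros(n, dtype=int), rng.integers(0, 3, n)],
        [0.0, 0.0],
    )
    choice = select_resolution(sweep, norm)
    assert choice.chosen_resolution == 0.1


def test_select_resolution_monotone_in_auc_threshold(rng):
    norm, true_labels = _separated_norm(rng)
    n = len(true_labels)
    sweep = _fake_sweep(
        [0.1, 0.2],
        [np.zeros(n, dtype=int), true_labels],
        [0.0, 0.4],
    )
    prev = np.inf
    for thr in (0.55, 0.75, 0.95, 0.999):
        try:
            mv = select_resolution(sweep, norm, auc_threshold=thr).max_valid_resolution
        except CotransmitError:
            mv = -np.inf
        assert mv <= prev + 1e-12
        prev = mv


def test_select_resolution_all_invalid_errors(rng):
    vals = rng.poisson(1.0, size=(6, 30)).astype(float)
    norm = make_norm(vals)
    sweep = _fake_sweep([0.1], [rng.integers(0, 3, 30)], [0.1])
    with pytest.raises(CotransmitError, match="no resolution"):
        select_resolution(sweep, norm, auc_threshold=0.99)


# ---------------------------------------------------------------------------
# Cluster similarity


def test_cluster_similarity_hand_vectors():
    # three clusters of 2 cells each, constant within cluster
    means = np.array(
        [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 1.0, 0.5]]
    )  # clusters x genes
    vals = np.repeat(means, 2, axis=0).T  # genes x cells
    norm = make_norm(vals)
    labels = np.repeat([0, 1, 2], 2)
    cond = np.array(["A"] * 6)
    mats = cluster_similarity(norm, labels, cond)
    mat = mats["A"]
    expected = np.corrcoef(means)
    np.testing.assert_allclose(mat.to_numpy(), expected, atol=1e-12)
    assert mat.loc[0, 0] == 1.0
    assert mat.loc[0, 1] == pytest.approx(1.0)  # proportional profiles


def test_cluster_similarity_missing_condition_is_nan():
    vals = np.array([[1.0, 2.0, 3.0, 4.0], [0.5, 1.0, 2.0, 1.0]])
    norm = make_norm(vals)
    labels = np.array([0, 0, 1, 1])
    cond = np.array(["A", "A", "A", "B"])  # cluster 0 absent in B
    mats = cluster_similarity(norm, labels, cond)
    assert np.isnan(mats["B"].loc[0, 1])
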