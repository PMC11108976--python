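import itertools
import logging

import numpy as np
import pytest

from scovnet.adjust import AssociationMatrix
from scovnet.errors import ComputeError, ValidationError
from scovnet.graphs import (
    BinaryGraph,
    binarize_at_density,
    density_grid,
    density_sweep,
    detect_hubs,
    find_dmin,
    nodal_metrics,
)


def assoc_from(r, prefix="n"):
    r = np.asarray(r, dtype=float)
    ids = [f"{prefix}{i:02d}" for i in range(r.shape[0])]
    return AssociationMatrix(group="g", region_ids=ids, r=r, n=50)


def graph_from_adj(A):
    A = np.asarray(A, dtype=np.int8)
    p = A.shape[0]
    density = A.sum() / 2 / (p * (p - 1) / 2)
    return BinaryGraph(region_ids=[f"n{i:02d}" for i in range(p)],
                       adjacency=A, density=min(max(density, 1e-6), 0.5))


# -- independent brute-force oracle ----------------------------------------


def brute_force_metrics(A):
    """Exhaustive shortest-path enumeration for graphs with few nodes."""
    A = np.asarray(A, dtype=int)
    p = A.shape[0]
    INF = float("inf")
    dist = np.full((p, p), INF)
    np.fill_diagonal(dist, 0)
    dist[A == 1] = 1
    for k in range(p):  # Floyd-Warshall
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])

    npaths = np.zeros((p, p))
    through = np.zeros((p, p, p))  # s, t, v: shortest paths via v
    for s in range(p):
        for t in range(p):
            if s == t or dist[s, t] == INF:
                continue
            # count shortest paths by dynamic programming over distance layers
            cnt = np.zeros(p)
            cnt[s] = 1
            order = sorted(range(p), key=lambda v: dist[s, v])
            for v in order:
                if v == s or dist[s, v] == INF:
                    continue
                cnt[v] = sum(cnt[u] for u in range(p)
                             if A[u, v] and dist[s, u] + 1 == dist[s, v])
            npaths[s, t] = cnt[t]
            for v in range(p):
                if v in (s, t) or dist[s, v] + dist[v, t] != dist[s, t]:
                    continue
                cnt_vt = np.zeros(p)
                cnt_vt[v] = 1
                for w in sorted(range(p), key=lambda x: dist[v, x]):
                    if w == v or dist[v, w] == INF:
                        continue
                    cnt_vt[w] = sum(cnt_vt[u] for u in range(p)
                                    if A[u, w] and dist[v, u] + 1 == dist[v, w])
                through[s, t, v] = cnt[v] * cnt_vt[t]

    betweenness = np.zeros(p)
    for v in range(p):
        total = 0.0
        for s, t in itertools.combinations(range(p), 2):
            if v in (s, t) or npaths[s, t] == 0:
                continue
            total += through[s, t, v] / npaths[s, t]
        betweenness[v] = total

    degree = A.sum(axis=1)
    clustering = np.zeros(p)
    for v in range(p):
        nbrs = np.nonzero(A[v])[0]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(A[a, b] for a, b in itertools.combinations(nbrs, 2))
        clustering[v] = 2 * links / (k * (k - 1))
    return degree, betweenness, clustering


class TestBinarize:
    def test_rank_selection_keeps_largest(self):
        rng = np.random.default_rng(0)
        vals = np.arange(10) / 10.0
        r = np.eye(5)
        iu = np.triu_indices(5, 1)
        r[iu] = rng.permutation(vals)
        r = r + r.T - np.eye(5) * (np.diag(r) - 1)
        np.fill_diagonal(r, 1.0)
        g = binarize_at_density(assoc_from(r), 0.2)
        assert g.n_edges == 2
        kept = [r[i, j] for i, j in zip(*np.nonzero(np.triu(g.adjacency, 1)))]
        assert sorted(kept) == sorted(vals)[-2:]

    def test_round_half_up_edge_count(self):
        # p=10: 45 pairs, 0.5*45 = 22.5 -> 23 edges
        rng = np.random.default_rng(1)
        r = rng.uniform(-1, 1, (10, 10))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        g = binarize_at_density(assoc_from(r), 0.5)
        assert g.n_edges == 23

    def test_ties_deterministic(self):
        r = np.full((6, 6), 0.5)
        np.fill_diagonal(r, 1.0)
        a = binarize_at_density(assoc_from(r), 0.3)
        b = binarize_at_density(assoc_from(r), 0.3)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)
        assert a.n_edges == 5  # round-half-up: 0.3 * 15 = 4.5 -> 5

    def test_zero_edge_density_errors(self):
        r = np.eye(4)
        with pytest.raises(ValidationError, match="zero edges"):
            binarize_at_density(assoc_from(r), 0.01)

    def test_density_bounds(self):
        r = np.eye(5)
        for bad in (0.0, 0.6, -0.1):
            with pytest.raises(ValidationError):
                binarize_at_density(assoc_from(r), bad)

    def test_nested_densities_edge_subset(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((40, 12))
        r = np.corrcoef(x, rowvar=False)
        assoc = assoc_from(r)
        prev = binarize_at_density(assoc, 0.1)
        for d in (0.2, 0.3, 0.4, 0.5):
            cur = binarize_at_density(assoc, d)
            assert np.all(prev.adjacency <= cur.adjacency)
            prev = cur

    def test_degree_sum_twice_edges(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((40, 15))
        assoc = assoc_from(np.corrcoef(x, rowvar=False))
        for d in density_grid(0.1):
            g = binarize_at_density(assoc, d)
            assert g.adjacency.sum() == 2 * g.n_edges


class TestFindDmin:
    def test_spanning_tree_at_first_grid_point(self):
        # hub-and-spokes top values connect everything with p-1 edges:
        # p=20 has 190 pairs, round(0.1*190)=19 edges = exactly the star
        p = 20
        r = np.full((p, p), 0.1)
        r[0, 1:] = r[1:, 0] = 0.9
        np.fill_diagonal(r, 1.0)
        a = assoc_from(r)
        assert find_dmin(a, a, step=0.1) == pytest.approx(0.1)

    def test_weak_node_raises_dmin(self):
        def make(weak):
            rng = np.random.default_rng(5)
            r = rng.uniform(0.4, 0.6, (10, 10))
            r = (r + r.T) / 2
            r[9, :] = r[:, 9] = weak
            np.fill_diagonal(r, 1.0)
            return assoc_from(r)
        strong = make(0.59)
        feeble = make(0.52)
        assert (find_dmin(strong, strong, step=0.02)
                <= find_dmin(feeble, feeble, step=0.02))

    def test_impossible_connectivity_errors(self):
        r = np.full((4, 4), 0.9)
        r[3, :] = r[:, 3] = -0.5  # node 3 always ranked last
        np.fill_diagonal(r, 1.0)
        a = assoc_from(r)
        with pytest.raises(ComputeError, match="no density"):
            find_dmin(a, a, step=0.1, d_max=0.5)

    def test_result_on_grid(self, registry, null_cohort):
        from scovnet.adjust import group_association_matrices

        assoc = group_association_matrices(
            null_cohort, registry.graph_nodes("nine_nuclei"))
        d = find_dmin(assoc["control"], assoc["case"], step=0.02)
        assert any(abs(d - g) < 1e-12 for g in density_grid(0.02))


class TestNodalMetrics:
    def test_complete_graph(self):
        A = 1 - np.eye(6, dtype=np.int8)
        m = nodal_metrics(graph_from_adj(A))
        np.testing.assert_array_equal(m.degree, [5] * 6)
        np.testing.assert_allclose(m.betweenness, 0.0)
        np.testing.assert_allclose(m.clustering, 1.0)

    def test_path_graph_hand_counts(self):
        # a-b-c-d-e: betweenness(c)=4 ({a,d},{a,e},{b,d},{b,e}), ends 0
        A = np.zeros((5, 5), dtype=np.int8)
        for i in range(4):
            A[i, i + 1] = A[i + 1, i] = 1
        m = nodal_metrics(graph_from_adj(A))
        np.testing.assert_allclose(m.betweenness, [0, 3, 4, 3, 0])
        np.testing.assert_array_equal(m.degree, [1, 2, 2, 2, 1])
        np.testing.assert_allclose(m.clustering, 0.0)

    def test_star_graph_hand_counts(self):
        A = np.zeros((7, 7), dtype=np.int8)
        A[0, 1:] = A[1:, 0] = 1
        m = nodal_metrics(graph_from_adj(A))
        assert m.betweenness[0] == pytest.approx(15.0)  # C(6,2)
        np.testing.assert_allclose(m.betweenness[1:], 0.0)

    def test_leaf_nodes_zero_betweenness_and_clustering(self):
        rng = np.random.default_rng(7)
        A = (rng.uniform(size=(10, 10)) < 0.3).astype(np.int8)
        A = np.triu(A, 1)
        A[0, :] = 0
        A[0, 1] = 1  # node 0 is a leaf
        A = A + A.T
        m = nodal_metrics(graph_from_adj(A))
        assert m.betweenness[0] == 0.0
        assert m.clustering[0] == 0.0

    @pytest.mark.parametrize("trial", range(10))
    def test_agrees_with_brute_force(self, trial):
        rng = np.random.default_rng(100 + trial)
        p = int(rng.integers(4, 13))
        A = (rng.uniform(size=(p, p)) < 0.35).astype(np.int8)
        A = np.triu(A, 1)
        A = A + A.T
        m = nodal_metrics(graph_from_adj(A))
        deg, bet, clus = brute_force_metrics(A)
        np.testing.assert_array_equal(m.degree, deg)
        np.testing.assert_allclose(m.betweenness, bet, atol=1e-9)
        np.testing.assert_allclose(m.clustering, clus, atol=1e-12)


class TestDetectHubs:
    def test_star_center_flagged(self):
        # integrated betweenness of a star: center 15, leaves 0
        scores = {"betweenness": np.array([15.0, 0, 0, 0, 0, 0, 0]),
                  "degree": np.array([6.0, 1, 1, 1, 1, 1, 1])}
        ids = [f"n{i}" for i in range(7)]
        hubs = detect_hubs(scores, ids, "control")
        flagged = {(h.region_id, h.metric) for h in hubs.hubs}
        assert ("n0", "betweenness") in flagged
        assert not any(rid != "n0" for rid, _ in flagged)

    def test_all_equal_no_hubs(self, caplog):
        scores = {"degree": np.full(5, 3.0), "betweenness": np.full(5, 1.0)}
        with caplog.at_level(logging.WARNING):
            hubs = detect_hubs(scores, [f"n{i}" for i in range(5)], "g")
        assert hubs.hubs == []
        assert "zero SD" in caplog.text

    def test_exactly_two_sd_not_flagged(self):
        # construct scores where the max sits exactly at mean + 2 SD
        x = np.array([0.0, 0.0, 0.0, 0.0, 2.0])
        mean, sd = x.mean(), x.std()
        assert x.max() == pytest.approx(mean + 2 * sd)
        hubs = detect_hubs({"degree": x}, [f"n{i}" for i in range(5)], "g")
        assert hubs.hubs == []

    def test_too_few_nodes(self):
        with pytest.raises(ValidationError):
            detect_hubs({"degree": np.array([1.0, 2.0])}, ["a", "b"], "g")


class TestDensitySweep:
    def test_sweep_structure(self, registry, null_cohort):
        from scovnet.adjust import group_association_matrices
        from scovnet.regions import aggregate_composites

        nodes = registry.graph_nodes("three_nuclei")
        cohort = aggregate_composites(null_cohort, registry)
        assoc = group_association_matrices(cohort, nodes)
        sweep = density_sweep(assoc, step=0.1)
        assert sweep.densities[0] == sweep.d_min
        assert sweep.densities[-1] == pytest.approx(0.5)
        for group in ("control", "case"):
            for metric in ("degree", "betweenness", "clustering"):
                assert sweep.curves[group][metric].shape == (
                    len(sweep.densities), len(nodes))
            for g in sweep.graphs_by_group[group]:
                assert g.is_connected() or g.density > sweep.d_min
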