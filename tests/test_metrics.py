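import itertools
import math

import numpy as np
import pytest

from dmnqol import errors
from dmnqol.connectivity import ConnectivityMatrix
from dmnqol.metrics import (
    complexity_index,
    compute_profile,
    degree_entropy,
    detect_partition,
    dunn_index,
    dunn_index_from_distances,
    global_clustering,
    local_clustering,
    modularity_q,
    node_degrees,
    node_triangles,
    path_length_stats,
    random_null_ensemble,
    shortest_paths,
    small_worldness,
    _double_edge_swap,
)

from conftest import (
    block_connectivity,
    complete_graph,
    graph_from_edges,
    random_graph,
)


# ---------------------------------------------------------------- oracles
def brute_triangles(g):
    n = g.n
    t = np.zeros(n, dtype=int)
    for i, j, h in itertools.combinations(range(n), 3):
        if g.adjacency[i, j] and g.adjacency[i, h] and g.adjacency[j, h]:
            t[i] += 1
            t[j] += 1
            t[h] += 1
    return t


def brute_bfs_distances(g):
    n = g.n
    d = np.full((n, n), np.inf)
    for s in range(n):
        d[s, s] = 0
        frontier = [s]
        depth = 0
        while frontier:
            depth += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if g.adjacency[u, v] and d[s, v] == np.inf:
                        d[s, v] = depth
                        nxt.append(v)
            frontier = nxt
    return d


def brute_modularity(g, modules):
    """Q via the Newman per-edge form sum_ij (a_ij - k_i k_j / 2m) / 2m."""
    a = g.adjacency.astype(float)
    k = a.sum(axis=1)
    m2 = a.sum()
    q = 0.0
    for i in range(g.n):
        for j in range(g.n):
            if modules[i] == modules[j]:
                q += (a[i, j] - k[i] * k[j] / m2) / m2
    return q


class TestDegrees:
    def test_complete_graph(self):
        assert node_degrees(complete_graph(4)).tolist() == [3, 3, 3, 3]

    def test_star(self):
        g = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert node_degrees(g).tolist() == [3, 1, 1, 1]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_row_sum_oracle(self, seed):
        g = random_graph(10, 0.4, seed)
        expected = [
            sum(g.adjacency[i, j] for j in range(10)) for i in range(10)
        ]
        assert node_degrees(g).tolist() == expected


class TestTriangles:
    def test_complete_graph(self):
        assert node_triangles(complete_graph(4)).tolist() == [3, 3, 3, 3]

    def test_cycle_has_none(self):
        g = graph_from_edges(5, [(i, (i + 1) % 5) for i in range(5)])
        assert node_triangles(g).tolist() == [0] * 5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        g = random_graph(12, 0.4, seed)
        np.testing.assert_array_equal(node_triangles(g), brute_triangles(g))


class TestClustering:
    def test_complete_graph_is_one(self):
        assert global_clustering(complete_graph(6)) == 1.0

    def test_star_is_zero(self):
        g = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        assert global_clustering(g) == 0.0

    def test_triangle_with_pendant(self):
        g = graph_from_edges(4, [(0, 1), (0, 2), (1, 2), (0, 3)])
        # hub: 2*1/(3*2) = 1/3; two triangle nodes: 1; pendant: 0
        assert global_clustering(g) == pytest.approx(7 / 12)

    def test_zero_degree_convention(self):
        g = graph_from_edges(3, [(0, 1)])
        assert local_clustering(g).tolist() == [0.0, 0.0, 0.0]


class TestShortestPaths:
    def test_complete_graph(self):
        d = shortest_paths(complete_graph(4))
        assert (d[~np.eye(4, dtype=bool)] == 1).all()

    def test_six_cycle(self):
        g = graph_from_edges(6, [(i, (i + 1) % 6) for i in range(6)])
        assert sorted(shortest_paths(g)[0][1:]) == [1, 1, 2, 2, 3]

    def test_disconnected_pairs_are_infinite(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        d = shortest_paths(g)
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bfs_oracle(self, seed):
        g = random_graph(11, 0.25, seed)
        np.testing.assert_array_equal(shortest_paths(g), brute_bfs_distances(g))


class TestPathLengthStats:
    def test_path_graph_hand_values(self):
        g = graph_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        stats = path_length_stats(g)
        np.testing.assert_allclose(stats.per_node, [2, 4 / 3, 4 / 3, 2])
        assert stats.char_path_length == pytest.approx(5 / 3)
        assert stats.sd_path_length == pytest.approx(
            np.std([2, 4 / 3, 4 / 3, 2], ddof=1)
        )

    def test_six_cycle(self):
        g = graph_from_edges(6, [(i, (i + 1) % 6) for i in range(6)])
        stats = path_length_stats(g)
        assert stats.char_path_length == pytest.approx(1.8)
        assert stats.sd_path_length == 0.0

    def test_single_edge(self):
        stats = path_length_stats(graph_from_edges(2, [(0, 1)]))
        assert stats.char_path_length == 1.0
        assert stats.sd_path_length == 0.0

    def test_isolated_nodes_excluded_and_counted(self):
        g = graph_from_edges(4, [(0, 1), (1, 2)])
        stats = path_length_stats(g)
        assert stats.n_isolated == 1
        assert np.isnan(stats.per_node[3])

    def test_edgeless_graph_rejected(self):
        g = graph_from_edges(3, [])
        with pytest.raises(errors.DegenerateGraphError):
            path_length_stats(g)


class TestModularity:
    def test_single_module_is_zero(self):
        g = random_graph(8, 0.4, 0)
        assert modularity_q(g, {i: 0 for i in range(8)}) == pytest.approx(0.0)

    def test_two_disconnected_triangles(self):
        g = graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        modules = {i: i // 3 for i in range(6)}
        assert modularity_q(g, modules) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_edge_oracle(self, seed):
        g = random_graph(10, 0.35, seed)
        rng = np.random.default_rng(seed)
        modules = {i: int(rng.integers(0, 3)) for i in range(10)}
        assert modularity_q(g, modules) == pytest.approx(
            brute_modularity(g, modules), abs=1e-12
        )

    def test_unassigned_node_rejected(self):
        g = random_graph(5, 0.5, 1)
        with pytest.raises(errors.PartitionError):
            modularity_q(g, {0: 0, 1: 0, 2: 1})

    def test_partition_e_matrix_sums_to_one(self):
        g = random_graph(12, 0.3, 3)
        part = detect_partition(g, seed=0)
        assert part.e.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(part.e, part.e.T)


class TestDetectPartition:
    def test_recovers_disconnected_triangles(self):
        g = graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        part = detect_partition(g, seed=0)
        assert modularity_q(g, part) == pytest.approx(0.5)
        assert len(set(part.modules.values())) == 2

    def test_complete_graph_single_module(self):
        part = detect_partition(complete_graph(6), seed=0)
        assert len(set(part.modules.values())) == 1

    def test_deterministic_given_seed(self):
        g = random_graph(16, 0.25, 4)
        assert (
            detect_partition(g, seed=9).modules
            == detect_partition(g, seed=9).modules
        )

    def test_never_worse_than_single_module(self):
        for seed in range(5):
            g = random_graph(10, 0.3, seed + 50)
            if g.n_edges == 0:
                continue
            assert modularity_q(g, detect_partition(g, seed=0)) >= 0.0

    def test_edgeless_graph_rejected(self):
        with pytest.raises(errors.DegenerateGraphError):
            detect_partition(graph_from_edges(3, []), seed=0)


class TestNullEnsemble:
    @pytest.mark.parametrize("seed", range(5))
    def test_swaps_preserve_degree_sequence(self, seed):
        g = random_graph(14, 0.3, seed)
        adj, _ = _double_edge_swap(
            g.adjacency, 10 * g.n_edges, 10 * g.n_edges,
            np.random.default_rng(seed),
        )
        assert (adj == adj.T).all() and not np.diag(adj).any()
        np.testing.assert_array_equal(adj.sum(1), g.adjacency.sum(1))

    def test_complete_graph_degenerate(self):
        ens = random_null_ensemble(complete_graph(5), n_null=3, seed=0)
        assert ens.degenerate
        assert ens.c_rand == 1.0 and ens.l_rand == 1.0

    def test_block_structure_has_excess_clustering(self):
        """Degree-preserving randomization destroys block clustering."""
        from dmnqol.connectivity import ConnectivityConfig, binarize_graph
        from dmnqol.synthetic import (
            SubnetworkSpec,
            gen_subject_timeseries,
            make_block_covariance,
        )

        cov = make_block_covariance(
            SubnetworkSpec(r_within=0.6, r_between=0.05)
        )
        wins = 0
        for seed in range(20):
            ts = gen_subject_timeseries(cov, time_points=220, seed=seed)
            from dmnqol.connectivity import pearson_connectivity

            g = binarize_graph(pearson_connectivity(ts), ConnectivityConfig())
            ens = random_null_ensemble(g, n_null=20, seed=seed)
            wins += global_clustering(g) > ens.c_rand
        assert wins >= 18


class TestSmallWorldness:
    def test_complete_graph_is_exactly_one(self):
        g = complete_graph(6)
        assert small_worldness(g, random_null_ensemble(g, 3, 0)) == 1.0

    def test_triangle_free_graph_is_zero(self):
        g = graph_from_edges(6, [(i, (i + 1) % 6) for i in range(6)])
        assert small_worldness(g, random_null_ensemble(g, 3, 0)) == 0.0

    def test_rewired_ring_with_shortcuts_exceeds_one(self):
        # ring lattice n=20, 4 neighbors, plus two seeded shortcuts
        edges = set()
        for i in range(20):
            edges.add(tuple(sorted((i, (i + 1) % 20))))
            edges.add(tuple(sorted((i, (i + 2) % 20))))
        edges |= {(0, 10), (5, 15)}
        g = graph_from_edges(20, sorted(edges))
        s = small_worldness(g, random_null_ensemble(g, 100, seed=0))
        assert s > 1.0

    def test_typical_random_graph_scores_near_one(self):
        values = []
        for seed in range(10):
            g = random_graph(18, 0.3, seed + 200)
            values.append(
                small_worldness(g, random_null_ensemble(g, 50, seed=seed))
            )
        assert np.mean(values) == pytest.approx(1.0, abs=0.1)


class TestEntropy:
    def test_regular_graph_zero(self):
        assert degree_entropy(complete_graph(5)) == 0.0

    def test_star_with_three_leaves(self):
        g = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        expected = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        assert degree_entropy(g) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_histogram_oracle(self, seed):
        g = random_graph(12, 0.35, seed)
        degrees = node_degrees(g).tolist()
        probs = [degrees.count(v) / 12 for v in sorted(set(degrees))]
        oracle = -sum(p * math.log2(p) for p in probs)
        assert degree_entropy(g) == pytest.approx(oracle, abs=1e-12)


class TestComplexityIndex:
    def test_complete_and_empty_are_zero(self):
        assert complexity_index(complete_graph(5)) == 0.0
        assert complexity_index(graph_from_edges(5, [])) == 0.0

    def test_k4_minus_one_edge(self):
        g = graph_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)])
        assert complexity_index(g) == pytest.approx(20 / 36)

    def test_maximal_at_half_density(self):
        # 4 nodes, m = 6 pairs: 3 edges is exactly half density
        g = graph_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        assert complexity_index(g) == 1.0


class TestDunnIndex:
    def test_planted_blocks_exact_value(self):
        conn = block_connectivity((4, 4, 4), r_within=0.9, r_between=0.0)
        # within distance 0.1, between distance 1.0
        assert dunn_index(conn, k=3) == pytest.approx(10.0)

    def test_two_block_variant(self):
        conn = block_connectivity((4, 4), r_within=0.9, r_between=0.0)
        assert dunn_index(conn, k=2) == pytest.approx(10.0)

    def test_toy_distance_input(self):
        pts = np.array([0.0, 0.1, 10.0, 10.1])
        d = np.abs(pts[:, None] - pts[None, :])
        assert dunn_index_from_distances(d, [1, 1, 2, 2]) == pytest.approx(99.0)

    def test_relabeling_invariance(self):
        conn = block_connectivity((4, 4), r_within=0.8, r_between=0.1)
        d = 1 - conn.values
        np.fill_diagonal(d, 0)
        assert dunn_index_from_distances(
            d, [1, 1, 1, 1, 2, 2, 2, 2]
        ) == pytest.approx(
            dunn_index_from_distances(d, [2, 2, 2, 2, 1, 1, 1, 1])
        )

    def test_singleton_only_clustering_is_infinite(self):
        d = np.zeros((3, 3))
        assert dunn_index_from_distances(d, [1, 2, 3]) == math.inf

    def test_k_bounds(self):
        conn = block_connectivity((4, 4))
        with pytest.raises(errors.ParameterError):
            dunn_index(conn, k=1)
        with pytest.raises(errors.ParameterError):
            dunn_index(conn, k=9)


class TestComputeProfile:
    def test_fields_match_individual_operations(self):
        from dmnqol.connectivity import (
            ConnectivityConfig,
            binarize_graph,
            pearson_connectivity,
        )
        from dmnqol.synthetic import (
            SubnetworkSpec,
            gen_subject_timeseries,
            make_block_covariance,
        )

        ts = gen_subject_timeseries(
            make_block_covariance(SubnetworkSpec()), 220, seed=5
        )
        conn = pearson_connectivity(ts)
        g = binarize_graph(conn, ConnectivityConfig())
        profile = compute_profile(g, conn, n_null=20, k=3, seed=11)
        assert profile.global_clustering == global_clustering(g)
        assert profile.n_triangles == node_triangles(g).sum() / 3
        assert profile.mean_degree == node_degrees(g).mean()
        assert profile.entropy == degree_entropy(g)
        assert profile.complexity == complexity_index(g)
        assert profile.dunn_index == dunn_index(conn, k=3)
        assert profile.modularity == modularity_q(
            g, detect_partition(g, seed=11)
        )
        assert profile.small_worldness == small_worldness(
            g, random_null_ensemble(g, n_null=20, seed=11)
        )

    def test_deterministic_given_seed(self):
        from dmnqol.connectivity import binarize_graph, pearson_connectivity
        from dmnqol.synthetic import (
            SubnetworkSpec,
            gen_subject_timeseries,
            make_block_covariance,
        )

        ts = gen_subject_timeseries(
            make_block_covariance(SubnetworkSpec()), 220, seed=6
        )
        conn = pearson_connectivity(ts)
        g = binarize_graph(conn)
        p1 = compute_profile(g, conn, n_null=10, seed=3)
        p2 = compute_profile(g, conn, n_null=10, seed=3)
        assert p1.as_series().equals(p2.as_series())

    def test_three_block_structure_prefers_k3(self):
        """Dunn at k=3 beats k=2 on cohorts with three planted blocks."""
        from dmnqol.connectivity import pearson_connectivity
        from dmnqol.synthetic import (
            SubnetworkSpec,
            gen_subject_timeseries,
            make_block_covariance,
        )

        cov = make_block_covariance(
            SubnetworkSpec(r_within=0.6, r_between=0.05)
        )
        wins = 0
        for seed in range(20):
            conn = pearson_connectivity(
                gen_subject_timeseries(cov, 500, seed=seed)
            )
            wins += dunn_index(conn, k=3) > dunn_index(conn, k=2)
        assert wins >= 15
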