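"""Markov clustering: flow-matrix mechanics, partitions, oracle agreement."""

import itertools

import networkx as nx
import numpy as np
import pytest

from amsnet.mcl import (
    ClusterResult,
    MCLParams,
    add_self_loops,
    cluster_median_profiles,
    extract_clusters,
    mcl_cluster,
    mcl_iterate,
    normalize_columns,
    _inflate,
    _prune,
)
from amsnet.network import NetworkParams, build_network
from amsnet.records import VAS_COLUMNS, qc_filter
from amsnet.synthetic import simulate_dataset

from _reference_mcl import reference_mcl_partition
from conftest import make_record_frame, small_sim_config


def two_cliques_graph() -> nx.Graph:
    """Two 4-cliques (w=0.95 inside) joined by a single 0.95 bridge."""
    g = nx.Graph()
    for block in (range(4), range(4, 8)):
        for a, b in itertools.combinations(block, 2):
            g.add_edge(a, b, weight=0.95)
    g.add_edge(3, 4, weight=0.95)
    return g


def modularity_best_bipartition(g: nx.Graph):
    """Exhaustive weighted-modularity-optimal bipartition (independent oracle)."""
    nodes = sorted(g.nodes)
    best, best_q = None, -np.inf
    for mask in range(1, 2 ** (len(nodes) - 1)):
        left = {nodes[i] for i in range(len(nodes)) if mask >> i & 1}
        right = set(nodes) - left
        q = nx.community.modularity(g, [left, right], weight="weight")
        if q > best_q:
            best_q, best = q, (left, right)
    return {frozenset(s) for s in best}


def as_partition(result: ClusterResult) -> set[frozenset]:
    return {frozenset(c) for c in result.raw_clusters}


def random_weighted_graph(rng: np.random.Generator) -> nx.Graph:
    n = int(rng.integers(12, 100))
    p = float(rng.uniform(0.05, 0.25))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    for _, _, d in g.edges(data=True):
        d["weight"] = float(rng.uniform(0.5, 1.0))
    g.remove_nodes_from(list(nx.isolates(g)))
    return g


class TestFlowMatrix:
    def test_columns_stochastic_after_each_operator(self):
        rng = np.random.default_rng(0)
        m = normalize_columns(rng.uniform(0.0, 1.0, (30, 30)) + np.eye(30))
        for op in (lambda x: _inflate(x, 1.4), lambda x: _prune(x, 1e-4)):
            m = op(m)
            np.testing.assert_allclose(m.sum(axis=0), 1.0, atol=1e-9)

    def test_limit_matrix_stochastic_and_idempotent(self):
        g = two_cliques_graph()
        params = MCLParams(inflation=2.0, min_cluster_size=1)
        adj = nx.to_numpy_array(g, nodelist=sorted(g.nodes), weight="weight")
        limit, converged, _ = mcl_iterate(adj, params)
        assert converged
        np.testing.assert_allclose(limit.sum(axis=0), 1.0, atol=1e-9)
        # one more expansion+inflation step no longer moves the matrix
        again = _prune(
            _inflate(np.linalg.matrix_power(limit, 2), params.inflation),
            params.prune_below,
        )
        assert np.abs(again - limit).max() < params.tol

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError, match="isolated"):
            normalize_columns(np.array([[1.0, 0.0], [0.0, 0.0]]))

    def test_self_loop_schemes(self):
        adj = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert add_self_loops(adj, "unit")[0, 0] == 1.0
        assert add_self_loops(adj, "max_weight")[0, 0] == 0.5
        assert add_self_loops(adj, "none")[0, 0] == 0.0


class TestPartitions:
    def test_two_cliques_split_at_high_inflation(self):
        g = two_cliques_graph()
        result = mcl_cluster(g, MCLParams(inflation=2.0, min_cluster_size=1))
        partition = as_partition(result)
        assert partition == {frozenset(range(4)), frozenset(range(4, 8))}
        # agrees with the modularity-optimal bipartition oracle
        assert partition == modularity_best_bipartition(g)
        # and with the reference MCL transcription
        adj = nx.to_numpy_array(g, nodelist=sorted(g.nodes), weight="weight")
        assert set(reference_mcl_partition(adj, inflation=2.0)) == partition

    def test_complete_graph_is_one_cluster(self):
        g = nx.complete_graph(9)
        nx.set_edge_attributes(g, 1.0, "weight")
        result = mcl_cluster(g, MCLParams(inflation=1.4, min_cluster_size=1))
        assert as_partition(result) == {frozenset(range(9))}

    def test_clusters_never_span_disconnected_components(self):
        g = nx.union(nx.complete_graph(5), nx.complete_graph(4), rename=("a", "b"))
        nx.set_edge_attributes(g, 1.0, "weight")
        result = mcl_cluster(g, MCLParams(inflation=1.4, min_cluster_size=1))
        for cluster in result.raw_clusters:
            prefixes = {str(n)[0] for n in cluster}
            assert len(prefixes) == 1

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            mcl_cluster(nx.Graph(), MCLParams())

    def test_small_clusters_reported_unclustered_not_dropped(self):
        g = nx.union(nx.complete_graph(6), nx.complete_graph(3), rename=("a", "b"))
        nx.set_edge_attributes(g, 1.0, "weight")
        result = mcl_cluster(g, MCLParams(inflation=1.4, min_cluster_size=5))
        assert result.sizes == [6]
        assert result.n_unclustered == 3
        assert set(result.assignment) == set(g.nodes)  # accounting preserved

    def test_partition_independent_of_node_insertion_order(self):
        g1 = two_cliques_graph()
        g2 = nx.Graph()
        for a, b, d in reversed(list(g1.edges(data=True))):
            g2.add_edge(a, b, **d)
        p1 = as_partition(mcl_cluster(g1, MCLParams(inflation=2.0, min_cluster_size=1)))
        p2 = as_partition(mcl_cluster(g2, MCLParams(inflation=2.0, min_cluster_size=1)))
        assert p1 == p2


class TestOracleAgreement:
    def test_matches_reference_on_random_graphs(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(25):
            g = random_weighted_graph(rng)
            if g.number_of_nodes() < 5:
                continue
            nodes = sorted(g.nodes)
            adj = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
            for inflation in (1.4, 2.0):
                ours = mcl_cluster(g, MCLParams(inflation=inflation, min_cluster_size=1))
                mine = {frozenset(nodes.index(n) for n in c) for c in ours.raw_clusters}
                ref = set(reference_mcl_partition(adj, inflation=inflation))
                assert mine == ref, f"partition mismatch at inflation {inflation}"
            checked += 1
        assert checked >= 20

    def test_inflation_granularity_monotone_on_synthetic_networks(self):
        for seed in range(5):
            df = simulate_dataset(small_sim_config(seed=seed))
            passed = df[qc_filter(df)]
            g = build_network(passed, NetworkParams())
            counts = []
            for inflation in (1.2, 1.4, 2.0, 4.0):
                res = mcl_cluster(g, MCLParams(inflation=inflation, min_cluster_size=1))
                counts.append(len(res.raw_clusters))
            assert counts == sorted(counts), f"seed {seed}: {counts}"

    def test_pruning_threshold_immaterial_at_desk_scale(self):
        g = two_cliques_graph()
        with_prune = mcl_cluster(g, MCLParams(inflation=2.0, min_cluster_size=1))
        without = mcl_cluster(
            g, MCLParams(inflation=2.0, min_cluster_size=1, prune_below=0.0)
        )
        assert as_partition(with_prune) == as_partition(without)


class TestMedianProfiles:
    def test_single_member_cluster_returns_its_items(self):
        df = make_record_frame([dict(zip(VAS_COLUMNS, range(10, 80, 10)))])
        medians = cluster_median_profiles([[0]], df)
        assert list(medians.loc[0]) == list(range(10, 80, 10))

    def test_odd_count_takes_middle_value(self):
        rows = [dict(zip(VAS_COLUMNS, [v] * 7)) for v in (10, 20, 90)]
        medians = cluster_median_profiles([[0, 1, 2]], make_record_frame(rows))
        assert (medians.loc[0] == 20).all()

    def test_even_count_takes_midpoint(self):
        rows = [dict(zip(VAS_COLUMNS, [v] * 7)) for v in (10, 30)]
        medians = cluster_median_profiles([[0, 1]], make_record_frame(rows))
        assert (medians.loc[0] == 20).all()

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_median_profiles([[]], make_record_frame([{}]))

    def test_archetype_medians_recover_generator_means(self, small_dataset):
        passed = small_dataset[qc_filter(small_dataset)]
        g = build_network(passed, NetworkParams())
        result = mcl_cluster(g, MCLParams(min_cluster_size=10), records=passed)
        from amsnet.synthetic import default_archetypes

        by_name = {a.name: a for a in default_archetypes()}
        for cid, cluster in enumerate(result.clusters):
            label = passed.loc[cluster, "sim_component"].mode()[0]
            if label not in by_name:
                continue
            arch = by_name[label]
            medians = result.median_profiles.loc[cid].to_numpy()
            assert np.abs(medians - np.asarray(arch.item_means)).max() <= arch.item_sd
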