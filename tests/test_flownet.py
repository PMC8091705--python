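"""Flow network construction, max flow vs oracles, path decomposition, bootstrap."""

from itertools import product

import numpy as np
import pytest

from stableflow.flownet import (
    SINK,
    SOURCE,
    LDGraph,
    StablePath,
    bootstrap_null,
    build_ld_graph,
    decompose_paths,
    distinct_variants,
    extract_variant_groups,
    max_flow,
    to_flow_network,
)
from stableflow.io_formats import GenotypeMatrix, VariantKey
from stableflow.selection_stability import FoldSelection

from conftest import random_layered_graph, two_chain_graph, vk


# ---------------------------------------------------------------------------
# independent oracles

def enumerate_st_paths(g: LDGraph):
    """All source-to-sink chains of the layered graph as (variant, fold) tuples."""
    succ = {}
    for (v1, f1, _), (v2, f2, _) in g.edges:
        succ.setdefault((v1, f1), []).append((v2, f2))
    paths = []

    def extend(node, acc):
        acc = acc + [node]
        if node[1] == g.k:
            paths.append(tuple(acc))
            return
        for nxt in succ.get(node, []):
            extend(nxt, acc)

    for v in g.nodes.get(1, []):
        extend((v.id, 1), [])
    return paths


def exhaustive_max_disjoint_paths(g: LDGraph) -> int:
    """Maximum number of node-disjoint s-t paths by backtracking search."""
    paths = [frozenset(p) for p in enumerate_st_paths(g)]
    best = 0

    def search(i, used, count):
        nonlocal best
        best = max(best, count)
        if i == len(paths) or count + (len(paths) - i) <= best:
            return
        if not (paths[i] & used):
            search(i + 1, used | paths[i], count + 1)
        search(i + 1, used, count)

    search(0, frozenset(), 0)
    return best


def networkx_max_flow(g: LDGraph) -> int:
    """Independent max-flow value on the node-split network via networkx."""
    import networkx as nx

    G = nx.DiGraph()
    for fold, variants in g.nodes.items():
        for v in variants:
            G.add_edge((v.id, fold, "in"), (v.id, fold, "out"), capacity=1)
    for (v1, f1, _), (v2, f2, _) in g.edges:
        G.add_edge((v1, f1, "out"), (v2, f2, "in"), capacity=1)
    for v in g.nodes.get(1, []):
        G.add_edge("s", (v.id, 1, "in"), capacity=1)
    for v in g.nodes.get(g.k, []):
        G.add_edge((v.id, g.k, "out"), "t", capacity=1)
    if "s" not in G or "t" not in G:
        return 0
    return nx.maximum_flow_value(G, "s", "t")


# ---------------------------------------------------------------------------

class TestBuildLdGraph:
    @staticmethod
    def _matrix_and_folds():
        """Two correlated chr-1 columns, one far chr-1 column, one chr-2 copy."""
        rng = np.random.default_rng(1)
        base = rng.normal(size=80)
        values = np.column_stack(
            [base, base + rng.normal(0, 0.1, 80), rng.normal(size=80), base]
        )
        variants = [vk(1, 10), vk(1, 20), vk(1, 30), vk(2, 10)]
        labels = np.array(["case"] * 40 + ["control"] * 40, dtype=object)
        m = GenotypeMatrix(values, [f"s{i}" for i in range(80)], variants, labels,
                           encoding_mode="continuous")
        folds = [
            FoldSelection(1, {"1:10:A:T": 1.0, "2:10:A:T": 0.5}),
            FoldSelection(2, {"1:20:A:T": 1.0, "1:30:A:T": 0.2}),
            FoldSelection(3, {"1:20:A:T": 0.8}),
        ]
        return m, folds

    def test_identical_variant_linked_across_neighbouring_folds(self):
        m, folds = self._matrix_and_folds()
        g = build_ld_graph(folds, m, threshold=0.8)
        assert (("1:20:A:T", 2, "whole"), ("1:20:A:T", 3, "whole")) in g.edges

    def test_correlated_same_chromosome_pair_linked(self):
        m, folds = self._matrix_and_folds()
        g = build_ld_graph(folds, m, threshold=0.8)
        assert (("1:10:A:T", 1, "whole"), ("1:20:A:T", 2, "whole")) in g.edges

    def test_cross_chromosome_and_uncorrelated_pairs_not_linked(self):
        m, folds = self._matrix_and_folds()
        g = build_ld_graph(folds, m, threshold=0.8)
        froms = {(a, b) for (a, _, _), (b, _, _) in g.edges}
        assert ("2:10:A:T", "1:20:A:T") not in froms  # different chromosome
        assert ("1:10:A:T", "1:30:A:T") not in froms  # below threshold

    def test_non_neighbouring_folds_never_linked(self):
        m, folds = self._matrix_and_folds()
        g = build_ld_graph(folds, m, threshold=0.0)
        assert all(f2 == f1 + 1 for (_, f1, _), (_, f2, _) in g.edges)

    def test_empty_fold_gives_empty_layer(self):
        m, folds = self._matrix_and_folds()
        folds[1] = FoldSelection(2, {})
        g = build_ld_graph(folds, m, threshold=0.8)
        assert g.nodes[2] == []
        value, _ = max_flow(to_flow_network(g))
        assert value == 0


class TestToFlowNetwork:
    def test_node_count_is_2n_plus_2(self, fig6_graph):
        L = to_flow_network(fig6_graph)
        assert L.n_nodes == 2 * fig6_graph.n_nodes + 2

    def test_edge_categories(self, fig6_graph):
        t = to_flow_network(fig6_graph).edge_tallies()
        assert t == {"cross_fold": 8, "split": 10, "source": 2, "sink": 2}

    def test_empty_graph_is_source_and_sink_only(self):
        g = LDGraph(k=5, nodes={f: [] for f in range(1, 6)}, edges=[])
        L = to_flow_network(g)
        assert L.n_nodes == 2 and not L.capacity

    def test_single_chain_yields_single_path(self):
        g = two_chain_graph(k=5)
        # drop chromosome 2 entirely
        g = LDGraph(
            k=5,
            nodes={f: [v for v in vs if v.chromosome == "1"] for f, vs in g.nodes.items()},
            edges=[e for e in g.edges if e[0][0].startswith("1")],
        )
        value, L = max_flow(to_flow_network(g))
        assert value == 1
        assert len(decompose_paths(L)) == 1


class TestMaxFlow:
    def test_two_chain_network_has_flow_two(self, fig6_graph):
        value, _ = max_flow(to_flow_network(fig6_graph), traversal_seed=0)
        assert value == 2

    def test_no_cross_fold_edges_means_zero_flow(self):
        g = LDGraph(
            k=5,
            nodes={f: [vk(1, f)] for f in range(1, 6)},
            edges=[],
        )
        value, _ = max_flow(to_flow_network(g))
        assert value == 0

    def test_flow_value_matches_exhaustive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            g = random_layered_graph(rng, max_variant_nodes=12)
            value, _ = max_flow(to_flow_network(g), traversal_seed=int(rng.integers(1000)))
            assert value == exhaustive_max_disjoint_paths(g)

    def test_flow_value_matches_networkx_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            g = random_layered_graph(rng, max_variant_nodes=12)
            value, _ = max_flow(to_flow_network(g))
            assert value == networkx_max_flow(g)

    def test_value_invariant_to_traversal_seed_paths_deterministic(self):
        rng = np.random.default_rng(5)
        g = random_layered_graph(rng, max_variant_nodes=12)
        results = []
        for seed in range(6):
            value, L = max_flow(to_flow_network(g), traversal_seed=seed)
            paths = decompose_paths(L)
            results.append((value, [tuple(v.id for v in p.unique_variants) for p in paths]))
        values = {v for v, _ in results}
        assert len(values) == 1  # the flow VALUE never depends on the seed
        v0, p0 = results[0]
        value_again, L_again = max_flow(to_flow_network(g), traversal_seed=0)
        assert [tuple(v.id for v in p.unique_variants) for p in decompose_paths(L_again)] == p0

    def test_crossing_chains_need_residual_edges(self):
        """A graph where pure greedy forward search underestimates the flow.

        Fold-1 node A reaches both fold-2 nodes, but B only reaches one; a
        greedy path through A can block B unless the search can push flow
        back along residual edges.
        """
        a, b = vk(1, 1), vk(1, 2)
        c, d = vk(1, 3), vk(1, 4)
        g = LDGraph(
            k=2,
            nodes={1: [a, b], 2: [c, d]},
            edges=[
                ((a.id, 1, "whole"), (c.id, 2, "whole")),
                ((a.id, 1, "whole"), (d.id, 2, "whole")),
                ((b.id, 1, "whole"), (c.id, 2, "whole")),
            ],
        )
        for seed in range(10):
            value, _ = max_flow(to_flow_network(g), traversal_seed=seed)
            assert value == 2

    def test_flow_bounded_by_smallest_fold(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            g = random_layered_graph(rng, max_variant_nodes=12)
            value, _ = max_flow(to_flow_network(g))
            assert value <= min(len(vs) for vs in g.nodes.values())

    def test_adding_edge_never_decreases_flow(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            g = random_layered_graph(rng, max_variant_nodes=10)
            value, _ = max_flow(to_flow_network(g))
            # add one random feasible cross-fold edge
            candidates = [
                ((v1.id, f, "whole"), (v2.id, f + 1, "whole"))
                for f in range(1, g.k)
                for v1, v2 in product(g.nodes[f], g.nodes[f + 1])
                if v1.chromosome == v2.chromosome
            ]
            new = [e for e in candidates if e not in g.edges]
            if not new:
                continue
            g2 = LDGraph(k=g.k, nodes=g.nodes, edges=g.edges + [new[0]])
            value2, _ = max_flow(to_flow_network(g2))
            assert value2 >= value


class TestDecomposePaths:
    def test_path_count_equals_flow_value_and_disjoint(self, fig6_graph):
        value, L = max_flow(to_flow_network(fig6_graph), traversal_seed=1)
        paths = decompose_paths(L)
        assert len(paths) == value == 2
        in_nodes = [
            (fn.variant.id, fn.fold) for p in paths for fn in p.fold_nodes if fn.side == "in"
        ]
        assert len(in_nodes) == len(set(in_nodes))  # node-disjoint

    def test_unique_variant_bounds_and_dedup(self, fig6_graph):
        _, L = max_flow(to_flow_network(fig6_graph), traversal_seed=1)
        for p in decompose_paths(L):
            assert 1 <= len(p.unique_variants) <= 5
            ids = [v.id for v in p.unique_variants]
            assert len(ids) == len(set(ids))

    def test_same_variant_in_all_folds_dedups_to_one(self):
        v = vk(1, 7)
        g = LDGraph(
            k=5,
            nodes={f: [v] for f in range(1, 6)},
            edges=[((v.id, f, "whole"), (v.id, f + 1, "whole")) for f in range(1, 5)],
        )
        _, L = max_flow(to_flow_network(g))
        paths = decompose_paths(L)
        assert len(paths) == 1
        assert [u.id for u in paths[0].unique_variants] == [v.id]


class TestVariantGroups:
    def test_two_singleton_paths_two_groups(self):
        paths = [
            StablePath(fold_nodes=[], unique_variants=[vk(1, 1)]),
            StablePath(fold_nodes=[], unique_variants=[vk(2, 1)]),
        ]
        groups = extract_variant_groups(paths)
        assert len(groups) == 2
        assert len(distinct_variants(groups)) == 2

    def test_global_dedup_across_groups(self):
        a, b, c = vk(1, 1), vk(1, 2), vk(2, 1)
        paths = [
            StablePath(fold_nodes=[], unique_variants=[a, b]),
            StablePath(fold_nodes=[], unique_variants=[c, a]),
        ]
        groups = extract_variant_groups(paths)
        assert [g.variant_ids for g in groups] == [[a.id, b.id], [c.id, a.id]]
        assert {v.id for v in distinct_variants(groups)} == {a.id, b.id, c.id}

    def test_empty_paths_empty_groups(self):
        assert extract_variant_groups([]) == []


class TestBootstrapNull:
    @staticmethod
    def _pool(n_features=300, seed=0):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(60, n_features))
        chroms = rng.integers(1, 6, size=n_features)
        variants = [vk(c, i + 1) for i, c in enumerate(chroms)]
        labels = np.array(["case"] * 30 + ["control"] * 30, dtype=object)
        return GenotypeMatrix(values, [f"s{i}" for i in range(60)], variants, labels,
                              encoding_mode="continuous")

    def test_sparse_pool_yields_zero_flow(self):
        m = self._pool()
        res = bootstrap_null(m, [10] * 5, n_iter=20, threshold=0.8, seed=1)
        assert res.flow_values == [0] * 20
        assert res.mean_cross_fold_edges >= 0.0

    def test_zero_fold_sizes_zero_flow(self):
        m = self._pool()
        res = bootstrap_null(m, [0] * 5, n_iter=5, threshold=0.8, seed=2)
        assert res.flow_values == [0] * 5
        assert res.cross_fold_edge_counts == [0] * 5

    def test_deterministic_given_seed(self):
        m = self._pool()
        a = bootstrap_null(m, [15] * 5, n_iter=5, threshold=0.5, seed=3)
        b = bootstrap_null(m, [15] * 5, n_iter=5, threshold=0.5, seed=3)
        assert a.flow_values == b.flow_values
        assert a.cross_fold_edge_counts == b.cross_fold_edge_counts

    def test_oversized_fold_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_null(self._pool(), [1000] * 5, n_iter=1, seed=0)
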