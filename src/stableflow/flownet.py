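"""k-partite LD graph, node-split flow network, max flow, and stable paths.

The five per-fold variant selections are cast as layers of a k-partite
graph G: node (v, f) exists when variant v was selected in fold f, and an
edge joins (v1, f) -> (v2, f+1) when the two variants sit on the same
chromosome and are either identical or in LD (R^2 above the threshold).
Because edges only connect neighbouring folds within one chromosome, G
decomposes into per-chromosome disjoint subgraphs.

To count *node*-disjoint source-to-sink chains, each node is split into an
in-node and an out-node joined by a unit-capacity edge; a source feeds every
fold-1 in-node and every fold-k out-node drains into the sink, all edges at
capacity 1. Maximum flow on this network (unit-capacity Ford-Fulkerson with
full residual-edge semantics) then equals the maximum number of node-disjoint
paths, and each unit of flow decomposes into one stable variant group.

The augmenting-path search visits neighbours in a deterministic order
derived from a traversal seed, so the flow VALUE is seed-invariant while the
particular path set — like any Ford-Fulkerson tie-break — may vary with it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenotypeMatrix, VariantKey
from .ld import ld_pairs_within_chromosome
from .selection_stability import FoldSelection

logger = logging.getLogger(__name__)

SOURCE = ("__source__", 0, "s")
SINK = ("__sink__", -1, "t")

# node keys inside the network are tuples (variant_id, fold, side)
NodeKey = tuple[str, int, str]


@dataclass(frozen=True)
class FoldNode:
    """A variant occurrence in one fold layer of the graph."""

    variant: VariantKey
    fold: int
    side: str = "whole"  # "whole" in G; "in"/"out" in the flow network

    def key(self) -> NodeKey:
        return (self.variant.id, self.fold, self.side)


@dataclass
class LDGraph:
    """k-partite graph of per-fold selections joined by LD edges."""

    k: int
    nodes: dict[int, list[VariantKey]]  # fold -> variants selected there
    edges: list[tuple[NodeKey, NodeKey]]  # ((v1, f, whole), (v2, f+1, whole))

    @property
    def n_nodes(self) -> int:
        return sum(len(v) for v in self.nodes.values())

    @property
    def n_cross_fold_edges(self) -> int:
        return len(self.edges)

    def chromosomes(self) -> set[str]:
        return {v.chromosome for vs in self.nodes.values() for v in vs}


@dataclass
class FlowNetwork:
    """Node-split unit-capacity flow network with source and sink."""

    k: int
    variants: dict[str, VariantKey]
    adjacency: dict[NodeKey, list[NodeKey]]
    capacity: dict[tuple[NodeKey, NodeKey], int]
    flow: dict[tuple[NodeKey, NodeKey], int] = field(default_factory=dict)
    flow_value: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.adjacency)

    def edge_tallies(self) -> dict[str, int]:
        """Edges by category: cross-fold LD, in/out split, source, sink."""
        tallies = {"cross_fold": 0, "split": 0, "source": 0, "sink": 0}
        for u, v in self.capacity:
            if u == SOURCE:
                tallies["source"] += 1
            elif v == SINK:
                tallies["sink"] += 1
            elif u[0] == v[0] and u[1] == v[1]:
                tallies["split"] += 1
            else:
                tallies["cross_fold"] += 1
        return tallies


@dataclass
class StablePath:
    """One unit-flow source-to-sink path: a chain of fold-nodes, folds 1..k."""

    fold_nodes: list[FoldNode]
    unique_variants: list[VariantKey]


@dataclass
class VariantGroup:
    """The deduplicated variants of one stable path; one grouped feature."""

    group_id: str
    variants: list[VariantKey]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]


def build_ld_graph(
    folds: list[FoldSelection],
    m: GenotypeMatrix,
    threshold: float = 0.8,
    fold_order: list[int] | None = None,
) -> LDGraph:
    """Assemble the k-partite LD graph from per-fold selections.

    Layer f holds the variants selected in fold ``fold_order[f-1]`` (CV index
    order by default); an edge joins consecutive layers when the two variants
    share a chromosome and are identical or have R^2 strictly above the
    threshold. LD is evaluated on the samples of ``m`` — pass the training
    matrix to keep held-out samples out of the LD estimates.
    """
    by_fold = {fs.fold: fs for fs in folds}
    order = fold_order if fold_order is not None else sorted(by_fold)
    if sorted(order) != sorted(by_fold):
        raise ValueError(f"fold_order {order} is not a permutation of folds {sorted(by_fold)}")
    k = len(order)
    vindex = {vid: v for vid, v in zip(m.variant_ids, m.variants)}

    nodes: dict[int, list[VariantKey]] = {}
    for layer, f in enumerate(order, start=1):
        ids = sorted(by_fold[f].variant_ids)
        nodes[layer] = [vindex[vid] for vid in ids]
        if not ids:
            logger.warning("fold %d selected no variants; layer %d is empty", f, layer)

    edges: list[tuple[NodeKey, NodeKey]] = []
    for layer in range(1, k):
        a_ids = [v.id for v in nodes[layer]]
        b_ids = [v.id for v in nodes[layer + 1]]
        for cand in ld_pairs_within_chromosome(m, a_ids, b_ids, threshold):
            edges.append(
                ((cand.variant_a.id, layer, "whole"), (cand.variant_b.id, layer + 1, "whole"))
            )
    logger.info(
        "LD graph: %d nodes, %d cross-fold edges, %d chromosomes",
        sum(len(v) for v in nodes.values()),
        len(edges),
        len({v.chromosome for vs in nodes.values() for v in vs}),
    )
    return LDGraph(k=k, nodes=nodes, edges=edges)


def to_flow_network(g: LDGraph) -> FlowNetwork:
    """Node-split transformation: vertex capacities become unit edge capacities.

    Every graph node (v, f) becomes in/out nodes joined by one unit-capacity
    edge; every G edge becomes out(f) -> in(f+1); the source feeds fold-1
    in-nodes and fold-k out-nodes drain to the sink. Node count is 2|G| + 2.
    """
    adjacency: dict[NodeKey, list[NodeKey]] = {SOURCE: [], SINK: []}
    capacity: dict[tuple[NodeKey, NodeKey], int] = {}
    variants: dict[str, VariantKey] = {}

    def add_edge(u: NodeKey, v: NodeKey) -> None:
        adjacency.setdefault(u, []).append(v)
        adjacency.setdefault(v, [])
        capacity[(u, v)] = 1

    for fold, vs in g.nodes.items():
        for variant in vs:
            variants[variant.id] = variant
            add_edge((variant.id, fold, "in"), (variant.id, fold, "out"))
    for (v1, f1, _), (v2, f2, _) in g.edges:
        add_edge((v1, f1, "out"), (v2, f2, "in"))
    for variant in g.nodes.get(1, []):
        add_edge(SOURCE, (variant.id, 1, "in"))
    for variant in g.nodes.get(g.k, []):
        add_edge((variant.id, g.k, "out"), SINK)
    return FlowNetwork(k=g.k, variants=variants, adjacency=adjacency, capacity=capacity)


def max_flow(network: FlowNetwork, traversal_seed: int = 0) -> tuple[int, FlowNetwork]:
    """Ford-Fulkerson with residual edges on the unit-capacity network.

    Augmenting paths are found by depth-first search; at every node the
    neighbours are visited in an order fixed by ``traversal_seed`` (a seeded
    shuffle of the id-sorted neighbour lists). Each augmentation adds one
    unit, so the loop runs at most V times at O(E) per search. Returns the
    integer flow value and the network with its flow assignment filled in.
    """
    rng = np.random.default_rng(traversal_seed)
    residual: dict[NodeKey, dict[NodeKey, int]] = {u: {} for u in network.adjacency}
    for (u, v), c in network.capacity.items():
        residual[u][v] = c
        residual[v].setdefault(u, 0)

    order: dict[NodeKey, list[NodeKey]] = {}
    for u in network.adjacency:
        nbrs = sorted(residual[u])
        rng.shuffle(nbrs)
        order[u] = nbrs

    value = 0
    while True:
        path = _find_augmenting_path(residual, order)
        if path is None:
            break
        for u, v in zip(path, path[1:]):
            residual[u][v] -= 1
            residual[v][u] = residual[v].get(u, 0) + 1
        value += 1

    flow = {
        (u, v): c - residual[u][v] for (u, v), c in network.capacity.items() if residual[u][v] < c
    }
    network.flow = flow
    network.flow_value = value
    logger.info("maximum flow value %d (%d nodes)", value, network.n_nodes)
    return value, network


def _find_augmenting_path(
    residual: dict[NodeKey, dict[NodeKey, int]],
    order: dict[NodeKey, list[NodeKey]],
) -> list[NodeKey] | None:
    """Iterative DFS for a source-to-sink path with positive residual capacity."""
    parent: dict[NodeKey, NodeKey] = {SOURCE: SOURCE}
    stack = [SOURCE]
    while stack:
        u = stack.pop()
        if u == SINK:
            break
        # reversed so the first neighbour in `order` is explored first
        for v in reversed(order[u]):
            if v not in parent and residual[u].get(v, 0) > 0:
                parent[v] = u
                stack.append(v)
    if SINK not in parent:
        return None
    path = [SINK]
    while path[-1] != SOURCE:
        path.append(parent[path[-1]])
    return path[::-1]


def decompose_paths(network: FlowNetwork) -> list[StablePath]:
    """Split a maximum-flow assignment into its node-disjoint unit paths.

    Starting at the source, each unit of flow is traced forward along
    flow-carrying edges (consuming them) until the sink; the node split
    guarantees the traced paths share no fold-node. ``unique_variants``
    deduplicates repeated variants along a path in first-appearance order.
    """
    remaining = dict(network.flow)
    _check_conservation(network, remaining)
    out_edges: dict[NodeKey, list[NodeKey]] = {}
    for u, v in sorted(remaining):
        out_edges.setdefault(u, []).append(v)

    paths: list[StablePath] = []
    for _ in range(network.flow_value):
        node = SOURCE
        chain: list[FoldNode] = []
        while node != SINK:
            nxt = None
            for v in out_edges.get(node, []):
                if remaining.get((node, v), 0) > 0:
                    nxt = v
                    break
            if nxt is None:
                raise RuntimeError("flow assignment does not decompose into s-t paths")
            remaining[(node, nxt)] -= 1
            if nxt != SINK:
                vid, fold, side = nxt
                chain.append(FoldNode(variant=network.variants[vid], fold=fold, side=side))
            node = nxt
        uniq: list[VariantKey] = []
        for fn in chain:
            if fn.side == "in" and (not uniq or all(fn.variant.id != u.id for u in uniq)):
                uniq.append(fn.variant)
        if not 1 <= len(uniq) <= network.k:
            raise RuntimeError(f"path has {len(uniq)} unique variants, expected 1..{network.k}")
        paths.append(StablePath(fold_nodes=chain, unique_variants=uniq))
    return paths


def _check_conservation(network: FlowNetwork, flow: dict[tuple[NodeKey, NodeKey], int]) -> None:
    balance: dict[NodeKey, int] = {}
    for (u, v), f in flow.items():
        if f > network.capacity[(u, v)]:
            raise RuntimeError(f"flow exceeds capacity on edge {u} -> {v}")
        balance[u] = balance.get(u, 0) - f
        balance[v] = balance.get(v, 0) + f
    for node, b in balance.items():
        if node not in (SOURCE, SINK) and b != 0:
            raise RuntimeError(f"flow conservation violated at node {node}")


def extract_variant_groups(paths: list[StablePath]) -> list[VariantGroup]:
    """One grouped feature per path: the path's unique variants."""
    return [
        VariantGroup(group_id=f"G{i:03d}", variants=list(p.unique_variants))
        for i, p in enumerate(paths, start=1)
    ]


def distinct_variants(groups: list[VariantGroup]) -> list[VariantKey]:
    """Globally deduplicated variant list across all groups, order-stable."""
    seen: set[str] = set()
    out: list[VariantKey] = []
    for g in groups:
        for v in g.variants:
            if v.id not in seen:
                seen.add(v.id)
                out.append(v)
    return out


@dataclass
class BootstrapResult:
    flow_values: list[int]
    cross_fold_edge_counts: list[int]

    @property
    def mean_cross_fold_edges(self) -> float:
        return float(np.mean(self.cross_fold_edge_counts))

    @property
    def max_flow_observed(self) -> int:
        return max(self.flow_values)


def bootstrap_null(
    m: GenotypeMatrix,
    fold_sizes: list[int],
    n_iter: int = 100,
    threshold: float = 0.8,
    seed: int = 0,
) -> BootstrapResult:
    """Null distribution of the flow value under random variant selections.

    Each iteration draws ``len(fold_sizes)`` uniform random variant subsets
    (without replacement within a fold, matching the original fold sizes),
    casts them as fold selections, rebuilds the LD flow network and records
    its maximum flow and cross-fold edge count.
    """
    n = m.n_features
    for s in fold_sizes:
        if s > n:
            raise ValueError(f"fold size {s} exceeds feature count {n}")
    rng = np.random.default_rng(seed)
    vids = m.variant_ids
    flows: list[int] = []
    edge_counts: list[int] = []
    for it in range(n_iter):
        folds = [
            FoldSelection(
                fold=f,
                coefficients={vids[j]: 1.0 for j in rng.choice(n, size=size, replace=False)},
            )
            for f, size in enumerate(fold_sizes, start=1)
        ]
        g = build_ld_graph(folds, m, threshold)
        value, _ = max_flow(to_flow_network(g), traversal_seed=int(rng.integers(2**31)))
        flows.append(value)
        edge_counts.append(g.n_cross_fold_edges)
    logger.info(
        "bootstrap null: %d iterations, max flow observed %d, mean cross-fold edges %.2f",
        n_iter,
        max(flows) if flows else 0,
        float(np.mean(edge_counts)) if edge_counts else 0.0,
    )
    return BootstrapResult(flow_values=flows, cross_fold_edge_counts=edge_counts)
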