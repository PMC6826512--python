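"""Interaction-network structure and its relation to evolutionary rates.

The physical/genetic interaction graph of the gene set is analyzed as an
undirected simple graph (regulatory direction and sign are annotation
only).  Node importance is measured by closeness and by the leading
eigenvector of the adjacency matrix, optionally corrected by each gene's
genome-wide interaction count — ``log10(centrality * total_interactions)``
— because a node peripheral in this small functional subnetwork can still
be a hub of the full interactome.  Community structure is found by
greedy (Clauset-Newman-Moore) and Louvain modularity optimization, exact
modularity maximization, and edge-betweenness (Girvan-Newman) splitting;
rate homogeneity is then tested across every bipartition induced by a
single edge separating communities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import TestResult
from .stats import mann_whitney, kruskal_wallis, spearman

__all__ = [
    "InteractionGraph",
    "Partition",
    "BipartitionResult",
    "read_edge_list",
    "closeness_centrality",
    "eigen_centrality",
    "corrected_importance",
    "importance_vector",
    "modularity",
    "communities",
    "exact_modularity_partition",
    "bipartition_scan",
    "centrality_rate_tests",
    "module_rate_test",
]

log = logging.getLogger(__name__)

EXACT_MAX_NODES = 14

COMMUNITY_METHODS = ("fast_greedy", "louvain", "exact", "edge_betweenness")


class InteractionGraph:
    """Undirected simple gene-interaction graph with optional annotations.

    ``total_interactions`` is each gene's genome-wide interaction count in
    the full interactome (always at least its degree here); ``rate`` an
    optional substitution rate (subs/lineage/Ma).  Directed signed
    regulatory edges are stored as annotations and do not affect graph
    structure.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        total_interactions: Mapping[str, int] | None = None,
        rates: Mapping[str, float] | None = None,
        annotations: Sequence[dict] | None = None,
    ):
        g = nx.Graph()
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop at node {u!r}")
            g.add_edge(u, v)
        self.graph = g
        self.annotations = list(annotations or [])
        self.total_interactions: dict[str, int] = {}
        self.rates: dict[str, float] = {}
        if total_interactions:
            for node, k in total_interactions.items():
                self.set_total_interactions(node, k)
        if rates:
            for node, r in rates.items():
                self.set_rate(node, r)

    def set_total_interactions(self, node: str, k: int) -> None:
        if node not in self.graph:
            raise KeyError(f"unknown node {node!r}")
        if k < self.graph.degree(node):
            raise ValueError(
                f"{node}: genome-wide interaction count {k} below in-graph degree "
                f"{self.graph.degree(node)}"
            )
        self.total_interactions[node] = int(k)

    def set_rate(self, node: str, rate: float) -> None:
        if node not in self.graph:
            raise KeyError(f"unknown node {node!r}")
        if rate <= 0:
            raise ValueError(f"{node}: rate must be positive")
        self.rates[node] = float(rate)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def to_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for node, k in self.total_interactions.items():
            g.nodes[node]["total_interactions"] = k
        for node, r in self.rates.items():
            g.nodes[node]["rate"] = r
        nx.write_graphml(g, str(path))


def read_edge_list(
    edges_path: str | Path, attrs_path: str | Path | None = None
) -> InteractionGraph:
    """Build a graph from an edge-list TSV and optional node-attribute TSV.

    Edge columns: ``node_a``, ``node_b``, optional ``type`` (physical or
    genetic) and ``sign``; genetic rows are also kept as annotations.
    Attribute columns: ``gene``, optional ``total_interactions``, ``rate``.
    """
    df = pd.read_csv(edges_path, sep="\t", dtype=str, keep_default_na=False)
    if not {"node_a", "node_b"} <= set(df.columns):
        raise ValueError(f"{edges_path}: need node_a and node_b columns")
    edges = list(zip(df["node_a"], df["node_b"]))
    annotations = []
    if "type" in df.columns:
        for _, row in df.iterrows():
            if row.get("type") == "genetic":
                annotations.append(
                    {
                        "source": row["node_a"],
                        "target": row["node_b"],
                        "sign": row.get("sign", "") or None,
                    }
                )
    ig = InteractionGraph(edges, annotations=annotations)
    if attrs_path is not None:
        attrs = pd.read_csv(attrs_path, sep="\t", dtype=str, keep_default_na=False)
        for _, row in attrs.iterrows():
            gene = row["gene"]
            if gene not in ig.graph:
                continue
            if row.get("total_interactions", "") not in ("", "-"):
                ig.set_total_interactions(gene, int(float(row["total_interactions"])))
            if row.get("rate", "") not in ("", "-"):
                ig.set_rate(gene, float(row["rate"]))
    return ig


@dataclass(frozen=True)
class Partition:
    """Assignment of every node to exactly one community."""

    assignment: Mapping[str, int]
    method: str = "unspecified"

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities_as_sets(self) -> list[frozenset]:
        out: dict[int, set] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, set()).add(node)
        return [frozenset(s) for _, s in sorted(out.items())]

    @classmethod
    def from_sets(cls, sets: Iterable[Iterable[str]], method: str) -> "Partition":
        assignment = {}
        for c, nodes in enumerate(sorted((sorted(s) for s in sets))):
            for node in nodes:
                assignment[node] = c
        return cls(assignment, method)


def _require_connected(g: InteractionGraph) -> None:
    if not g.is_connected():
        raise ValueError("graph must be connected")


def closeness_centrality(g: InteractionGraph) -> dict[str, float]:
    """Closeness ``(n - 1) / sum of shortest-path distances``, in (0, 1]."""
    _require_connected(g)
    return {node: float(c) for node, c in nx.closeness_centrality(g.graph).items()}


def eigen_centrality(
    g: InteractionGraph, tol: float = 1e-10, max_iter: int = 10_000
) -> dict[str, float]:
    """Leading adjacency eigenvector by power iteration, max entry scaled to 1."""
    _require_connected(g)
    if g.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    nodes = g.nodes
    a = nx.to_numpy_array(g.graph, nodelist=nodes)
    # shift by +I: same Perron vector, but kills the +/-lambda oscillation
    # of bipartite adjacency spectra
    a = a + np.eye(len(nodes))
    v = np.ones(len(nodes))
    v /= np.linalg.norm(v)
    for _ in range(max_iter):
        w = a @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("power iteration collapsed (empty graph?)")
        w /= norm
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    else:
        raise RuntimeError(f"power iteration did not converge in {max_iter} iterations")
    v = np.abs(v)
    v /= v.max()
    return dict(zip(nodes, (float(x) for x in v)))


def corrected_importance(centrality: float, total_interactions: int) -> float:
    """``log10(centrality * total_interactions)`` — importance corrected by
    the gene's genome-wide interaction count."""
    if centrality <= 0:
        raise ValueError("centrality must be positive")
    if total_interactions < 1:
        raise ValueError("total_interactions must be at least 1")
    return math.log10(centrality * total_interactions)


def importance_vector(
    g: InteractionGraph, measure: str = "closeness", corrected: bool = False
) -> dict[str, float]:
    """Node importance by the chosen measure, optionally corrected."""
    if measure == "closeness":
        cent = closeness_centrality(g)
    elif measure in ("eigen", "eigen_centrality"):
        cent = eigen_centrality(g)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    if not corrected:
        return cent
    out = {}
    for node, c in cent.items():
        if node not in g.total_interactions:
            raise KeyError(f"{node}: no total_interactions count for correction")
        out[node] = corrected_importance(c, g.total_interactions[node])
    return out


def modularity(g: InteractionGraph, p: Partition) -> float:
    """Newman modularity Q on undirected unweighted edges."""
    missing = set(g.graph.nodes) - set(p.assignment)
    if missing:
        raise ValueError(f"partition misses nodes: {sorted(missing)}")
    m = g.n_edges
    if m == 0:
        return 0.0
    q = 0.0
    for comm in p.communities_as_sets():
        sub = g.graph.subgraph(comm)
        e_c = sub.number_of_edges()
        d_c = sum(g.graph.degree(v) for v in comm)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


# -- exact modularity maximization ---------------------------------------


def exact_modularity_partition(g: InteractionGraph, override_size: bool = False) -> Partition:
    """Globally Q-optimal partition by branch-and-bound over set partitions.

    Nodes are assigned one at a time (in sorted label order) to an
    existing block or a fresh one; a branch is pruned when an upper bound
    on its best achievable Q — remaining edges all counted as
    intra-community, degree penalties frozen at their partial values —
    cannot beat the incumbent.  Exponential in the worst case; refused
    above ``EXACT_MAX_NODES`` nodes unless ``override_size``.
    """
    n = g.n_nodes
    if n > EXACT_MAX_NODES and not override_size:
        raise ValueError(
            f"exact modularity limited to {EXACT_MAX_NODES} nodes (got {n}); "
            "use fast_greedy or louvain, or pass override_size=True"
        )
    nodes = g.nodes
    m = g.n_edges
    if m == 0:
        return Partition({v: 0 for v in nodes}, "exact")
    deg = {v: g.graph.degree(v) for v in nodes}
    adj = {v: set(g.graph.neighbors(v)) for v in nodes}

    # edges entirely among nodes[:k] for each prefix, to compute "remaining"
    prefix_edges = [0] * (n + 1)
    for k in range(1, n + 1):
        v = nodes[k - 1]
        prefix_edges[k] = prefix_edges[k - 1] + sum(
            1 for u in adj[v] if u in set(nodes[: k - 1])
        )

    best_q = -math.inf
    best_blocks: list[list[str]] | None = None
    blocks: list[list[str]] = []
    block_deg: list[int] = []
    block_intra: list[int] = []

    def recurse(k: int, intra: int, penalty: float) -> None:
        nonlocal best_q, best_blocks
        remaining = m - prefix_edges[k]
        bound = (intra + remaining) / m - penalty
        if bound <= best_q + 1e-12:
            return
        if k == n:
            q = intra / m - penalty
            if q > best_q:
                best_q = q
                best_blocks = [list(b) for b in blocks]
            return
        v = nodes[k]
        for b in range(len(blocks)):
            gain = sum(1 for u in blocks[b] if u in adj[v])
            old_deg = block_deg[b]
            new_penalty = (
                penalty
                - (old_deg / (2 * m)) ** 2
                + ((old_deg + deg[v]) / (2 * m)) ** 2
            )
            blocks[b].append(v)
            block_deg[b] += deg[v]
            recurse(k + 1, intra + gain, new_penalty)
            blocks[b].pop()
            block_deg[b] -= deg[v]
        # open a new block
        blocks.append([v])
        block_deg.append(deg[v])
        recurse(k + 1, intra, penalty + (deg[v] / (2 * m)) ** 2)
        blocks.pop()
        block_deg.pop()

    recurse(0, 0, 0.0)
    assert best_blocks is not None
    return Partition.from_sets(best_blocks, "exact")


def communities(
    g: InteractionGraph, method: str = "fast_greedy", seed: int | None = None
) -> Partition:
    """Detect communities by the chosen modularity strategy.

    ``fast_greedy`` (agglomerative max-dQ merging), ``louvain`` (seeded
    node sweeps), ``exact`` (branch-and-bound, small graphs only), and
    ``edge_betweenness`` (iterative removal of max-betweenness edges,
    cutting the dendrogram at the max-Q level).
    """
    _require_connected(g)
    if method == "fast_greedy":
        sets = nx.community.greedy_modularity_communities(g.graph)
        return Partition.from_sets(sets, method)
    if method == "louvain":
        sets = nx.community.louvain_communities(g.graph, seed=seed)
        return Partition.from_sets(sets, method)
    if method == "exact":
        return exact_modularity_partition(g)
    if method == "edge_betweenness":
        best = Partition({v: 0 for v in g.nodes}, method)
        best_q = modularity(g, best)
        for level in nx.community.girvan_newman(g.graph):
            p = Partition.from_sets(level, method)
            q = modularity(g, p)
            if q > best_q:
                best_q, best = q, p
        return best
    raise ValueError(f"unknown method {method!r}; choose from {COMMUNITY_METHODS}")


# -- bipartition scan ------------------------------------------------------


@dataclass(frozen=True)
class BipartitionResult:
    """Rate contrast across one community-separating cut edge."""

    cut_edge: tuple[str, str]
    side_a: tuple[str, ...]
    side_b: tuple[str, ...]
    result: TestResult


def bipartition_scan(
    g: InteractionGraph,
    p: Partition,
    rates: Mapping[str, float] | None = None,
) -> list[BipartitionResult]:
    """Test rate homogeneity across every community-separating cut edge.

    Communities are collapsed to a quotient graph; an inter-community
    edge qualifies as a cut when it is the only edge between its two
    communities and removing it disconnects the quotient.  Each qualifying
    cut splits the communities into two sides whose pooled node rates are
    compared with a Mann-Whitney test (nodes without rates are dropped;
    cuts leaving fewer than two rated nodes on a side are skipped).
    """
    if p.n_communities < 2:
        log.warning("partition has a single community; no cuts to scan")
        return []
    rates = dict(rates if rates is not None else g.rates)

    comm_sets = p.communities_as_sets()
    comm_of = {node: c for c, s in enumerate(comm_sets) for node in s}
    quotient = nx.MultiGraph()
    quotient.add_nodes_from(range(len(comm_sets)))
    originals: dict[tuple[int, int], list[tuple[str, str]]] = {}
    for u, v in g.graph.edges:
        cu, cv = comm_of[u], comm_of[v]
        if cu != cv:
            key = (min(cu, cv), max(cu, cv))
            quotient.add_edge(*key)
            originals.setdefault(key, []).append((u, v))

    simple = nx.Graph(quotient)
    bridges = set(frozenset(e) for e in nx.bridges(simple)) if simple.number_of_edges() else set()

    results: list[BipartitionResult] = []
    for key, edge_list in sorted(originals.items()):
        if len(edge_list) != 1:
            continue  # parallel inter-community edges: not a clean cut
        if frozenset(key) not in bridges:
            continue
        cut = nx.Graph(simple)
        cut.remove_edge(*key)
        comps = list(nx.connected_components(cut))
        side_of = {c: i for i, comp in enumerate(comps) for c in comp}
        side_nodes: list[list[str]] = [[], []]
        for node, c in comm_of.items():
            side_nodes[side_of[c]].append(node)
        # deterministic orientation: side containing the lexicographically
        # smaller cut endpoint first
        u0, v0 = edge_list[0]
        if comm_of[min(u0, v0)] not in comps[0]:
            side_nodes.reverse()
        pools = [
            sorted(n for n in side if n in rates) for side in side_nodes
        ]
        if min(len(pools[0]), len(pools[1])) < 2:
            log.warning("cut %s skipped: fewer than 2 rated nodes on a side", edge_list[0])
            continue
        res = mann_whitney(
            [rates[n] for n in pools[0]], [rates[n] for n in pools[1]]
        )
        results.append(
            BipartitionResult(
                cut_edge=edge_list[0],
                side_a=tuple(sorted(side_nodes[0])),
                side_b=tuple(sorted(side_nodes[1])),
                result=res,
            )
        )
    if not results:
        log.warning("no qualifying cut edge in partition")
    return results


def centrality_rate_tests(
    g: InteractionGraph,
    rates: Mapping[str, float] | None = None,
    measure: str = "closeness",
    corrected: bool = False,
) -> TestResult:
    """Spearman correlation between node importance and substitution rate.

    Restricted to nodes with rate data; at least three complete pairs are
    required.
    """
    rates = dict(rates if rates is not None else g.rates)
    imp = importance_vector(g, measure=measure, corrected=corrected)
    nodes = sorted(n for n in imp if n in rates)
    if len(nodes) < 3:
        raise ValueError(f"only {len(nodes)} nodes have both importance and rate")
    return spearman([imp[n] for n in nodes], [rates[n] for n in nodes])


def module_rate_test(
    g: InteractionGraph,
    p: Partition,
    rates: Mapping[str, float] | None = None,
    min_per_group: int = 2,
) -> TestResult:
    """Kruskal-Wallis test of rate homogeneity across partition modules.

    Modules with fewer than ``min_per_group`` rated nodes are pooled out
    of the comparison (dropped).
    """
    rates = dict(rates if rates is not None else g.rates)
    groups = []
    for comm in p.communities_as_sets():
        vals = [rates[n] for n in sorted(comm) if n in rates]
        if len(vals) >= min_per_group:
            groups.append(vals)
    if len(groups) < 2:
        raise ValueError("fewer than two modules with enough rated nodes")
    return kruskal_wallis(groups)
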