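"""Steiner-tree induction of a connected pathway module from target genes.

Differential target genes are mapped onto a signaling network; the mapped
nodes become *terminals*.  A minimal connected subgraph spanning the
terminals is approximated in the undirected view of the network with the
classic metric-closure (Kou–Markowsky–Berman) heuristic, which carries a
2·(1 − 1/|T|) approximation guarantee on the tree cost.  Non-terminal
nodes the tree introduces are *Steiner nodes*.  The final module is the
induced signed directed subnetwork on all tree nodes, annotated with the
terminals' fold-changes.

All tie-breaking is lexicographic on node names, so identical inputs give
identical modules on every platform.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .graph_core import (
    NetworkError,
    SignalingNetwork,
    induced_subgraph,
    normalize_gene,
    to_undirected,
)


@dataclass
class TerminalSet:
    """Targets split into network-mapped terminals and unmapped symbols."""

    terminals: set[str]
    unmapped: set[str]


@dataclass
class SteinerModule:
    """Connected pathway module: terminals + Steiner nodes + induced subnetwork.

    ``annotation`` holds each terminal's log2 fold-change (Steiner nodes map
    to ``None``); ``display_annotation`` additionally clamps values to
    [-2, +2] for plotting, leaving the raw values untouched.
    """

    terminals: set[str]
    steiner_nodes: set[str]
    tree_edges: set[frozenset]
    subnetwork: SignalingNetwork
    annotation: dict = field(default_factory=dict)
    display_annotation: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.terminals) + len(self.steiner_nodes)


def map_targets(net: SignalingNetwork, targets: Iterable[str]) -> TerminalSet:
    """Intersect target genes with network nodes (exact match on uppercased symbols)."""
    uniq = {normalize_gene(t) for t in targets}
    if not uniq:
        raise NetworkError("empty target list")
    terminals = uniq & net.nodes
    return TerminalSet(terminals=terminals, unmapped=uniq - terminals)


def _lex_shortest_path(g: nx.Graph, u: str, v: str) -> list[str]:
    """Lexicographically smallest shortest path from u to v (unit weights)."""
    dist_to_v = nx.single_source_shortest_path_length(g, v)
    if u not in dist_to_v:
        raise NetworkError(f"no path between {u} and {v}")
    path = [u]
    cur = u
    while cur != v:
        d = dist_to_v[cur]
        nxt = min(n for n in g.neighbors(cur) if dist_to_v.get(n, float("inf")) == d - 1)
        path.append(nxt)
        cur = nxt
    return path


def _mst_edges(g: nx.Graph) -> list[tuple[str, str]]:
    """Kruskal MST with deterministic tie-breaking (weight, then node names)."""
    edges = sorted(
        (g.edges[e].get("weight", 1), *sorted(e)) for e in g.edges
    )
    uf = nx.utils.UnionFind(g.nodes)
    out = []
    for _, a, b in edges:
        if uf[a] != uf[b]:
            uf.union(a, b)
            out.append((a, b))
    return out


def approx_steiner_tree(
    g: nx.Graph, terminals: Iterable[str]
) -> tuple[set[str], set[frozenset]]:
    """Metric-closure Steiner-tree heuristic on a unit-weight undirected graph.

    Steps: (1) complete graph on terminals weighted by BFS distance,
    (2) MST of that closure, (3) expand each closure edge to the
    lexicographically smallest shortest path, (4) MST of the expanded
    union, (5) prune non-terminal leaves.  Returns (tree nodes, tree edges
    as unordered pairs).
    """
    terms = sorted({normalize_gene(t) for t in terminals})
    if not terms:
        raise NetworkError("no terminals given")
    missing = [t for t in terms if t not in g]
    if missing:
        raise NetworkError(f"terminals absent from graph: {missing}")
    # connectivity check with a component partition in the error message
    comp_of = {}
    for i, comp in enumerate(nx.connected_components(g)):
        for n in comp:
            comp_of[n] = i
    by_comp: dict[int, list[str]] = {}
    for t in terms:
        by_comp.setdefault(comp_of[t], []).append(t)
    if len(by_comp) > 1:
        parts = "; ".join(str(sorted(v)) for v in by_comp.values())
        raise NetworkError(f"terminals span {len(by_comp)} components: {parts}")
    if len(terms) == 1:
        return {terms[0]}, set()

    dist = {t: nx.single_source_shortest_path_length(g, t) for t in terms}
    closure = nx.Graph()
    closure.add_nodes_from(terms)
    for a, b in itertools.combinations(terms, 2):
        closure.add_edge(a, b, weight=dist[a][b])

    union = nx.Graph()
    for a, b in _mst_edges(closure):
        path = _lex_shortest_path(g, *sorted((a, b)))
        nx.add_path(union, path)

    tree = nx.Graph()
    tree.add_nodes_from(union.nodes)
    tree.add_edges_from(_mst_edges(union))

    # prune non-terminal leaves until fixpoint
    term_set = set(terms)
    while True:
        leaves = [n for n in tree.nodes if tree.degree(n) <= 1 and n not in term_set]
        if not leaves:
            break
        tree.remove_nodes_from(leaves)

    return set(tree.nodes), {frozenset(e) for e in tree.edges}


def exact_steiner_tree(
    g: nx.Graph, terminals: Iterable[str], max_nodes: int = 16
) -> tuple[set[str], set[frozenset], int]:
    """Exact minimum-edge-count Steiner tree by Steiner-node-subset enumeration.

    Intended as a small-instance oracle; refuses graphs above ``max_nodes``.
    Returns (tree nodes, tree edges, cost in edges).
    """
    terms = sorted({normalize_gene(t) for t in terminals})
    if not terms:
        raise NetworkError("no terminals given")
    if g.number_of_nodes() > max_nodes:
        raise NetworkError(
            f"exact enumeration limited to {max_nodes} nodes, got {g.number_of_nodes()}"
        )
    nonterm = sorted(set(g.nodes) - set(terms))
    term_set = set(terms)
    for extra in range(len(nonterm) + 1):
        for combo in itertools.combinations(nonterm, extra):
            nodes = term_set | set(combo)
            sub = g.subgraph(nodes)
            if nx.is_connected(sub):
                span = nx.Graph()
                span.add_nodes_from(nodes)
                span.add_edges_from(_mst_edges(nx.Graph(sub.edges)))
                if extra == 0 and len(nodes) == 1:
                    return nodes, set(), 0
                return (
                    nodes,
                    {frozenset(e) for e in span.edges},
                    len(nodes) - 1,
                )
    raise NetworkError("terminals are not connected in the graph")


def build_module(
    net: SignalingNetwork,
    annotations: Mapping[str, float],
    clamp: float = 2.0,
) -> SteinerModule:
    """Full module induction: map targets, span them, induce the subnetwork.

    ``annotations`` maps target gene symbols to log2 fold-changes (the
    significant differential targets).  Terminals in different network
    components are spanned per component and the trees are unioned.
    """
    fc = {normalize_gene(k): float(v) for k, v in annotations.items()}
    tset = map_targets(net, list(fc))
    if not tset.terminals:
        raise NetworkError("no target gene maps onto the network")
    und = to_undirected(net)

    comp_of = {}
    for i, comp in enumerate(nx.connected_components(und)):
        for n in comp:
            comp_of[n] = i
    by_comp: dict[int, list[str]] = {}
    for t in sorted(tset.terminals):
        by_comp.setdefault(comp_of[t], []).append(t)

    tree_nodes: set[str] = set()
    tree_edges: set[frozenset] = set()
    for terms in by_comp.values():
        nodes, edges = approx_steiner_tree(und, terms)
        tree_nodes |= nodes
        tree_edges |= edges

    steiner = tree_nodes - tset.terminals
    sub = induced_subgraph(net, tree_nodes)
    annotation = {n: (fc[n] if n in tset.terminals else None) for n in tree_nodes}
    display = {
        n: (max(-clamp, min(clamp, v)) if v is not None else None)
        for n, v in annotation.items()
    }
    return SteinerModule(
        terminals=tset.terminals,
        steiner_nodes=steiner,
        tree_edges=tree_edges,
        subnetwork=sub,
        annotation=annotation,
        display_annotation=display,
    )


def write_module_tables(module: SteinerModule, node_path, edge_path) -> None:
    """Export node (gene, role, log2fc, clamped) and edge (source, relation, target) TSVs."""
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("gene\trole\tlog2fc\tlog2fc_clamped\n")
        for n in sorted(module.terminals | module.steiner_nodes):
            role = "terminal" if n in module.terminals else "steiner"
            raw = module.annotation.get(n)
            clamped = module.display_annotation.get(n)
            fh.write(
                f"{n}\t{role}\t{'NA' if raw is None else f'{raw:.6g}'}\t"
                f"{'NA' if clamped is None else f'{clamped:.6g}'}\n"
            )
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("source\trelation\ttarget\n")
        for e in sorted(module.subnetwork.edges, key=lambda e: (e.source, e.target)):
            fh.write(f"{e.source}\t{e.sign}\t{e.target}\n")
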