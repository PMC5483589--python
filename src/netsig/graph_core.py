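"""Signed directed signaling-network model and elementary graph operations.

A signaling network is a directed graph whose nodes are gene symbols and
whose edges carry a sign: ``activation`` or ``inhibition``.  Networks of
this kind (e.g. curated Wnt-pathway models) are exchanged as SIF-style
three-column text files.  All downstream analyses — target mapping,
Steiner-tree module induction, induced-subnetwork extraction — are built
on the small set of primitives defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

ACTIVATION = "activation"
INHIBITION = "inhibition"
_RELATIONS = frozenset({ACTIVATION, INHIBITION})


class NetworkError(ValueError):
    """Raised for malformed networks or network files."""


def normalize_gene(symbol: str) -> str:
    """Canonicalize a gene symbol: strip whitespace, uppercase.

    Raises :class:`NetworkError` for empty symbols or symbols containing
    internal whitespace.
    """
    s = str(symbol).strip().upper()
    if not s:
        raise NetworkError("empty gene symbol")
    if any(c.isspace() for c in s):
        raise NetworkError(f"gene symbol contains whitespace: {symbol!r}")
    return s


@dataclass(frozen=True)
class SignedEdge:
    """A directed signed interaction between two genes."""

    source: str
    target: str
    sign: str

    def __post_init__(self) -> None:
        if self.sign not in _RELATIONS:
            raise NetworkError(f"unknown relation {self.sign!r}")


@dataclass
class SignalingNetwork:
    """Signed directed gene graph.

    Invariants enforced on construction: every edge endpoint is a node, at
    most one edge per ordered (source, target) pair, at least one node,
    and no self-loops unless ``allow_self_loops`` was set.
    """

    nodes: set[str]
    edges: list[SignedEdge] = field(default_factory=list)
    name: str = ""

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, str]],
        extra_nodes: Iterable[str] = (),
        name: str = "",
        allow_self_loops: bool = False,
    ) -> "SignalingNetwork":
        """Build a network from (source, relation-sign, target) triples.

        Exactly duplicated triples are deduplicated; the same ordered pair
        with conflicting signs is rejected (silent overwrite would hide
        curation errors).
        """
        seen: dict[tuple[str, str], str] = {}
        out: list[SignedEdge] = []
        nodes: set[str] = {normalize_gene(n) for n in extra_nodes}
        for src, sign, dst in edges:
            s, t = normalize_gene(src), normalize_gene(dst)
            if sign not in _RELATIONS:
                raise NetworkError(f"unknown relation {sign!r}")
            if s == t and not allow_self_loops:
                raise NetworkError(f"self-loop on {s} (pass allow_self_loops=True to keep)")
            key = (s, t)
            if key in seen:
                if seen[key] != sign:
                    raise NetworkError(
                        f"conflicting signs for edge {s}->{t}: {seen[key]} vs {sign}"
                    )
                continue
            seen[key] = sign
            out.append(SignedEdge(s, t, sign))
            nodes.add(s)
            nodes.add(t)
        if not nodes:
            raise NetworkError("network must contain at least one node")
        return cls(nodes=nodes, edges=out, name=name)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph(name=self.name)
        g.add_nodes_from(sorted(self.nodes))
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalingNetwork):
            return NotImplemented
        return self.nodes == other.nodes and set(self.edges) == set(other.edges)


def read_sif(path: str | Path, allow_self_loops: bool = False) -> SignalingNetwork:
    """Read a signed network from a SIF-style TSV file.

    Each non-comment line is ``source<TAB>relation<TAB>target`` with
    relation in {activation, inhibition}.  Whitespace-separated files are
    accepted as well.  Lines starting with ``#`` are comments.
    """
    path = Path(path)
    triples: list[tuple[str, str, str]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise NetworkError(
                    f"{path}:{lineno}: expected 3 fields (source, relation, target), got {len(parts)}"
                )
            src, rel, dst = parts
            if rel not in _RELATIONS:
                raise NetworkError(f"{path}:{lineno}: unknown relation token {rel!r}")
            triples.append((src, rel, dst))
    if not triples:
        raise NetworkError(f"{path}: no edges found (network must have at least one node)")
    return SignalingNetwork.from_edges(triples, name=path.stem, allow_self_loops=allow_self_loops)


def write_sif(net: SignalingNetwork, path: str | Path) -> None:
    """Write a network as a SIF-style TSV (sorted for reproducible bytes)."""
    path = Path(path)
    lines = sorted((e.source, e.sign, e.target) for e in net.edges)
    with path.open("w", encoding="utf-8") as fh:
        for s, rel, t in lines:
            fh.write(f"{s}\t{rel}\t{t}\n")
        for n in sorted(net.nodes - {e.source for e in net.edges} - {e.target for e in net.edges}):
            # isolated nodes kept on a degenerate self-describing line is not
            # valid SIF; record them as comments so the round-trip is explicit
            fh.write(f"# isolated\t{n}\n")


def to_undirected(net: SignalingNetwork) -> nx.Graph:
    """Collapse to an undirected, unsigned, unit-weight graph.

    One undirected edge per unordered node pair with at least one directed
    edge in either orientation; the node set is preserved.
    """
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for e in net.edges:
        if e.source != e.target:
            g.add_edge(e.source, e.target)
    return g


def induced_subgraph(net: SignalingNetwork, keep: Iterable[str]) -> SignalingNetwork:
    """Subnetwork on ``keep`` with every original directed signed edge retained."""
    keep_set = {normalize_gene(k) for k in keep}
    missing = keep_set - net.nodes
    if missing:
        raise NetworkError(f"nodes not in network: {sorted(missing)}")
    edges = [e for e in net.edges if e.source in keep_set and e.target in keep_set]
    return SignalingNetwork(nodes=keep_set, edges=edges, name=net.name)


def shortest_path_lengths(
    g: nx.Graph, sources: Iterable[str]
) -> dict[str, Mapping[str, float]]:
    """Unit-weight BFS distances from each source to every node.

    Unreachable nodes get ``math.inf``.
    """
    sources = list(sources)
    missing = [s for s in sources if s not in g]
    if missing:
        raise NetworkError(f"sources not in graph: {sorted(missing)}")
    out: dict[str, Mapping[str, float]] = {}
    for s in sources:
        d = nx.single_source_shortest_path_length(g, s)
        out[s] = {n: float(d.get(n, math.inf)) for n in g.nodes}
    return out
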