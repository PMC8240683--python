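"""Weighted network container with a per-node on-disk neighbor store.

The network is an undirected, positively weighted graph (for protein
interaction data, nodes are proteins and weights are interaction-confidence
scores).  During candidate growth the algorithm only ever needs the neighbor
lists of the nodes currently in the subgraph, so the graph can also be
persisted as one small record per node and read back on demand; the
:class:`WeightedGraph` keeps an in-memory :class:`networkx.Graph` as the
working representation and the store is the durable, per-node-addressable
form of the same edge set.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "WeightedGraph",
    "Community",
    "NeighborMap",
    "load_edge_list",
    "write_node_store",
    "load_node_store",
    "induced_subgraph",
    "neighbor_map",
]

NodeId = str


class EdgeListParseError(ValueError):
    """Raised when an edge-list line cannot be parsed; carries the line number."""


@dataclass
class WeightedGraph:
    """Undirected weighted network.

    Invariants: no self-loops, all weights strictly positive, symmetric.
    ``storage_dir`` is set once the graph has been written to a node store.
    """

    g: nx.Graph
    storage_dir: Path | None = None

    @property
    def nodes(self) -> set[NodeId]:
        return set(self.g.nodes)

    @property
    def n(self) -> int:
        return self.g.number_of_nodes()

    @property
    def m(self) -> int:
        return self.g.number_of_edges()

    def edge(self, u: NodeId, v: NodeId) -> float:
        return float(self.g[u][v]["weight"])

    def has_edge(self, u: NodeId, v: NodeId) -> bool:
        return self.g.has_edge(u, v)

    def neighbors(self, u: NodeId) -> list[tuple[NodeId, float]]:
        """Neighbor record of ``u``: the same content as its store file."""
        return [(v, float(d["weight"])) for v, d in self.g.adj[u].items()]

    def edges(self) -> Iterable[tuple[NodeId, NodeId, float]]:
        for u, v, d in self.g.edges(data=True):
            yield u, v, float(d["weight"])


@dataclass
class Community:
    """A node set together with its induced-subgraph edge bookkeeping."""

    nodes: frozenset[NodeId]
    n_c: int
    m_c: int
    score: float | None = None
    label: str = "learned"  # positive | negative | learned

    def __post_init__(self) -> None:
        if self.n_c != len(self.nodes):
            raise ValueError("n_c must equal |nodes|")

    def key(self) -> tuple[NodeId, ...]:
        return tuple(sorted(self.nodes))


@dataclass
class NeighborMap:
    """Boundary of a subgraph: external neighbor -> (max weight, connecting edges).

    Keys are exactly the nodes adjacent to the subgraph that are not members;
    each value records the best single connecting edge weight plus the full
    list of (member, weight) connections, supporting O(1) lookup during
    growth.
    """

    entries: dict[NodeId, tuple[float, list[tuple[NodeId, float]]]] = field(
        default_factory=dict
    )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, node: NodeId) -> bool:
        return node in self.entries

    def max_weight(self, node: NodeId) -> float:
        return self.entries[node][0]

    def connecting_edges(self, node: NodeId) -> list[tuple[NodeId, float]]:
        return self.entries[node][1]

    def add_edge(self, neighbor: NodeId, member: NodeId, weight: float) -> None:
        if neighbor in self.entries:
            w, edges = self.entries[neighbor]
            edges.append((member, weight))
            if weight > w:
                self.entries[neighbor] = (weight, edges)
        else:
            self.entries[neighbor] = (weight, [(member, weight)])

    def remove(self, node: NodeId) -> None:
        self.entries.pop(node, None)


def load_edge_list(path: str | os.PathLike, weight_cutoff: float = 0.0) -> WeightedGraph:
    """Read a whitespace-separated ``node_a node_b weight`` edge list.

    Self-loops are dropped, duplicate undirected edges are collapsed keeping
    the maximum weight, and edges below ``weight_cutoff`` are removed.  A
    header line is skipped automatically when its third column is not
    numeric.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise EdgeListParseError(
                    f"line {lineno}: expected 3 columns, got {len(parts)}"
                )
            u, v = parts[0], parts[1]
            try:
                w = float(parts[2])
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise EdgeListParseError(
                    f"line {lineno}: weight {parts[2]!r} is not a number"
                ) from None
            if u == v:
                continue
            if w < weight_cutoff or w <= 0:
                continue
            if g.has_edge(u, v):
                if w > g[u][v]["weight"]:
                    g[u][v]["weight"] = w
            else:
                g.add_edge(u, v, weight=w)
    if g.number_of_edges() == 0:
        raise ValueError(f"no edges survive cutoff {weight_cutoff} in {path}")
    return WeightedGraph(g)


def graph_from_edges(edges: Iterable[tuple[NodeId, NodeId, float]]) -> WeightedGraph:
    """Build a WeightedGraph in memory, applying the same cleaning rules."""
    g = nx.Graph()
    for u, v, w in edges:
        if u == v or w <= 0:
            continue
        if g.has_edge(u, v):
            if w > g[u][v]["weight"]:
                g[u][v]["weight"] = w
        else:
            g.add_edge(u, v, weight=float(w))
    return WeightedGraph(g)


# --- node store -----------------------------------------------------------
#
# Layout: <dir>/index.tsv maps node id -> record file name (node ids may not
# be filesystem safe, so records are numbered); each record file holds
# "neighbor<TAB>weight" lines.


def write_node_store(graph: WeightedGraph, dir: str | os.PathLike) -> Path:
    """Persist the graph as one neighbor-list record per node.

    Reading every record back reconstructs the edge multiset exactly (each
    undirected edge appears in exactly two records).
    """
    store = Path(dir)
    store.mkdir(parents=True, exist_ok=True)
    index_lines = []
    for i, node in enumerate(sorted(graph.nodes)):
        fname = f"node_{i}.tsv"
        index_lines.append(f"{node}\t{fname}")
        with open(store / fname, "w") as fh:
            for v, w in sorted(graph.neighbors(node)):
                fh.write(f"{v}\t{w!r}\n")
    with open(store / "index.tsv", "w") as fh:
        fh.write("\n".join(index_lines) + "\n")
    graph.storage_dir = store
    return store


def read_node_record(store: str | os.PathLike, node: NodeId) -> list[tuple[NodeId, float]]:
    """Per-node lookup against the on-disk store."""
    store = Path(store)
    index = _read_index(store)
    if node not in index:
        raise KeyError(node)
    out = []
    with open(store / index[node]) as fh:
        for line in fh:
            v, w = line.rstrip("\n").split("\t")
            out.append((v, float(w)))
    return out


def _read_index(store: Path) -> dict[NodeId, str]:
    index: dict[NodeId, str] = {}
    with open(store / "index.tsv") as fh:
        for line in fh:
            if line.strip():
                node, fname = line.rstrip("\n").split("\t")
                index[node] = fname
    return index


def load_node_store(store: str | os.PathLike) -> WeightedGraph:
    """Rebuild the full graph from a node store directory."""
    store = Path(store)
    g = nx.Graph()
    for node, fname in _read_index(store).items():
        g.add_node(node)
        with open(store / fname) as fh:
            for line in fh:
                v, w = line.rstrip("\n").split("\t")
                g.add_edge(node, v, weight=float(w))
    return WeightedGraph(g, storage_dir=store)


# --- subgraph operations --------------------------------------------------


def induced_subgraph(
    graph: WeightedGraph, nodes: Iterable[NodeId], label: str = "learned"
) -> Community:
    """Community induced by ``nodes`` on the graph.

    Nodes absent from the network are silently dropped (they carry no edge
    information); an empty remainder is an error.
    """
    present = frozenset(n for n in nodes if n in graph.g)
    if not present:
        raise ValueError("no community nodes are present in the graph")
    m_c = graph.g.subgraph(present).number_of_edges()
    return Community(nodes=present, n_c=len(present), m_c=m_c, label=label)


def community_is_connected(graph: WeightedGraph, community: Community) -> bool:
    sub = graph.g.subgraph(community.nodes)
    return nx.is_connected(sub)


def neighbor_map(graph: WeightedGraph, community: Community | Iterable[NodeId]) -> NeighborMap:
    """Hash map of the subgraph's external boundary.

    For every node adjacent to the subgraph but outside it, records the
    maximum connecting edge weight and the list of connecting edges.
    """
    members = community.nodes if isinstance(community, Community) else frozenset(community)
    if not members:
        raise ValueError("community is empty")
    nm = NeighborMap()
    for u in members:
        for v, w in graph.neighbors(u):
            if v not in members:
                nm.add_edge(v, u, w)
    return nm


def extend_neighbor_map(
    graph: WeightedGraph,
    nm: NeighborMap,
    members: set[NodeId],
    added: NodeId,
) -> None:
    """Incrementally update ``nm`` after ``added`` joins ``members``.

    ``members`` must already contain ``added``.
    """
    nm.remove(added)
    for v, w in graph.neighbors(added):
        if v not in members:
            nm.add_edge(v, added, w)
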