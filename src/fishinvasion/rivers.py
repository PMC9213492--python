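"""River networks, migration barriers and along-network distances.

A river network is an undirected tree of confluence nodes with edge lengths in
km (real hydrography is acyclic above the estuary, and the synthetic generator
emits dendritic binary trees).  Positions on the network — barriers and
sampling sites alike — are given as an edge plus an offset from the edge's
first endpoint, so distances are measured along the wetted channel rather than
as the crow flies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

#: barrier categories in increasing order of passability impact
BARRIER_CATEGORIES = {1: "small jump", 2: "high jump", 3: "minor dam", 4: "major dam"}


@dataclass(frozen=True)
class NetworkPosition:
    """A point on the network: edge (u, v) at ``offset`` km from ``u``."""

    u: int
    v: int
    offset: float


@dataclass(frozen=True)
class Barrier:
    position: NetworkPosition
    category: int

    def __post_init__(self):
        if self.category not in BARRIER_CATEGORIES:
            raise ValueError(f"barrier category must be 1-4, got {self.category}")


class RiverNetwork:
    """Tree-shaped river network with km edge lengths."""

    def __init__(self, graph: nx.Graph):
        if graph.number_of_edges() and not nx.is_tree(graph):
            raise ValueError("river network must be a tree")
        self.graph = graph

    def edge_length(self, u: int, v: int) -> float:
        return self.graph.edges[u, v]["length"]

    def total_length(self) -> float:
        return sum(d["length"] for _, _, d in self.graph.edges(data=True))

    def validate_position(self, pos: NetworkPosition) -> None:
        if not self.graph.has_edge(pos.u, pos.v):
            raise ValueError(f"position edge ({pos.u}, {pos.v}) not on network")
        length = self.edge_length(pos.u, pos.v)
        if not 0 <= pos.offset <= length:
            raise ValueError(
                f"offset {pos.offset} outside edge length {length} for "
                f"({pos.u}, {pos.v})"
            )

    def distance(self, a: NetworkPosition, b: NetworkPosition) -> float:
        """Along-network distance between two positions (tree: unique path)."""
        self.validate_position(a)
        self.validate_position(b)
        same_edge = {a.u, a.v} == {b.u, b.v}
        if same_edge:
            ob = b.offset if (a.u, a.v) == (b.u, b.v) else self.edge_length(b.u, b.v) - b.offset
            return abs(a.offset - ob)
        la = self.edge_length(a.u, a.v)
        lb = self.edge_length(b.u, b.v)
        best = float("inf")
        for node_a, off_a in ((a.u, a.offset), (a.v, la - a.offset)):
            for node_b, off_b in ((b.u, b.offset), (b.v, lb - b.offset)):
                dn = nx.shortest_path_length(
                    self.graph, node_a, node_b, weight="length"
                )
                best = min(best, off_a + dn + off_b)
        return best

    def to_geojson(self, path: str | Path | None = None) -> dict:
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": [[u, 0], [v, 0]]},
                "properties": {"u": u, "v": v, "length": d["length"]},
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        doc = {"type": "FeatureCollection", "features": features}
        if path is not None:
            Path(path).write_text(json.dumps(doc))
        return doc


class BarrierSet:
    """Categorized barriers on a river network."""

    def __init__(self, network: RiverNetwork, barriers: Iterable[Barrier]):
        self.network = network
        self.barriers = list(barriers)
        for b in self.barriers:
            network.validate_position(b.position)

    def __len__(self) -> int:
        return len(self.barriers)

    def to_geojson(self, path: str | Path | None = None) -> dict:
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [b.position.u, b.position.offset]},
                "properties": {
                    "u": b.position.u,
                    "v": b.position.v,
                    "offset_km": b.position.offset,
                    "category": b.category,
                    "category_label": BARRIER_CATEGORIES[b.category],
                },
            }
            for b in self.barriers
        ]
        doc = {"type": "FeatureCollection", "features": features}
        if path is not None:
            Path(path).write_text(json.dumps(doc))
        return doc


def dendritic_network(depth: int, edge_lengths: Iterable[float]) -> RiverNetwork:
    """Binary dendritic tree of the given depth with declared edge lengths.

    Nodes are numbered heap-style (root 0, children of i are 2i+1, 2i+2);
    ``edge_lengths`` supplies one length per edge, parent-to-child in node
    order.
    """
    lengths = list(edge_lengths)
    g = nx.Graph()
    g.add_node(0)
    n_edges = 2 ** (depth + 1) - 2 if depth >= 0 else 0
    if len(lengths) < n_edges:
        raise ValueError(f"need {n_edges} edge lengths, got {len(lengths)}")
    idx = 0
    for parent in range(2**depth - 1):
        for child in (2 * parent + 1, 2 * parent + 2):
            g.add_edge(parent, child, length=float(lengths[idx]))
            idx += 1
    return RiverNetwork(g)
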