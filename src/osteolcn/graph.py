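"""Graph container for osteocyte networks.

Osteocytes are nodes; dendritic processes are the material of edges.  A
dendrite component that overlaps two osteocytes is an edge, one that overlaps
exactly one is a dead end (a blunted canaliculus), and one that overlaps none
is recorded as isolated.  The same container holds both planted ground-truth
topologies from the synthetic generator and graphs extracted from label masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["LcnNode", "LcnEdge", "DeadEnd", "LcnGraph"]


@dataclass
class LcnNode:
    id: int
    centroid: tuple[float, float]  # (row, col) in px
    area: float  # px^2


@dataclass
class LcnEdge:
    node_a: int
    node_b: int
    component_id: int
    length_um: float
    thickness_um: float
    #: rendered centreline (N, 2) float array for planted edges; not serialised
    path: np.ndarray | None = None


@dataclass
class DeadEnd:
    node_id: int
    component_id: int
    length_um: float = float("nan")


@dataclass
class IsolatedDendrite:
    component_id: int
    length_um: float = float("nan")


@dataclass
class LcnGraph:
    nodes: list[LcnNode] = field(default_factory=list)
    edges: list[LcnEdge] = field(default_factory=list)
    dead_ends: list[DeadEnd] = field(default_factory=list)
    isolated_dendrites: list[IsolatedDendrite] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def validate(self) -> None:
        ids = {n.id for n in self.nodes}
        if len(ids) != len(self.nodes):
            raise ValueError("duplicate node ids")
        for e in self.edges:
            if e.node_a not in ids or e.node_b not in ids:
                raise ValueError(f"edge endpoint missing: {e.node_a}-{e.node_b}")
        # a dendrite component may appear as several edges only through the
        # multi-overlap clique rule; across categories it appears exactly once
        edge_comps = {e.component_id for e in self.edges}
        dead_comps = {d.component_id for d in self.dead_ends}
        iso_comps = {i.component_id for i in self.isolated_dendrites}
        if (edge_comps & dead_comps) or (edge_comps & iso_comps) or (dead_comps & iso_comps):
            raise ValueError("a dendrite component is classified in two categories")

    def to_networkx(self) -> nx.MultiGraph:
        """Topology + scalar attributes as a MultiGraph (parallel dendrites kept)."""
        g = nx.MultiGraph()
        for n in self.nodes:
            g.add_node(n.id, row=float(n.centroid[0]), col=float(n.centroid[1]),
                       area=float(n.area))
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, component_id=int(e.component_id),
                       length_um=float(e.length_um), thickness_um=float(e.thickness_um))
        g.graph["dead_ends"] = [
            (int(d.node_id), int(d.component_id), float(d.length_um)) for d in self.dead_ends
        ]
        g.graph["isolated_dendrites"] = [
            (int(i.component_id), float(i.length_um)) for i in self.isolated_dendrites
        ]
        return g

    @classmethod
    def from_networkx(cls, g: nx.MultiGraph) -> "LcnGraph":
        nodes = [LcnNode(id=int(n), centroid=(d["row"], d["col"]), area=d["area"])
                 for n, d in g.nodes(data=True)]
        edges = [LcnEdge(node_a=int(a), node_b=int(b), component_id=int(d["component_id"]),
                         length_um=float(d["length_um"]), thickness_um=float(d["thickness_um"]))
                 for a, b, d in g.edges(data=True)]
        dead = [DeadEnd(node_id=n, component_id=c, length_um=l)
                for n, c, l in g.graph.get("dead_ends", [])]
        iso = [IsolatedDendrite(component_id=c, length_um=l)
               for c, l in g.graph.get("isolated_dendrites", [])]
        return cls(nodes=nodes, edges=edges, dead_ends=dead, isolated_dendrites=iso)
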