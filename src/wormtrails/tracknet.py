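"""Directed acyclic track network and the motif machinery used by all corrections.

A recording's short tracks become nodes of a DAG; an arc u→v asserts that
track v could have been produced by the same animal as track u, immediately
after it.  Arcs come from the upstream tracker's split/merge link records
and, later, from gap inference.  All correction operations (collision
untangling, pruning, consolidation) are graph rewrites on this structure,
and every rewrite must preserve acyclicity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .blob_io import BlobObservation, IntegrityError, LinkTable, TrackNode

__all__ = [
    "TrackGraph",
    "Motif",
    "MergeError",
    "build_graph",
    "find_sources_sinks",
    "find_split_rejoin_motifs",
    "merge_nodes",
]


class MergeError(ValueError):
    """A node contraction was refused (it would corrupt the graph)."""


@dataclass
class Motif:
    """A named subgraph pattern targeted by a correction operation."""

    kind: str  # "orphan" | "split_rejoin" | "collision_candidate"
    members: frozenset
    span: float
    parent: object = None
    intermediaries: tuple = ()
    child: object = None


@dataclass
class TrackGraph:
    """Mutable DAG of track nodes with provenance and a pruned-node side table.

    ``provenance`` maps each current node id to the set of original tracker
    node ids merged into it; together with ``pruned`` it partitions the
    original node universe at all times, which is what makes the
    blob-conservation audit possible.
    """

    nodes: dict = field(default_factory=dict)          # node_id -> TrackNode
    digraph: nx.DiGraph = field(default_factory=nx.DiGraph)
    provenance: dict = field(default_factory=dict)     # node_id -> frozenset
    pruned: dict = field(default_factory=dict)         # node_id -> TrackNode
    _counter: itertools.count = field(default_factory=lambda: itertools.count())

    # -- basic accessors ----------------------------------------------------

    def node(self, nid) -> TrackNode:
        return self.nodes[nid]

    def arcs(self) -> set:
        return set(self.digraph.edges())

    def parents(self, nid) -> list:
        return list(self.digraph.predecessors(nid))

    def children(self, nid) -> list:
        return list(self.digraph.successors(nid))

    def in_degree(self, nid) -> int:
        return self.digraph.in_degree(nid)

    def out_degree(self, nid) -> int:
        return self.digraph.out_degree(nid)

    def __len__(self) -> int:
        return len(self.nodes)

    def fresh_id(self, prefix: str) -> str:
        while True:
            nid = f"{prefix}{next(self._counter)}"
            if nid not in self.nodes and nid not in self.pruned:
                return nid

    # -- mutation -----------------------------------------------------------

    def add_node(self, node: TrackNode, provenance: frozenset | None = None) -> None:
        if node.node_id in self.nodes:
            raise IntegrityError(f"duplicate node id {node.node_id!r}")
        self.nodes[node.node_id] = node
        self.digraph.add_node(node.node_id)
        self.provenance[node.node_id] = (
            provenance if provenance is not None else frozenset([node.node_id])
        )

    def add_arc(self, u, v, inferred: bool = False) -> None:
        if u not in self.nodes or v not in self.nodes:
            raise IntegrityError(f"arc ({u!r},{v!r}) references unknown node")
        if u == v:
            raise IntegrityError(f"self-arc on {u!r}")
        self.digraph.add_edge(u, v, inferred=inferred)

    def remove_node(self, nid, prune: bool = False) -> None:
        node = self.nodes.pop(nid)
        self.digraph.remove_node(nid)
        if prune:
            self.pruned[nid] = node
        else:
            del self.provenance[nid]

    def inferred_arcs(self) -> set:
        return {(u, v) for u, v, d in self.digraph.edges(data=True) if d.get("inferred")}

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise IntegrityError on violation."""
        if not nx.is_directed_acyclic_graph(self.digraph):
            raise IntegrityError("track graph contains a cycle")
        for u, v in self.digraph.edges():
            nu, nv = self.nodes[u], self.nodes[v]
            if nu.start_frame > nv.start_frame or nu.end_frame > nv.end_frame:
                raise IntegrityError(
                    f"arc ({u!r},{v!r}) points backwards in time"
                )
        for nid in self.nodes:
            if nid not in self.provenance:
                raise IntegrityError(f"node {nid!r} missing provenance")


def build_graph(nodes: list, links: LinkTable) -> TrackGraph:
    """Build the track DAG: one node per track, one arc per tracker link.

    A cycle among the links indicates upstream corruption and is an error.
    """
    g = TrackGraph()
    for node in nodes:
        g.add_node(node)
    links.validate(g.nodes.keys())
    for parent, child in links.links:
        g.add_arc(parent, child)
    if not nx.is_directed_acyclic_graph(g.digraph):
        cyc = nx.find_cycle(g.digraph)
        raise IntegrityError(f"link table contains a cycle: {cyc}")
    return g


def find_sources_sinks(graph: TrackGraph) -> tuple[set, set]:
    """Nodes where identity begins (in-degree 0) or is lost (out-degree 0).

    Isolated nodes are both a source and a sink.
    """
    sources = {n for n in graph.nodes if graph.in_degree(n) == 0}
    sinks = {n for n in graph.nodes if graph.out_degree(n) == 0}
    return sources, sinks


def _motif_span(graph: TrackGraph, parent, inters, child, mode: str) -> float:
    if mode == "intermediaries":
        return (max(graph.node(i).end_time for i in inters)
                - min(graph.node(i).start_time for i in inters))
    if mode == "parent_child":
        return graph.node(child).end_time - graph.node(parent).start_time
    raise ValueError(f"unknown span mode {mode!r}")


def find_split_rejoin_motifs(graph: TrackGraph, max_span_s: float,
                             span_mode: str = "intermediaries") -> list:
    """Find split-rejoin motifs: one parent → ≥2 intermediaries → one child.

    This is the signature of a single animal segmented as multiple blobs
    whose tracks reconverge.  Requirements: every child of the parent is an
    intermediary with in-degree 1 and out-degree 1, all sharing one common
    child distinct from the parent; motif span (by default the window the
    intermediaries occupy) strictly below ``max_span_s``.  Overlapping
    motifs are resolved greedily in temporal order and the returned list is
    node-disjoint.
    """
    if max_span_s <= 0:
        raise ValueError("max_span_s must be positive")
    candidates = []
    for p in graph.nodes:
        inters = graph.children(p)
        if len(inters) < 2:
            continue
        if any(graph.in_degree(i) != 1 or graph.out_degree(i) != 1 for i in inters):
            continue
        child_sets = {graph.children(i)[0] for i in inters}
        if len(child_sets) != 1:
            continue
        c = child_sets.pop()
        if c == p or c in inters:
            continue
        span = _motif_span(graph, p, inters, c, span_mode)
        if span >= max_span_s:
            continue
        inters_sorted = tuple(sorted(inters, key=str))
        candidates.append(Motif(
            kind="split_rejoin",
            members=frozenset([p, c, *inters]),
            span=span,
            parent=p,
            intermediaries=inters_sorted,
            child=c,
        ))
    candidates.sort(key=lambda m: (graph.node(m.parent).start_time, str(m.parent)))
    used: set = set()
    chosen = []
    for m in candidates:
        if m.members & used:
            continue
        used |= m.members
        chosen.append(m)
    return chosen


def _combine_same_frame(blobs: list) -> BlobObservation:
    """Union same-frame fragments of one animal into a single observation."""
    if len(blobs) == 1:
        return blobs[0]
    mask = frozenset().union(*(b.mask for b in blobs))
    origin = frozenset().union(*(b.origin for b in blobs))
    if mask:
        cx = sum(p[0] for p in mask) / len(mask)
        cy = sum(p[1] for p in mask) / len(mask)
    else:  # mask-less data: fall back to area-unweighted centroid mean
        cx = sum(b.centroid[0] for b in blobs) / len(blobs)
        cy = sum(b.centroid[1] for b in blobs) / len(blobs)
    return BlobObservation(
        frame=blobs[0].frame,
        time=min(b.time for b in blobs),
        centroid=(cx, cy),
        mask=mask,
        origin=origin,
    )


def merge_nodes(graph: TrackGraph, ids: list) -> object:
    """Contract ``ids`` into one node; returns the merged node's id.

    Blobs are pooled and frame-sorted; same-frame duplicates (the two halves
    of a split animal) are combined by pixel-set union with the centroid
    recomputed as the union's pixel-mass centroid.  Arcs to/from the members
    are rewired to the merged node and provenance sets are unioned.  The
    contraction is refused with :class:`MergeError` if it would create a
    cycle or if the members are not weakly connected.
    """
    ids = list(dict.fromkeys(ids))
    if len(ids) < 2:
        raise MergeError("need at least two nodes to merge")
    missing = [i for i in ids if i not in graph.nodes]
    if missing:
        raise MergeError(f"unknown node(s) {missing!r}")
    sub = graph.digraph.subgraph(ids)
    if not nx.is_weakly_connected(sub):
        raise MergeError(f"nodes {ids!r} do not induce a connected subgraph")

    member_set = set(ids)
    preds = {p for i in ids for p in graph.parents(i)} - member_set
    succs = {s for i in ids for s in graph.children(i)} - member_set

    # cycle check on a contracted copy before mutating anything
    trial = graph.digraph.copy()
    merged_probe = object()
    trial.add_node(merged_probe)
    for p in preds:
        trial.add_edge(p, merged_probe)
    for s in succs:
        trial.add_edge(merged_probe, s)
    trial.remove_nodes_from(ids)
    if not nx.is_directed_acyclic_graph(trial):
        raise MergeError(f"contracting {ids!r} would create a cycle")

    by_frame: dict = {}
    for i in ids:
        for blob in graph.node(i).blobs:
            by_frame.setdefault(blob.frame, []).append(blob)
    blobs = [_combine_same_frame(by_frame[f]) for f in sorted(by_frame)]
    new_id = graph.fresh_id("m")
    merged = TrackNode(node_id=new_id, blobs=blobs)
    provenance = frozenset().union(*(graph.provenance[i] for i in ids))

    pred_inferred = {p: any(graph.digraph.edges[p, i].get("inferred")
                            for i in ids if graph.digraph.has_edge(p, i))
                     for p in preds}
    succ_inferred = {s: any(graph.digraph.edges[i, s].get("inferred")
                            for i in ids if graph.digraph.has_edge(i, s))
                     for s in succs}

    for i in ids:
        del graph.provenance[i]
        del graph.nodes[i]
        graph.digraph.remove_node(i)
    graph.add_node(merged, provenance=provenance)
    for p in preds:
        graph.add_arc(p, new_id, inferred=pred_inferred[p])
    for s in succs:
        graph.add_arc(new_id, s, inferred=succ_inferred[s])
    return new_id
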