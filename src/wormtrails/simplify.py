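"""The correction pipeline: untangle collisions, infer gaps, prune, consolidate.

Each pass applies the four heuristics in a fixed order — (i) collision
untangling, (ii) missing-arc inference, (iii) pruning of sub-second orphan
tracks, (iv) consolidation of split-rejoin motifs — and the full sequence is
repeated until a pass changes nothing (bounded by ``max_passes``).  The
simplified graph decomposes into chains, each of which becomes one per-animal
:class:`~wormtrails.blob_io.Trail`.

Defaults follow the field-standard tuning for adult C. elegans at 5 fps with
a ~50 px body: gaps are bridged only below 50 frames and 50 px (strict), the
connection minimising Δt×Δd wins, pruning removes parentless/childless
tracks under 1 s, consolidation absorbs motifs spanning under 3 s, and
collision votes need a 100-px overlap margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .blob_io import RecordingMeta, Trail
from .collide import untangle_collisions
from .tracknet import TrackGraph, find_split_rejoin_motifs, find_sources_sinks, merge_nodes

__all__ = [
    "SimplifyParams",
    "GapCandidate",
    "prune",
    "consolidate",
    "find_gap_candidates",
    "select_gap_arcs",
    "infer_gaps",
    "simplify_recording",
    "extract_trails",
    "coverage_stats",
    "blob_census",
]


@dataclass
class SimplifyParams:
    """All pipeline thresholds, with the standard defaults."""

    body_length_px: float = 50.0
    overlap_threshold: float = 100.0
    max_gap_frames: int = 50
    max_gap_px: float = 50.0
    prune_max_s: float = 1.0
    consolidate_max_s: float = 3.0
    max_passes: int = 10


@dataclass(frozen=True)
class GapCandidate:
    """A possible missing arc from a sink track to a later source track."""

    sink: object
    source: object
    dt_frames: int
    dd_px: float

    @property
    def score(self) -> float:
        return self.dt_frames * self.dd_px


def prune(graph: TrackGraph, max_duration_s: float = 1.0) -> int:
    """Remove parentless or childless tracks shorter than ``max_duration_s``.

    These are transient segmentation debris (a momentarily-seen fragment).
    Applied iteratively: removing a node can orphan its neighbour, which is
    then itself eligible.  Pruned nodes go to the graph's side table, never
    deleted outright.  Returns the number of nodes pruned.
    """
    if max_duration_s <= 0:
        raise ValueError("max_duration_s must be positive")
    n_removed = 0
    while True:
        removable = [
            nid for nid in graph.nodes
            if (graph.in_degree(nid) == 0 or graph.out_degree(nid) == 0)
            and graph.node(nid).duration < max_duration_s
        ]
        if not removable:
            return n_removed
        for nid in removable:
            graph.remove_node(nid, prune=True)
            n_removed += 1


def consolidate(graph: TrackGraph, max_span_s: float = 3.0,
                span_mode: str = "intermediaries") -> int:
    """Merge every split-rejoin motif spanning under ``max_span_s`` seconds.

    Repeats until no motif remains (a merge can create a new motif).
    Returns the number of motif merges performed.
    """
    n_merged = 0
    while True:
        motifs = find_split_rejoin_motifs(graph, max_span_s, span_mode=span_mode)
        if not motifs:
            return n_merged
        for m in motifs:
            merge_nodes(graph, [m.parent, *m.intermediaries, m.child])
            n_merged += 1


def find_gap_candidates(graph: TrackGraph, max_dt_frames: int,
                        max_dd_px: float) -> list:
    """Enumerate sink→source pairs with both gaps strictly inside the caps."""
    sources, sinks = find_sources_sinks(graph)
    candidates = []
    for s in sinks:
        ns = graph.node(s)
        for r in sources:
            if r == s:
                continue
            nr = graph.node(r)
            dt = nr.start_frame - ns.end_frame
            if not (0 < dt < max_dt_frames):
                continue
            dd = math.dist(ns.last_centroid, nr.first_centroid)
            if not (dd < max_dd_px):
                continue
            candidates.append(GapCandidate(sink=s, source=r, dt_frames=dt, dd_px=dd))
    return candidates


def select_gap_arcs(candidates: list) -> list:
    """Greedy ascending-score matching with one-in/one-out constraints.

    Candidates are taken in order of (Δt×Δd score, Δt, sink id, source id);
    each sink gains at most one inferred outgoing arc and each source at
    most one inferred incoming arc.  This is the global formalisation of
    the local rule "only the connection with the smallest Δt×Δd is
    selected", and equals the lexicographically-minimal maximal matching.
    """
    ordered = sorted(candidates,
                     key=lambda c: (c.score, c.dt_frames, str(c.sink), str(c.source)))
    used_sinks: set = set()
    used_sources: set = set()
    chosen = []
    for c in ordered:
        if c.sink in used_sinks or c.source in used_sources:
            continue
        used_sinks.add(c.sink)
        used_sources.add(c.source)
        chosen.append(c)
    return chosen


def infer_gaps(graph: TrackGraph, max_dt_frames: int = 50,
               max_dd_px: float = 50.0) -> int:
    """Add missing succession arcs across small tracking dropouts.

    An arc sink→source is inferred only when the time gap is under
    ``max_dt_frames`` frames and the distance gap under ``max_dd_px`` pixels
    (both strict), choosing the smallest Δt×Δd when several pairings
    compete.  Inferred arcs are marked as such.  Returns the number added.
    """
    chosen = select_gap_arcs(find_gap_candidates(graph, max_dt_frames, max_dd_px))
    for c in chosen:
        graph.add_arc(c.sink, c.source, inferred=True)
    return len(chosen)


@dataclass
class SimplifyReport:
    passes: list = field(default_factory=list)   # per-pass operation counts
    converged: bool = True
    audit: list = field(default_factory=list)    # collision audit entries

    @property
    def totals(self) -> dict:
        keys = ("collisions_resolved", "arcs_inferred", "pruned", "consolidated")
        return {k: sum(p[k] for p in self.passes) for k in keys}

    def to_dict(self) -> dict:
        return {"passes": self.passes, "totals": self.totals,
                "converged": self.converged, "audit": self.audit}


def simplify_recording(graph: TrackGraph,
                       params: SimplifyParams | None = None) -> tuple[TrackGraph, SimplifyReport]:
    """Run the full correction pipeline to a fixpoint.

    Phase order within a pass: collisions, gap inference, pruning,
    consolidation.  The sequence repeats until a pass applies zero
    operations or ``max_passes`` is reached (then ``report.converged`` is
    False; never an exception).
    """
    p = params or SimplifyParams()
    report = SimplifyReport()
    for _ in range(p.max_passes):
        n_coll, audit = untangle_collisions(graph, p.body_length_px, p.overlap_threshold)
        n_gaps = infer_gaps(graph, p.max_gap_frames, p.max_gap_px)
        n_pruned = prune(graph, p.prune_max_s)
        n_cons = consolidate(graph, p.consolidate_max_s)
        report.audit.extend(audit)
        counts = {
            "collisions_resolved": n_coll,
            "arcs_inferred": n_gaps,
            "pruned": n_pruned,
            "consolidated": n_cons,
        }
        report.passes.append(counts)
        if sum(counts.values()) == 0:
            return graph, report
    report.converged = False
    return graph, report


def extract_trails(graph: TrackGraph, meta: RecordingMeta) -> list:
    """Decompose the simplified graph into per-animal trails.

    An arc u→v belongs to a chain iff u has out-degree 1 and v in-degree 1;
    maximal chains become trails, so any remaining branching (an unresolved
    collision) terminates the trails meeting it and the branching node forms
    its own trail.  Coverage is the fraction of the recording's frames with
    an observation.
    """
    def chain_next(u):
        succ = graph.children(u)
        if len(succ) == 1 and graph.in_degree(succ[0]) == 1:
            return succ[0]
        return None

    def chain_prev(v):
        pred = graph.parents(v)
        if len(pred) == 1 and graph.out_degree(pred[0]) == 1:
            return pred[0]
        return None

    starts = [n for n in graph.nodes if chain_prev(n) is None]
    starts.sort(key=lambda n: (graph.node(n).start_frame, str(n)))
    total_frames = max(meta.n_frames, 1)
    trails = []
    seen: set = set()
    for idx, start in enumerate(starts):
        chain = [start]
        nxt = chain_next(start)
        while nxt is not None:
            chain.append(nxt)
            nxt = chain_next(nxt)
        seen.update(chain)
        blobs = [b for nid in chain for b in graph.node(nid).blobs]
        frames = {b.frame for b in blobs}
        trails.append(Trail(
            trail_id=f"t{idx}",
            node_ids=chain,
            blobs=blobs,
            coverage=min(1.0, len(frames) / total_frames),
        ))
    assert seen == set(graph.nodes)
    return trails


def coverage_stats(trails: list, meta: RecordingMeta,
                   thresholds: tuple = (0.5, 0.9, 0.99),
                   short_trail_s: float = 60.0) -> dict:
    """Coverage summary: fraction of trails above each coverage threshold,
    plus how many trails are shorter than the noise-filter duration (1 min)."""
    n = len(trails)
    out = {
        "n_trails": n,
        "fraction_above": {
            str(th): (sum(1 for t in trails if t.coverage > th) / n if n else 0.0)
            for th in thresholds
        },
        "n_shorter_than_filter": sum(1 for t in trails if t.duration < short_trail_s),
    }
    return out


def blob_census(items) -> set:
    """The set of (origin node id, frame) pairs covered by nodes or trails.

    Used for the conservation audit: after any amount of rewiring, the
    census of (extracted trails ∪ pruned side table) must equal the census
    of the raw input — no observation invented, none silently dropped.
    """
    census: set = set()
    for item in items:
        for blob in item.blobs:
            for o in blob.origin:
                census.add((o, blob.frame))
    return census
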