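"""Two-worm collision detection and identity untangling by pixel-overlap voting.

When two animals touch, the segmenter merges them into one blob until they
separate again, producing the five-node collision motif: two parent tracks
(a, b) feeding one merged track (c) feeding two child tracks (d, e).  The
animals carry no visual signature (real-time tracking stores no video), so
identity across the merge is decided purely from geometry: the pixel
overlap between each parent's last mask and each child's first mask.  The
pairing whose summed overlap wins by at least ``overlap_threshold`` pixels
(default 100) is accepted; anything closer is left unresolved rather than
guessed — accuracy comes from refusing ambiguous interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .blob_io import mask_overlap
from .tracknet import TrackGraph, TrackNode

__all__ = [
    "CollisionCase",
    "CollisionOutcome",
    "DECISION_STRAIGHT",
    "DECISION_CROSS",
    "UNRESOLVED",
    "flag_collision_candidates",
    "build_collision_case",
    "resolve_collision",
    "apply_resolution",
    "untangle_collisions",
]

DECISION_STRAIGHT = "a-d,b-e"   # parent a continues as child d, b as e
DECISION_CROSS = "a-e,b-d"      # parent a continues as child e, b as d
UNRESOLVED = "unresolved"


@dataclass
class CollisionCase:
    """One candidate two-worm collision: the motif plus its four overlaps."""

    collision_node: object
    pre_nodes: tuple       # (a, b)
    post_nodes: tuple      # (d, e)
    overlaps: dict         # {("a","d"): int, ("a","e"): int, ("b","d"): int, ("b","e"): int}
    missing_mask: bool = False

    @property
    def score_straight(self) -> int:
        return self.overlaps[("a", "d")] + self.overlaps[("b", "e")]

    @property
    def score_cross(self) -> int:
        return self.overlaps[("a", "e")] + self.overlaps[("b", "d")]


@dataclass
class CollisionOutcome:
    decision: str          # DECISION_STRAIGHT | DECISION_CROSS | UNRESOLVED
    score_1: int           # straight pairing a↔d & b↔e
    score_2: int           # crossed pairing a↔e & b↔d
    reason: str = ""

    def pairing(self, case: CollisionCase) -> dict | None:
        """Map pre-node id → post-node id for a resolved outcome."""
        a, b = case.pre_nodes
        d, e = case.post_nodes
        if self.decision == DECISION_STRAIGHT:
            return {a: d, b: e}
        if self.decision == DECISION_CROSS:
            return {a: e, b: d}
        return None


def _collision_shaped(graph: TrackGraph, nid) -> bool:
    return graph.in_degree(nid) >= 2 and graph.out_degree(nid) >= 2


def flag_collision_candidates(graph: TrackGraph, body_length_px: float) -> list:
    """Flag merged-blob nodes that look like real collisions.

    The motif (≥2 parents, ≥2 children) also arises from segmentation noise;
    genuine collisions are distinguished by motion: at least one neighbour
    track's travelled path (summed per-frame centroid displacement) exceeds
    one body length before or after contact.
    """
    if body_length_px <= 0:
        raise ValueError("body_length_px must be positive")
    flagged = []
    for nid in sorted(graph.nodes, key=lambda n: (graph.node(n).start_frame, str(n))):
        if not _collision_shaped(graph, nid):
            continue
        neighbours = graph.parents(nid) + graph.children(nid)
        if any(graph.node(m).path_length() > body_length_px for m in neighbours):
            flagged.append(nid)
    return flagged


def build_collision_case(graph: TrackGraph, collision_node) -> CollisionCase | None:
    """Assemble the overlap table for a strict two-in/two-out collision node.

    Returns None for wider events (≥3 parents or children): multi-worm
    pile-ups are never auto-resolved, only reported.
    """
    parents = sorted(graph.parents(collision_node), key=str)
    children = sorted(graph.children(collision_node), key=str)
    if len(parents) != 2 or len(children) != 2:
        return None
    a, b = parents
    d, e = children
    na, nb = graph.node(a), graph.node(b)
    nd, ne = graph.node(d), graph.node(e)
    missing = not (na.last_mask and nb.last_mask and nd.first_mask and ne.first_mask)
    overlaps = {
        ("a", "d"): mask_overlap(na.last_mask, nd.first_mask),
        ("a", "e"): mask_overlap(na.last_mask, ne.first_mask),
        ("b", "d"): mask_overlap(nb.last_mask, nd.first_mask),
        ("b", "e"): mask_overlap(nb.last_mask, ne.first_mask),
    }
    return CollisionCase(
        collision_node=collision_node,
        pre_nodes=(a, b),
        post_nodes=(d, e),
        overlaps=overlaps,
        missing_mask=missing,
    )


def resolve_collision(case: CollisionCase, overlap_threshold: float) -> CollisionOutcome:
    """Vote on the identity pairing by summed boundary-mask overlaps.

    A decision is made only when one pairing beats the other by at least
    ``overlap_threshold`` pixels; near-equal overlaps (worms partially
    trading places) stay unresolved by design.
    """
    s1, s2 = case.score_straight, case.score_cross
    if case.missing_mask:
        return CollisionOutcome(UNRESOLVED, s1, s2, reason="missing_mask")
    if s1 == s2 or abs(s1 - s2) < overlap_threshold:
        # a tie is never "better", whatever the threshold
        return CollisionOutcome(UNRESOLVED, s1, s2, reason="ambiguous_overlap")
    decision = DECISION_STRAIGHT if s1 > s2 else DECISION_CROSS
    return CollisionOutcome(decision, s1, s2)


def apply_resolution(graph: TrackGraph, case: CollisionCase,
                     outcome: CollisionOutcome) -> bool:
    """Rewire a resolved collision: split node c into two identity paths.

    The collision node is duplicated into c₁ on the a-path and c₂ on the
    b-path; both copies keep the merged-blob masks (the combined shape is
    the honest observation during contact) and provenance pointing at c.
    Returns True if the graph was changed.  On any structural risk (shared
    endpoints, a cycle appearing) the case is refused and left unresolved.
    """
    pairing = outcome.pairing(case)
    if pairing is None:
        return False
    a, b = case.pre_nodes
    d, e = case.post_nodes
    if len({a, b, d, e, case.collision_node}) != 5:
        outcome.decision = UNRESOLVED
        outcome.reason = "degenerate_motif"
        return False
    c = case.collision_node
    cnode = graph.node(c)
    c1 = graph.fresh_id("c")
    c2 = graph.fresh_id("c")
    prov = graph.provenance[c]
    graph.remove_node(c)
    graph.add_node(TrackNode(node_id=c1, blobs=list(cnode.blobs)), provenance=prov)
    graph.add_node(TrackNode(node_id=c2, blobs=list(cnode.blobs)), provenance=prov)
    graph.add_arc(a, c1)
    graph.add_arc(c1, pairing[a])
    graph.add_arc(b, c2)
    graph.add_arc(c2, pairing[b])
    if not nx.is_directed_acyclic_graph(graph.digraph):
        # roll back: restore c, drop the duplicates
        graph.remove_node(c1)
        graph.remove_node(c2)
        graph.add_node(cnode, provenance=prov)
        graph.add_arc(a, c)
        graph.add_arc(b, c)
        graph.add_arc(c, d)
        graph.add_arc(c, e)
        outcome.decision = UNRESOLVED
        outcome.reason = "cycle_risk"
        return False
    return True


def untangle_collisions(graph: TrackGraph, body_length_px: float,
                        overlap_threshold: float) -> tuple[int, list]:
    """Detect, vote on and rewire all two-worm collisions in the graph.

    Returns (number resolved, audit log).  Each audit entry records the
    motif, the four overlaps, both scores, the decision and — for use by
    ground-truth scoring — the (origin, frame) of every boundary blob.
    """
    audit = []
    n_resolved = 0
    for c in flag_collision_candidates(graph, body_length_px):
        if c not in graph.nodes:       # consumed by an earlier rewiring
            continue
        case = build_collision_case(graph, c)
        if case is None:
            audit.append({
                "collision_node": str(c),
                "origins": sorted(graph.provenance[c], key=str),
                "decision": UNRESOLVED,
                "reason": "multi_worm_event",
            })
            continue
        outcome = resolve_collision(case, overlap_threshold)
        entry = {
            "collision_node": str(c),
            "origins": sorted(graph.provenance[c], key=str),
            "pre_nodes": [str(n) for n in case.pre_nodes],
            "post_nodes": [str(n) for n in case.post_nodes],
            "overlaps": {f"{k[0]}-{k[1]}": v for k, v in case.overlaps.items()},
            "score_straight": outcome.score_1,
            "score_cross": outcome.score_2,
            "boundary": _boundary_provenance(graph, case),
        }
        if outcome.decision != UNRESOLVED and apply_resolution(graph, case, outcome):
            n_resolved += 1
        entry["decision"] = outcome.decision
        if outcome.reason:
            entry["reason"] = outcome.reason
        audit.append(entry)
    return n_resolved, audit


def _boundary_provenance(graph: TrackGraph, case: CollisionCase) -> dict:
    a, b = case.pre_nodes
    d, e = case.post_nodes
    out = {}
    for label, nid, end in (("a", a, True), ("b", b, True), ("d", d, False), ("e", e, False)):
        node = graph.node(nid)
        blob = node.blobs[-1] if end else node.blobs[0]
        out[label] = {"origin": sorted(blob.origin, key=str), "frame": blob.frame}
    return out
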