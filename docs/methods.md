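# Methods

## The track network

The atomic observation is a blob: a connected cluster of foreground pixels
segmented from one frame, with its centroid and full pixel mask.  The
upstream real-time tracker chains blobs into tracks and emits a new track id
whenever identity is lost; it also emits parent/child link records when a
blob visibly splits or merges.  `wormtrails` represents a recording as a
directed acyclic graph with one node per track and one arc per link; an arc
u → v asserts that v could continue u.  Acyclicity is an input contract
(links point forward in time); a cycle means upstream corruption and is
rejected at build time.  Every graph rewrite preserves two audit
structures: per-node *provenance* (the set of original tracker ids merged
into the node) and a *pruned* side table, so that at any point the original
id universe is exactly partitioned between live nodes and pruned nodes, and
every blob still carries the original id(s) it came from.  The invariant
checked in every end-to-end test is census conservation: the set of
(original id, frame) pairs covered by extracted trails plus the pruned
table equals that of the raw input.

Coordinates are 0-based pixels, x rightward, y downward; frames are
0-based; time = frame / fps.  fps is a required metadata field (default
recordings here use 5 fps, so 50 frames = 10 s) and is never inferred.

## Correction operations

Per pass, in fixed order — collisions, gap inference, pruning,
consolidation — repeated until a pass changes nothing (`max_passes` = 10
bounds the loop; non-convergence returns a flagged report, never an
exception).  Order matters when motifs overlap; within one operation,
overlapping motifs are taken greedily in temporal order (earliest parent
first), which is deterministic and auditable.

**Collision untangling.**  A candidate collision node has ≥2 parents and ≥2
children and at least one neighbour whose *travelled path* (summed
per-frame centroid displacement, not net displacement) exceeds one body
length (50 px): stationary clutter produces the same motif shape but not
that motion signature.  Only strict two-in/two-out cases are voted on;
events with three or more parents or children are reported and left alone.
The vote compares summed boundary-mask overlaps for the two possible
pairings and requires a winning margin of `overlap_threshold` = 100 px;
ties and sub-margin differences stay unresolved (the accuracy of this
method comes from refusing ambiguous interactions, and unresolved is a
first-class outcome).  The margin reading — |S₁−S₂| ≥ threshold — is the
only semantics under which "better by a given threshold" is well defined,
and 100 px is the standard operating value.  A resolved node is duplicated
onto the two identity paths; both copies keep the merged-blob masks, since
the combined shape is the honest observation during contact, and provenance
records both copies as views of the same original node.  On a DAG this
rewiring can never create a cycle (a new cycle through a duplicate would
require a pre-existing back path that would already have been cyclic); the
defensive check remains and refuses rather than corrupts.  Boundary
comparison uses exactly one blob on each side (window size 1); a window
parameter is left for exploration but is not the default.

**Gap inference.**  Candidates are sink → source pairs with
0 < Δt < 50 frames and Δd < 50 px, both strict (boundary values 50 are
rejected); Δt runs from the sink's last frame to the source's first frame
exclusive, Δd between last and first centroids.  Competing candidates are
ordered by (Δt×Δd, Δt, sink id, source id) and accepted greedily with at
most one inferred arc out of a sink and into a source.  This greedy rule is
the global formalisation of "the smallest Δt×Δd wins": it produces the
lexicographically minimal maximal matching, which the tests verify against
exhaustive enumeration.  (Total-sum-optimal assignment is a *different*
objective that can contradict the local rule; it is deliberately not used.)
Tie-breaks by ids make runs platform-independent.

**Pruning** removes parentless or childless nodes shorter than 1 s,
iterating because a removal can orphan a neighbour.  Pruned nodes are
retained in the side table for the conservation audit.

**Consolidation** merges the split-rejoin motif: a parent all of whose ≥2
children are intermediaries with in/out degree exactly 1 sharing one common
child.  The 3-s span cap is measured over the window the intermediaries
occupy (earliest intermediary start to latest intermediary end) — the
interval the error physically spans; a parent-start-to-child-end
alternative is available behind `span_mode`.  Same-frame blobs from two
fragments of one animal are combined by pixel-set union with the centroid
recomputed as the union's pixel-mass centroid.  Merging repeats until no
motif remains, because a merge can create a new motif.

**Trail extraction** walks maximal chains (arcs whose tail has out-degree 1
and head in-degree 1); any residual branching — an unresolved collision —
terminates the trails meeting it, and the branching node becomes its own
trail.  Coverage is the fraction of the recording's frames carrying an
observation.

## The simulator

The simulator emulates the tracker's output, not its imagery.  Worms
perform a persistent random walk (per-frame direction blend with
persistence 0.9, speed drawn per worm from N(3, 1) px/s clipped below at
0.5) inside a reflecting arena, emulating the physical frame that keeps
animals in the field of view.  Each worm is rendered as the last ~50 px of
its head path stamped with a 5-px-wide disk — the simplest body mask that
supports overlap voting; there is no undulation, posture dynamics or
intensity.  A model segmenter then emits blobs per frame: visible worms
whose masks touch within a 1-px dilation become one merged blob carrying
both identities (merged until the masks genuinely separate); a split event
(per-frame start probability `p_split` = 0.004, exponential duration with
mean 1.5 s) renders one worm as two fragments; a dropout
(`p_dropout` = 0.002, mean 2 s) hides a worm entirely.  A new node id is
issued at every discontinuity, with link records across visible splits and
merges and *no* link across dropouts — exactly the evidence a tracker
provides.  Rates were chosen once to match the observed order of magnitude
of tracker disruptions for adults on food (a few hundredths of an event per
worm-second) and are exposed, not tuned.  Identical parameters and seed
give byte-identical recordings.

Ground truth maps every (node, frame) to the set of true worm ids (merged
collision blobs map to both animals), and records dropout events with their
Δt/Δd.  Scoring counts: trails whose single-animal blobs come from more
than one worm (id switches, assessed outside honest collision frames);
trails that are majority collision blobs (collision trails); trails that
absorbed multi-animal blobs never flagged by the detector (undetected
collisions); the fraction of overlap-vote decisions matching the true
pairing; and dropout recovery (a dropout is recovered when one trail
contains both flanking tracks).

The collision benchmark steers two worms to cross near the arena centre
with randomised geometry: crossing angle 35–110°, lateral jitter ±8 px,
speeds uniform 3–6 px/s.  The angle range is kept transverse because as the
paths approach antiparallel each worm exits along the other's entry path —
the animals swap far sides, which is the place-trading interaction the vote
refuses by design; the benchmark measures accuracy on crossings *without*
side swaps, where the true pairing is unambiguous.  At the 100-px margin
roughly 70% of these cases are (correctly) left undecided; accuracy is
reported over the decided remainder.

What passing these tests does *not* show: real worms deform, collide by
pushing rather than passing through, and produce segmentation artefacts far
richer than two-fragment splits; absolute error rates on real recordings
will differ.  The simulator validates the *logic* of the corrections — that
each operation fixes exactly the disruption class it targets and nothing
else — not field performance.

## Motility analysis

Stitched trails keep observation gaps.  Gaps shorter than 1 s are filled by
linear interpolation (a worm's position is effectively constant on that
timescale); longer gaps are excluded from analysis, and smoothing windows
never cross them (each contiguous valid run is processed independently,
with centred windows that shrink at run ends — edge handling is a package
choice, stated here because it is not externally fixed).  Positions are
smoothed with a 1-s centred running mean to suppress centroid jitter; speed
is the central-difference displacement rate in px/s; speeds are smoothed
with a 1-min running mean because the target signal is slow activity
change.  Population profiles pool all valid samples per 1-min bin across
worms (sample-weighted), excluding trails shorter than 1 min (the standard
noise filter).  Activity classification counts minutes with smoothed speed
above `active_speed_threshold` within each observation window (defaults
0–30, 30–90, 90–180 min) and labels a worm active when that exceeds 5 min.
No external definition of "active movement" exists, so the default
threshold is a declared package choice: 0.02 body lengths/s = 1 px/s at a
50-px body, configurable.

## Numerical and degenerate-input choices

- Masks are exact integer pixel sets; overlap is exact set intersection.
- A mask-less boundary blob makes a collision case unresolved with reason
  `missing_mask`; equal vote scores are unresolved regardless of threshold.
- Single-frame tracks have duration 0 and are prunable when orphaned.
- Empty graphs, empty trails and all-invalid speed bins return empty/NaN
  results, never exceptions.
- Merged same-frame blobs with empty masks fall back to unweighted centroid
  means.
- All randomness flows from one integer seed through
  `numpy.random.default_rng`; file writers sort records so equal inputs
  give byte-identical files.

## Problem sizes used in the shipped checks

The shipped test suite runs the full pipeline on recordings of 2–10 worms
and 10–120 s at 5 fps, the oracle comparisons on 500 random instances each,
and the collision benchmark on 1,000 steered crossings (ten seeds); these
sizes exercise every code path at full fidelity while keeping the suite
quick on a single CPU.  All thresholds in the checks are the operating
defaults above, not quantities fitted to the tests.

## Known limitations

- Only two-worm collisions are resolved; three-or-more-worm events are
  reported and left unresolved (they are the residual error source).
- The heuristic pipeline is deliberately local and greedy; it does not
  attempt globally optimal track linking (e.g. min-cost flow), which is out
  of scope.
- Near-antiparallel pass-throughs are structurally undecidable for overlap
  voting and are excluded from the benchmark's decided-case condition.
- The simulator's bodies are rigid path-ribbons; posture-dependent effects
  (omega turns, coiling) are not modelled.
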