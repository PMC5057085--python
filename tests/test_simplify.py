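"""Pruning, consolidation, gap inference, the pipeline driver and trails."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wormtrails.blob_io import RecordingMeta
from wormtrails.simplify import (GapCandidate, SimplifyParams, blob_census,
                                 consolidate, coverage_stats, extract_trails,
                                 find_gap_candidates, infer_gaps, prune,
                                 select_gap_arcs, simplify_recording)

from conftest import FPS, graph_of, make_node


class TestPrune:
    def test_subsecond_isolated_node_removed(self):
        g = graph_of([make_node(1, 0, 3)])  # 0.4 s
        assert prune(g, 1.0) == 1
        assert not g.nodes and 1 in g.pruned

    def test_long_parentless_node_kept(self):
        g = graph_of([make_node(1, 0, 11)])  # 2.0 s
        assert prune(g, 1.0) == 0
        assert 1 in g.nodes

    def test_cascade_through_a_chain(self):
        # removing the parentless 0.4 s node orphans its 0.4 s child
        g = graph_of([make_node(1, 0, 3), make_node(2, 3, 3)], [(1, 2)])
        assert prune(g, 1.0) == 2
        assert not g.nodes and set(g.pruned) == {1, 2}

    def test_interior_nodes_are_protected(self):
        g = graph_of([make_node(1, 0, 11), make_node(2, 11, 2), make_node(3, 13, 11)],
                     [(1, 2), (2, 3)])
        assert prune(g, 1.0) == 0  # the short node has both parent and child

    def test_idempotent(self):
        g = graph_of([make_node(1, 0, 3), make_node(2, 10, 11)])
        prune(g, 1.0)
        assert prune(g, 1.0) == 0


class TestConsolidate:
    def test_motif_replaced_by_single_node(self):
        nodes = [make_node("p", 0, 5), make_node("i1", 5, 5), make_node("i2", 5, 5),
                 make_node("c", 10, 5)]
        g = graph_of(nodes, [("p", "i1"), ("p", "i2"), ("i1", "c"), ("i2", "c")])
        assert consolidate(g, 3.0) == 1
        assert len(g) == 1
        (nid,) = g.nodes
        assert g.provenance[nid] == frozenset({"p", "i1", "i2", "c"})

    def test_motif_above_span_cap_untouched(self):
        nodes = [make_node("p", 0, 5), make_node("i1", 5, 21), make_node("i2", 5, 21),
                 make_node("c", 26, 5)]  # interior span 4 s
        g = graph_of(nodes, [("p", "i1"), ("p", "i2"), ("i1", "c"), ("i2", "c")])
        assert consolidate(g, 3.0) == 0
        assert len(g) == 4

    def test_nested_motifs_merge_across_iterations(self):
        # the inner merge turns P -> {inner-chain, Y} -> C into an outer motif
        nodes = [make_node("P", 0, 3),
                 make_node("X1", 3, 2),
                 make_node("X2", 5, 2), make_node("X3", 5, 2),  # inner pair
                 make_node("X4", 7, 2),
                 make_node("Y", 3, 6),
                 make_node("C", 9, 3)]
        links = [("P", "X1"), ("X1", "X2"), ("X1", "X3"), ("X2", "X4"),
                 ("X3", "X4"), ("P", "Y"), ("X4", "C"), ("Y", "C")]
        g = graph_of(nodes, links)
        assert consolidate(g, 3.0) == 2
        assert len(g) == 1
        (nid,) = g.nodes
        assert g.provenance[nid] == frozenset("P X1 X2 X3 X4 Y C".split())

    def test_idempotent(self):
        nodes = [make_node("p", 0, 5), make_node("i1", 5, 5), make_node("i2", 5, 5),
                 make_node("c", 10, 5)]
        g = graph_of(nodes, [("p", "i1"), ("p", "i2"), ("i1", "c"), ("i2", "c")])
        consolidate(g, 3.0)
        assert consolidate(g, 3.0) == 0


def random_track_graph(rng, max_nodes=12, arc_p=0.25):
    k = int(rng.integers(3, max_nodes + 1))
    starts = np.sort(rng.integers(0, 40, size=k))
    nodes = [make_node(int(i), int(starts[i]), int(rng.integers(1, 12)))
             for i in range(k)]
    pairs = [(int(i), int(j)) for i in range(k) for j in range(i + 1, k)
             if rng.random() < arc_p]
    return nodes, pairs


class TestFixpointOracles:
    def test_prune_matches_exhaustive_rescan(self, rng):
        """Iterative pruning equals a naive re-scan-to-fixpoint oracle."""
        for _ in range(250):
            nodes, pairs = random_track_graph(rng)
            g = graph_of(nodes, pairs)
            durations = {n.node_id: n.duration for n in nodes}
            prune(g, 1.0)
            # oracle: recompute degrees from scratch each sweep
            alive = set(durations)
            changed = True
            while changed:
                changed = False
                for n in sorted(alive):
                    has_parent = any(v == n and u in alive for u, v in pairs)
                    has_child = any(u == n and v in alive for u, v in pairs)
                    if (not has_parent or not has_child) and durations[n] < 1.0:
                        alive.discard(n)
                        changed = True
                        break
            assert set(g.nodes) == alive

    def test_consolidate_matches_merge_to_fixpoint_oracle(self, rng):
        """Greedy consolidation equals exhaustive motif-merge-to-fixpoint on
        an independent adjacency-set representation."""
        for _ in range(250):
            nodes, pairs = random_track_graph(rng)
            g = graph_of(nodes, pairs)
            consolidate(g, 3.0)
            got = {frozenset(p) for p in g.provenance.values()}

            # oracle state: provenance groups with merged time extents
            groups = {i: frozenset([n.node_id]) for i, n in enumerate(nodes)}
            times = {i: (n.start_time, n.end_time) for i, n in enumerate(nodes)}
            arcs = {(i, j) for i, n in enumerate(nodes) for j, m in enumerate(nodes)
                    if (n.node_id, m.node_id) in pairs}
            while True:
                motif = None
                for p in sorted(times, key=lambda q: (times[q][0], q)):
                    inters = sorted(j for i, j in arcs if i == p)
                    if len(inters) < 2:
                        continue
                    if any(sum(1 for a in arcs if a[1] == i) != 1
                           or sum(1 for a in arcs if a[0] == i) != 1
                           for i in inters):
                        continue
                    cs = {b for a, b in arcs if a in inters}
                    if len(cs) != 1:
                        continue
                    c = cs.pop()
                    if c == p or c in inters:
                        continue
                    span = (max(times[i][1] for i in inters)
                            - min(times[i][0] for i in inters))
                    if span < 3.0:
                        motif = (p, inters, c)
                        break
                if motif is None:
                    break
                p, inters, c = motif
                members = [p, *inters, c]
                new = min(members)
                groups[new] = frozenset().union(*(groups[m] for m in members))
                times[new] = (min(times[m][0] for m in members),
                              max(times[m][1] for m in members))
                member_set = set(members)
                arcs = {(new if a in member_set else a, new if b in member_set else b)
                        for a, b in arcs}
                arcs = {(a, b) for a, b in arcs if a != b}
                for m in members:
                    if m != new:
                        groups.pop(m)
                        times.pop(m)
            assert got == set(groups.values())


class TestInferGaps:
    def sink_source(self, dt=10, dd=20.0):
        sink = make_node("s", 0, 201, start=(100.0 - 200 * 0.0, 100.0))
        source = make_node("r", 200 + dt, 50, start=(100.0 + dd, 100.0))
        return graph_of([sink, source])

    def test_gap_inside_both_caps_is_bridged(self):
        g = self.sink_source(dt=10, dd=20.0)
        assert infer_gaps(g) == 1
        assert g.inferred_arcs() == {("s", "r")}

    def test_distance_beyond_body_length_never_bridged(self):
        g = self.sink_source(dt=10, dd=60.0)
        assert infer_gaps(g) == 0

    @pytest.mark.parametrize("dt,dd,expect", [
        (49, 49.0, 1), (50, 49.0, 0), (51, 49.0, 0),
        (49, 50.0, 0), (49, 51.0, 0), (50, 50.0, 0),
    ])
    def test_strict_boundary_at_both_caps(self, dt, dd, expect):
        g = self.sink_source(dt=dt, dd=dd)
        assert infer_gaps(g, max_dt_frames=50, max_dd_px=50.0) == expect

    def test_smallest_score_wins_when_sink_has_options(self):
        sink = make_node("s", 0, 201, start=(100.0, 100.0))
        far = make_node("r1", 210, 50, start=(120.0, 100.0))   # score 10*20=200
        near = make_node("r2", 203, 50, start=(130.0, 100.0))  # score 3*30=90
        g = graph_of([sink, far, near])
        infer_gaps(g)
        assert g.inferred_arcs() == {("s", "r2")}

    def test_one_in_one_out_constraint(self):
        s1 = make_node("s1", 0, 201, start=(100.0, 100.0))   # score 10*20 = 200
        s2 = make_node("s2", 0, 201, start=(104.0, 100.0))   # score 10*16 = 160
        r = make_node("r", 210, 50, start=(120.0, 100.0))
        g = graph_of([s1, s2, r])
        assert infer_gaps(g) == 1  # the source accepts only its best sink
        assert g.inferred_arcs() == {("s2", "r")}

    def test_idempotent(self):
        g = self.sink_source()
        infer_gaps(g)
        assert infer_gaps(g) == 0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_caps_and_no_temporal_overlap_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 9))
        nodes = [make_node(int(i), int(rng.integers(0, 120)), int(rng.integers(1, 40)),
                           start=(float(rng.uniform(0, 200)), float(rng.uniform(0, 200))))
                 for i in range(k)]
        try:
            g = graph_of(nodes)
        except Exception:
            return
        infer_gaps(g)
        for u, v in g.inferred_arcs():
            nu, nv = g.node(u), g.node(v)
            dt = nv.start_frame - nu.end_frame
            dd = np.hypot(nu.last_centroid[0] - nv.first_centroid[0],
                          nu.last_centroid[1] - nv.first_centroid[1])
            assert 0 < dt < 50 and dd < 50

    def test_greedy_equals_bruteforce_lexmin_matching(self, rng):
        """Greedy selection equals the lexicographically-minimal maximal
        matching found by exhaustive subset enumeration (unique optima)."""
        checked = 0
        while checked < 500:
            n_sinks = int(rng.integers(1, 7))
            n_sources = int(rng.integers(1, 7))
            cands = [GapCandidate(sink=f"s{i}", source=f"r{j}",
                                  dt_frames=int(rng.integers(1, 50)),
                                  dd_px=float(rng.uniform(0.1, 50.0)))
                     for i in range(n_sinks) for j in range(n_sources)
                     if rng.random() < 0.35]
            if not cands or len(cands) > 9:
                continue
            key = lambda c: (c.score, c.dt_frames, str(c.sink), str(c.source))
            best_sig, best_sets = None, []
            for r in range(len(cands) + 1):
                for combo in itertools.combinations(cands, r):
                    sinks = [c.sink for c in combo]
                    sources = [c.source for c in combo]
                    if len(set(sinks)) < len(sinks) or len(set(sources)) < len(sources):
                        continue
                    maximal = all(c in combo or c.sink in sinks or c.source in sources
                                  for c in cands)
                    if not maximal:
                        continue
                    sig = tuple(sorted(key(c) for c in combo))
                    if best_sig is None or sig < best_sig:
                        best_sig, best_sets = sig, [set(combo)]
                    elif sig == best_sig:
                        best_sets.append(set(combo))
            if len(best_sets) != 1:
                continue
            checked += 1
            assert set(select_gap_arcs(cands)) == best_sets[0]


class TestPipelineDriver:
    def test_already_simplified_graph_is_a_fixpoint(self):
        g = graph_of([make_node(1, 0, 100)])
        g2, report = simplify_recording(g)
        assert len(report.passes) == 1
        assert report.totals == {"collisions_resolved": 0, "arcs_inferred": 0,
                                 "pruned": 0, "consolidated": 0}

    def test_one_instance_of_each_disruption_class(self):
        nodes = [
            # collision cluster near the origin
            make_node("a", 0, 11, start=(0, 0), step=(8.0, 0.0), mask_side=20),
            make_node("b", 0, 11, start=(0, 100), step=(2.0, 0.0), mask_side=20),
            make_node("c", 11, 10, start=(90, 50), mask_side=20),
            make_node("d", 21, 11, start=(80, 0), step=(2.0, 0.0), mask_side=20),
            make_node("e", 21, 11, start=(20, 100), step=(2.0, 0.0), mask_side=20),
            # dropout pair at (300, 300)
            make_node("g1", 0, 201, start=(300.0, 300.0)),
            make_node("g2", 210, 60, start=(320.0, 300.0)),
            # sub-second isolated fragment
            make_node("x", 50, 3, start=(500.0, 100.0)),
            # split-rejoin motif at (600, 600)
            make_node("p", 0, 11, start=(600.0, 600.0)),
            make_node("i1", 11, 5, start=(600.0, 600.0)),
            make_node("i2", 11, 5, start=(610.0, 600.0)),
            make_node("q", 16, 11, start=(600.0, 600.0)),
        ]
        links = [("a", "c"), ("b", "c"), ("c", "d"), ("c", "e"),
                 ("p", "i1"), ("p", "i2"), ("i1", "q"), ("i2", "q")]
        g = graph_of(nodes, links)
        census_before = blob_census(g.nodes.values())
        g2, report = simplify_recording(g)
        assert report.converged
        assert report.passes[0] == {"collisions_resolved": 1, "arcs_inferred": 1,
                                    "pruned": 1, "consolidated": 1}
        # conservation: trails + pruned cover exactly the input observations
        meta = RecordingMeta(fps=FPS, image_width=1000, image_height=1000,
                             duration=54.0)
        trails = extract_trails(g2, meta)
        census_after = blob_census(trails) | blob_census(g2.pruned.values())
        assert census_after == census_before


class TestTrails:
    def test_single_full_length_node_covers_recording(self):
        meta = RecordingMeta(fps=FPS, image_width=100, image_height=100, duration=20.0)
        g = graph_of([make_node(1, 0, 100)])
        trails = extract_trails(g, meta)
        assert len(trails) == 1 and trails[0].coverage == 1.0

    def test_unresolved_collision_node_forms_its_own_trail(self):
        nodes = [make_node("a", 0, 3), make_node("b", 0, 3), make_node("c", 3, 3),
                 make_node("d", 6, 3), make_node("e", 6, 3)]
        g = graph_of(nodes, [("a", "c"), ("b", "c"), ("c", "d"), ("c", "e")])
        meta = RecordingMeta(fps=FPS, image_width=100, image_height=100, duration=2.0)
        trails = extract_trails(g, meta)
        assert len(trails) == 5
        assert {tuple(t.node_ids) for t in trails} == {("a",), ("b",), ("c",),
                                                       ("d",), ("e",)}

    def test_empty_graph_gives_no_trails(self):
        meta = RecordingMeta(fps=FPS, image_width=100, image_height=100, duration=2.0)
        assert extract_trails(graph_of([]), meta) == []

    def test_chain_becomes_one_trail(self):
        meta = RecordingMeta(fps=FPS, image_width=100, image_height=100, duration=4.0)
        g = graph_of([make_node(1, 0, 10), make_node(2, 10, 10)], [(1, 2)])
        trails = extract_trails(g, meta)
        assert len(trails) == 1
        assert trails[0].node_ids == [1, 2]
        assert trails[0].coverage == 1.0


class TestCoverageStats:
    def _trail(self, coverage, duration_s):
        from wormtrails.blob_io import Trail, BlobObservation
        n = max(2, int(duration_s * FPS))
        blobs = [BlobObservation(frame=i, time=i / FPS, centroid=(0, 0))
                 for i in range(n)]
        return Trail(trail_id="t", node_ids=[], blobs=blobs, coverage=coverage)

    def test_full_coverage_trail_clears_every_threshold(self, meta):
        stats = coverage_stats([self._trail(1.0, 100.0)], meta)
        assert all(v == 1.0 for v in stats["fraction_above"].values())

    def test_mixed_coverages(self, meta):
        trails = [self._trail(0.95, 100.0), self._trail(0.3, 100.0)]
        stats = coverage_stats(trails, meta)
        assert stats["fraction_above"]["0.9"] == 0.5

    def test_short_trail_counter_uses_one_minute_filter(self, meta):
        trails = [self._trail(0.5, 30.0), self._trail(0.5, 90.0)]
        stats = coverage_stats(trails, meta)
        assert stats["n_shorter_than_filter"] == 1
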