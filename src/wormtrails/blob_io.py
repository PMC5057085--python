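"""Data model and I/O for fragmented multi-worm tracker output.

The upstream real-time tracker segments each video frame into "blobs"
(connected clusters of foreground pixels) and chains them into short
"tracks", emitting a new track id whenever identity is lost.  This module
defines the in-memory containers for that data — :class:`BlobObservation`,
:class:`TrackNode`, :class:`LinkTable`, :class:`RecordingMeta` — and a
canonical JSON-lines dialect for reading and writing whole recordings.

Conventions (enforced everywhere): pixel coordinates are 0-based integers,
x rightward, y downward; frames are 0-based; times are seconds from the
start of the recording.  Pixel masks are explicit coordinate sets so that
the collision-resolution primitive, :func:`mask_overlap`, is an exact set
intersection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "BlobObservation",
    "TrackNode",
    "LinkTable",
    "RecordingMeta",
    "Trail",
    "ParseError",
    "IntegrityError",
    "mask_overlap",
    "read_recording",
    "write_recording",
    "write_trails",
    "read_trails",
    "decode_rle_mask",
    "encode_rle_mask",
]

Pixel = tuple[int, int]
Mask = frozenset  # frozenset[Pixel]


class ParseError(ValueError):
    """A line of a recording file could not be parsed."""


class IntegrityError(ValueError):
    """A recording violates a structural invariant (ordering, unknown ids...)."""


@dataclass(frozen=True)
class BlobObservation:
    """One segmented object at one frame.

    ``origin`` records the original tracker node id(s) this observation came
    from; it is preserved through every graph operation so that stitched
    output can always be audited against the raw input (and, for synthetic
    data, against ground truth).
    """

    frame: int
    time: float
    centroid: tuple[float, float]
    mask: Mask = frozenset()
    origin: frozenset = frozenset()

    @property
    def area(self) -> int:
        return len(self.mask)


@dataclass
class TrackNode:
    """A time-ordered run of blob observations sharing one tracker id."""

    node_id: object
    blobs: list  # list[BlobObservation], strictly frame-ordered

    def __post_init__(self) -> None:
        if not self.blobs:
            raise IntegrityError(f"node {self.node_id!r}: empty blob sequence")
        for a, b in zip(self.blobs, self.blobs[1:]):
            if b.frame <= a.frame:
                raise IntegrityError(
                    f"node {self.node_id!r}: frames not strictly increasing "
                    f"({a.frame} then {b.frame})"
                )
            if b.time <= a.time:
                raise IntegrityError(
                    f"node {self.node_id!r}: times not strictly increasing at frame {b.frame}"
                )

    @property
    def start_frame(self) -> int:
        return self.blobs[0].frame

    @property
    def end_frame(self) -> int:
        return self.blobs[-1].frame

    @property
    def start_time(self) -> float:
        return self.blobs[0].time

    @property
    def end_time(self) -> float:
        return self.blobs[-1].time

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    @property
    def first_centroid(self) -> tuple[float, float]:
        return self.blobs[0].centroid

    @property
    def last_centroid(self) -> tuple[float, float]:
        return self.blobs[-1].centroid

    @property
    def first_mask(self) -> Mask:
        return self.blobs[0].mask

    @property
    def last_mask(self) -> Mask:
        return self.blobs[-1].mask

    @property
    def origins(self) -> frozenset:
        out: set = set()
        for b in self.blobs:
            out |= b.origin
        return frozenset(out)

    def path_length(self) -> float:
        """Summed per-frame centroid displacement (travelled path, not net)."""
        total = 0.0
        for a, b in zip(self.blobs, self.blobs[1:]):
            total += ((b.centroid[0] - a.centroid[0]) ** 2 + (b.centroid[1] - a.centroid[1]) ** 2) ** 0.5
        return total


@dataclass
class LinkTable:
    """Parent→child succession evidence reported by the upstream tracker."""

    links: set = field(default_factory=set)  # set[tuple[node_id, node_id]]

    def add(self, parent, child) -> None:
        if parent == child:
            raise IntegrityError(f"self-link on node {parent!r}")
        self.links.add((parent, child))

    def validate(self, known_ids: Iterable) -> None:
        known = set(known_ids)
        for p, c in self.links:
            if p == c:
                raise IntegrityError(f"self-link on node {p!r}")
            if p not in known:
                raise IntegrityError(f"link references unknown parent node {p!r}")
            if c not in known:
                raise IntegrityError(f"link references unknown child node {c!r}")


@dataclass
class RecordingMeta:
    """Recording-level metadata. fps is required and never inferred."""

    fps: float
    image_width: int
    image_height: int
    duration: float
    body_length_px: float = 50.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise IntegrityError("fps must be positive")
        if self.body_length_px <= 0:
            raise IntegrityError("body_length_px must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))


@dataclass
class Trail:
    """A stitched per-animal trajectory with provenance of constituent nodes."""

    trail_id: object
    node_ids: list
    blobs: list  # time-ordered BlobObservation
    coverage: float

    @property
    def start_time(self) -> float:
        return self.blobs[0].time

    @property
    def end_time(self) -> float:
        return self.blobs[-1].time

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    @property
    def origins(self) -> frozenset:
        out: set = set()
        for b in self.blobs:
            out |= b.origin
        return frozenset(out)


def mask_overlap(a: Mask, b: Mask) -> int:
    """Number of pixels shared by two masks: ``|a ∩ b|``.

    Symmetric, bounded by ``min(|a|, |b|)``; empty masks are allowed.
    """
    if len(b) < len(a):
        a, b = b, a
    return len(a & b) if isinstance(a, (set, frozenset)) else len(frozenset(a) & frozenset(b))


# ---------------------------------------------------------------------------
# Run-length-encoded mask strings: "x,y,n;x,y,n;..." — a run of n pixels
# starting at (x, y) extending along +x.


def decode_rle_mask(s: str) -> Mask:
    pixels: set = set()
    if not s:
        return frozenset()
    for run in s.split(";"):
        parts = run.split(",")
        if len(parts) != 3:
            raise ParseError(f"bad RLE run {run!r}")
        x, y, n = (int(p) for p in parts)
        if n <= 0:
            raise ParseError(f"bad RLE run length in {run!r}")
        for i in range(n):
            pixels.add((x + i, y))
    return frozenset(pixels)


def encode_rle_mask(mask: Mask) -> str:
    runs = []
    for x, y in sorted(mask, key=lambda p: (p[1], p[0])):
        if runs and runs[-1][1] == y and runs[-1][0] + runs[-1][2] == x:
            runs[-1][2] += 1
        else:
            runs.append([x, y, 1])
    return ";".join(f"{x},{y},{n}" for x, y, n in runs)


# ---------------------------------------------------------------------------
# Canonical JSON-lines recording format.
#
#   line 1:  {"type": "meta", "fps": ..., "image_width": ..., ...}
#   then     {"type": "blob", "node_id": ..., "frame": ..., "time": ...,
#             "x": ..., "y": ..., "mask": [[x, y], ...] or "RLE string"}
#   then     {"type": "link", "parent": ..., "child": ...}
#
# UTF-8, no BOM.  Unknown keys in the meta record are ignored (they may
# carry provenance); unknown record types are an error.


def _parse_mask(value, lineno: int) -> Mask:
    if value is None:
        return frozenset()
    if isinstance(value, str):
        try:
            return decode_rle_mask(value)
        except ParseError as e:
            raise ParseError(f"line {lineno}: {e}") from e
    try:
        return frozenset((int(x), int(y)) for x, y in value)
    except (TypeError, ValueError) as e:
        raise ParseError(f"line {lineno}: bad mask: {e}") from e


def read_recording(path) -> tuple[list, LinkTable, RecordingMeta]:
    """Read a canonical JSON-lines recording.

    Returns frame-sorted :class:`TrackNode` objects, the :class:`LinkTable`
    and the :class:`RecordingMeta` from the header record.  Every blob's
    ``origin`` is initialised to the singleton of its own node id.
    """
    meta = None
    blobs_by_node: dict = {}
    frames_seen: dict = {}
    links = LinkTable()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as e:
                raise ParseError(f"line {lineno}: invalid JSON: {e}") from e
            if not isinstance(rec, dict) or "type" not in rec:
                raise ParseError(f"line {lineno}: record has no 'type'")
            kind = rec["type"]
            if kind == "meta":
                if meta is not None:
                    raise ParseError(f"line {lineno}: duplicate meta record")
                try:
                    meta = RecordingMeta(
                        fps=float(rec["fps"]),
                        image_width=int(rec["image_width"]),
                        image_height=int(rec["image_height"]),
                        duration=float(rec["duration"]),
                        body_length_px=float(rec.get("body_length_px", 50.0)),
                    )
                except KeyError as e:
                    raise ParseError(f"line {lineno}: meta missing key {e}") from e
            elif kind == "blob":
                if meta is None:
                    raise ParseError(f"line {lineno}: blob before meta header")
                try:
                    nid = rec["node_id"]
                    frame = int(rec["frame"])
                    t = float(rec["time"])
                    x = float(rec["x"])
                    y = float(rec["y"])
                except (KeyError, TypeError, ValueError) as e:
                    raise ParseError(f"line {lineno}: bad blob record: {e}") from e
                mask = _parse_mask(rec.get("mask"), lineno)
                for px, py in mask:
                    if px < 0 or py < 0 or px >= meta.image_width or py >= meta.image_height:
                        raise IntegrityError(
                            f"line {lineno}: mask pixel ({px},{py}) outside image bounds"
                        )
                seen = frames_seen.setdefault(nid, set())
                if frame in seen:
                    raise IntegrityError(f"line {lineno}: duplicate frame {frame} in node {nid!r}")
                seen.add(frame)
                origin = rec.get("origin")
                blob = BlobObservation(
                    frame=frame,
                    time=t,
                    centroid=(x, y),
                    mask=mask,
                    origin=frozenset(origin) if origin is not None else frozenset([nid]),
                )
                blobs_by_node.setdefault(nid, []).append(blob)
            elif kind == "link":
                try:
                    links.add(rec["parent"], rec["child"])
                except KeyError as e:
                    raise ParseError(f"line {lineno}: link missing key {e}") from e
            elif kind == "trail":
                continue  # trail provenance records are ignored on plain reads
            else:
                raise ParseError(f"line {lineno}: unknown record type {kind!r}")
    if meta is None:
        raise ParseError("recording has no meta header")
    nodes = []
    for nid in sorted(blobs_by_node, key=str):
        blobs = sorted(blobs_by_node[nid], key=lambda b: b.frame)
        nodes.append(TrackNode(node_id=nid, blobs=blobs))  # validates ordering
    links.validate(blobs_by_node.keys())
    nodes.sort(key=lambda n: (n.start_frame, str(n.node_id)))
    return nodes, links, meta


def _meta_record(meta: RecordingMeta, provenance: dict | None = None) -> dict:
    rec = {
        "type": "meta",
        "fps": meta.fps,
        "image_width": meta.image_width,
        "image_height": meta.image_height,
        "body_length_px": meta.body_length_px,
        "duration": meta.duration,
    }
    if provenance:
        rec["provenance"] = provenance
    return rec


def _blob_record(nid, blob: BlobObservation, with_origin: bool = False) -> dict:
    rec = {
        "type": "blob",
        "node_id": nid,
        "frame": blob.frame,
        "time": blob.time,
        "x": blob.centroid[0],
        "y": blob.centroid[1],
        "mask": sorted(blob.mask),
    }
    if with_origin:
        rec["origin"] = sorted(blob.origin, key=str)
    return rec


def write_recording(nodes: Sequence, links: LinkTable, meta: RecordingMeta, path,
                    provenance: dict | None = None) -> None:
    """Write a recording in the canonical JSON-lines dialect.

    Output is deterministic: nodes ordered by (start_frame, id), blobs by
    frame, links sorted; identical inputs produce byte-identical files.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps(_meta_record(meta, provenance)) + "\n")
        for node in sorted(nodes, key=lambda n: (n.start_frame, str(n.node_id))):
            for blob in node.blobs:
                fh.write(json.dumps(_blob_record(node.node_id, blob)) + "\n")
        for parent, child in sorted(links.links, key=lambda pc: (str(pc[0]), str(pc[1]))):
            fh.write(json.dumps({"type": "link", "parent": parent, "child": child}) + "\n")


def write_trails(trails: Sequence, meta: RecordingMeta, path,
                 provenance: dict | None = None) -> None:
    """Write stitched trails in the canonical dialect.

    Blob records carry the trail id as node_id plus their original-node
    ``origin`` lists; a trail record per trail lists its provenance.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps(_meta_record(meta, provenance)) + "\n")
        for trail in trails:
            for blob in trail.blobs:
                fh.write(json.dumps(_blob_record(trail.trail_id, blob, with_origin=True)) + "\n")
        for trail in trails:
            fh.write(json.dumps({
                "type": "trail",
                "trail_id": trail.trail_id,
                "node_ids": [str(n) for n in trail.node_ids],
                "coverage": trail.coverage,
            }) + "\n")


def read_trails(path) -> tuple[list, RecordingMeta]:
    """Read trails written by :func:`write_trails`."""
    meta = None
    blobs_by_trail: dict = {}
    trail_meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as e:
                raise ParseError(f"line {lineno}: invalid JSON: {e}") from e
            kind = rec.get("type")
            if kind == "meta":
                meta = RecordingMeta(
                    fps=float(rec["fps"]),
                    image_width=int(rec["image_width"]),
                    image_height=int(rec["image_height"]),
                    duration=float(rec["duration"]),
                    body_length_px=float(rec.get("body_length_px", 50.0)),
                )
            elif kind == "blob":
                origin = rec.get("origin", [rec["node_id"]])
                blob = BlobObservation(
                    frame=int(rec["frame"]),
                    time=float(rec["time"]),
                    centroid=(float(rec["x"]), float(rec["y"])),
                    mask=_parse_mask(rec.get("mask"), lineno),
                    origin=frozenset(origin),
                )
                blobs_by_trail.setdefault(rec["node_id"], []).append(blob)
            elif kind == "trail":
                trail_meta[rec["trail_id"]] = rec
            elif kind == "link":
                continue
            else:
                raise ParseError(f"line {lineno}: unknown record type {kind!r}")
    if meta is None:
        raise ParseError("trail file has no meta header")
    trails = []
    for tid in sorted(blobs_by_trail, key=str):
        blobs = sorted(blobs_by_trail[tid], key=lambda b: b.frame)
        rec = trail_meta.get(tid, {})
        trails.append(Trail(
            trail_id=tid,
            node_ids=rec.get("node_ids", [tid]),
            blobs=blobs,
            coverage=float(rec.get("coverage", 0.0)),
        ))
    return trails, meta
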