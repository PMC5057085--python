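"""Shared builders for synthetic track fixtures.

All fixtures are constructed programmatically; times follow the package
convention time = frame / fps throughout.
"""

from __future__ import annotations

import numpy as np
import pytest

from wormtrails.blob_io import BlobObservation, LinkTable, RecordingMeta, TrackNode
from wormtrails.tracknet import build_graph

FPS = 5.0


def square_mask(cx: float, cy: float, side: int = 20) -> frozenset:
    x0, y0 = int(round(cx - side / 2)), int(round(cy - side / 2))
    return frozenset((x0 + i, y0 + j) for i in range(side) for j in range(side))


def make_node(nid, start_frame: int, n_frames: int, *, fps: float = FPS,
              start: tuple = (0.0, 0.0), step: tuple = (0.0, 0.0),
              mask_side: int = 0) -> TrackNode:
    """A track whose centroid moves linearly; optional square masks."""
    blobs = []
    for i in range(n_frames):
        cx = start[0] + i * step[0]
        cy = start[1] + i * step[1]
        blobs.append(BlobObservation(
            frame=start_frame + i,
            time=(start_frame + i) / fps,
            centroid=(cx, cy),
            mask=square_mask(cx, cy, mask_side) if mask_side else frozenset(),
            origin=frozenset([nid]),
        ))
    return TrackNode(node_id=nid, blobs=blobs)


def graph_of(nodes, links_pairs=()):
    table = LinkTable()
    for p, c in links_pairs:
        table.add(p, c)
    return build_graph(list(nodes), table)


@pytest.fixture
def meta():
    return RecordingMeta(fps=FPS, image_width=1000, image_height=1000,
                         duration=100.0, body_length_px=50.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
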