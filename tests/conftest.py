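import numpy as np
import pytest

from graphtrack.core_io import LabeledSequence, LineageRecord
from graphtrack.tracks import Track, TrackingGraph


def make_track(tid: int, begin: int, end: int, offset: int = 0) -> Track:
    """A 1-pixel-per-frame track for graph-structure tests."""
    return Track(tid, {t: np.array([[tid + offset, t + 1]]) for t in range(begin, end + 1)})


@pytest.fixture
def fig4_graph() -> TrackingGraph:
    """The worked-example graph: track 5 with predecessors {2,3,4} and
    successors {6,7}, no shared links anywhere else."""
    tracks = {
        2: make_track(2, 0, 1),
        3: make_track(3, 0, 1),
        4: make_track(4, 0, 1),
        5: make_track(5, 2, 4),
        6: make_track(6, 5, 6),
        7: make_track(7, 5, 6),
    }
    g = TrackingGraph(tracks, (16, 16), 7)
    for p in (2, 3, 4):
        g.add_edge(p, 5)
    for s in (6, 7):
        g.add_edge(5, s)
    return g


def sequence_from_positions(
    positions: dict[int, dict[int, tuple[int, ...]]],
    shape: tuple[int, ...] = (32, 32),
    n_frames: int | None = None,
    size: int = 3,
    lineage: list[LineageRecord] | None = None,
) -> LabeledSequence:
    """Build a label sequence from ``{label: {frame: top-left corner}}``
    using ``size x size`` square masks."""
    if n_frames is None:
        n_frames = 1 + max(t for frames in positions.values() for t in frames)
    frames = [np.zeros(shape, dtype=np.int32) for _ in range(n_frames)]
    for lab, by_frame in positions.items():
        for t, corner in by_frame.items():
            sl = tuple(slice(c, c + size) for c in corner)
            frames[t][sl] = lab
    if lineage is None:
        lineage = [
            LineageRecord(lab, min(fr), max(fr), 0) for lab, fr in positions.items()
        ]
    return LabeledSequence(frames, lineage)
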