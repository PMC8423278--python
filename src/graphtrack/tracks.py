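"""Track containers shared by the matching, untangling and FN-correction steps.

A :class:`Track` holds, per frame, the set of mask pixels assigned to it,
plus the predecessor and successor track ids established by the matching
step. Before untangling a track may have any number of predecessors and
successors; afterwards at most one predecessor and at most two successors
remain (two successors model a cell division).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import LabeledSequence, LineageRecord


@dataclass
class Track:
    track_id: int
    masks: dict[int, np.ndarray]  # frame -> (n, ndim) pixel coordinates
    predecessors: set[int] = field(default_factory=set)
    successors: set[int] = field(default_factory=set)

    @property
    def begin(self) -> int:
        return min(self.masks)

    @property
    def end(self) -> int:
        return max(self.masks)

    @property
    def span(self) -> int:
        """Temporal length of the track in frames."""
        return self.end - self.begin + 1

    def centroid(self, t: int) -> np.ndarray:
        return self.masks[t].mean(axis=0)

    def gap_frames(self) -> list[int]:
        """Frames strictly inside the span with no mask (false negatives)."""
        return [t for t in range(self.begin, self.end + 1) if t not in self.masks]


@dataclass
class TrackingGraph:
    """A set of tracks with predecessor/successor links, over a fixed image
    geometry (``shape`` per frame, ``n_frames`` frames)."""

    tracks: dict[int, Track]
    shape: tuple[int, ...]
    n_frames: int

    def __post_init__(self) -> None:
        for tr in self.tracks.values():
            for p in tr.predecessors:
                if p not in self.tracks:
                    raise ValueError(f"track {tr.track_id}: unknown predecessor {p}")
            for s in tr.successors:
                if s not in self.tracks:
                    raise ValueError(f"track {tr.track_id}: unknown successor {s}")

    def is_valid_lineage(self) -> bool:
        """True iff every track has at most 1 predecessor and 2 successors."""
        return all(
            len(tr.predecessors) <= 1 and len(tr.successors) <= 2
            for tr in self.tracks.values()
        )

    def next_track_id(self) -> int:
        return max(self.tracks, default=0) + 1

    def remove_edge(self, pred: int, succ: int) -> None:
        self.tracks[pred].successors.discard(succ)
        self.tracks[succ].predecessors.discard(pred)

    def add_edge(self, pred: int, succ: int) -> None:
        self.tracks[pred].successors.add(succ)
        self.tracks[succ].predecessors.add(pred)

    def copy(self) -> "TrackingGraph":
        return TrackingGraph(
            {
                tid: Track(
                    tid,
                    {t: m.copy() for t, m in tr.masks.items()},
                    set(tr.predecessors),
                    set(tr.successors),
                )
                for tid, tr in self.tracks.items()
            },
            self.shape,
            self.n_frames,
        )

    def to_labeled_sequence(self) -> LabeledSequence:
        """Render the graph as label images + CTC lineage records.

        Track labels are the track ids; parent = the single predecessor
        (0 if none). Raises on overlapping pixel claims or multi-predecessor
        tracks — both must be resolved before writing.
        """
        frames = [np.zeros(self.shape, dtype=np.int32) for _ in range(self.n_frames)]
        for tid, tr in self.tracks.items():
            if len(tr.predecessors) > 1:
                raise ValueError(f"track {tid} has {len(tr.predecessors)} predecessors; untangle first")
            for t, coords in tr.masks.items():
                idx = tuple(coords.T)
                if np.any(frames[t][idx] != 0):
                    other = int(frames[t][idx][frames[t][idx] != 0][0])
                    raise ValueError(f"tracks {other} and {tid} overlap in frame {t}")
                frames[t][idx] = tid
        lineage = []
        for tid in sorted(self.tracks):
            tr = self.tracks[tid]
            parent = next(iter(tr.predecessors)) if tr.predecessors else 0
            lineage.append(LineageRecord(tid, tr.begin, tr.end, parent))
        return LabeledSequence(frames, lineage)


def graph_from_sequence(seq: LabeledSequence) -> TrackingGraph:
    """Build a :class:`TrackingGraph` from a labeled sequence with lineage.

    Each lineage record becomes one track; parent links become
    predecessor/successor edges.
    """
    records = seq.lineage
    if not records:
        raise ValueError("sequence has no lineage records")
    tracks: dict[int, Track] = {}
    for r in records:
        masks = {}
        for t in range(r.begin, r.end + 1):
            coords = np.argwhere(seq.frames[t] == r.label)
            if len(coords):
                masks[t] = coords
        if not masks:
            continue  # all masks of this track were removed (e.g. simulated FN)
        tracks[r.label] = Track(r.label, masks)
    for r in records:
        if r.parent and r.parent in tracks and r.label in tracks:
            tracks[r.parent].successors.add(r.label)
            tracks[r.label].predecessors.add(r.parent)
    return TrackingGraph(tracks, seq.shape, len(seq.frames))
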