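"""False-negative correction: fill internal track gaps with interpolated
masks and resolve the resulting pixel conflicts.

A gap is a run of frames strictly inside a track's span with no mask. The
last mask before the gap is translated to centroid positions linearly
interpolated between the two anchor masks; gaps at the start or end of a
track (only one anchor) are left alone. Inserted masks may overlap existing
ones; conflicted pixels go to the mask with the closest centroid.
"""

from __future__ import annotations

import numpy as np

from .tracks import TrackingGraph


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def interpolate_masks(graph: TrackingGraph, log: list[str] | None = None) -> TrackingGraph:
    """Insert interpolated masks into every internal track gap (in place on
    a copy). The pre-gap mask shape is translated, not morphed."""
    log = log if log is not None else []
    out = graph.copy()
    extent = np.asarray(out.shape)
    for tid in sorted(out.tracks):
        tr = out.tracks[tid]
        gaps = tr.gap_frames()
        if not gaps:
            continue
        present = sorted(tr.masks)
        for t in gaps:
            t_a = max(f for f in present if f < t)
            t_b = min(f for f in present if f > t)
            c_a = tr.centroid(t_a)
            c_b = tr.centroid(t_b)
            frac = (t - t_a) / (t_b - t_a)
            target = c_a + frac * (c_b - c_a)
            offset = _round_half_up(target - c_a)
            coords = tr.masks[t_a] + offset
            inside = np.all((coords >= 0) & (coords < extent), axis=1)
            if not np.all(inside):
                log.append(f"track {tid}: interpolated mask at frame {t} clipped at border")
            coords = coords[inside]
            if len(coords):
                tr.masks[t] = coords
        log.append(f"track {tid}: interpolated {len(gaps)} missing mask(s)")
    return out


def resolve_conflicts(graph: TrackingGraph) -> TrackingGraph:
    """Assign every pixel claimed by several tracks in one frame to the
    track whose centroid (in that frame) is closest; ties go to the lower
    track id. Pixels outside overlap regions are never modified."""
    out = graph.copy()
    by_frame: dict[int, list[int]] = {}
    for tid, tr in out.tracks.items():
        for t in tr.masks:
            by_frame.setdefault(t, []).append(tid)
    for t, tids in by_frame.items():
        if len(tids) < 2:
            continue
        claims: dict[tuple, list[int]] = {}
        for tid in tids:
            for c in map(tuple, out.tracks[tid].masks[t]):
                claims.setdefault(c, []).append(tid)
        conflicted = {c: ids for c, ids in claims.items() if len(ids) > 1}
        if not conflicted:
            continue
        centroids = {tid: out.tracks[tid].centroid(t) for tid in tids}
        losers: dict[int, set[tuple]] = {}
        for c, ids in conflicted.items():
            winner = min(ids, key=lambda tid: (float(np.linalg.norm(centroids[tid] - c)), tid))
            for tid in ids:
                if tid != winner:
                    losers.setdefault(tid, set()).add(c)
        for tid, lost in losers.items():
            tr = out.tracks[tid]
            keep = np.array([tuple(c) not in lost for c in tr.masks[t]])
            if keep.any():
                tr.masks[t] = tr.masks[t][keep]
            else:
                del tr.masks[t]
    return out


def correct_false_negatives(graph: TrackingGraph, log: list[str] | None = None) -> TrackingGraph:
    """Interpolate masks into gaps, then resolve pixel conflicts."""
    return resolve_conflicts(interpolate_masks(graph, log))
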