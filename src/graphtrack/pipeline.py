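"""End-to-end tracking pipeline: tracklet step, matching step and
post-processing (untangling + false-negative correction)."""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .core_io import LabeledSequence, extract_features
from .fn_correction import correct_false_negatives
from .matching import MatchingConfig, match_sequence
from .tracklet import default_roi_size, find_candidates
from .tracks import Track, TrackingGraph
from .untangling import untangle


@dataclass
class RunManifest:
    """Reproducibility record of a tracking run."""

    config: dict = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)
    n_tracks: int = 0

    def as_dict(self) -> dict:
        return {
            "config": self.config,
            "timings": self.timings,
            "log": self.log,
            "n_tracks": self.n_tracks,
        }


def _ablate_untangle(graph: TrackingGraph, log: list[str]) -> TrackingGraph:
    """Ablation stand-in for the untangling step: drop predecessor info of
    multi-predecessor tracks and successor info of tracks with more than two
    successors."""
    out = graph.copy()
    for tid in sorted(out.tracks):
        tr = out.tracks[tid]
        if len(tr.predecessors) > 1:
            log.append(f"ablation: dropping {len(tr.predecessors)} predecessors of track {tid}")
            for p in sorted(tr.predecessors):
                out.remove_edge(p, tid)
        if len(tr.successors) > 2:
            log.append(f"ablation: dropping {len(tr.successors)} successors of track {tid}")
            for s in sorted(tr.successors):
                out.remove_edge(tid, s)
    return out


def _ablate_fn_correction(graph: TrackingGraph, log: list[str]) -> TrackingGraph:
    """Ablation stand-in for FN correction: break each gapped track into
    gap-free segments, the later segments becoming predecessor-less tracks."""
    out = graph.copy()
    for tid in sorted(list(out.tracks)):
        tr = out.tracks[tid]
        if not tr.gap_frames():
            continue
        frames = sorted(tr.masks)
        segments: list[list[int]] = [[frames[0]]]
        for f in frames[1:]:
            if f == segments[-1][-1] + 1:
                segments[-1].append(f)
            else:
                segments.append([f])
        log.append(f"ablation: track {tid} split into {len(segments)} gap-free segments")
        succs = sorted(tr.successors)
        for s in succs:
            out.remove_edge(tid, s)
        all_masks = dict(tr.masks)
        tr.masks = {f: all_masks[f] for f in segments[0]}
        last_id = tid
        for seg in segments[1:]:
            nid = out.next_track_id()
            out.tracks[nid] = Track(nid, {f: all_masks[f] for f in seg})
            last_id = nid
        # reattach successors to the final segment
        for s in succs:
            out.add_edge(last_id, s)
    return out


def track_sequence(
    seg: LabeledSequence,
    raw: list[np.ndarray] | None = None,
    delta_t: int = 3,
    roi_scale: float = 2.0,
    window_length: int = 10,
    apply_untangling: bool = True,
    apply_fn_correction: bool = True,
) -> tuple[TrackingGraph, RunManifest]:
    """Track a segmented sequence and correct segmentation errors.

    Returns the final :class:`TrackingGraph` (at most one predecessor and
    two successors per track when untangling is on) and a run manifest with
    config, timings and operation log.
    """
    manifest = RunManifest(
        config={
            "delta_t": delta_t,
            "roi_scale": roi_scale,
            "window_length": window_length,
            "untangling": apply_untangling,
            "fn_correction": apply_fn_correction,
        }
    )
    log = manifest.log
    t_start = time.perf_counter()
    objects_per_frame = {
        t: extract_features(frame, t) for t, frame in enumerate(seg.frames)
    }
    all_objects = [o for objs in objects_per_frame.values() for o in objs]
    if not all_objects:
        log.append("warning: empty segmentation, nothing to track")
        return TrackingGraph({}, seg.shape, len(seg.frames)), manifest
    roi_size, alpha = default_roi_size(all_objects)
    roi_size = roi_size * (roi_scale / 2.0)  # default_roi_size already doubles
    manifest.config["alpha"] = alpha
    manifest.timings["features"] = time.perf_counter() - t_start

    t0 = time.perf_counter()
    candidates = find_candidates(objects_per_frame, raw, delta_t, roi_size=roi_size)
    manifest.timings["tracklet"] = time.perf_counter() - t0

    cfg = MatchingConfig(alpha=alpha, delta_t=delta_t, window_length=window_length)
    t0 = time.perf_counter()
    graph = match_sequence(objects_per_frame, candidates, cfg, seg.shape, len(seg.frames))
    manifest.timings["matching"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if apply_untangling:
        graph, ops = untangle(graph, log)
        log.append(
            f"untangling: {len(ops.merges)} merges, {sum(ops.splits.values())} splits, "
            f"{len(ops.edge_removals)} edge removals"
        )
    else:
        graph = _ablate_untangle(graph, log)
    manifest.timings["untangling"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if apply_fn_correction:
        graph = correct_false_negatives(graph, log)
    else:
        graph = _ablate_fn_correction(graph, log)
    manifest.timings["fn_correction"] = time.perf_counter() - t0
    manifest.n_tracks = len(graph.tracks)
    return graph, manifest
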