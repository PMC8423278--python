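"""Tracking and segmentation scores: SEG, TRA and DET.

SEG is the mean Jaccard index over ground-truth masks, where a ground-truth
mask only counts as matched when the result mask covers more than half of
it. TRA and DET are normalized acyclic-graph edit distances between the
result and ground-truth lineage graphs (a simplified implementation of the
AOGM family of measures): the result graph is transformed into the
ground-truth graph by adding/removing/splitting nodes and
adding/removing/re-labelling edges, each with a penalty weight, and the
total penalty is normalized by the cost of building the ground-truth graph
from nothing. DET uses node penalties only.

Penalty weights follow the published AOGM convention; adding missing nodes
(false negatives) is penalized the most.
"""

from __future__ import annotations

import numpy as np

from .core_io import LabeledSequence

# AOGM penalty weights
W_NODE_SPLIT = 5.0
W_NODE_ADD = 10.0  # FN: a ground-truth node missing from the result
W_NODE_DEL = 1.0  # FP: a result node matching nothing
W_EDGE_DEL = 1.0
W_EDGE_ADD = 1.5
W_EDGE_SEMANTIC = 1.0

GraphNode = tuple[int, int]  # (frame, label)


def _frame_masks(frame: np.ndarray) -> dict[int, int]:
    labs, counts = np.unique(frame[frame > 0], return_counts=True)
    return {int(l): int(c) for l, c in zip(labs, counts)}


def _overlaps(gt: np.ndarray, res: np.ndarray) -> dict[tuple[int, int], int]:
    """Pixel-overlap counts between nonzero gt and res labels of one frame."""
    both = (gt > 0) & (res > 0)
    if not both.any():
        return {}
    pairs = np.stack([gt[both], res[both]])
    uniq, counts = np.unique(pairs, axis=1, return_counts=True)
    return {(int(g), int(r)): int(c) for (g, r), c in zip(uniq.T, counts)}


def seg_score(gt: LabeledSequence, res: LabeledSequence) -> float:
    """Mean Jaccard index over all ground-truth masks; a result mask matches
    a ground-truth mask only if it covers more than half of it, otherwise
    the mask scores 0."""
    if len(gt.frames) != len(res.frames) or gt.shape != res.shape:
        raise ValueError("ground truth and result have different geometry")
    scores = []
    for g, r in zip(gt.frames, res.frames):
        gt_sizes = _frame_masks(g)
        res_sizes = _frame_masks(r)
        inter = _overlaps(g, r)
        for lab, size in gt_sizes.items():
            best = 0.0
            for (gl, rl), c in inter.items():
                if gl == lab and c > 0.5 * size:
                    union = size + res_sizes[rl] - c
                    best = c / union
                    break
            scores.append(best)
    return float(np.mean(scores)) if scores else 0.0


def _lineage_graph(seq: LabeledSequence) -> tuple[set[GraphNode], dict[tuple[GraphNode, GraphNode], str]]:
    """Nodes and typed edges ("link" or "parent") of a sequence's lineage.

    Labels present in the images define the nodes. If lineage records are
    absent, each label is treated as one track spanning its frames of
    presence (no parent links).
    """
    nodes: set[GraphNode] = set()
    frames_of: dict[int, list[int]] = {}
    for t, f in enumerate(seq.frames):
        for lab in np.unique(f[f > 0]):
            nodes.add((t, int(lab)))
            frames_of.setdefault(int(lab), []).append(t)
    edges: dict[tuple[GraphNode, GraphNode], str] = {}
    for lab, frames in frames_of.items():
        for a, b in zip(frames, frames[1:]):
            if b == a + 1:
                edges[((a, lab), (b, lab))] = "link"
            else:  # track with a gap: still a temporal link in the graph
                edges[((a, lab), (b, lab))] = "link"
    for rec in seq.lineage:
        if rec.parent and rec.parent in frames_of and rec.label in frames_of:
            p_end = frames_of[rec.parent][-1]
            c_begin = frames_of[rec.label][0]
            if p_end < c_begin:
                edges[((p_end, rec.parent), (c_begin, rec.label))] = "parent"
    return nodes, edges


def _edit_counts(gt: LabeledSequence, res: LabeledSequence):
    gt_nodes, gt_edges = _lineage_graph(gt)
    res_nodes, res_edges = _lineage_graph(res)

    # node matching: result mask detects a GT mask if it covers > half of it
    det_by_res: dict[GraphNode, set[GraphNode]] = {rn: set() for rn in res_nodes}
    res_of_gt: dict[GraphNode, GraphNode] = {}
    for t, (g, r) in enumerate(zip(gt.frames, res.frames)):
        gt_sizes = _frame_masks(g)
        for (gl, rl), c in _overlaps(g, r).items():
            if c > 0.5 * gt_sizes[gl]:
                det_by_res[(t, rl)].add((t, gl))
                res_of_gt[(t, gl)] = (t, rl)

    fn = len(gt_nodes) - len(res_of_gt)
    fp = sum(1 for dets in det_by_res.values() if not dets)
    ns = sum(len(dets) - 1 for dets in det_by_res.values() if len(dets) > 1)

    ea = ec = 0
    for (g1, g2), sem in gt_edges.items():
        r1, r2 = res_of_gt.get(g1), res_of_gt.get(g2)
        if r1 is None or r2 is None or (r1, r2) not in res_edges:
            ea += 1
        elif res_edges[(r1, r2)] != sem:
            ec += 1
    ed = 0
    for (r1, r2), sem in res_edges.items():
        d1, d2 = det_by_res.get(r1, set()), det_by_res.get(r2, set())
        if not d1 or not d2:
            ed += 1
        elif not any((g1, g2) in gt_edges for g1 in d1 for g2 in d2):
            ed += 1
    return fn, fp, ns, ea, ed, ec, len(gt_nodes), len(gt_edges)


def tra_det_scores(gt: LabeledSequence, res: LabeledSequence) -> tuple[float, float]:
    """Normalized graph-edit scores ``(TRA, DET)`` in [0, 1]; 1 means the
    result graph matches the ground-truth graph perfectly. DET ignores all
    edge edits."""
    if len(gt.frames) != len(res.frames) or gt.shape != res.shape:
        raise ValueError("ground truth and result have different geometry")
    fn, fp, ns, ea, ed, ec, n_nodes, n_edges = _edit_counts(gt, res)
    aogm = (
        W_NODE_ADD * fn + W_NODE_DEL * fp + W_NODE_SPLIT * ns
        + W_EDGE_ADD * ea + W_EDGE_DEL * ed + W_EDGE_SEMANTIC * ec
    )
    aogm_0 = W_NODE_ADD * n_nodes + W_EDGE_ADD * n_edges
    aogm_d = W_NODE_ADD * fn + W_NODE_DEL * fp + W_NODE_SPLIT * ns
    aogm_d0 = W_NODE_ADD * n_nodes
    tra = 1.0 - min(aogm, aogm_0) / aogm_0 if aogm_0 > 0 else 1.0
    det = 1.0 - min(aogm_d, aogm_d0) / aogm_d0 if aogm_d0 > 0 else 1.0
    return tra, det


def evaluate(gt: LabeledSequence, res: LabeledSequence) -> dict[str, float]:
    """All three scores as a dict ``{"SEG", "TRA", "DET"}``."""
    tra, det = tra_det_scores(gt, res)
    return {"SEG": seg_score(gt, res), "TRA": tra, "DET": det}
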