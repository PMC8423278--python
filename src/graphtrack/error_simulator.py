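"""Simulation of segmentation errors on ground-truth sequences.

Degrades a ground-truth :class:`LabeledSequence` with false negatives
(masks removed), over-segmentation (masks cut in two), under-segmentation
(neighboring masks merged by morphological closing) or an equal mixture, at
a target fraction of n% of all masks. All simulators are deterministic
functions of (sequence, spec).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .core_io import LabeledSequence, extract_features
from .tracklet import default_roi_size

ERROR_TYPES = ("fn", "over", "under", "mixed")


@dataclass(frozen=True)
class ErrorSpec:
    """Which error to simulate, at what mask fraction, with which seed."""

    error_type: str
    fraction: float  # percent of ground-truth masks to modify
    seed: int = 0
    run: int = 0

    def __post_init__(self) -> None:
        if self.error_type not in ERROR_TYPES:
            raise ValueError(f"unknown error type {self.error_type!r}")
        if not 0 < self.fraction <= 100:
            raise ValueError(f"fraction must be in (0, 100], got {self.fraction}")


def _all_masks(seq: LabeledSequence) -> list[tuple[int, int]]:
    return [(t, int(lab)) for t, f in enumerate(seq.frames) for lab in np.unique(f[f > 0])]


def _target_count(seq: LabeledSequence, fraction: float) -> int:
    return int(len(_all_masks(seq)) * fraction / 100.0)


def simulate_fn(seq: LabeledSequence, spec: ErrorSpec) -> LabeledSequence:
    """Remove ``floor(n% * total)`` masks drawn uniformly without
    replacement; the lineage records are left untouched."""
    rng = np.random.default_rng(spec.seed)
    out = seq.copy()
    masks = _all_masks(seq)
    k = _target_count(seq, spec.fraction)
    for idx in rng.choice(len(masks), size=k, replace=False):
        t, lab = masks[int(idx)]
        out.frames[t][out.frames[t] == lab] = 0
    return out


def _random_cut(coords: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Split a pixel set in two nonempty parts by a random hyperplane
    through the centroid; falls back to a median split when a draw leaves
    one side empty."""
    centroid = coords.mean(axis=0)
    rel = coords - centroid
    for _ in range(8):
        direction = rng.normal(size=coords.shape[1])
        norm = np.linalg.norm(direction)
        if norm == 0:
            continue
        proj = rel @ (direction / norm)
        left = proj < 0
        if left.any() and (~left).any():
            return coords[left], coords[~left]
    direction = rng.normal(size=coords.shape[1])
    direction /= max(np.linalg.norm(direction), 1e-9)
    proj = rel @ direction
    order = np.argsort(proj, kind="stable")
    half = len(coords) // 2
    return coords[order[:half]], coords[order[half:]]


def simulate_overseg(seq: LabeledSequence, spec: ErrorSpec, log: list[str] | None = None) -> LabeledSequence:
    """Split ``floor(n% * total)`` randomly chosen masks into two parts
    (fresh labels) by a random straight cut through the centroid."""
    log = log if log is not None else []
    rng = np.random.default_rng(spec.seed)
    out = seq.copy()
    masks = _all_masks(seq)
    k = _target_count(seq, spec.fraction)
    next_label = max((int(f.max()) for f in out.frames), default=0) + 1
    order = rng.permutation(len(masks))
    done = 0
    for idx in order:
        if done >= k:
            break
        t, lab = masks[int(idx)]
        coords = np.argwhere(out.frames[t] == lab)
        if len(coords) < 2:
            log.append(f"mask {lab} at frame {t} too small to split; resampled")
            continue
        part_a, part_b = _random_cut(coords, rng)
        out.frames[t][tuple(coords.T)] = 0
        out.frames[t][tuple(part_a.T)] = next_label
        out.frames[t][tuple(part_b.T)] = next_label + 1
        next_label += 2
        done += 1
    return out


def _merge_pair(frame: np.ndarray, lab_a: int, lab_b: int, new_label: int) -> None:
    """Merge two labels into one connected mask via morphological closing
    with a ball whose radius is half the boundary gap between the masks.
    Pixels of other labels are never overwritten."""
    coords_a = np.argwhere(frame == lab_a)
    coords_b = np.argwhere(frame == lab_b)
    gap = float(cdist(coords_a, coords_b).min())
    radius = max(int(np.ceil(gap / 2.0)), 1)
    union = np.vstack([coords_a, coords_b])
    lo = np.maximum(union.min(axis=0) - radius - 1, 0)
    hi = np.minimum(union.max(axis=0) + radius + 2, np.array(frame.shape))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    crop = frame[sl]
    mask = (crop == lab_a) | (crop == lab_b)
    ball = _ball(radius, frame.ndim)
    closed = ndimage.binary_closing(np.pad(mask, radius), structure=ball)
    closed = closed[tuple(slice(radius, s + radius) for s in mask.shape)]
    writable = closed & ((crop == 0) | mask)
    crop[writable] = new_label


def _ball(radius: int, ndim: int) -> np.ndarray:
    grids = np.indices((2 * radius + 1,) * ndim) - radius
    return (grids**2).sum(axis=0) <= radius**2


def simulate_underseg(
    seq: LabeledSequence,
    spec: ErrorSpec,
    log: list[str] | None = None,
    eligible: set[tuple[int, int]] | None = None,
    target: int | None = None,
) -> LabeledSequence:
    """Merge neighboring masks until at least n% of the ground-truth masks
    are merged, sampling pairs with inverse-distance weights (closer pairs
    merge with higher probability); chains of more than two cells are
    allowed. Stops early (logged) when no neighbor pairs remain.
    """
    log = log if log is not None else []
    rng = np.random.default_rng(spec.seed)
    out = seq.copy()
    k = target if target is not None else _target_count(seq, spec.fraction)
    objects = [
        o for t, f in enumerate(seq.frames) for o in extract_features(f, t)
    ]
    if not objects:
        return out
    _, roi_edge = default_roi_size(objects)
    reach = 2.0 * roi_edge
    # real under-segmentation merges masks whose borders (nearly) touch: a
    # segmentation cannot invent foreground across a wide background gap, so
    # pairs are only eligible while their boundary gap is at most one mean
    # cell radius
    ndim = seq.ndim
    areas = np.array([o.size for o in objects], dtype=float)
    if ndim == 2:
        mean_radius = float(np.mean(np.sqrt(areas / np.pi)))
    else:
        mean_radius = float(np.mean((3.0 * areas / (4.0 * np.pi)) ** (1.0 / 3.0)))
    max_gap = max(mean_radius, 2.0)
    next_label = max((int(f.max()) for f in out.frames), default=0) + 1
    # per-frame centroids of current masks; merged masks can merge again
    merged_members: dict[tuple[int, int], set[int]] = {}  # (t,label)->original labels
    merged_count = 0
    while merged_count < k:
        pairs: list[tuple[int, int, int, float]] = []  # (t, lab_a, lab_b, boundary gap)
        for t, frame in enumerate(out.frames):
            labs = np.unique(frame[frame > 0])
            if eligible is not None:
                labs = [
                    lab for lab in labs
                    if (t, int(lab)) in eligible or (t, int(lab)) in merged_members
                ]
            if len(labs) < 2:
                continue
            coords = {int(lab): np.argwhere(frame == lab) for lab in labs}
            cents = np.array([coords[int(lab)].mean(axis=0) for lab in labs])
            d = cdist(cents, cents)
            for i in range(len(labs)):
                for j in range(i + 1, len(labs)):
                    if d[i, j] < reach:
                        # the pair distance is the boundary gap between the
                        # masks: under-segmentation in real data merges
                        # touching cells, so closeness of the mask borders,
                        # not of the centroids, drives the sampling weight
                        gap = float(
                            cdist(coords[int(labs[i])], coords[int(labs[j])]).min()
                        )
                        if gap <= max_gap:
                            pairs.append((t, int(labs[i]), int(labs[j]), gap))
        if not pairs:
            log.append(f"under-segmentation: no neighbor pairs left, merged {merged_count}/{k}")
            break
        weights = np.array([1.0 / (p[3] + 1e-6) for p in pairs])
        t, lab_a, lab_b, _ = pairs[int(rng.choice(len(pairs), p=weights / weights.sum()))]
        _merge_pair(out.frames[t], lab_a, lab_b, next_label)
        members = merged_members.pop((t, lab_a), {lab_a}) | merged_members.pop((t, lab_b), {lab_b})
        merged_members[(t, next_label)] = members
        merged_count = sum(len(m) for m in merged_members.values())
        next_label += 1
    return out


def simulate_mixed(seq: LabeledSequence, spec: ErrorSpec, log: list[str] | None = None) -> LabeledSequence:
    """Apply FN, over- and under-segmentation in equal shares on disjoint
    mask selections so that in total n% of the masks are modified; the
    integer remainder of the three-way division goes to FN."""
    log = log if log is not None else []
    rng = np.random.default_rng(spec.seed)
    k = _target_count(seq, spec.fraction)
    share = k // 3
    k_fn = k - 2 * share
    masks = _all_masks(seq)
    order = rng.permutation(len(masks))
    fn_set = {masks[int(i)] for i in order[:k_fn]}
    over_set = {masks[int(i)] for i in order[k_fn : k_fn + share]}
    under_pool = {masks[int(i)] for i in order[k_fn + share :]}

    out = seq.copy()
    for t, lab in sorted(fn_set):
        out.frames[t][out.frames[t] == lab] = 0
    next_label = max((int(f.max()) for f in out.frames), default=0) + 1
    for t, lab in sorted(over_set):
        coords = np.argwhere(out.frames[t] == lab)
        if len(coords) < 2:
            log.append(f"mixed: mask {lab} at frame {t} too small to split")
            continue
        part_a, part_b = _random_cut(coords, rng)
        out.frames[t][tuple(coords.T)] = 0
        out.frames[t][tuple(part_a.T)] = next_label
        out.frames[t][tuple(part_b.T)] = next_label + 1
        next_label += 2
    if share > 0:
        out = simulate_underseg(
            out,
            replace(spec, seed=spec.seed + 1),
            log=log,
            eligible=under_pool,
            target=share,
        )
    return out


_SIMULATORS = {
    "fn": simulate_fn,
    "over": simulate_overseg,
    "under": simulate_underseg,
    "mixed": simulate_mixed,
}


def simulate(seq: LabeledSequence, spec: ErrorSpec) -> LabeledSequence:
    """Dispatch to the simulator for ``spec.error_type``."""
    return _SIMULATORS[spec.error_type](seq, spec)


def generate_benchmark_grid(
    sequences: list[LabeledSequence],
    fractions: tuple[float, ...] = (1, 2, 5, 10, 20),
    error_types: tuple[str, ...] = ERROR_TYPES,
    runs: int = 5,
    base_seed: int = 0,
    materialize: bool = False,
) -> list[tuple[int, ErrorSpec, LabeledSequence | None]]:
    """Cartesian product sequences x fractions x error types x runs, each
    item with a distinct derived seed.

    Returns ``(sequence_index, spec, degraded_or_None)`` tuples; the default
    benchmark protocol (5 fractions, 4 error types, 5 runs, 4 sequences)
    yields 400 data sets. With ``materialize=False`` only the specs are
    enumerated.
    """
    if not sequences or not fractions or not error_types or runs < 1:
        raise ValueError("benchmark grid inputs must be nonempty")
    items = []
    idx = 0
    for s_i in range(len(sequences)):
        for frac in fractions:
            for etype in error_types:
                for run in range(runs):
                    seed = (base_seed + 9973 * idx + 7) % (2**31 - 1)
                    spec = ErrorSpec(etype, frac, seed=seed, run=run)
                    degraded = simulate(sequences[s_i], spec) if materialize else None
                    items.append((s_i, spec, degraded))
                    idx += 1
    return items
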