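"""Tracklet step: ROI propagation and matching-candidate discovery.

Each segmented object gets a rectangular region of interest (ROI) whose size
is derived from the average segmentation-mask size. The ROI is propagated to
the next frames with a displacement estimated by phase correlation between
raw-image crops; objects whose bounding box intersects the propagated ROI
become matching candidates for the graph construction of the matching step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import SegmentedObject


@dataclass(frozen=True)
class ROI:
    """Axis-aligned region of interest: a center and per-axis extent."""

    center: np.ndarray
    size: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.size) <= 0):
            raise ValueError(f"ROI size must be positive, got {self.size}")

    @property
    def low(self) -> np.ndarray:
        return np.asarray(self.center) - np.asarray(self.size) / 2.0

    @property
    def high(self) -> np.ndarray:
        return np.asarray(self.center) + np.asarray(self.size) / 2.0

    def intersects_box(self, box_min: np.ndarray, box_max: np.ndarray) -> bool:
        """Does the ROI intersect the (inclusive) pixel box?"""
        return bool(np.all(self.low <= box_max) and np.all(self.high >= box_min))


class CandidateMap(dict):
    """Mapping ``(object_id, t) -> {t': set of candidate object_ids}`` for
    ``t' in t+1 .. t+delta_t``. Also stores the per-step displacement
    estimates ``displacements[(object_id, t, t')]`` (the shift from frame
    ``t'`` to ``t'+1`` of the ROI tracking object ``(object_id, t)``)."""

    def __init__(self) -> None:
        super().__init__()
        self.displacements: dict[tuple[int, int, int], np.ndarray] = {}


def default_roi_size(objects: list[SegmentedObject]) -> tuple[np.ndarray, float]:
    """Default ROI size: per axis twice the mean bounding-box extent over all
    objects of the sequence. Returns ``(size, alpha)`` where ``alpha`` is the
    largest edge of the default ROI (used as the appear/disappear threshold).
    """
    if not objects:
        raise ValueError("cannot derive an ROI size without objects")
    extents = np.stack([o.bbox_extent for o in objects])
    size = 2.0 * extents.mean(axis=0)
    return size, float(size.max())


def estimate_displacement(crop_t: np.ndarray, crop_t1: np.ndarray) -> np.ndarray:
    """Integer-pixel translation from ``crop_t`` to ``crop_t1`` by phase
    correlation.

    Returns the shift ``d`` such that ``crop_t1 ≈ crop_t translated by d``.
    Falls back to the zero vector when the correlation peak is degenerate
    (e.g. constant crops).
    """
    crop_t = np.asarray(crop_t, dtype=float)
    crop_t1 = np.asarray(crop_t1, dtype=float)
    if crop_t.shape != crop_t1.shape:
        raise ValueError(f"crop shapes differ: {crop_t.shape} vs {crop_t1.shape}")
    if crop_t.size == 0 or crop_t.std() == 0 or crop_t1.std() == 0:
        return np.zeros(crop_t.ndim)
    f0 = np.fft.fftn(crop_t - crop_t.mean())
    f1 = np.fft.fftn(crop_t1 - crop_t1.mean())
    cross = f1 * np.conj(f0)
    denom = np.abs(cross)
    if not np.any(denom > 1e-12):
        return np.zeros(crop_t.ndim)
    # regularized spectrum normalization: a pure 1/|cross| whitening is very
    # noise-sensitive on small crops, so the spectrum is only softly whitened
    surface = np.real(np.fft.ifftn(cross / (denom + 0.1 * denom.mean() + 1e-12)))
    peak = np.unravel_index(np.argmax(surface), surface.shape)
    shift = np.array(peak, dtype=float)
    # wrap to signed shifts
    for ax, n in enumerate(surface.shape):
        if shift[ax] > n // 2:
            shift[ax] -= n
    return shift


def _crop(image: np.ndarray, center: np.ndarray, size: np.ndarray) -> np.ndarray | None:
    lo = np.round(np.asarray(center) - np.asarray(size) / 2.0).astype(int)
    hi = lo + np.maximum(np.round(size).astype(int), 1)
    lo = np.clip(lo, 0, np.array(image.shape))
    hi = np.clip(hi, 0, np.array(image.shape))
    if np.any(hi - lo < 2):
        return None
    return image[tuple(slice(l, h) for l, h in zip(lo, hi))]


def find_candidates(
    objects_per_frame: dict[int, list[SegmentedObject]],
    raw: list[np.ndarray] | None,
    delta_t: int,
    roi_size: np.ndarray | None = None,
) -> CandidateMap:
    """Collect matching candidates by propagating each object's ROI over up
    to ``delta_t`` successive frames.

    For every object at frame ``t`` the ROI is centered on its centroid and
    moved by the phase-correlation displacement between the raw-image crops
    of consecutive frames (zero displacement if ``raw`` is None). Objects at
    the target frame whose bounding box intersects the propagated ROI are
    candidates.
    """
    if delta_t < 1:
        raise ValueError(f"delta_t must be >= 1, got {delta_t}")
    all_objects = [o for objs in objects_per_frame.values() for o in objs]
    cmap = CandidateMap()
    if not all_objects:
        return cmap
    if roi_size is None:
        roi_size, _ = default_roi_size(all_objects)
    frames = sorted(objects_per_frame)
    last = frames[-1] if frames else -1
    for t in frames:
        for obj in objects_per_frame[t]:
            center = obj.centroid.astype(float).copy()
            last_shift = np.zeros(len(center))
            for step in range(1, delta_t + 1):
                tp = t + step
                if tp > last:
                    break
                shift = last_shift
                if raw is not None:
                    c0 = _crop(raw[tp - 1], center, roi_size)
                    c1 = _crop(raw[tp], center, roi_size)
                    if c0 is not None and c1 is not None and c0.shape == c1.shape:
                        shift = estimate_displacement(c0, c1)
                else:
                    shift = np.zeros(len(center))
                cmap.displacements[(obj.object_id, t, tp - 1)] = shift
                center = center + shift
                last_shift = shift
                roi = ROI(center, np.asarray(roi_size, dtype=float))
                hits = {
                    o2.object_id
                    for o2 in objects_per_frame.get(tp, [])
                    if roi.intersects_box(o2.bbox_min, o2.bbox_max)
                }
                cmap.setdefault((obj.object_id, t), {})[tp] = hits
    return cmap
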