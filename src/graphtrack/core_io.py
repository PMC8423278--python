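"""Domain types, CTC-format readers/writers, and per-object feature extraction.

Conventions used throughout the package: 0-based integer pixel indices, axis
order ``(y, x)`` in 2D and ``(z, y, x)`` in 3D; frame indices are 0-based.
Label images are integer grids with 0 = background.

On-disk layout follows the Cell Tracking Challenge (CTC): one TIFF label image
per frame with a zero-padded frame index in the file name, plus a 4-column
whitespace-separated lineage file (``res_track.txt`` / ``man_track.txt``) with
one line ``label begin end parent`` per track (parent 0 = none).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

#: maximum number of representative interior points kept per mask
MAX_MASK_POINTS = 50


@dataclass(frozen=True)
class LineageRecord:
    """One track of a lineage: ``label begin end parent`` (CTC convention)."""

    label: int
    begin: int
    end: int
    parent: int = 0

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise ValueError(f"track label must be positive, got {self.label}")
        if self.begin > self.end:
            raise ValueError(f"track {self.label}: begin {self.begin} > end {self.end}")
        if self.parent < 0:
            raise ValueError(f"track {self.label}: negative parent {self.parent}")


@dataclass
class LabeledSequence:
    """A time-ordered sequence of instance-segmentation label images.

    Parameters
    ----------
    frames
        List of integer label arrays, one per time point, all the same shape.
    lineage
        Track records; may be empty for raw segmentation input.
    """

    frames: list[np.ndarray]
    lineage: list[LineageRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("sequence must contain at least one frame")
        shape = self.frames[0].shape
        for t, f in enumerate(self.frames):
            if not np.issubdtype(f.dtype, np.integer):
                raise ValueError(f"frame {t}: non-integer pixel type {f.dtype}")
            if f.shape != shape:
                raise ValueError(f"frame {t}: shape {f.shape} != {shape}")

    @property
    def ndim(self) -> int:
        return self.frames[0].ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.frames[0].shape

    def __len__(self) -> int:
        return len(self.frames)

    def total_mask_count(self) -> int:
        return sum(len(np.unique(f[f > 0])) for f in self.frames)

    def copy(self) -> "LabeledSequence":
        return LabeledSequence(
            [f.copy() for f in self.frames], list(self.lineage)
        )


@dataclass
class SegmentedObject:
    """One labeled mask at one frame, with the geometric features used for
    cost evaluation: centroid ``p``, bounding box ``B`` (corner pair), a set of
    representative interior mask points ``Q`` and the full pixel set.
    """

    object_id: int  # label in the frame's label image
    time: int
    centroid: np.ndarray  # float, (ndim,)
    bbox_min: np.ndarray  # int, (ndim,) inclusive
    bbox_max: np.ndarray  # int, (ndim,) inclusive
    mask_points: np.ndarray  # int, (k, ndim), k <= MAX_MASK_POINTS
    pixels: np.ndarray  # int, (n, ndim)

    @property
    def bbox_diagonal(self) -> float:
        """Euclidean length of the bounding-box diagonal."""
        return float(np.linalg.norm(self.bbox_max - self.bbox_min))

    @property
    def bbox_extent(self) -> np.ndarray:
        return self.bbox_max - self.bbox_min + 1

    @property
    def size(self) -> int:
        return len(self.pixels)


def extract_features(label_image: np.ndarray, time: int) -> list[SegmentedObject]:
    """Extract one :class:`SegmentedObject` per nonzero label of a frame.

    The mask-point set ``Q`` contains interior pixels whose Euclidean
    distance-transform value is at least half the mask's maximum distance
    value, subsampled by uniform stride to at most :data:`MAX_MASK_POINTS`
    points.
    """
    if not np.issubdtype(label_image.dtype, np.integer):
        raise ValueError(f"label image must be integer, got {label_image.dtype}")
    objects: list[SegmentedObject] = []
    labels = np.unique(label_image)
    labels = labels[labels > 0]
    slices = ndimage.find_objects(label_image)
    for lab in labels:
        sl = slices[int(lab) - 1] if int(lab) - 1 < len(slices) else None
        if sl is None:  # labels need not be dense; fall back to full search
            coords = np.argwhere(label_image == lab)
        else:
            local = label_image[sl] == lab
            coords = np.argwhere(local) + np.array([s.start for s in sl])
        centroid = coords.mean(axis=0)
        bbox_min = coords.min(axis=0)
        bbox_max = coords.max(axis=0)
        mask_points = _interior_points(coords, bbox_min, bbox_max)
        objects.append(
            SegmentedObject(
                object_id=int(lab),
                time=time,
                centroid=centroid,
                bbox_min=bbox_min,
                bbox_max=bbox_max,
                mask_points=mask_points,
                pixels=coords,
            )
        )
    return objects


def _interior_points(coords: np.ndarray, bbox_min: np.ndarray, bbox_max: np.ndarray) -> np.ndarray:
    """Distance-transform core of a mask, capped at MAX_MASK_POINTS points."""
    shape = tuple(bbox_max - bbox_min + 1)
    mask = np.zeros(shape, dtype=bool)
    local = coords - bbox_min
    mask[tuple(local.T)] = True
    # pad so pixels touching the bbox edge get distance 1, not "infinite"
    padded = np.pad(mask, 1)
    dt = ndimage.distance_transform_edt(padded)[tuple(slice(1, -1) for _ in shape)]
    core = np.argwhere(dt >= 0.5 * dt.max()) + bbox_min
    if len(core) > MAX_MASK_POINTS:
        idx = np.linspace(0, len(core) - 1, MAX_MASK_POINTS).round().astype(int)
        core = core[np.unique(idx)]
    return core


# ---------------------------------------------------------------------------
# CTC directory I/O
# ---------------------------------------------------------------------------

_FRAME_RE = re.compile(r"(\d+)\.tiff?$", re.IGNORECASE)
_LINEAGE_NAMES = ("res_track.txt", "man_track.txt", "track.txt")


def read_ctc_sequence(directory: str | Path, kind: str = "segmentation") -> LabeledSequence:
    """Read a CTC-layout directory of per-frame TIFF label images.

    Parameters
    ----------
    directory
        Directory containing TIFF files whose names end in a frame index
        (e.g. ``mask000.tif`` or ``man_track012.tif``).
    kind
        ``"segmentation"`` (lineage file optional) or ``"ground_truth"``
        (lineage file required).
    """
    directory = Path(directory)
    if kind not in ("segmentation", "ground_truth"):
        raise ValueError(f"unknown kind {kind!r}")
    frame_files: dict[int, Path] = {}
    for f in sorted(directory.iterdir()):
        m = _FRAME_RE.search(f.name)
        if m and f.is_file():
            frame_files[int(m.group(1))] = f
    if not frame_files:
        raise FileNotFoundError(f"no TIFF label images found in {directory}")
    indices = sorted(frame_files)
    lo, hi = indices[0], indices[-1]
    missing = sorted(set(range(lo, hi + 1)) - set(indices))
    if missing:
        raise FileNotFoundError(f"missing frame {missing[0]} in {directory}")
    frames = []
    for t in indices:
        arr = tifffile.imread(frame_files[t])
        arr = np.asarray(arr)
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"frame {t}: non-integer pixel type {arr.dtype}")
        frames.append(arr)
    lineage: list[LineageRecord] = []
    for name in _LINEAGE_NAMES:
        path = directory / name
        if path.exists():
            lineage = _read_lineage(path)
            break
    else:
        if kind == "ground_truth":
            raise FileNotFoundError(f"no lineage file in {directory} (ground truth requires one)")
    return LabeledSequence(frames, lineage)


def _read_lineage(path: Path) -> list[LineageRecord]:
    records = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}: malformed lineage line {line!r}")
        lab, begin, end, parent = (int(p) for p in parts)
        records.append(LineageRecord(lab, begin, end, parent))
    return records


def write_ctc_sequence(seq: LabeledSequence, directory: str | Path,
                       lineage_name: str = "res_track.txt",
                       prefix: str = "mask") -> None:
    """Write a :class:`LabeledSequence` in CTC layout (16-bit TIFF + lineage)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    digits = max(3, len(str(len(seq.frames) - 1)))
    for t, frame in enumerate(seq.frames):
        if frame.max() > np.iinfo(np.uint16).max:
            raise ValueError(f"frame {t}: label exceeds uint16 range")
        tifffile.imwrite(directory / f"{prefix}{t:0{digits}d}.tif", frame.astype(np.uint16))
    lines = [f"{r.label} {r.begin} {r.end} {r.parent}" for r in seq.lineage]
    (directory / lineage_name).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_tracking_result(graph, directory: str | Path) -> None:
    """Write a tracking result (a :class:`~graphtrack.tracks.TrackingGraph`)
    as a CTC result directory: one label TIFF per frame, labels = track ids,
    plus ``res_track.txt``.

    Raises if two tracks claim the same pixel in one frame (conflicts must be
    resolved upstream) or if a track still has more than one predecessor.
    """
    seq = graph.to_labeled_sequence()
    write_ctc_sequence(seq, directory)
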