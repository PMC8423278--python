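"""Synthetic fixture generator: moving elliptical cells with divisions.

Produces raw intensity images and a ground-truth :class:`LabeledSequence`
with lineage, emulating fluorescence time-lapse data in which cell movement
is small compared to the image size. Cells follow a Brownian walk with a
constant per-cell drift, reflect at the image border, and may divide into
two adjacent daughters. A thin-3D mode (few z slices) exercises the 3D code
paths cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import LabeledSequence, LineageRecord


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic sequence generator.

    ``displacement`` is the per-frame Brownian step scale in pixels and must
    stay small relative to the image extent; ``n_divisions`` schedules that
    many division events at seeded random frames (mothers chosen without
    replacement), while ``division_prob`` adds per-cell-per-frame random
    divisions on top (default 0)."""

    shape: tuple[int, ...] = (128, 128)
    n_frames: int = 30
    n_cells: int = 15
    radius_range: tuple[float, float] = (4.0, 7.0)
    displacement: float = 1.5
    drift: float = 0.5
    division_prob: float = 0.0
    n_divisions: int = 0
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.displacement * 10 > max(self.shape):  # thin-3D: z may be tiny
            raise ValueError("displacement must be small compared to the image size")
        if self.n_cells < 1 or self.n_frames < 1:
            raise ValueError("need at least one cell and one frame")


@dataclass
class _Cell:
    label: int
    pos: np.ndarray
    radii: np.ndarray
    drift: np.ndarray
    begin: int
    parent: int = 0
    end: int | None = None


def _place_cells(cfg: SimulationConfig, rng: np.random.Generator) -> list[_Cell]:
    extent = np.asarray(cfg.shape, dtype=float)
    r_lo, r_hi = cfg.radius_range
    cells: list[_Cell] = []
    min_sep = 2.0 * r_hi + 2.0
    for label in range(1, cfg.n_cells + 1):
        radii = rng.uniform(r_lo, r_hi, size=len(extent))
        if len(extent) == 3:  # thin-3D mode: flatter in z
            radii[0] = min(radii[0], cfg.shape[0] / 2.5)
        # per-axis placement margin, clamped for very thin axes
        margin = np.minimum(radii + 1, (extent - 1) / 2.0 - 0.5)
        for _ in range(2000):
            pos = rng.uniform(margin, extent - margin)
            if all(np.linalg.norm(pos - c.pos) >= min_sep for c in cells):
                break
        else:
            raise RuntimeError(
                "could not place cells without overlap; lower the density "
                "(fewer cells, smaller radii, or a larger image)"
            )
        drift = rng.normal(scale=cfg.drift, size=len(extent))
        cells.append(_Cell(label, pos, radii, drift, begin=0))
    return cells


def _separate(cells: list[_Cell], extent: np.ndarray) -> None:
    """Push overlapping cells apart so masks stay disjoint."""
    for _ in range(20):
        moved = False
        for i, a in enumerate(cells):
            for b in cells[i + 1 :]:
                need = float(max(a.radii.max(), b.radii.max()) + min(a.radii.max(), b.radii.max())) + 1.0
                delta = b.pos - a.pos
                dist = float(np.linalg.norm(delta))
                if dist < need:
                    direction = delta / dist if dist > 1e-6 else np.eye(len(extent))[len(extent) - 1]
                    push = (need - dist) / 2.0 + 0.5
                    a.pos = np.clip(a.pos - direction * push, a.radii + 1, extent - a.radii - 1)
                    b.pos = np.clip(b.pos + direction * push, b.radii + 1, extent - b.radii - 1)
                    moved = True
        if not moved:
            return


def _paint(cells: list[_Cell], shape: tuple[int, ...]) -> np.ndarray:
    frame = np.zeros(shape, dtype=np.int32)
    for c in cells:
        lo = np.maximum(np.floor(c.pos - c.radii).astype(int), 0)
        hi = np.minimum(np.ceil(c.pos + c.radii).astype(int) + 1, np.array(shape))
        grids = np.indices(tuple(hi - lo)) + lo.reshape((-1,) + (1,) * len(shape))
        dist = sum(
            ((grids[k] - c.pos[k]) / c.radii[k]) ** 2 for k in range(len(shape))
        )
        region = tuple(slice(a, b) for a, b in zip(lo, hi))
        inside = dist <= 1.0
        target = frame[region]
        target[inside & (target == 0)] = c.label
    return frame


def generate_sequence(cfg: SimulationConfig) -> tuple[list[np.ndarray], LabeledSequence]:
    """Generate ``(raw_images, ground_truth)`` for the configured conditions.

    Deterministic for a fixed config. Raw images are smoothed per-cell
    intensities plus Gaussian noise, suitable for phase-correlation
    displacement estimation.
    """
    rng = np.random.default_rng(cfg.seed)
    extent = np.asarray(cfg.shape, dtype=float)
    cells = _place_cells(cfg, rng)
    finished: list[_Cell] = []
    next_label = cfg.n_cells + 1

    division_frames: dict[int, int] = {}  # label -> frame at which the mother divides
    if cfg.n_divisions:
        mothers = rng.choice(cfg.n_cells, size=min(cfg.n_divisions, cfg.n_cells), replace=False)
        lo_f = max(1, cfg.n_frames // 4)
        hi_f = max(lo_f + 1, 3 * cfg.n_frames // 4)
        for m in mothers:
            division_frames[int(m) + 1] = int(rng.integers(lo_f, hi_f))

    frames: list[np.ndarray] = []
    raw: list[np.ndarray] = []
    intensity = {c.label: rng.uniform(0.5, 1.0) for c in cells}

    for t in range(cfg.n_frames):
        if t > 0:
            for c in cells:
                step = rng.normal(scale=cfg.displacement, size=len(extent))
                c.pos = c.pos + c.drift + step
                low = np.minimum(c.radii + 1, (extent - 1) / 2.0 - 0.5)
                high = extent - low
                c.pos = np.where(c.pos < low, 2 * low - c.pos, c.pos)  # reflect
                c.pos = np.where(c.pos > high, 2 * high - c.pos, c.pos)
                c.pos = np.clip(c.pos, low, high)
            _separate(cells, extent)
            # divisions: mother ends at t-1, daughters appear at t. A
            # division at the image border is not identifiable from
            # positions alone (a daughter leaving the field is
            # indistinguishable from an appearance), so the ground-truth
            # lineage would be ambiguous; a scheduled event whose mother sits
            # at the border is therefore handed to the most interior cell.
            interior = 2.0 * cfg.radius_range[1]

            def border_dist(c: _Cell) -> float:
                return float(min(np.minimum(c.pos, extent - 1 - c.pos)))

            dividing = []
            for c in list(cells):
                if c in dividing:
                    continue
                scheduled = division_frames.get(c.label, cfg.n_frames + 1) <= t
                random_div = cfg.division_prob > 0 and rng.random() < cfg.division_prob
                if not (scheduled or random_div):
                    continue
                if border_dist(c) < interior:
                    candidates_int = [
                        o for o in cells
                        if o.label not in division_frames
                        and o not in dividing
                        and border_dist(o) >= interior
                    ]
                    if scheduled:
                        del division_frames[c.label]
                    if candidates_int:
                        c = max(candidates_int, key=border_dist)
                        division_frames[c.label] = t
                    else:
                        continue
                dividing.append(c)
            for mother in dividing:
                cells.remove(mother)
                division_frames.pop(mother.label, None)
                mother.end = t - 1
                finished.append(mother)
                # daughters symmetric around the mother (the biological
                # prior the mitosis costs encode); the division axis is the
                # candidate direction with most clearance from other cells
                best_axis, best_clear = None, -np.inf
                for _ in range(8):
                    axis = rng.normal(size=len(extent))
                    axis /= max(np.linalg.norm(axis), 1e-9)
                    offset = axis * (mother.radii.max() * 0.8 + 0.5)
                    clear = min(
                        float(np.linalg.norm((mother.pos + sgn * offset) - o.pos))
                        for sgn in (+1.0, -1.0)
                        for o in cells
                    ) if cells else 1e9
                    if clear > best_clear:
                        best_axis, best_clear = axis, clear
                # adjacent daughters: each sits one daughter radius
                # (0.8x the mother radius) from the division plane
                offset = best_axis * (mother.radii.max() * 0.8 + 0.5)
                for sgn in (+1.0, -1.0):
                    pos = np.clip(mother.pos + sgn * offset, mother.radii * 0.8 + 1, extent - mother.radii * 0.8 - 1)
                    d = _Cell(
                        next_label,
                        pos,
                        mother.radii * 0.8,
                        rng.normal(scale=cfg.drift, size=len(extent)),
                        begin=t,
                        parent=mother.label,
                    )
                    intensity[d.label] = rng.uniform(0.5, 1.0)
                    cells.append(d)
                    next_label += 1
            _separate(cells, extent)
        frame = _paint(cells, cfg.shape)
        frames.append(frame)
        img = np.zeros(cfg.shape, dtype=float)
        for c in cells:
            img[frame == c.label] = intensity[c.label]
        img = ndimage.gaussian_filter(img, sigma=1.0)
        img += rng.normal(scale=cfg.noise_sigma, size=cfg.shape)
        raw.append(img)

    for c in cells:
        c.end = cfg.n_frames - 1
        finished.append(c)
    lineage = [
        LineageRecord(c.label, c.begin, int(c.end), c.parent)
        for c in sorted(finished, key=lambda c: c.label)
    ]
    return raw, LabeledSequence(frames, lineage)


#: named presets for the fixture CLI
PRESETS: dict[str, SimulationConfig] = {
    "sparse": SimulationConfig(n_cells=8, n_frames=20),
    "dense": SimulationConfig(n_cells=25, n_frames=20, radius_range=(3.0, 5.0)),
    "mitotic": SimulationConfig(n_cells=12, n_frames=30, n_divisions=3),
    "3d": SimulationConfig(
        shape=(6, 96, 96), n_cells=8, n_frames=12, radius_range=(2.5, 4.0), displacement=1.0
    ),
}
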