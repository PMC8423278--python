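# Methods

`graphtrack` is a tracking-by-detection pipeline for time-lapse microscopy.
It takes a per-frame instance segmentation (integer label images, 0 =
background, 2D or 3D) and, optionally, the raw intensity images, and
produces a cell lineage in which every track has at most one predecessor
and at most two successors (two successors model a division). Along the
way it detects and repairs three kinds of segmentation error: false
negatives (missing masks), over-segmentation (one cell cut into several
masks) and under-segmentation (several cells fused into one mask).

The method rests on two assumptions: cell movement between frames is small
compared to the image size, and the majority of masks segment single cells
correctly. All costs are purely positional — no appearance or texture
features and no learned weights — so the tracker runs on new data without
training.

## Stage 1 — tracklet step (candidate discovery)

Each segmented object gets an axis-aligned region of interest (ROI) whose
per-axis extent is twice the mean bounding-box extent over all objects of
the sequence. The ROI is propagated up to `delta_t` frames forward; at each
step its center is displaced by a translation estimated between raw-image
crops by phase correlation (integer-pixel peak of the inverse cross-power
spectrum). Objects whose bounding box intersects the propagated ROI become
matching candidates. With no raw images the displacement is zero.

Numerical choices: the cross-power spectrum is only softly whitened
(normalized by `|C| + 0.1·mean|C|`) after mean subtraction — full `1/|C|`
whitening is extremely noise-sensitive on the small crops used here and
produced essentially random shifts at realistic noise levels; the softened
version still returns exact integer shifts for pure translations.
Constant crops, empty crops, or crops clipped to nothing at the image edge
fall back to zero displacement. Shifts larger than half the crop extent
alias and cannot be recovered; the ROI must therefore comfortably exceed
the largest plausible per-frame displacement.

## Stage 2 — matching (coupled minimum-cost flow)

Objects and their candidates become a typed directed graph: object nodes
(one per mask), skip nodes (`delta_t − 1` per object, letting a track
bridge missing detections), split nodes (mitosis or over-segmentation),
merge nodes (under-segmentation), appearance and disappearance nodes, and
a source/sink pair. Integer flow variables on the edges are optimized by
an ILP: one unit of flow is forced through every object node, flow is
conserved everywhere, and ordering inequalities force the flow through any
merge or split node to be zero or at least two. Mitosis is distinguished
from over-segmentation by pairwise-coupled daughter variables: a coupled
pair carries one unit to each of two daughters and pays the mitosis cost,
while plain split-node flow pays the over-segmentation cost, and a
mutual-exclusion constraint keeps a split node from doing both. At most
ten candidate daughter pairs are kept per object (ranked by mitosis cost,
ties broken by daughter id).

Costs are Euclidean distances between (displacement-propagated) centroids;
for split and merge edges the distance is measured from the propagated
interior mask points — the set of pixels whose distance-transform value is
at least half the mask maximum, subsampled to at most 50 — to the
counterpart centroid, which stays small when a correctly segmented cell
meets a merged mask whose centroid is far away. Appearance and
disappearance cost the distance to the nearest image border, capped at
`alpha` (the largest edge of the default ROI). Implausible configurations
(a daughter pair farther apart than 1.5× the mother's bounding-box
diagonal, a split/merge counterpart outside the propagated bounding box)
get the prohibitive constant `theta = 1000·alpha`, and such edges are
pruned before solving. The mitosis cost deliberately uses the mother's
unpropagated position: a crop containing one mother at `t` and two
daughters at `t+1` gives meaningless phase-correlation shifts.

Long sequences are solved on overlapping windows (default 10 frames,
overlap `max(delta_t, 2)`) and stitched by object identity; the earlier
window is authoritative up to the overlap midpoint. Chains of one-to-one
links become tracks; division, over-segmentation and merge links become
predecessor/successor edges between tracks.

The ILP is solved exactly with HiGHS via `scipy.optimize.milp`. On graphs
small enough for exhaustive enumeration of all feasible integer flows, the
ILP objective is verified to equal the brute-force minimum (see
`tests/oracles.py`).

## Stage 3a — untangling

After matching, a track may have several predecessors or more than two
successors. Three operations repair this: remove a predecessor–successor
edge, split a track into several parallel tracks, or merge a set of tracks
into one. Sets of tracks are mergeable when they share the same
predecessors and successors, or share successors while predecessor-less
members begin after the predecessor-bearing member starts, or the mirror
condition on the successor side. All subsets of size ≥ 2 of each such
group are admitted (group size capped at 12 for subset enumeration).

A per-track predecessor inequality and successor inequality couple the
operation variables (binary merges and edge removals, integer splits;
a split variable's value is the number of *added* parts, so splitting into
K parts has value K − 1 and costs `span·(K−1)`, exactly mirroring the
merge cost `span·(N−1)`). Each track may join at most one merged set, and
edge removals within a merged set are coupled so the members drop a shared
link together or not at all. Costs: an edge removal costs
`gamma = 2·ceil(q30(track spans) · q99(per-track link counts))`, where a
track's link count is its number of predecessor plus successor links;
merges and splits cost temporal span times the number of tracks added or
absorbed. The minimizing operation set is found by ILP (ties broken toward
fewer operations); on graphs with few tracks the objective is verified
against exhaustive search over all valid operation combinations.

One caveat of the printed inequality system: a track with exactly three
successors, each having only that track as predecessor, satisfies its
successor inequality at zero operations (right-hand side
`−3 + 2·1 + 1 = 0`), so the ILP alone does not force a fix. A
deterministic repair pass therefore follows: any remaining track with more
than two successors is split into `ceil(|S|/2)` parts, and any remaining
multi-predecessor track keeps only its nearest predecessor. In practice
the repair pass is idle on all but rare mixed-error constellations.

Applying the operations: merges concatenate the member masks per frame;
splits compute per frame as many seed points as parts — the highest
distance-transform local maxima under a greedy minimum-separation rule —
and assign every mask pixel to its nearest seed. Part identity is kept
stable over time by matching part centroids between consecutive frames
(Hungarian assignment), and predecessor/successor links are reattached to
the nearest part, at most one predecessor and two successors per part.
Pixel sets are conserved exactly: splitting and merging never create or
destroy a mask pixel.

## Stage 3b — false-negative correction

For every track gap (missing frames strictly inside the span) the last
mask before the gap is translated — shape unchanged — to centroid
positions linearly interpolated between the two anchor masks, rounded
half-up per axis. Gaps at a track's start or end have only one anchor and
are left alone. Inserted masks may overlap existing ones; every conflicted
pixel goes to the track whose centroid in that frame is closest, ties to
the lower track id, and pixels outside overlap regions are never touched.

## Segmentation-error simulator

The simulator degrades a ground-truth sequence so the corrector can be
tested against a known answer. For a target fraction n% of all masks:

- **fn** removes `floor(n%·total)` masks drawn uniformly without
  replacement.
- **over** splits that many masks in two by a random hyperplane through
  the centroid (redrawn if a side would be empty; median split as a last
  resort); both parts get fresh labels.
- **under** repeatedly samples a pair of neighboring masks and merges them
  via morphological closing (ball radius = half the boundary gap) until n%
  of masks are merged; chains of more than two cells are allowed. Pairs
  are drawn with inverse-distance weights, where distance is the *boundary
  gap* between the masks, and only pairs whose gap is at most one mean
  cell radius are eligible (within the centroid-distance pool bound of 2×
  the ROI edge). Rationale: a segmentation algorithm merges masks whose
  borders touch; welding cells across tens of background pixels produces
  blobs no segmenter would emit and makes the ground truth unrecoverable
  in principle. The merged mask never overwrites other labels.
- **mixed** applies the three equally on disjoint mask selections, with
  the integer remainder of the three-way division going to fn.

All simulators are pure functions of (sequence, spec); a benchmark grid
over sequences × fractions × error types × runs derives one distinct seed
per item (the standard design — 4 sequences, fractions 1/2/5/10/20%, four
error types, five runs — enumerates 400 data sets).

## Evaluation

SEG is the mean Jaccard index over ground-truth masks, where a result mask
matches only if it covers strictly more than half the ground-truth mask
(unmatched masks score 0). TRA and DET are simplified acyclic-graph-edit
scores: ground truth and result lineages become graphs (nodes = masks,
edges = temporal links or parent links), nodes are matched by the same
>50% rule, and the weighted count of operations needed to build the ground
truth from the result — add node 10, split node 5, delete node 1, add
edge 1.5, delete edge 1, change edge semantics 1 — is normalized by the
cost of building the ground-truth graph from nothing; DET uses node
penalties only. The weights follow the published AOGM convention; this
implementation is deliberately simplified and does not aim for bit-exact
agreement with the official benchmark executable.

## Synthetic data generator

The fixture generator emulates fluorescence time-lapse recordings:
elliptical (2D) or ellipsoidal (thin-3D) cells with per-axis radii drawn
from `radius_range`, isotropic Gaussian steps (`displacement`, default
1.5 px on a 128² image) plus a constant per-cell drift, reflective
borders, and a soft pairwise separation pass that keeps masks disjoint.
Raw images are smoothed per-cell intensities plus Gaussian noise. Scheduled
divisions replace a mother by two adjacent daughters — each one daughter
radius from the division plane, symmetric about the mother, along the
candidate axis with the most clearance from other cells — and daughters
start the frame after the mother ends, so the lineage is a forest.

Two identifiability rules are deliberate: a scheduled division whose
mother sits within two cell radii of the border is handed to the most
interior cell (a border division is indistinguishable, from positions
alone, from one daughter leaving the field while another cell enters), and
daughters are placed adjacent (widely separated daughters are
geometrically confusable with unrelated appearances). These rules make
"perfect input ⇒ exact lineage recovery" a well-posed test.

What the generator does **not** emulate: realistic cell texture and shape
variability, photobleaching, uneven illumination, segmentation-boundary
noise, densely packed colonies, and cell death. Passing tests on this
fixture therefore demonstrate the correctness of the graph machinery and
the error-correction logic under the method's stated assumptions, not
performance on real microscopy data.

Known limitation (observed on the fixture, inherent to positional costs):
when an unrelated cell passes within about a cell diameter of a division,
the matching can weave it into the division (the same ambiguity class as
two cells swapping positions, which positional costs cannot resolve). In a
12-seed survey of the default mitotic fixture, 9 of 12 seeds recover the
ground-truth lineage exactly; the three misses are all of this kind.

## Defaults

| parameter | default | meaning |
| --- | --- | --- |
| `delta_t` | 3 frames | maximum gap bridged by skip nodes |
| ROI size | 2× mean mask extent per axis | candidate search region |
| `alpha` | largest ROI edge (px) | appear/disappear cost cap |
| `theta` | 1000·alpha | prohibitive cost / pruning threshold |
| `window_length` | 10 frames | ILP window |
| `window_overlap` | `max(delta_t, 2)` | stitching overlap |
| `N_max` | 10 | daughter pairs kept per object |
| `gamma` | `2·ceil(q30(spans)·q99(links))` | edge-removal cost |

Problem sizes used by the test-suite fixtures (10–30 frames, 8–15 cells,
128² images) were chosen so that each matching window ILP has a few
thousand variables and the whole suite exercises every stage, including
windowed solving and all four error types, on commodity hardware.
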