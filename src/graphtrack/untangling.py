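"""Untangling step: resolve many-to-one / one-to-many track links.

After matching, a track may have several predecessors (under-segmentation)
or more than two successors (over-segmentation). The untangling step selects
a minimum-cost combination of three operations — remove a predecessor/
successor edge, split a track into several tracks, merge a set of tracks —
by solving an integer linear program, then applies the operations to the
tracks and their masks so that every track ends up with at most one
predecessor and at most two successors (two = mitosis).

Mergeable sets of tracks must (a) share the same predecessors and
successors, or (b) share the same successors where predecessor-less members
begin after the predecessor-bearing member starts, or (c) share the same
predecessors where successor-less members end before the successor-bearing
member ends.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import ceil

import numpy as np
from scipy import ndimage, sparse
from scipy.optimize import Bounds, LinearConstraint, linear_sum_assignment, milp

from .tracks import Track, TrackingGraph

# variable keys: ("s", n) split, ("e", p, n) edge removal, ("m", frozenset) merge
VarKey = tuple

#: cap on the size of a maximal mergeable group for subset enumeration
_MAX_GROUP = 12


@dataclass
class Inequality:
    """One constraint ``sum(coeffs * z) <= rhs``."""

    coeffs: dict[VarKey, float]
    rhs: float

    def coefficient(self, key: VarKey) -> float:
        return self.coeffs.get(key, 0.0)


@dataclass
class UntanglingProblem:
    graph: TrackingGraph
    merge_sets: list[frozenset[int]]
    variables: list[VarKey]
    costs: dict[VarKey, float]
    upper: dict[VarKey, int]
    pred_inequalities: dict[int, Inequality]
    succ_inequalities: dict[int, Inequality]
    extra_constraints: list[Inequality] = field(default_factory=list)
    gamma: float = 0.0

    def all_inequalities(self) -> list[Inequality]:
        return (
            list(self.pred_inequalities.values())
            + list(self.succ_inequalities.values())
            + self.extra_constraints
        )


@dataclass
class UntanglingOps:
    merges: list[frozenset[int]] = field(default_factory=list)
    splits: dict[int, int] = field(default_factory=dict)  # track -> parts added
    edge_removals: list[tuple[int, int]] = field(default_factory=list)
    objective: float = 0.0

    def count(self) -> int:
        return len(self.merges) + len(self.edge_removals) + sum(self.splits.values())


# ---------------------------------------------------------------------------
# mergeable sets
# ---------------------------------------------------------------------------


def _mergeable_subset(graph: TrackingGraph, subset: tuple[int, ...]) -> bool:
    tracks = [graph.tracks[n] for n in subset]
    # successor-shared route (conditions a and b)
    succs = {frozenset(t.successors) for t in tracks}
    preds = {frozenset(t.predecessors) for t in tracks}
    if len(succs) == 1 and next(iter(succs)):
        with_pred = [t for t in tracks if t.predecessors]
        pred_sets = {frozenset(t.predecessors) for t in with_pred}
        if len(pred_sets) <= 1:
            if not with_pred:
                return True  # all predecessor-less, same successors
            anchor_begin = min(t.begin for t in with_pred)
            if all(t.begin > anchor_begin for t in tracks if not t.predecessors):
                return True
    # predecessor-shared route (conditions a and c)
    if len(preds) == 1 and next(iter(preds)):
        with_succ = [t for t in tracks if t.successors]
        succ_sets = {frozenset(t.successors) for t in with_succ}
        if len(succ_sets) <= 1:
            if not with_succ:
                return True
            anchor_end = max(t.end for t in with_succ)
            if all(t.end < anchor_end for t in tracks if not t.successors):
                return True
    return False


def enumerate_mergeable_sets(graph: TrackingGraph) -> list[frozenset[int]]:
    """All candidate sets of >= 2 tracks that may be merged into one track.

    Maximal groups are found by pooling tracks with a common (non-empty)
    successor or predecessor set; every subset of size >= 2 of a pool that
    satisfies one of the merge conditions is emitted.
    """
    pools: dict[tuple[str, frozenset[int]], set[int]] = {}
    for tid, tr in graph.tracks.items():
        if tr.successors:
            pools.setdefault(("S", frozenset(tr.successors)), set()).add(tid)
        if tr.predecessors:
            pools.setdefault(("P", frozenset(tr.predecessors)), set()).add(tid)
    found: set[frozenset[int]] = set()
    for pool in pools.values():
        members = sorted(pool)[:_MAX_GROUP]
        for size in range(2, len(members) + 1):
            for subset in itertools.combinations(members, size):
                fs = frozenset(subset)
                if fs not in found and _mergeable_subset(graph, subset):
                    found.add(fs)
    return sorted(found, key=lambda s: (len(s), sorted(s)))


# ---------------------------------------------------------------------------
# ILP construction
# ---------------------------------------------------------------------------


def untangling_gamma(graph: TrackingGraph) -> float:
    """Edge-removal cost gamma = 2 * ceil(q30(track spans) * q99(link counts)).

    The link count of a track is its number of predecessor plus successor
    links. Gamma defines the cut-off where removing a wrong link becomes
    cheaper than merging or splitting tracks.
    """
    spans = np.array([tr.span for tr in graph.tracks.values()], dtype=float)
    links = np.array(
        [len(tr.predecessors) + len(tr.successors) for tr in graph.tracks.values()],
        dtype=float,
    )
    if len(spans) == 0:
        return 1.0
    q_span = float(np.quantile(spans, 0.3))
    q_links = float(np.quantile(links, 0.99))
    return max(2.0 * ceil(q_span * q_links), 1.0)


def build_untangling_ilp(graph: TrackingGraph) -> UntanglingProblem:
    """Construct the untangling ILP: one predecessor inequality and one
    successor inequality per track, a one-merge-per-track constraint, and
    edge-removal coupling constraints for merged sets."""
    merge_sets = enumerate_mergeable_sets(graph)
    tracks = graph.tracks

    sets_containing: dict[int, list[frozenset[int]]] = {n: [] for n in tracks}
    for r in merge_sets:
        for n in r:
            sets_containing[n].append(r)

    def w_set(n: int) -> set[int]:
        # all tracks mergeable with n, including n itself
        w = {n}
        for r in sets_containing[n]:
            w |= r
        return w

    variables: list[VarKey] = []
    costs: dict[VarKey, float] = {}
    upper: dict[VarKey, int] = {}
    gamma = untangling_gamma(graph)

    for n, tr in sorted(tracks.items()):
        key = ("s", n)
        variables.append(key)
        costs[key] = float(tr.span)
        upper[key] = max(len(tr.predecessors), len(tr.successors), 1)
        for p in sorted(tr.predecessors):
            ekey = ("e", p, n)
            variables.append(ekey)
            costs[ekey] = gamma
            upper[ekey] = 1
    for r in merge_sets:
        key = ("m", r)
        variables.append(key)
        span = max(tracks[m].end for m in r) - min(tracks[m].begin for m in r) + 1
        costs[key] = float(span * (len(r) - 1))
        upper[key] = 1

    pred_ineqs: dict[int, Inequality] = {}
    succ_ineqs: dict[int, Inequality] = {}

    for n, tr in sorted(tracks.items()):
        p_n = frozenset(tr.predecessors)
        s_n = frozenset(tr.successors)
        w_n = w_set(n)

        # --- predecessor inequality ---
        coeffs: dict[VarKey, float] = {}

        def acc(key: VarKey, val: float, coeffs=None) -> None:
            if val:
                coeffs[key] = coeffs.get(key, 0.0) + val

        for r in sets_containing[n]:  # merge tracks (with n in the set)
            p_nr = sum(1 for m in r if frozenset(tracks[m].predecessors) == p_n)
            acc(("m", r), p_nr - 1, coeffs)
        for w in w_n:  # split tracks
            acc(("s", w), -1.0, coeffs)
            for p in tracks[w].predecessors:  # remove edges to predecessors
                acc(("e", p, w), -1.0, coeffs)
        for p in sorted(p_n):  # split predecessors
            acc(("s", p), 1.0, coeffs)
        for q in merge_sets:  # merge predecessors
            if q & p_n:
                s_qn = sum(1 for m in q if n in tracks[m].successors)
                acc(("m", q), min(0, -s_qn + 1), coeffs)
        succ_union = set().union(*(tracks[p].successors for p in p_n)) if p_n else set()
        rhs = -len(p_n) + max(1, len(succ_union))
        pred_ineqs[n] = Inequality(coeffs, float(rhs))

        # --- successor inequality ---
        coeffs = {}
        for r in sets_containing[n]:
            s_nr = sum(1 for m in r if frozenset(tracks[m].successors) == s_n)
            acc(("m", r), s_nr - 1, coeffs)
        for w in w_n:
            acc(("s", w), -1.0, coeffs)
            for v in tracks[w].successors:
                acc(("e", w, v), -1.0, coeffs)
        for v in sorted(s_n):
            acc(("s", v), 1.0, coeffs)
        for q in merge_sets:
            if q & s_n:
                p_qn = sum(1 for m in q if n in tracks[m].predecessors)
                acc(("m", q), min(0, -p_qn + 1), coeffs)
        pred_union = set().union(*(tracks[v].predecessors for v in s_n)) if s_n else set()
        rhs = -len(s_n) + 2 * len(pred_union) + 1
        succ_ineqs[n] = Inequality(coeffs, float(rhs))

    extra: list[Inequality] = []
    # each track merged with at most one set
    for n in sorted(tracks):
        if sets_containing[n]:
            extra.append(
                Inequality({("m", r): 1.0 for r in sets_containing[n]}, 1.0)
            )
    # coupled edge removals inside a merged set
    for r in merge_sets:
        for n, v in itertools.combinations(sorted(r), 2):
            shared_p = tracks[n].predecessors & tracks[v].predecessors
            for p in sorted(shared_p):
                extra.append(Inequality({("e", p, n): 1.0, ("e", p, v): -1.0, ("m", r): 1.0}, 1.0))
                extra.append(Inequality({("e", p, n): -1.0, ("e", p, v): 1.0, ("m", r): 1.0}, 1.0))
            shared_s = tracks[n].successors & tracks[v].successors
            for u in sorted(shared_s):
                extra.append(Inequality({("e", n, u): 1.0, ("e", v, u): -1.0, ("m", r): 1.0}, 1.0))
                extra.append(Inequality({("e", n, u): -1.0, ("e", v, u): 1.0, ("m", r): 1.0}, 1.0))

    return UntanglingProblem(
        graph=graph,
        merge_sets=merge_sets,
        variables=variables,
        costs=costs,
        upper=upper,
        pred_inequalities=pred_ineqs,
        succ_inequalities=succ_ineqs,
        extra_constraints=extra,
        gamma=gamma,
    )


def solve_untangling(problem: UntanglingProblem) -> UntanglingOps:
    """Minimize the untangling objective; ties are broken toward fewer
    operations (then earlier variables) by an epsilon-weighted secondary
    objective. The reported objective uses the true costs."""
    variables = problem.variables
    if not variables:
        return UntanglingOps()
    v_index = {k: i for i, k in enumerate(variables)}
    n = len(variables)
    eps = 1e-6 / max(n, 1)
    cost = np.array(
        [problem.costs[k] + eps * (1.0 + i * 1e-3) for i, k in enumerate(variables)]
    )
    lo = np.zeros(n)
    hi = np.array([problem.upper[k] for k in variables], dtype=float)

    ineqs = problem.all_inequalities()
    a_mat = sparse.lil_matrix((len(ineqs), n))
    ub = np.empty(len(ineqs))
    for r, ineq in enumerate(ineqs):
        for key, c in ineq.coeffs.items():
            if key in v_index:
                a_mat[r, v_index[key]] = c
        ub[r] = ineq.rhs
    res = milp(
        c=cost,
        constraints=LinearConstraint(a_mat.tocsr(), -np.inf, ub),
        integrality=np.ones(n),
        bounds=Bounds(lo, hi),
    )
    if not res.success:
        raise RuntimeError(f"untangling ILP failed: {res.message}")
    x = np.round(res.x).astype(int)
    ops = UntanglingOps()
    for k, key in enumerate(variables):
        if x[k] <= 0:
            continue
        if key[0] == "m":
            ops.merges.append(key[1])
        elif key[0] == "s":
            ops.splits[key[1]] = int(x[k])
        else:
            ops.edge_removals.append((key[1], key[2]))
    ops.objective = float(sum(problem.costs[k] * x[v_index[k]] for k in variables))
    return ops


# ---------------------------------------------------------------------------
# applying operations to tracks and masks
# ---------------------------------------------------------------------------


def _split_seeds(coords: np.ndarray, k: int) -> np.ndarray:
    """``k`` seed points for a mask: highest distance-transform local maxima
    with greedy minimum-separation selection; farthest-point fallback."""
    if len(coords) <= k:
        return coords[np.lexsort(coords.T[::-1])][:k]
    lo = coords.min(axis=0)
    shape = tuple(coords.max(axis=0) - lo + 1)
    mask = np.zeros(shape, dtype=bool)
    mask[tuple((coords - lo).T)] = True
    dt = ndimage.distance_transform_edt(np.pad(mask, 1))[
        tuple(slice(1, -1) for _ in shape)
    ]
    order = np.argsort(dt[tuple((coords - lo).T)])[::-1]
    ranked = coords[order]
    min_sep = max(np.max(shape) / (2.0 * k), 1.0)
    seeds = [ranked[0]]
    for c in ranked[1:]:
        if len(seeds) == k:
            break
        if min(np.linalg.norm(c - s) for s in seeds) >= min_sep:
            seeds.append(c)
    while len(seeds) < k:  # farthest-point completion
        d = np.min(
            np.linalg.norm(coords[:, None, :] - np.array(seeds)[None], axis=2), axis=1
        )
        seeds.append(coords[int(np.argmax(d))])
    return np.array(seeds)


def _split_track(graph: TrackingGraph, n: int, parts: int, log: list[str]) -> list[int]:
    """Split track ``n`` into ``parts`` tracks by nearest-seed partition of
    each frame's mask; parts are kept temporally consistent by matching part
    centroids between consecutive frames. Returns the new track ids."""
    tr = graph.tracks[n]
    new_ids = [n] + [graph.next_track_id() + i for i in range(parts - 1)]
    part_masks: list[dict[int, np.ndarray]] = [dict() for _ in range(parts)]
    prev_centroids: np.ndarray | None = None
    for t in sorted(tr.masks):
        coords = tr.masks[t]
        k = min(parts, len(coords))
        if k < parts:
            log.append(f"split track {n}: frame {t} has {len(coords)} px < {parts} parts")
        seeds = _split_seeds(coords, k)
        assign = np.argmin(
            np.linalg.norm(coords[:, None, :] - seeds[None], axis=2), axis=1
        )
        groups = [coords[assign == j] for j in range(k)]
        groups = [g for g in groups if len(g)]
        cents = np.array([g.mean(axis=0) for g in groups])
        if prev_centroids is None or len(groups) != len(prev_centroids):
            order = np.arange(len(groups))
        else:
            # keep part identity stable over time
            cost = np.linalg.norm(prev_centroids[:, None] - cents[None], axis=2)
            row, col = linear_sum_assignment(cost)
            order = np.empty(len(groups), dtype=int)
            order[row] = col
        for slot, j in enumerate(order):
            part_masks[slot][t] = groups[j]
        prev_centroids = cents[order]
    preds = sorted(tr.predecessors)
    succs = sorted(tr.successors)
    for p in preds:
        graph.remove_edge(p, n)
    for s in succs:
        graph.remove_edge(n, s)
    del graph.tracks[n]
    created = []
    for tid, masks in zip(new_ids, part_masks):
        if not masks:
            continue
        graph.tracks[tid] = Track(tid, masks)
        created.append(tid)
    # reconnect predecessors: each part takes at most one
    if preds:
        firsts = np.array([graph.tracks[tid].centroid(graph.tracks[tid].begin) for tid in created])
        lasts = np.array([graph.tracks[p].centroid(graph.tracks[p].end) for p in preds])
        cost = np.linalg.norm(lasts[:, None] - firsts[None], axis=2)
        row, col = linear_sum_assignment(cost)
        for i, j in zip(row, col):
            graph.add_edge(preds[i], created[j])
        if len(preds) > len(created):
            log.append(f"split track {n}: {len(preds) - len(created)} predecessor links dropped")
    # reconnect successors: each part takes at most two
    if succs:
        slots = [tid for tid in created for _ in range(2)]
        ends = np.array([graph.tracks[tid].centroid(graph.tracks[tid].end) for tid in slots])
        begins = np.array([graph.tracks[s].centroid(graph.tracks[s].begin) for s in succs])
        cost = np.linalg.norm(begins[:, None] - ends[None], axis=2)
        row, col = linear_sum_assignment(cost)
        for i, j in zip(row, col):
            graph.add_edge(slots[j], succs[i])
        if len(succs) > len(slots):
            log.append(f"split track {n}: {len(succs) - len(slots)} successor links dropped")
    return created


def _merge_tracks(graph: TrackingGraph, r: frozenset[int]) -> int:
    """Merge the tracks of ``r`` into one track (pixel union per frame)."""
    keep = min(r)
    members = [graph.tracks[m] for m in sorted(r)]
    masks: dict[int, np.ndarray] = {}
    for tr in members:
        for t, coords in tr.masks.items():
            masks[t] = coords if t not in masks else np.vstack([masks[t], coords])
    preds = set().union(*(tr.predecessors for tr in members)) - r
    succs = set().union(*(tr.successors for tr in members)) - r
    for m in sorted(r):
        tr = graph.tracks[m]
        for p in list(tr.predecessors):
            graph.remove_edge(p, m)
        for s in list(tr.successors):
            graph.remove_edge(m, s)
        del graph.tracks[m]
    graph.tracks[keep] = Track(keep, masks)
    for p in preds:
        graph.add_edge(p, keep)
    for s in succs:
        graph.add_edge(keep, s)
    return keep


def apply_operations(
    graph: TrackingGraph, ops: UntanglingOps, log: list[str] | None = None
) -> TrackingGraph:
    """Apply edge removals, merges and splits (in that order) to a copy of
    the graph. Pixel sets are conserved: merges concatenate masks per frame,
    splits partition them by nearest seed point."""
    log = log if log is not None else []
    out = graph.copy()
    for p, n in ops.edge_removals:
        if n in out.tracks and p in out.tracks:
            out.remove_edge(p, n)
    for r in ops.merges:
        present = frozenset(m for m in r if m in out.tracks)
        if len(present) >= 2:
            _merge_tracks(out, present)
    for n, added in sorted(ops.splits.items()):
        if n in out.tracks:
            _split_track(out, n, added + 1, log)
    return out


def _repair(graph: TrackingGraph, log: list[str]) -> None:
    """Deterministic cleanup for residual lineage violations the inequality
    system does not force out (e.g. a track with exactly three successors,
    which satisfies the successor inequality at zero operations)."""
    changed = True
    while changed:
        changed = False
        for n in sorted(graph.tracks):
            tr = graph.tracks.get(n)
            if tr is None:
                continue
            if len(tr.successors) > 2:
                parts = ceil(len(tr.successors) / 2)
                log.append(f"repair: splitting track {n} into {parts} parts ({len(tr.successors)} successors)")
                _split_track(graph, n, parts, log)
                changed = True
                break
            if len(tr.predecessors) > 1:
                # keep the predecessor whose end centroid is closest
                p0 = tr.centroid(tr.begin)
                best = min(
                    sorted(tr.predecessors),
                    key=lambda p: float(
                        np.linalg.norm(graph.tracks[p].centroid(graph.tracks[p].end) - p0)
                    ),
                )
                for p in sorted(tr.predecessors - {best}):
                    log.append(f"repair: removing extra predecessor edge {p}->{n}")
                    graph.remove_edge(p, n)
                changed = True
                break


def untangle(graph: TrackingGraph, log: list[str] | None = None) -> tuple[TrackingGraph, UntanglingOps]:
    """Run the full untangling step: enumerate mergeable sets, build and
    solve the ILP, apply the selected operations, and clean up any residual
    violations. The returned graph satisfies |P_n| <= 1 and |S_n| <= 2."""
    log = log if log is not None else []
    problem = build_untangling_ilp(graph)
    ops = solve_untangling(problem)
    out = apply_operations(graph, ops, log)
    _repair(out, log)
    if not out.is_valid_lineage():
        raise AssertionError("untangling left an invalid lineage graph")
    return out, ops
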