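"""Matching step: typed flow graph, position-based costs, and the coupled
minimum-cost-flow ILP linking segmented objects into a preliminary
:class:`~graphtrack.tracks.TrackingGraph`.

Node types
----------
``q-``/``q+``   source / sink
``o_{i,t}``     one per segmented object
``x_{i,t+k}``   skip nodes (k = 1 .. delta_t-1), modelling false negatives
``s_{i,t+1}``   split nodes, modelling mitosis or over-segmentation
``m_{i}``       merge nodes (for object i at t, sitting at t-1), modelling
                under-segmentation
``a_t``/``d_t`` appearance at t+1 / disappearance at t-1

Flow of one unit is forced through every object node; merge and split nodes
carry either zero flow or at least two units, which is what lets a single
mask absorb several objects (under-segmentation) or one object emit several
masks (over-segmentation / mitosis). Mitosis is distinguished from
over-segmentation by pairwise-coupled daughter flow variables with their own
cost; a split node models one or the other, never both.

Long image sequences are solved on overlapping time windows and stitched by
object identity, the earlier window being authoritative up to the overlap
midpoint.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .core_io import SegmentedObject
from .tracklet import CandidateMap
from .tracks import Track, TrackingGraph

OID = tuple[int, int]  # (frame, label)
Node = tuple


@dataclass(frozen=True)
class MatchingConfig:
    """Parameters of the matching step.

    ``alpha`` is the appear/disappear threshold (pixels), derived from the
    largest edge of the default ROI; ``theta = 1000 * alpha`` is the large
    constant marking implausible links. ``delta_t`` is the maximum temporal
    gap a track may bridge via skip nodes.
    """

    alpha: float
    delta_t: int = 3
    window_length: int = 10
    window_overlap: int | None = None
    n_max_pairs: int = 10
    prune_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.delta_t < 1:
            raise ValueError("delta_t must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def theta(self) -> float:
        return 1000.0 * self.alpha

    @property
    def overlap(self) -> int:
        ov = self.window_overlap if self.window_overlap is not None else self.delta_t
        return max(ov, 2)

    @property
    def prune_at(self) -> float:
        return self.prune_threshold if self.prune_threshold is not None else self.theta


@dataclass
class EdgeVar:
    cost: float = 0.0
    capacity: int = 1
    lower: int = 0


@dataclass
class PairVar:
    """Coupled mitosis flow variable: one unit on both edges (s -> o_j) and
    (s -> o_l). The per-edge cost is ``cost``; the variable contributes
    ``2 * cost`` to the objective."""

    split: Node
    j: OID
    l: OID
    cost: float = 0.0


@dataclass
class FlowGraph:
    window: tuple[int, int]
    shape: tuple[int, ...]
    objects: dict[OID, SegmentedObject]
    objects_by_frame: dict[int, list[OID]]
    edges: dict[tuple[Node, Node], EdgeVar]
    pairs: list[PairVar]
    cfg: MatchingConfig
    candidates: CandidateMap
    displacements: dict = field(default_factory=dict)

    def n_objects(self, t: int) -> int:
        return len(self.objects_by_frame.get(t, []))

    def out_edges(self, node: Node) -> list[tuple[Node, Node]]:
        return [e for e in self.edges if e[0] == node]

    def in_edges(self, node: Node) -> list[tuple[Node, Node]]:
        return [e for e in self.edges if e[1] == node]


SRC: Node = ("src",)
SNK: Node = ("snk",)


def _cand(candidates: CandidateMap, oid: OID, tp: int) -> set[int]:
    t, lab = oid
    return candidates.get((lab, t), {}).get(tp, set())


def build_flow_graph(
    objects_per_frame: dict[int, list[SegmentedObject]],
    candidates: CandidateMap,
    cfg: MatchingConfig,
    window: tuple[int, int],
    shape: tuple[int, ...],
) -> FlowGraph:
    """Construct the typed flow graph for one time window ``[t0, t1]``.

    Split nodes connect only to the object nodes their parent (object or
    skip) node connects to; merge nodes connect only from the nodes their
    object node is connected from. Capacities follow the flow model: unit
    capacity on edges touching object/skip nodes, count-dependent capacity
    on merge-to-delete, appear-to-split and delete-to-sink edges.
    """
    t0, t1 = window
    if t1 - t0 + 1 < 2:
        raise ValueError("window must span at least 2 frames")
    objects: dict[OID, SegmentedObject] = {}
    by_frame: dict[int, list[OID]] = {}
    for t in range(t0, t1 + 1):
        for obj in objects_per_frame.get(t, []):
            oid = (t, obj.object_id)
            objects[oid] = obj
            by_frame.setdefault(t, []).append(oid)
    for (lab, t), frames in candidates.items():
        if t0 <= t <= t1:
            for tp, labs in frames.items():
                for lab2 in labs:
                    if tp <= t1 and (tp, lab2) not in objects and (t, lab) in objects:
                        raise ValueError(f"candidate {(tp, lab2)} references unknown object")

    edges: dict[tuple[Node, Node], EdgeVar] = {}
    pairs: list[PairVar] = []

    def add(u: Node, v: Node, capacity: int = 1, lower: int = 0) -> None:
        edges[(u, v)] = EdgeVar(capacity=capacity, lower=lower)

    # appearance / disappearance backbone
    for t in range(t0, t1):
        n_next = len(by_frame.get(t + 1, []))
        add(SRC, ("a", t), capacity=n_next, lower=n_next)  # required flow (|O_{t+1}|)
        add(("a", t), ("d", t + 1), capacity=max(n_next, 1))
        for oid in by_frame.get(t + 1, []):
            add(("a", t), ("o", oid))
    for t in range(t0 + 1, t1 + 1):
        cap = sum(len(by_frame.get(tp, [])) for tp in range(t - cfg.delta_t, t + 1))
        add(("d", t), SNK, capacity=max(cap, 1))

    # object, skip and movement edges
    for t in range(t0, t1 + 1):
        for oid in by_frame.get(t, []):
            if t == t0:
                add(SRC, ("o", oid))
            if t == t1:
                add(("o", oid), SNK)
            else:
                add(("o", oid), ("d", t + 1))
                for lab2 in _cand(candidates, oid, t + 1):
                    if (t + 1, lab2) in objects:
                        add(("o", oid), ("o", (t + 1, lab2)))
            # skip chain x_{i,t+1} .. x_{i,t+delta_t-1}
            prev: Node = ("o", oid)
            for tau in range(t + 1, min(t + cfg.delta_t, t1 + 1)):
                xnode: Node = ("x", oid, tau)
                add(prev, xnode)
                if tau == t1:
                    add(xnode, SNK)
                else:
                    for lab2 in _cand(candidates, oid, tau + 1):
                        if (tau + 1, lab2) in objects:
                            add(xnode, ("o", (tau + 1, lab2)))
                prev = xnode

    # split nodes: one per object/skip node with >= 2 daughter candidates
    for t in range(t0, t1 + 1):
        for oid in by_frame.get(t, []):
            origins: list[tuple[Node, int]] = [(("o", oid), t)]
            for tau in range(t + 1, min(t + cfg.delta_t, t1 + 1)):
                origins.append((("x", oid, tau), tau))
            for origin, tau in origins:
                if tau >= t1:
                    continue
                daughters = [
                    (tau + 1, lab2)
                    for lab2 in sorted(_cand(candidates, oid, tau + 1))
                    if (tau + 1, lab2) in objects
                ]
                if len(daughters) < 2:
                    continue
                snode: Node = ("s", oid, tau + 1)
                if (origin, snode) in edges:
                    continue
                add(origin, snode)
                add(("a", tau), snode, capacity=len(daughters))
                for d in daughters:
                    add(snode, ("o", d))
                for j, l in itertools.combinations(daughters, 2):
                    pairs.append(PairVar(snode, j, l))

    # merge nodes: one per object node with >= 2 incoming candidate nodes
    for t in range(t0 + 1, t1 + 1):
        for oid in by_frame.get(t, []):
            sources: list[Node] = []
            for oid2 in by_frame.get(t - 1, []):
                if oid[1] in _cand(candidates, oid2, t):
                    sources.append(("o", oid2))
            for (u, v), _ in list(edges.items()):
                if u[0] == "x" and v == ("o", oid) and u[2] == t - 1:
                    sources.append(u)
            if len(sources) < 2:
                continue
            mnode: Node = ("m", oid)
            for src_node in sources:
                add(src_node, mnode)
            add(mnode, ("o", oid))
            add(mnode, ("d", t), capacity=len(sources))

    graph = FlowGraph(
        window=window,
        shape=shape,
        objects=objects,
        objects_by_frame=by_frame,
        edges=edges,
        pairs=pairs,
        cfg=cfg,
        candidates=candidates,
        displacements=dict(candidates.displacements),
    )
    return graph


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------


def _propagated_shift(graph: FlowGraph, oid: OID, target: int) -> np.ndarray:
    """Cumulative displacement of object ``oid`` from its frame to ``target``."""
    t, lab = oid
    ndim = len(graph.shape)
    shift = np.zeros(ndim)
    for tp in range(t, target):
        shift += graph.displacements.get((lab, t, tp), np.zeros(ndim))
    return shift


def _border_distance(p: np.ndarray, shape: tuple[int, ...]) -> float:
    extent = np.asarray(shape, dtype=float)
    return float(min(np.minimum(p, extent - 1 - p)))


def compute_costs(graph: FlowGraph, displacements: dict | None = None) -> FlowGraph:
    """Attach costs to the flow graph edges and mitosis pairs.

    Movement costs are distances between (displacement-propagated) centroids;
    skip costs additionally require the propagated centroid to lie outside
    every bounding box at the target frame; split/merge costs use the minimal
    distance between propagated mask points and the counterpart centroid,
    gated by bounding-box containment; appearance/disappearance costs are the
    border distance capped at ``alpha``. All other edges cost 0.
    """
    if displacements is not None:
        graph.displacements = dict(displacements)
    cfg = graph.cfg
    theta = cfg.theta

    def pos(oid: OID) -> np.ndarray:
        return graph.objects[oid].centroid

    def prop_pos(oid: OID, target: int) -> np.ndarray:
        return pos(oid) + _propagated_shift(graph, oid, target)

    def inside_any_bbox(p: np.ndarray, t: int) -> bool:
        for oid in graph.objects_by_frame.get(t, []):
            o = graph.objects[oid]
            if np.all(p >= o.bbox_min) and np.all(p <= o.bbox_max):
                return True
        return False

    def inside_bbox(p: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> bool:
        return bool(np.all(p >= lo) and np.all(p <= hi))

    for (u, v), edge in graph.edges.items():
        if u[0] == "o" and v[0] == "o":
            i, j = u[1], v[1]
            edge.cost = float(np.linalg.norm(prop_pos(i, j[0]) - pos(j)))
        elif u[0] in ("o", "x") and v[0] == "x":
            i = u[1]
            tau = v[2]
            p_hat = prop_pos(i, tau)
            step = p_hat - prop_pos(i, tau - 1)
            edge.cost = theta if inside_any_bbox(p_hat, tau) else float(np.linalg.norm(step))
        elif u[0] == "x" and v[0] == "o":
            i, j = u[1], v[1]
            edge.cost = float(np.linalg.norm(prop_pos(i, j[0]) - pos(j)))
        elif u[0] == "s" and v[0] == "o":
            i, tau = u[1], u[2]
            j = v[1]
            shift = _propagated_shift(graph, i, tau)
            oi = graph.objects[i]
            if inside_bbox(pos(j), oi.bbox_min + shift, oi.bbox_max + shift):
                q_hat = oi.mask_points + shift
                edge.cost = float(np.min(np.linalg.norm(q_hat - pos(j), axis=1)))
            else:
                edge.cost = theta
        elif v[0] == "m":
            i = v[1]  # merged (target) object at frame i[0]
            oi = graph.objects[i]
            src_oid = u[1]
            p_hat = prop_pos(src_oid, i[0])
            if inside_bbox(p_hat, oi.bbox_min, oi.bbox_max):
                edge.cost = float(np.min(np.linalg.norm(oi.mask_points - p_hat, axis=1)))
            else:
                edge.cost = theta
        elif u[0] == "a" and v[0] == "o":
            edge.cost = min(cfg.alpha, _border_distance(pos(v[1]), graph.shape))
        elif u[0] == "o" and v[0] == "d":
            edge.cost = min(cfg.alpha, _border_distance(pos(u[1]), graph.shape))
        else:
            edge.cost = 0.0

    for pair in graph.pairs:
        i = pair.split[1]
        oi = graph.objects[i]
        pi, pj, pl = pos(i), pos(pair.j), pos(pair.l)
        c3 = float(np.linalg.norm(pj - pl))
        if c3 <= 1.5 * oi.bbox_diagonal:
            c1 = float(np.linalg.norm(pi - 0.5 * (pj + pl)))
            c2 = abs(float(np.linalg.norm(pi - pj)) - float(np.linalg.norm(pi - pl)))
            pair.cost = c1 + c2
        else:
            pair.cost = theta
    return graph


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------

#: edge kinds that must survive pruning to keep the model feasible
_STRUCTURAL_HEADS = {"a", "d", "m", "s", "src", "snk"}


def _prune(graph: FlowGraph) -> None:
    """Drop implausible (cost >= prune threshold) non-structural edges and
    pairs, then drop split/merge nodes that lost too many edges and fix the
    dependent capacities."""
    cut = graph.cfg.prune_at
    drop = [
        (u, v)
        for (u, v), e in graph.edges.items()
        if e.cost >= cut and not (u[0] in ("a", "src", "m") or v[0] in ("d", "snk", "m", "s"))
    ]
    for key in drop:
        del graph.edges[key]
    # merge edges (v -> m) may also be implausible
    drop = [(u, v) for (u, v), e in graph.edges.items() if v[0] == "m" and e.cost >= cut]
    for key in drop:
        del graph.edges[key]
    graph.pairs = [p for p in graph.pairs if p.cost < cut]

    # split nodes: daughters reachable via plain edge or any pair
    for node in {e[0] for e in graph.edges if e[0][0] == "s"} | {p.split for p in graph.pairs}:
        plain = [(u, v) for (u, v) in graph.edges if u == node and v[0] == "o"]
        daughters = {v[1] for _, v in plain}
        for p in graph.pairs:
            if p.split == node:
                daughters |= {p.j, p.l}
        if len(daughters) < 2:
            for u, v in list(graph.edges):
                if u == node or v == node:
                    del graph.edges[(u, v)]
            graph.pairs = [p for p in graph.pairs if p.split != node]
        else:
            # recompute a -> s capacity = number of distinct daughter edges
            for u, v in list(graph.edges):
                if v == node and u[0] == "a":
                    graph.edges[(u, v)].capacity = len(daughters)

    # merge nodes with fewer than two remaining sources cannot carry flow
    for node in {e[1] for e in graph.edges if e[1][0] == "m"} | {
        e[0] for e in graph.edges if e[0][0] == "m"
    }:
        sources = [(u, v) for (u, v) in graph.edges if v == node]
        if len(sources) < 2:
            for u, v in list(graph.edges):
                if u == node or v == node:
                    del graph.edges[(u, v)]
        else:
            for u, v in list(graph.edges):
                if u == node and v[0] == "d":
                    graph.edges[(u, v)].capacity = len(sources)


@dataclass
class FlowSolution:
    flows: dict[tuple[Node, Node], int]
    pair_flows: list[int]
    objective: float


def solve_matching(graph: FlowGraph, prune: bool = True) -> FlowSolution:
    """Solve the coupled minimum-cost-flow ILP for one window.

    Constraints: flow conservation on every non-source/sink node, unit flow
    through each object node, the required appearance flows, edge capacities,
    merge/split ordering inequalities (flow 0 or >= 2 through merge and split
    nodes), at most one coupled daughter pair per split node, and mutual
    exclusion of coupled-pair (mitosis) and plain (over-segmentation) flow
    out of the same split node.
    """
    if prune:
        _prune(graph)
    edge_keys = sorted(graph.edges, key=repr)
    e_index = {k: i for i, k in enumerate(edge_keys)}
    n_edges = len(edge_keys)
    n_pairs = len(graph.pairs)
    n = n_edges + n_pairs

    lo = np.zeros(n)
    hi = np.zeros(n)
    cost = np.zeros(n)
    for k, key in enumerate(edge_keys):
        e = graph.edges[key]
        lo[k], hi[k], cost[k] = e.lower, e.capacity, e.cost
    for k, p in enumerate(graph.pairs):
        hi[n_edges + k] = 1
        cost[n_edges + k] = 2.0 * p.cost

    rows: list[dict[int, float]] = []
    lbs: list[float] = []
    ubs: list[float] = []

    def constrain(coefs: dict[int, float], lb: float, ub: float) -> None:
        rows.append(coefs)
        lbs.append(lb)
        ubs.append(ub)

    in_map: dict[Node, list[int]] = {}
    out_map: dict[Node, list[int]] = {}
    for k, (u, v) in enumerate(edge_keys):
        out_map.setdefault(u, []).append(k)
        in_map.setdefault(v, []).append(k)
    pair_in: dict[Node, list[int]] = {}  # object node -> pair var indices
    pair_out: dict[Node, list[int]] = {}  # split node -> pair var indices
    for k, p in enumerate(graph.pairs):
        pair_in.setdefault(("o", p.j), []).append(n_edges + k)
        pair_in.setdefault(("o", p.l), []).append(n_edges + k)
        pair_out.setdefault(p.split, []).append(n_edges + k)

    nodes = set(in_map) | set(out_map) | set(pair_in) | set(pair_out)
    nodes -= {SRC, SNK}
    for node in nodes:
        coefs: dict[int, float] = {}
        for k in in_map.get(node, []):
            coefs[k] = coefs.get(k, 0.0) + 1.0
        for k in pair_in.get(node, []):
            coefs[k] = coefs.get(k, 0.0) + 1.0
        for k in out_map.get(node, []):
            coefs[k] = coefs.get(k, 0.0) - 1.0
        for k in pair_out.get(node, []):
            coefs[k] = coefs.get(k, 0.0) - 2.0  # a pair sends one unit to each daughter
        constrain(coefs, 0.0, 0.0)
        if node[0] == "o":  # unit flow through every object node
            inflow = {k: 1.0 for k in in_map.get(node, [])}
            for k in pair_in.get(node, []):
                inflow[k] = inflow.get(k, 0.0) + 1.0
            constrain(inflow, 1.0, 1.0)

    # merge ordering: z(m,o) <= z(m,d); z(v,m) <= z(m,o)
    for node in {e[1] for e in edge_keys if e[1][0] == "m"}:
        k_mo = next(e_index[(u, v)] for (u, v) in edge_keys if u == node and v[0] == "o")
        k_md = next(e_index[(u, v)] for (u, v) in edge_keys if u == node and v[0] == "d")
        constrain({k_mo: 1.0, k_md: -1.0}, -np.inf, 0.0)
        for u, v in edge_keys:
            if v == node:
                constrain({e_index[(u, v)]: 1.0, k_mo: -1.0}, -np.inf, 0.0)

    # split ordering: z(origin,s) <= z(a,s); per-daughter total <= z(origin,s)
    split_nodes = {e[1] for e in edge_keys if e[1][0] == "s"} | {p.split for p in graph.pairs}
    for node in split_nodes:
        k_as = None
        k_os = None
        for u, v in edge_keys:
            if v == node:
                if u[0] == "a":
                    k_as = e_index[(u, v)]
                else:
                    k_os = e_index[(u, v)]
        if k_as is None or k_os is None:
            continue
        constrain({k_os: 1.0, k_as: -1.0}, -np.inf, 0.0)
        daughters: dict[OID, dict[int, float]] = {}
        for u, v in edge_keys:
            if u == node and v[0] == "o":
                daughters.setdefault(v[1], {})[e_index[(u, v)]] = 1.0
        for k, p in enumerate(graph.pairs):
            if p.split == node:
                daughters.setdefault(p.j, {})[n_edges + k] = 1.0
                daughters.setdefault(p.l, {})[n_edges + k] = 1.0
        for coefs in daughters.values():
            constrain({**coefs, k_os: coefs.get(k_os, 0.0) - 1.0}, -np.inf, 0.0)
        # at most one coupled daughter pair per split node
        pair_idx = pair_out.get(node, [])
        if pair_idx:
            constrain({k: 1.0 for k in pair_idx}, 0.0, 1.0)
        # mitosis XOR over-segmentation
        plain_idx = [e_index[(u, v)] for (u, v) in edge_keys if u == node and v[0] == "o"]
        for kp in pair_idx:
            for ke in plain_idx:
                constrain({kp: 1.0, ke: 1.0}, 0.0, 1.0)

    if n == 0:
        return FlowSolution({}, [], 0.0)

    a_mat = sparse.lil_matrix((len(rows), n))
    for r, coefs in enumerate(rows):
        for k, c in coefs.items():
            a_mat[r, k] = c
    res = milp(
        c=cost,
        constraints=LinearConstraint(a_mat.tocsr(), np.array(lbs), np.array(ubs)),
        integrality=np.ones(n),
        bounds=Bounds(lo, hi),
    )
    if not res.success:
        raise RuntimeError(f"matching ILP infeasible or failed: {res.message}")
    x = np.round(res.x).astype(int)
    flows = {key: int(x[e_index[key]]) for key in edge_keys if x[e_index[key]] > 0}
    pair_flows = [int(x[n_edges + k]) for k in range(n_pairs)]
    return FlowSolution(flows, pair_flows, float(res.fun))


# ---------------------------------------------------------------------------
# flows -> tracks
# ---------------------------------------------------------------------------


def _window_links(graph: FlowGraph, sol: FlowSolution, owned: range) -> list[tuple[OID, OID, str]]:
    """Object-level links implied by a window solution, for object nodes in
    the owned frame range. Kinds: move, divide (coupled pair), split
    (over-segmentation), merge (under-segmentation)."""
    out: dict[Node, list[Node]] = {}
    for (u, v), f in sol.flows.items():
        if f > 0:
            out.setdefault(u, []).append(v)
    pair_by_split: dict[Node, list[PairVar]] = {}
    for p, f in zip(graph.pairs, sol.pair_flows):
        if f > 0:
            pair_by_split.setdefault(p.split, []).append(p)

    links: list[tuple[OID, OID, str]] = []
    for t in owned:
        for oid in graph.objects_by_frame.get(t, []):
            node: Node = ("o", oid)
            targets = out.get(node, [])
            for v in targets:
                links.extend(_follow(graph, out, pair_by_split, oid, v))
    return links


def _follow(graph, out, pair_by_split, src: OID, v: Node) -> list[tuple[OID, OID, str]]:
    if v[0] == "o":
        return [(src, v[1], "move")]
    if v[0] == "m":
        return [(src, v[1], "merge")]
    if v[0] == "s":
        links = []
        for p in pair_by_split.get(v, []):
            links.append((src, p.j, "divide"))
            links.append((src, p.l, "divide"))
        for v2 in out.get(v, []):
            if v2[0] == "o":
                links.append((src, v2[1], "split"))
        return links
    if v[0] == "x":
        links = []
        for v2 in out.get(v, []):
            links.extend(_follow(graph, out, pair_by_split, src, v2))
        return links
    return []  # d_t or sink: track ends


def windows_for(n_frames: int, cfg: MatchingConfig) -> list[tuple[int, int]]:
    """Overlapping solve windows covering ``[0, n_frames-1]``."""
    length = max(cfg.window_length, cfg.overlap + 1, 2)
    if n_frames <= length:
        return [(0, n_frames - 1)]
    windows = []
    start = 0
    while True:
        end = min(start + length - 1, n_frames - 1)
        windows.append((start, end))
        if end == n_frames - 1:
            break
        start = end - cfg.overlap + 1
    return windows


def _owned_ranges(windows: list[tuple[int, int]]) -> list[range]:
    """Frame ownership: earlier window authoritative up to the overlap midpoint."""
    owned = []
    prev_cut = windows[0][0]
    for k, (t0, t1) in enumerate(windows):
        if k == len(windows) - 1:
            owned.append(range(prev_cut, t1 + 1))
        else:
            nxt = windows[k + 1][0]
            mid = (nxt + t1) // 2
            owned.append(range(prev_cut, mid + 1))
            prev_cut = mid + 1
    return owned


def flows_to_tracks(
    window_results: list[tuple[FlowGraph, FlowSolution]],
    objects: dict[OID, SegmentedObject],
    shape: tuple[int, ...],
    n_frames: int,
) -> TrackingGraph:
    """Stitch window solutions into a preliminary :class:`TrackingGraph`.

    Object-to-object links are taken from the window owning the source frame.
    Chains of one-to-one ``move`` links become single tracks; division, over-
    segmentation and merge links become predecessor/successor edges between
    tracks (to be untangled later).
    """
    windows = [g.window for g, _ in window_results]
    owned = _owned_ranges(windows)
    raw_links: dict[OID, list[tuple[OID, str, int]]] = {}  # dst -> (src, kind, window)
    for k, (graph, sol) in enumerate(window_results):
        for src, dst, kind in _window_links(graph, sol, owned[k]):
            raw_links.setdefault(dst, []).append((src, kind, k))

    in_map: dict[OID, list[tuple[OID, str]]] = {}
    for dst, entries in raw_links.items():
        first = min(e[2] for e in entries)
        kept = [(src, kind) for src, kind, k in entries if k == first]
        in_map[dst] = kept
    out_map: dict[OID, list[tuple[OID, str]]] = {}
    for dst, entries in in_map.items():
        for src, kind in entries:
            out_map.setdefault(src, []).append((dst, kind))

    def continues(src: OID, dst: OID, kind: str) -> bool:
        return (
            kind == "move"
            and len(out_map.get(src, [])) == 1
            and len(in_map.get(dst, [])) == 1
        )

    track_of: dict[OID, int] = {}
    tracks: dict[int, Track] = {}
    next_id = 1
    for oid in sorted(objects):
        if oid in track_of:
            continue
        ins = in_map.get(oid, [])
        if len(ins) == 1 and continues(ins[0][0], oid, ins[0][1]) and ins[0][0] in track_of:
            continue  # handled while walking from the chain start
        # start of a new track: walk the one-to-one chain
        tid = next_id
        next_id += 1
        chain = [oid]
        cur = oid
        while True:
            outs = out_map.get(cur, [])
            if len(outs) == 1 and continues(cur, outs[0][0], outs[0][1]):
                cur = outs[0][0]
                chain.append(cur)
            else:
                break
        masks = {o[0]: objects[o].pixels for o in chain}
        tracks[tid] = Track(tid, masks)
        for o in chain:
            track_of[o] = tid

    graph = TrackingGraph(tracks, shape, n_frames)
    for dst, entries in in_map.items():
        for src, kind in entries:
            if track_of[src] != track_of[dst]:
                graph.add_edge(track_of[src], track_of[dst])
    return graph


def match_sequence(
    objects_per_frame: dict[int, list[SegmentedObject]],
    candidates: CandidateMap,
    cfg: MatchingConfig,
    shape: tuple[int, ...],
    n_frames: int,
) -> TrackingGraph:
    """Run the matching step over all windows of a sequence."""
    results = []
    for window in windows_for(n_frames, cfg):
        graph = build_flow_graph(objects_per_frame, candidates, cfg, window, shape)
        compute_costs(graph)
        sol = solve_matching(graph)
        results.append((graph, sol))
    objects = {}
    for t, objs in objects_per_frame.items():
        for o in objs:
            objects[(t, o.object_id)] = o
    return flows_to_tracks(results, objects, shape, n_frames)
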