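"""Independent brute-force oracles for the two ILPs.

These enumerate feasible solutions directly from the model descriptions
(flow conservation, capacities, merge/split ordering, coupling rules for
the matching problem; the predecessor/successor inequality system for the
untangling problem) without going through the scipy MILP path, so that the
optimized objectives can be cross-checked on tiny instances.
"""

from __future__ import annotations

import itertools

from graphtrack.matching import SNK, SRC, FlowGraph


# ---------------------------------------------------------------------------
# matching: exhaustive enumeration of integer flows
# ---------------------------------------------------------------------------


def _node_key(node) -> float:
    """Topological processing order: a node only sends flow to nodes with a
    strictly larger key."""
    kind = node[0]
    if kind == "src":
        return -1e9
    if kind == "snk":
        return 1e9
    if kind == "o":
        return 10.0 * node[1][0] + 5
    if kind == "x":
        return 10.0 * node[2] + 5
    if kind == "a":
        return 10.0 * node[1] + 6
    if kind == "s":
        return 10.0 * (node[2] - 1) + 7
    if kind == "m":
        return 10.0 * node[1][0] - 3
    if kind == "d":
        return 10.0 * node[1] - 2
    raise ValueError(node)


def brute_force_min_flow(graph: FlowGraph) -> float | None:
    """Minimum objective over all feasible integer flows, or None if none.

    Enumerates node by node in temporal order, distributing each node's
    inflow over its outgoing edges (and coupled daughter pairs) within
    capacities, and checks the merge/split ordering rules and the unit-flow
    requirement through object nodes.
    """
    edges = sorted(graph.edges, key=lambda e: (_node_key(e[0]), repr(e)))
    out_edges: dict = {}
    for u, v in edges:
        out_edges.setdefault(u, []).append((u, v))
    pairs_at: dict = {}
    for idx, p in enumerate(graph.pairs):
        pairs_at.setdefault(p.split, []).append(idx)

    nodes = sorted(
        {u for u, _ in edges} | {v for _, v in edges} - {SRC, SNK}, key=_node_key
    )
    nodes = [n for n in nodes if n not in (SRC, SNK)]

    best: list[float | None] = [None]

    def objective(flow: dict, pair_flow: dict) -> float:
        c = sum(graph.edges[e].cost * f for e, f in flow.items() if f)
        c += sum(2.0 * graph.pairs[i].cost * f for i, f in pair_flow.items() if f)
        return c

    def distributions(amount: int, caps: list[int]):
        """All ways to write ``amount`` as a sum over slots bounded by caps."""
        if not caps:
            if amount == 0:
                yield ()
            return
        for first in range(min(amount, caps[0]) + 1):
            for rest in distributions(amount - first, caps[1:]):
                yield (first,) + rest

    def ok_merge(node, flow) -> bool:
        f_mo = sum(f for (u, v), f in flow.items() if u == node and v[0] == "o")
        f_md = sum(f for (u, v), f in flow.items() if u == node and v[0] == "d")
        if f_mo > f_md:
            return False
        return all(
            f <= f_mo for (u, v), f in flow.items() if v == node
        )

    def ok_split(node, flow, pair_flow) -> bool:
        f_as = sum(f for (u, v), f in flow.items() if v == node and u[0] == "a")
        f_os = sum(f for (u, v), f in flow.items() if v == node and u[0] in ("o", "x"))
        if f_os > f_as:
            return False
        per_edge: dict = {}
        for (u, v), f in flow.items():
            if u == node and v[0] == "o":
                per_edge[v] = per_edge.get(v, 0) + f
        active_pairs = [i for i in pairs_at.get(node, []) if pair_flow.get(i)]
        if len(active_pairs) > 1:
            return False
        for i in active_pairs:
            p = graph.pairs[i]
            per_edge[("o", p.j)] = per_edge.get(("o", p.j), 0) + 1
            per_edge[("o", p.l)] = per_edge.get(("o", p.l), 0) + 1
            # mitosis XOR over-segmentation: no plain flow alongside a pair
            if any(
                f for (u, v), f in flow.items() if u == node and v[0] == "o"
            ):
                return False
        return all(f <= f_os for f in per_edge.values())

    def recurse(i: int, flow: dict, pair_flow: dict, inflow: dict) -> None:
        if i == len(nodes):
            obj = objective(flow, pair_flow)
            if best[0] is None or obj < best[0]:
                best[0] = obj
            return
        node = nodes[i]
        need = inflow.get(node, 0)
        if node[0] == "o" and need != 1:
            return  # unit flow through every object node
        outs = out_edges.get(node, [])
        caps = [graph.edges[e].capacity for e in outs]
        pair_ids = pairs_at.get(node, []) if node[0] == "s" else []
        # choose an active pair (or none), consuming 2 units
        for chosen in [None] + pair_ids:
            pair_used = 2 if chosen is not None else 0
            if need - pair_used < 0:
                continue
            for dist in distributions(need - pair_used, caps):
                new_flow = dict(flow)
                new_inflow = dict(inflow)
                feasible = True
                for e, f in zip(outs, dist):
                    if f:
                        new_flow[e] = f
                        tgt = e[1]
                        new_inflow[tgt] = new_inflow.get(tgt, 0) + f
                        if tgt[0] in ("o", "x") and new_inflow[tgt] > 1:
                            feasible = False
                            break
                if not feasible:
                    continue
                new_pairs = dict(pair_flow)
                if chosen is not None:
                    new_pairs[chosen] = 1
                    p = graph.pairs[chosen]
                    for d in (p.j, p.l):
                        new_inflow[("o", d)] = new_inflow.get(("o", d), 0) + 1
                        if new_inflow[("o", d)] > 1:
                            feasible = False
                    if not feasible:
                        continue
                if node[0] == "m" and not ok_merge(node, new_flow):
                    continue
                if node[0] == "s" and not ok_split(node, new_flow, new_pairs):
                    continue
                recurse(i + 1, new_flow, new_pairs, new_inflow)

    # source: required appearance flows plus a 0/1 choice per first-frame object
    a_edges = [(u, v) for (u, v) in out_edges.get(SRC, []) if v[0] == "a"]
    o_edges = [(u, v) for (u, v) in out_edges.get(SRC, []) if v[0] == "o"]
    flow0 = {}
    inflow0: dict = {}
    for e in a_edges:
        f = graph.edges[e].lower
        if f:
            flow0[e] = f
            inflow0[e[1]] = inflow0.get(e[1], 0) + f
    for e in o_edges:  # every first-frame object can only be fed by the source
        flow0[e] = 1
        inflow0[e[1]] = 1
    recurse(0, flow0, {}, inflow0)
    return best[0]


# ---------------------------------------------------------------------------
# untangling: exhaustive search over operation combinations
# ---------------------------------------------------------------------------


def _untangling_constraints(graph):
    """Independent transcription of the untangling inequality system,
    evaluated directly from the track graph (not via UntanglingProblem)."""
    from graphtrack.untangling import enumerate_mergeable_sets

    tracks = graph.tracks
    merge_sets = enumerate_mergeable_sets(graph)
    sets_of = {n: [r for r in merge_sets if n in r] for n in tracks}

    def lhs_rhs(n, side):
        tr = tracks[n]
        p_n, s_n = tr.predecessors, tr.successors
        w_n = {n} | {m for r in sets_of[n] for m in r}
        terms = {}

        def add(key, val):
            if val:
                terms[key] = terms.get(key, 0.0) + val

        if side == "pred":
            for r in sets_of[n]:
                add(("m", r), sum(1 for m in r if tracks[m].predecessors == p_n) - 1)
            for w in w_n:
                add(("s", w), -1)
                for p in tracks[w].predecessors:
                    add(("e", p, w), -1)
            for p in p_n:
                add(("s", p), 1)
            for q in merge_sets:
                if q & p_n:
                    add(("m", q), min(0, -sum(1 for m in q if n in tracks[m].successors) + 1))
            union = set().union(*(tracks[p].successors for p in p_n)) if p_n else set()
            rhs = -len(p_n) + max(1, len(union))
        else:
            for r in sets_of[n]:
                add(("m", r), sum(1 for m in r if tracks[m].successors == s_n) - 1)
            for w in w_n:
                add(("s", w), -1)
                for v in tracks[w].successors:
                    add(("e", w, v), -1)
            for v in s_n:
                add(("s", v), 1)
            for q in merge_sets:
                if q & s_n:
                    add(("m", q), min(0, -sum(1 for m in q if n in tracks[m].predecessors) + 1))
            union = set().union(*(tracks[v].predecessors for v in s_n)) if s_n else set()
            rhs = -len(s_n) + 2 * len(union) + 1
        return terms, rhs

    constraints = []
    for n in tracks:
        constraints.append(lhs_rhs(n, "pred"))
        constraints.append(lhs_rhs(n, "succ"))
    return merge_sets, constraints


def brute_force_untangling(graph, upper: dict) -> float | None:
    """Minimum cost over all operation combinations satisfying the
    inequality system, the one-merge-per-track rule, and the coupled edge
    removals of merged sets. ``upper`` bounds the split variables (same
    bounds as the ILP, so the search spaces coincide)."""
    from graphtrack.untangling import untangling_gamma

    tracks = graph.tracks
    merge_sets, constraints = _untangling_constraints(graph)
    gamma = untangling_gamma(graph)
    edge_vars = sorted(
        (p, n) for n, tr in tracks.items() for p in tr.predecessors
    )
    split_vars = sorted(tracks)

    def cost_of(merge_sel, splits, edges_sel):
        c = gamma * len(edges_sel)
        for r in merge_sel:
            span = max(tracks[m].end for m in r) - min(tracks[m].begin for m in r) + 1
            c += span * (len(r) - 1)
        for n, z in splits.items():
            c += tracks[n].span * z
        return c

    best = None
    merge_options = []
    for k in range(len(merge_sets) + 1):
        for combo in itertools.combinations(merge_sets, k):
            # each track in at most one selected set => sets pairwise disjoint
            if len({m for r in combo for m in r}) == sum(len(r) for r in combo):
                merge_options.append(combo)
    split_ranges = [range(upper.get(("s", n), 0) + 1) for n in split_vars]
    for merge_sel in merge_options:
        for edges_bits in itertools.product((0, 1), repeat=len(edge_vars)):
            edges_sel = {e for e, b in zip(edge_vars, edges_bits) if b}
            # coupled edge removals inside merged sets
            coupled_ok = True
            for r in merge_sel:
                for n, v in itertools.combinations(sorted(r), 2):
                    for p in tracks[n].predecessors & tracks[v].predecessors:
                        if ((p, n) in edges_sel) != ((p, v) in edges_sel):
                            coupled_ok = False
                    for u in tracks[n].successors & tracks[v].successors:
                        if ((n, u) in edges_sel) != ((v, u) in edges_sel):
                            coupled_ok = False
            if not coupled_ok:
                continue
            for split_combo in itertools.product(*split_ranges):
                splits = dict(zip(split_vars, split_combo))
                assignment = {}
                for r in merge_sets:
                    assignment[("m", r)] = 1 if r in merge_sel else 0
                for e in edge_vars:
                    assignment[("e", e[0], e[1])] = 1 if e in edges_sel else 0
                for n, z in splits.items():
                    assignment[("s", n)] = z
                if all(
                    sum(c * assignment.get(k, 0) for k, c in terms.items()) <= rhs
                    for terms, rhs in constraints
                ):
                    c = cost_of(merge_sel, splits, edges_sel)
                    if best is None or c < best:
                        best = c
    return best
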