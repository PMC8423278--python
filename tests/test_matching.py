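import numpy as np
import pytest

from graphtrack.core_io import extract_features
from graphtrack.matching import (
    SNK,
    SRC,
    MatchingConfig,
    build_flow_graph,
    compute_costs,
    flows_to_tracks,
    match_sequence,
    solve_matching,
    windows_for,
)
from graphtrack.tracklet import find_candidates

from conftest import sequence_from_positions
from oracles import brute_force_min_flow


def setup_problem(positions, delta_t=2, shape=(32, 32), size=3, roi=12.0, window=None):
    seq = sequence_from_positions(positions, shape=shape, size=size)
    opf = {t: extract_features(f, t) for t, f in enumerate(seq.frames)}
    cand = find_candidates(opf, None, delta_t, roi_size=np.array([roi] * len(shape)))
    cfg = MatchingConfig(alpha=roi, delta_t=delta_t)
    if window is None:
        window = (0, len(seq.frames) - 1)
    graph = build_flow_graph(opf, cand, cfg, window, shape)
    compute_costs(graph)
    return seq, opf, graph, cfg


def assert_flow_invariants(graph, sol):
    """Conservation, unit object flow, and merge/split quantization."""
    inflow, outflow = {}, {}
    for (u, v), f in sol.flows.items():
        outflow[u] = outflow.get(u, 0) + f
        inflow[v] = inflow.get(v, 0) + f
    for p, f in zip(graph.pairs, sol.pair_flows):
        if f:
            outflow[p.split] = outflow.get(p.split, 0) + 2 * f
            inflow[("o", p.j)] = inflow.get(("o", p.j), 0) + f
            inflow[("o", p.l)] = inflow.get(("o", p.l), 0) + f
    nodes = {u for u, _ in sol.flows} | {v for _, v in sol.flows}
    for node in nodes - {SRC, SNK}:
        assert inflow.get(node, 0) == outflow.get(node, 0), f"conservation at {node}"
        if node[0] == "o":
            assert inflow.get(node, 0) == 1, f"object node {node} flow != 1"
        if node[0] in ("m", "s"):
            assert inflow.get(node, 0) >= 2, f"{node} carries flow 1"


class TestBuildFlowGraph:
    def test_skip_node_per_object_at_delta_t_2(self):
        _, _, graph, _ = setup_problem(
            {1: {0: (5, 5), 1: (6, 6), 2: (7, 7)}}, delta_t=2
        )
        skip_nodes = {e[1] for e in graph.edges if e[1][0] == "x"}
        # one skip node per object node except at the last frame
        assert skip_nodes == {("x", (0, 1), 1), ("x", (1, 1), 2)}

    def test_empty_window_has_only_backbone_nodes(self):
        opf = {t: [] for t in range(3)}
        cfg = MatchingConfig(alpha=10.0, delta_t=2)
        graph = build_flow_graph(opf, find_candidates({}, None, 2), cfg, (0, 2), (32, 32))
        kinds = {u[0] for u, v in graph.edges} | {v[0] for u, v in graph.edges}
        assert kinds <= {"src", "snk", "a", "d"}
        sol = solve_matching(graph)
        assert sol.objective == 0

    def test_single_candidate_edge_set_matches_hand_enumeration(self):
        _, _, graph, _ = setup_problem(
            {1: {0: (5, 5)}, 2: {1: (6, 6)}}, delta_t=1, window=(0, 1)
        )
        o0, o1 = ("o", (0, 1)), ("o", (1, 2))
        expected = {
            (SRC, o0),  # first-frame object fed by the source
            (SRC, ("a", 0)),  # appearance backbone
            (("a", 0), o1),
            (("a", 0), ("d", 1)),
            (("d", 1), SNK),
            (o0, o1),  # the single movement candidate
            (o0, ("d", 1)),  # disappearance
            (o1, SNK),
        }
        assert set(graph.edges) == expected

    def test_unknown_candidate_is_an_error(self):
        seq = sequence_from_positions({1: {0: (5, 5), 1: (6, 6)}})
        opf = {t: extract_features(f, t) for t, f in enumerate(seq.frames)}
        cand = find_candidates(opf, None, 1)
        cand[(1, 0)][1].add(99)
        cfg = MatchingConfig(alpha=10.0, delta_t=1)
        with pytest.raises(ValueError, match="unknown object"):
            build_flow_graph(opf, cand, cfg, (0, 1), (32, 32))

    def test_delete_capacity_sums_object_counts(self):
        _, _, graph, _ = setup_problem(
            {1: {0: (5, 5), 1: (6, 6), 2: (7, 7)}, 2: {0: (20, 20), 1: (20, 20), 2: (20, 20)}},
            delta_t=2,
        )
        cap = graph.edges[(("d", 2), SNK)].capacity
        assert cap == 6  # |O_0| + |O_1| + |O_2|


class TestComputeCosts:
    def test_zero_displacement_coincident_centroids(self):
        _, _, graph, _ = setup_problem({1: {0: (5, 5), 1: (5, 5)}}, delta_t=1)
        assert graph.edges[(("o", (0, 1)), ("o", (1, 1)))].cost == 0

    def test_symmetric_mitosis_pair_costs_zero(self):
        # daughters symmetric around the mother and close together
        # (inter-daughter distance below 1.5x the mother's bbox diagonal):
        # c1 = c2 = 0, so the pair cost is 0
        _, _, graph, _ = setup_problem(
            {1: {0: (10, 10)}, 2: {1: (8, 10)}, 3: {1: (12, 10)}}, delta_t=1
        )
        (pair,) = [p for p in graph.pairs if {p.j, p.l} == {(1, 2), (1, 3)}]
        assert pair.cost == pytest.approx(0.0)

    def test_distant_daughters_get_theta(self):
        _, _, graph, cfg = setup_problem(
            {1: {0: (10, 10)}, 2: {1: (2, 2)}, 3: {1: (26, 26)}},
            delta_t=1, roi=40.0,
        )
        (pair,) = [p for p in graph.pairs if {p.j, p.l} == {(1, 2), (1, 3)}]
        assert pair.cost == cfg.theta

    def test_border_centroid_appears_for_free(self):
        _, _, graph, _ = setup_problem(
            {1: {0: (5, 5)}, 2: {1: (0, 10)}}, delta_t=1
        )
        # centroid row = 1.0 -> border distance 1; appear cost min(alpha, 1)
        assert graph.edges[(("a", 0), ("o", (1, 2)))].cost == pytest.approx(1.0)
        img = np.zeros((32, 32), dtype=np.int32)
        img[0:1, 10:13] = 2  # flat mask on the border row
        obj = extract_features(img, 1)[0]
        assert obj.centroid[0] == 0.0

    def test_merge_cost_beats_centroid_cost_for_underseg(self):
        # two correct objects at t, one merged mask at t+1: linking via the
        # merge node (mask-point distance) is cheaper than the plain
        # object-to-object (centroid) distance
        img0 = np.zeros((32, 32), dtype=np.int32)
        img0[10:14, 4:10] = 1
        img0[10:14, 20:26] = 2
        img1 = np.zeros((32, 32), dtype=np.int32)
        img1[10:14, 4:26] = 3  # under-segmented union spanning both
        opf = {t: extract_features(f, t) for t, f in enumerate([img0, img1])}
        cand = find_candidates(opf, None, 1, roi_size=np.array([24.0, 24.0]))
        cfg = MatchingConfig(alpha=24.0, delta_t=1)
        graph = build_flow_graph(opf, cand, cfg, (0, 1), (32, 32))
        compute_costs(graph)
        merge_cost = graph.edges[(("o", (0, 1)), ("m", (1, 3)))].cost
        move_cost = graph.edges[(("o", (0, 1)), ("o", (1, 3)))].cost
        assert merge_cost < move_cost


class TestSolveMatching:
    def test_identity_assignment_matches_brute_force(self):
        positions = {
            1: {t: (5 + t, 5) for t in range(4)},
            2: {t: (20, 20 + 2 * t) for t in range(4)},
        }
        _, _, graph, _ = setup_problem(positions, delta_t=2, shape=(40, 40))
        expected = brute_force_min_flow(graph)
        sol = solve_matching(graph)
        assert sol.objective == pytest.approx(expected)
        assert_flow_invariants(graph, sol)
        # identity links carry flow
        for t in range(3):
            assert sol.flows[(("o", (t, 1)), ("o", (t + 1, 1)))] == 1
            assert sol.flows[(("o", (t, 2)), ("o", (t + 1, 2)))] == 1

    def test_gap_routed_through_skip_node(self):
        positions = {1: {0: (10, 10), 2: (12, 12)}}  # missing in frame 1
        _, _, graph, _ = setup_problem(positions, delta_t=2)
        sol = solve_matching(graph)
        assert sol.flows[(("o", (0, 1)), ("x", (0, 1), 1))] == 1
        assert sol.flows[(("x", (0, 1), 1), ("o", (2, 1)))] == 1
        assert sol.objective == pytest.approx(brute_force_min_flow(graph))

    def test_division_uses_coupled_pair(self):
        positions = {1: {0: (10, 10)}, 2: {1: (8, 10)}, 3: {1: (12, 10)}}
        _, _, graph, _ = setup_problem(positions, delta_t=1)
        sol = solve_matching(graph)
        active = [f for f in sol.pair_flows if f > 0]
        assert active == [1]
        snode = ("s", (0, 1), 1)
        assert sol.flows[(("o", (0, 1)), snode)] == 1
        assert sol.flows[(("a", 0), snode)] == 1
        assert sol.objective == pytest.approx(brute_force_min_flow(graph))
        assert_flow_invariants(graph, sol)

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_on_random_instances(self, seed):
        """ILP objective equals exhaustive enumeration on small graphs
        (up to 3 frames x 3 objects per frame)."""
        rng = np.random.default_rng(seed)
        n_frames = int(rng.integers(2, 4))
        positions = {}
        lab = 1
        for t in range(n_frames):
            for _ in range(int(rng.integers(1, 4))):
                pos = tuple(int(x) for x in rng.integers(2, 26, size=2))
                positions.setdefault(lab, {})[t] = pos
                lab += 1
        seq = sequence_from_positions(positions, shape=(32, 32), size=2)
        opf = {t: extract_features(f, t) for t, f in enumerate(seq.frames)}
        cand = find_candidates(opf, None, 2, roi_size=np.array([14.0, 14.0]))
        cfg = MatchingConfig(alpha=14.0, delta_t=2)
        graph = build_flow_graph(opf, cand, cfg, (0, n_frames - 1), (32, 32))
        compute_costs(graph)
        sol = solve_matching(graph)  # prunes, then solves
        expected = brute_force_min_flow(graph)
        assert expected is not None
        assert sol.objective == pytest.approx(expected)
        assert_flow_invariants(graph, sol)


class TestFlowsToTracks:
    def test_single_path_single_track(self):
        positions = {1: {t: (5 + t, 5) for t in range(5)}}
        seq, opf, graph, cfg = setup_problem(positions, delta_t=2, shape=(40, 40))
        sol = solve_matching(graph)
        objects = {(t, o.object_id): o for t, objs in opf.items() for o in objs}
        tg = flows_to_tracks([(graph, sol)], objects, (40, 40), 5)
        assert len(tg.tracks) == 1
        (tr,) = tg.tracks.values()
        assert (tr.begin, tr.end) == (0, 4)
        assert tr.predecessors == set() and tr.successors == set()

    def test_merge_gives_two_predecessors(self):
        img0 = np.zeros((32, 32), dtype=np.int32)
        img0[10:13, 4:8] = 1
        img0[10:13, 12:16] = 2
        img1 = np.zeros((32, 32), dtype=np.int32)
        img1[10:13, 4:16] = 3
        opf = {t: extract_features(f, t) for t, f in enumerate([img0, img1])}
        cand = find_candidates(opf, None, 1, roi_size=np.array([14.0, 14.0]))
        cfg = MatchingConfig(alpha=14.0, delta_t=1)
        graph = build_flow_graph(opf, cand, cfg, (0, 1), (32, 32))
        compute_costs(graph)
        sol = solve_matching(graph)
        objects = {(t, o.object_id): o for t, objs in opf.items() for o in objs}
        tg = flows_to_tracks([(graph, sol)], objects, (32, 32), 2)
        merged = [tr for tr in tg.tracks.values() if len(tr.predecessors) == 2]
        assert len(merged) == 1

    def test_two_windows_stitch_to_one_track(self):
        n_frames = 17
        positions = {1: {t: (5 + t, 5) for t in range(n_frames)}}
        seq = sequence_from_positions(positions, shape=(40, 40))
        opf = {t: extract_features(f, t) for t, f in enumerate(seq.frames)}
        cand = find_candidates(opf, None, 3, roi_size=np.array([12.0, 12.0]))
        cfg = MatchingConfig(alpha=12.0, delta_t=3, window_length=10)
        assert len(windows_for(n_frames, cfg)) == 2
        tg = match_sequence(opf, cand, cfg, (40, 40), n_frames)
        assert len(tg.tracks) == 1
        assert (tg.tracks[1].begin, tg.tracks[1].end) == (0, n_frames - 1)


class TestGroundTruthRecovery:
    def test_perfect_segmentation_without_divisions_reproduces_links(self):
        from graphtrack.synthetic_data import SimulationConfig, generate_sequence

        cfg = SimulationConfig(n_frames=10, n_cells=8, seed=11)
        raw, seq = generate_sequence(cfg)
        opf = {t: extract_features(f, t) for t, f in enumerate(seq.frames)}
        from graphtrack.tracklet import default_roi_size

        roi, alpha = default_roi_size([o for objs in opf.values() for o in objs])
        cand = find_candidates(opf, raw, 3, roi_size=roi)
        mcfg = MatchingConfig(alpha=alpha, delta_t=3)
        tg = match_sequence(opf, cand, mcfg, seq.shape, len(seq.frames))
        assert len(tg.tracks) == 8
        for tr in tg.tracks.values():
            assert (tr.begin, tr.end) == (0, 9)
            assert not tr.predecessors and not tr.successors
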