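import numpy as np
import pytest

from graphtrack.tracks import Track, TrackingGraph
from graphtrack.untangling import (
    apply_operations,
    build_untangling_ilp,
    enumerate_mergeable_sets,
    solve_untangling,
    untangle,
    untangling_gamma,
)

from conftest import make_track
from oracles import brute_force_untangling


class TestEnumerateMergeableSets:
    def test_worked_example_predecessor_sets(self, fig4_graph):
        sets = enumerate_mergeable_sets(fig4_graph)
        mp5 = {frozenset(s) for s in sets if s & {2, 3, 4}}
        assert mp5 == {
            frozenset({2, 3}),
            frozenset({2, 4}),
            frozenset({3, 4}),
            frozenset({2, 3, 4}),
        }
        ms5 = {frozenset(s) for s in sets if s & {6, 7}}
        assert ms5 == {frozenset({6, 7})}

    def test_chain_graph_has_no_mergeable_sets(self):
        tracks = {1: make_track(1, 0, 2), 2: make_track(2, 3, 5), 3: make_track(3, 6, 8)}
        g = TrackingGraph(tracks, (16, 16), 9)
        g.add_edge(1, 2)
        g.add_edge(2, 3)
        assert enumerate_mergeable_sets(g) == []

    def test_condition_b_predecessorless_late_starter(self):
        # A has predecessor X and frames 3..9; B has no predecessor, starts
        # later (5..9); both share successor Y -> {A, B} is mergeable
        tracks = {
            1: make_track(1, 0, 2),  # X
            2: make_track(2, 3, 9),  # A
            3: make_track(3, 5, 9),  # B
            4: make_track(4, 10, 12),  # Y
        }
        g = TrackingGraph(tracks, (16, 16), 13)
        g.add_edge(1, 2)
        g.add_edge(2, 4)
        g.add_edge(3, 4)
        assert frozenset({2, 3}) in set(enumerate_mergeable_sets(g))

    def test_condition_b_requires_later_begin(self):
        # same as above but B starts before A: not mergeable
        tracks = {
            1: make_track(1, 0, 2),
            2: make_track(2, 3, 9),
            3: make_track(3, 2, 9),
            4: make_track(4, 10, 12),
        }
        g = TrackingGraph(tracks, (16, 16), 13)
        g.add_edge(1, 2)
        g.add_edge(2, 4)
        g.add_edge(3, 4)
        assert frozenset({2, 3}) not in set(enumerate_mergeable_sets(g))


class TestBuildUntanglingIlp:
    def test_worked_example_rhs_and_coefficients(self, fig4_graph):
        prob = build_untangling_ilp(fig4_graph)
        pred5 = prob.pred_inequalities[5]
        succ5 = prob.succ_inequalities[5]
        assert pred5.rhs == -2  # -|P_5| + max(1, 1)
        assert succ5.rhs == 1  # -|S_5| + 2*1 + 1
        assert pred5.coefficient(("m", frozenset({2, 3, 4}))) == -2
        for pair in ({2, 3}, {2, 4}, {3, 4}):
            assert pred5.coefficient(("m", frozenset(pair))) == -1
        # remove-edge and split terms exactly as in the printed inequality
        for p in (2, 3, 4):
            assert pred5.coefficient(("e", p, 5)) == -1
            assert pred5.coefficient(("s", p)) == 1
        assert pred5.coefficient(("s", 5)) == -1
        assert succ5.coefficient(("m", frozenset({6, 7}))) == -1

    def test_merge_and_split_costs_are_symmetric(self, fig4_graph):
        # merging K tracks over a span costs the same as splitting one track
        # of that span into K parts
        prob = build_untangling_ilp(fig4_graph)
        k = 3
        merge_cost = prob.costs[("m", frozenset({2, 3, 4}))]  # span 2, 3 tracks
        span = fig4_graph.tracks[2].span
        assert merge_cost == span * (k - 1)
        split_cost_per_part = prob.costs[("s", 2)]
        assert split_cost_per_part * (k - 1) == merge_cost

    def test_gamma_quantile_formula(self, fig4_graph):
        spans = np.array([t.span for t in fig4_graph.tracks.values()])
        links = np.array(
            [len(t.predecessors) + len(t.successors) for t in fig4_graph.tracks.values()]
        )
        expected = 2 * np.ceil(np.quantile(spans, 0.3) * np.quantile(links, 0.99))
        assert untangling_gamma(fig4_graph) == expected


class TestSolveUntangling:
    def test_valid_graph_needs_no_operations(self):
        tracks = {1: make_track(1, 0, 4), 2: make_track(2, 5, 9), 3: make_track(3, 5, 9)}
        g = TrackingGraph(tracks, (16, 16), 10)
        g.add_edge(1, 2)
        g.add_edge(1, 3)
        ops = solve_untangling(build_untangling_ilp(g))
        assert ops.count() == 0 and ops.objective == 0

    def test_worked_example_matches_exhaustive_search(self, fig4_graph):
        prob = build_untangling_ilp(fig4_graph)
        ops = solve_untangling(prob)
        expected = brute_force_untangling(fig4_graph, prob.upper)
        assert ops.objective == pytest.approx(expected)
        out = apply_operations(fig4_graph, ops)
        assert out.is_valid_lineage()

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_on_random_graphs(self, seed):
        """ILP objective equals exhaustive operation search on graphs with
        up to 6 tracks."""
        g = random_tangled_graph(seed)
        prob = build_untangling_ilp(g)
        ops = solve_untangling(prob)
        expected = brute_force_untangling(g, prob.upper)
        assert expected is not None
        assert ops.objective == pytest.approx(expected)


def random_tangled_graph(seed: int, n_tracks: int = 6) -> TrackingGraph:
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, n_tracks + 1))
    # two generations: early tracks (0..4), late tracks (5..9)
    n_early = max(1, n // 2)
    tracks = {}
    for tid in range(1, n + 1):
        if tid <= n_early:
            tracks[tid] = make_track(tid, 0, int(rng.integers(2, 5)))
        else:
            tracks[tid] = make_track(tid, 5, int(rng.integers(6, 10)))
    g = TrackingGraph(tracks, (32, 32), 10)
    for tid in range(n_early + 1, n + 1):
        for p in range(1, n_early + 1):
            if rng.random() < 0.6:
                g.add_edge(p, tid)
    return g


class TestApplyOperations:
    def test_split_dumbbell_partitions_pixels(self):
        # dumbbell: two 3x3 lobes joined by a 1-px bridge
        coords = []
        for r in range(3):
            for c in range(3):
                coords.append((r + 1, c))
                coords.append((r + 1, c + 6))
        coords.append((2, 3))
        coords.append((2, 4))
        coords.append((2, 5))
        mask = np.array(sorted(coords))
        g = TrackingGraph({1: Track(1, {0: mask})}, (8, 12), 1)
        from graphtrack.untangling import UntanglingOps

        out = apply_operations(g, UntanglingOps(splits={1: 1}))
        assert len(out.tracks) == 2
        parts = [set(map(tuple, tr.masks[0])) for tr in out.tracks.values()]
        assert parts[0] | parts[1] == set(map(tuple, mask))
        assert parts[0] & parts[1] == set()
        # each part contains one full lobe
        lobes = [{(r + 1, c) for r in range(3) for c in range(3)},
                 {(r + 1, c + 6) for r in range(3) for c in range(3)}]
        for lobe in lobes:
            assert any(lobe <= p for p in parts)

    def test_merge_unions_pixels(self):
        a = Track(1, {0: np.array([[1, 1], [1, 2]])})
        b = Track(2, {0: np.array([[5, 5]])})
        g = TrackingGraph({1: a, 2: b, 3: make_track(3, 1, 2)}, (8, 8), 3)
        g.add_edge(1, 3)
        g.add_edge(2, 3)
        from graphtrack.untangling import UntanglingOps

        out = apply_operations(g, UntanglingOps(merges=[frozenset({1, 2})]))
        merged = out.tracks[1]
        assert set(map(tuple, merged.masks[0])) == {(1, 1), (1, 2), (5, 5)}
        assert out.tracks[3].predecessors == {1}

    def test_edge_removal(self, fig4_graph):
        from graphtrack.untangling import UntanglingOps

        out = apply_operations(fig4_graph, UntanglingOps(edge_removals=[(2, 5)]))
        assert out.tracks[5].predecessors == {3, 4}
        assert out.tracks[2].successors == set()

    def test_pixel_conservation_under_split_and_merge(self, fig4_graph):
        out, _ = untangle(fig4_graph)
        for t in range(7):
            before = sorted(
                tuple(p)
                for tr in fig4_graph.tracks.values()
                for p in tr.masks.get(t, np.empty((0, 2), dtype=int))
            )
            after = sorted(
                tuple(p)
                for tr in out.tracks.values()
                for p in tr.masks.get(t, np.empty((0, 2), dtype=int))
            )
            assert before == after


class TestUntangle:
    def test_idempotent_on_valid_graph(self):
        tracks = {1: make_track(1, 0, 4), 2: make_track(2, 5, 9), 3: make_track(3, 5, 9)}
        g = TrackingGraph(tracks, (16, 16), 10)
        g.add_edge(1, 2)
        g.add_edge(1, 3)
        out, ops = untangle(g)
        assert ops.count() == 0
        assert {(tid, tr.begin, tr.end) for tid, tr in out.tracks.items()} == {
            (1, 0, 4), (2, 5, 9), (3, 5, 9)
        }
        assert out.tracks[1].successors == {2, 3}

    @pytest.mark.parametrize("seed", range(10))
    def test_final_graph_always_valid(self, seed):
        g = random_tangled_graph(seed)
        out, _ = untangle(g)
        assert out.is_valid_lineage()
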