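import networkx as nx
import numpy as np
import pytest

from comirnet.config import McodeParams
from comirnet.mcode import (
    CooperativeModule,
    core_number,
    find_complexes,
    format_score,
    mcode,
    post_process,
    score_complex,
    vertex_weight,
    vertex_weights,
)

# every (nodes, edges, score) triple printed for the 17 up-regulation and
# 8 down-regulation cooperative modules
UP_MODULE_TRIPLES = [
    (43, 696, "33.143"), (31, 211, "14.067"), (21, 94, "9.4"), (43, 188, "8.952"),
    (32, 113, "7.29"), (25, 62, "5.167"), (4, 6, "4"), (4, 5, "3.333"),
    (13, 18, "3"), (3, 3, "3"), (3, 3, "3"), (3, 3, "3"), (3, 3, "3"),
    (3, 3, "3"), (3, 3, "3"), (3, 3, "3"), (3, 3, "3"),
]
DOWN_MODULE_TRIPLES = [
    (34, 374, "22.667"), (34, 237, "14.364"), (5, 10, "5"), (17, 38, "4.75"),
    (5, 9, "4.5"), (4, 5, "3.333"), (6, 8, "3.2"), (3, 3, "3"),
]


def two_triangles_with_bridge():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("a", "c"), ("b", "c"),
                      ("d", "e"), ("d", "f"), ("e", "f"),
                      ("x", "a"), ("x", "d")])
    return g


class TestCoreNumber:
    def test_triangle_all_two(self):
        g = nx.complete_graph(3)
        assert core_number(g) == {v: 2 for v in g}

    def test_path_all_one(self):
        assert core_number(nx.path_graph(3)) == {0: 1, 1: 1, 2: 1}

    def test_k5_all_four(self):
        assert core_number(nx.complete_graph(5)) == {v: 4 for v in range(5)}

    def test_matches_networkx_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(2, 31))
            g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(2**31)))
            assert core_number(g) == nx.core_number(g)

    def test_matches_peeling_oracle(self):
        # independent oracle: for each k, repeatedly strip degree<k vertices
        def oracle(g):
            core = {}
            for v in g:
                k = 0
                while True:
                    sub = g.copy()
                    changed = True
                    while changed:
                        drop = [u for u in sub if sub.degree(u) < k + 1]
                        changed = bool(drop)
                        sub.remove_nodes_from(drop)
                    if v in sub:
                        k += 1
                    else:
                        break
                core[v] = k
            return core

        rng = np.random.default_rng(1)
        for _ in range(5):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
            assert core_number(g) == oracle(g)

    def test_rejects_self_loops(self):
        g = nx.Graph([("a", "a")])
        with pytest.raises(ValueError, match="self-loop"):
            core_number(g)


class TestVertexWeight:
    def test_isolated_vertex_zero(self):
        g = nx.Graph()
        g.add_node("v")
        assert vertex_weight(g, "v") == 0.0

    def test_triangle_vertex_weighs_two(self):
        # closed neighbourhood is K3: highest core k=2, density 1
        g = nx.complete_graph(3)
        assert vertex_weight(g, 0) == pytest.approx(2.0)

    def test_k4_vertex_weighs_three(self):
        g = nx.complete_graph(4)
        assert vertex_weight(g, 0) == pytest.approx(3.0)

    def test_bridge_vertex_weight_below_threshold(self):
        g = two_triangles_with_bridge()
        # x's closed neighbourhood {x,a,d} is a path: k=1, density 2/3
        assert vertex_weight(g, "x") == pytest.approx(2.0 / 3.0)
        assert vertex_weight(g, "a") == pytest.approx(2.0)


class TestFindComplexes:
    def test_two_triangles_isolated_from_bridge(self):
        complexes = find_complexes(two_triangles_with_bridge())
        assert sorted(sorted(c) for c in complexes) == [["a", "b", "c"], ["d", "e", "f"]]

    def test_k5_single_complex(self):
        complexes = find_complexes(nx.complete_graph(5))
        assert complexes == [frozenset(range(5))]

    def test_edgeless_graph_no_complexes(self):
        g = nx.empty_graph(6)
        assert find_complexes(g) == []

    def test_vertex_disjoint_without_fluff(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            g = nx.gnp_random_graph(25, 0.2, seed=int(rng.integers(2**31)))
            complexes = find_complexes(g)
            seen = set()
            for c in complexes:
                assert not (c & seen)
                seen |= c


class TestPostProcess:
    def test_triangle_survives_with_score_three(self):
        g = nx.complete_graph(3)
        mods = post_process([frozenset(g)], g)
        assert len(mods) == 1
        assert mods[0].score == pytest.approx(3.0)

    def test_star_filtered_by_two_core_rule(self):
        g = nx.star_graph(3)  # K1,3: no 2-core
        assert post_process([frozenset(g)], g) == []

    def test_haircut_removes_pendant(self):
        g = nx.complete_graph(3)
        g.add_edge(0, "p")
        mods = post_process([frozenset(g)], g, McodeParams(haircut=True))
        assert mods[0].members == frozenset({0, 1, 2})
        assert mods[0].score == pytest.approx(3.0)

    def test_haircut_off_keeps_pendant(self):
        g = nx.complete_graph(3)
        g.add_edge(0, "p")
        mods = post_process([frozenset(g)], g, McodeParams(haircut=False))
        assert mods[0].members == frozenset({0, 1, 2, "p"})

    def test_fluff_adds_dense_neighbour(self):
        g = nx.complete_graph(4)
        g.add_edges_from([(0, "n"), (1, "n"), (2, "n")])
        mods = post_process(
            [frozenset({0, 1, 2, 3})], g,
            McodeParams(haircut=False, fluff=True, fluff_cutoff=0.2),
        )
        assert "n" in mods[0].members


class TestScoreComplex:
    @pytest.mark.parametrize("nodes, edges, printed", UP_MODULE_TRIPLES + DOWN_MODULE_TRIPLES)
    def test_reproduces_printed_module_scores(self, nodes, edges, printed):
        assert format_score(score_complex(nodes, edges)) == printed

    def test_rejects_single_node(self):
        with pytest.raises(ValueError):
            score_complex(1, 0)

    def test_identity_2e_over_v_minus_1(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            v = int(rng.integers(2, 50))
            e = int(rng.integers(0, v * (v - 1) // 2 + 1))
            assert score_complex(v, e) == pytest.approx(2 * e / (v - 1))


class TestMcodeEndToEnd:
    def test_two_triangle_modules_under_defaults(self):
        mods = mcode(two_triangles_with_bridge())
        assert len(mods) == 2
        assert {m.members for m in mods} == {
            frozenset({"a", "b", "c"}), frozenset({"d", "e", "f"})
        }
        assert all(m.score == pytest.approx(3.0) for m in mods)

    def test_modules_contain_k_core_and_min_degree(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            g = nx.gnp_random_graph(30, 0.15, seed=int(rng.integers(2**31)))
            for m in mcode(g):
                sub = g.subgraph(m.members)
                assert max(core_number(sub).values()) >= 2
                assert min(dict(sub.degree()).values()) >= 2  # haircut on

    def test_deterministic_under_vertex_relabelling_order(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(25, 0.25, seed=99)
        g = nx.relabel_nodes(g, {v: f"n{v:02d}" for v in g})
        baseline = mcode(g)
        for _ in range(3):
            order = list(g.nodes)
            rng.shuffle(order)
            h = nx.Graph()
            h.add_nodes_from(order)
            edges = list(g.edges)
            rng.shuffle(edges)
            h.add_edges_from(edges)
            mods = mcode(h)
            assert [(m.members, m.rank, m.score) for m in mods] == [
                (m.members, m.rank, m.score) for m in baseline
            ]

    def test_rejects_directed_and_multigraphs(self):
        with pytest.raises(ValueError):
            mcode(nx.DiGraph([("a", "b")]))
        with pytest.raises(ValueError):
            mcode(nx.MultiGraph([("a", "b")]))


class TestFormatScore:
    @pytest.mark.parametrize(
        "value, expected",
        [(33.142857142857, "33.143"), (9.4, "9.4"), (3.0, "3"),
         (14.0666666, "14.067"), (4.75, "4.75"), (3.3333333, "3.333")],
    )
    def test_rounding_and_trimming(self, value, expected):
        assert format_score(value) == expected
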