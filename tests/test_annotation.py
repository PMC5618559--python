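"""Annotation storage and the functional-interdependence statistic."""

import numpy as np
import pytest

from coreattach import (
    AnnotationMap,
    InterdependenceTable,
    PPINetwork,
    count_real_edges,
    dominant_term,
    expected_edges,
)

TOY_EDGES = [("A", "B"), ("A", "C"), ("B", "C"), ("C", "D"),
             ("D", "E"), ("E", "F"), ("B", "F")]


@pytest.fixture
def toy():
    """6 proteins, 7 edges, items i (on C) and j (on D) meeting across C-D."""
    net = PPINetwork(edges=TOY_EDGES)
    ann = AnnotationMap({"C": {"i"}, "D": {"j"}})
    return net, ann


class TestAnnotationMap:
    def test_indices_are_inverses(self):
        ann = AnnotationMap({"A": {"x", "y"}, "B": {"x"}})
        assert ann.proteins_of("x") == {"A", "B"}
        assert ann.proteins_of("y") == {"A"}
        for p in ann.proteins:
            for item in ann.terms_of(p):
                assert p in ann.proteins_of(item)
        assert ann.items == {"x", "y"}

    def test_unknown_protein_has_empty_set(self):
        assert AnnotationMap().terms_of("nope") == frozenset()

    def test_restrict_items(self):
        ann = AnnotationMap({"A": {"x", "y"}, "B": {"y"}})
        sub = ann.restrict_items({"x"})
        assert sub.items == {"x"} and sub.proteins == {"A"}


class TestRealAndExpectedEdges:
    def test_minimal_cross_edge(self):
        net = PPINetwork(edges=[("A", "B")])
        ann = AnnotationMap({"A": {"i"}, "B": {"j"}})
        assert count_real_edges(net, ann, "i", "j") == 1

    def test_edge_counted_once_not_per_combination(self):
        # both endpoints carry both items: still one edge
        net = PPINetwork(edges=[("A", "B")])
        ann = AnnotationMap({"A": {"i", "j"}, "B": {"i", "j"}})
        assert count_real_edges(net, ann, "i", "j") == 1

    def test_unknown_items_give_zero(self, toy):
        net, ann = toy
        assert count_real_edges(net, ann, "i", "zzz") == 0

    def test_expected_edges_hand_value(self):
        # 4 edges, 2 touch i (A-B, B-C), 2 touch j (C-D, D-E) -> 2*2/4 = 1
        net = PPINetwork(edges=[("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
        ann = AnnotationMap({"B": {"i"}, "D": {"j"}})
        assert expected_edges(net, ann, "i", "j") == pytest.approx(1.0)

    def test_expected_edges_diagonal_upper_bound(self):
        # i touching every edge: ee(i,i) = |E|
        net = PPINetwork(edges=[("A", "B"), ("B", "C")])
        ann = AnnotationMap({"B": {"i"}})
        assert expected_edges(net, ann, "i", "i") == pytest.approx(net.n_edges)

    def test_absent_item_expected_zero(self, toy):
        net, ann = toy
        assert expected_edges(net, ann, "i", "zzz") == 0.0

    def test_empty_edge_set_rejected(self):
        net = PPINetwork(vertices=["A", "B"])
        with pytest.raises(ValueError):
            expected_edges(net, AnnotationMap({"A": {"i"}}), "i", "i")


class TestInterdependence:
    def test_frozen_toy_value_as_printed(self, toy):
        # independent hand derivation: m_i=3, m_j=2, re=1, |E|=7, S=5,
        # ee=6/7, brackets 34/49 and 39/49 -> fr = 2401/7956
        net, ann = toy
        table = InterdependenceTable(net, ann)
        assert table.real_edges("i", "j") == 1
        assert table.expected("i", "j") == pytest.approx(6 / 7)
        assert table.fr("i", "j") == pytest.approx(0.3017848164906988)

    def test_frozen_toy_value_z_score(self, toy):
        net, ann = toy
        table = InterdependenceTable(net, ann, variant="z-score")
        assert table.fr("i", "j") == pytest.approx(0.2076345747738762)

    def test_zero_when_observed_equals_expected(self):
        # u (item i) and v (item j) each touch 3 of the 9 edges and meet
        # once across u-v: ee = 3*3/9 = 1 = re, so fr is exactly 0
        net = PPINetwork(edges=[("u", "a"), ("u", "b"), ("u", "v"),
                                ("v", "d"), ("v", "e"),
                                ("w1", "w2"), ("w3", "w4"), ("w5", "w6"), ("w7", "w8")])
        ann = AnnotationMap({"u": {"i"}, "v": {"j"}})
        table = InterdependenceTable(net, ann)
        assert table.real_edges("i", "j") == 1
        assert table.expected("i", "j") == pytest.approx(1.0)
        assert table.fr("i", "j") == 0.0

    def test_positive_when_observed_exceeds_expected(self):
        net = PPINetwork(edges=[("A", "B"), ("C", "D"), ("E", "F"), ("G", "H")])
        ann = AnnotationMap({"A": {"i"}, "B": {"j"}})
        table = InterdependenceTable(net, ann)
        # m_i=m_j=1, |E|=4, ee=1/4, re=1 > ee
        assert table.fr("i", "j") > 0

    def test_symmetry(self, toy):
        net, ann = toy
        table = InterdependenceTable(net, ann)
        assert table.fr("i", "j") == table.fr("j", "i")
        assert table.is_interdependent("i", "j") == table.is_interdependent("j", "i")

    def test_identity_always_interdependent(self, toy):
        net, ann = toy
        table = InterdependenceTable(net, ann)
        assert table.is_interdependent("i", "i")
        assert table.is_interdependent("unseen", "unseen")

    def test_threshold_is_strict(self, toy):
        net, ann = toy
        value = InterdependenceTable(net, ann).fr("i", "j")
        at = InterdependenceTable(net, ann, threshold=value)
        assert not at.is_interdependent("i", "j")  # fr == threshold -> not >
        below = InterdependenceTable(net, ann, threshold=value - 1e-9)
        assert below.is_interdependent("i", "j")

    def test_undefined_fr_is_not_interdependent(self, toy):
        net, ann = toy
        table = InterdependenceTable(net, ann)
        assert table.fr("i", "zzz") is None
        assert not table.is_interdependent("i", "zzz")

    def test_build_is_pure(self, toy):
        net, ann = toy
        a = InterdependenceTable(net, ann)
        b = InterdependenceTable(net, ann)
        assert a.fr("i", "j") == b.fr("i", "j")
        assert a.real_edges("i", "j") == b.real_edges("i", "j")

    def test_expected_upper_bounds_null_mean(self):
        """ee counts both orientations, so it upper-bounds the expected
        cross-annotated count under random placement (the statistic is
        conservative); re centres on about ee/2 for disjoint single-item
        annotations."""
        rng = np.random.default_rng(42)
        n, target_edges = 60, 90
        edges = set()
        while len(edges) < target_edges:
            u, v = rng.integers(n, size=2)
            if u != v:
                edges.add((f"p{min(u, v)}", f"p{max(u, v)}"))
        net = PPINetwork(edges=sorted(edges))
        diffs, half_diffs = [], []
        for _ in range(200):
            pick = rng.choice(n, size=12, replace=False)
            ann = AnnotationMap(
                {f"p{k}": {"i"} for k in pick[:6]} | {f"p{k}": {"j"} for k in pick[6:]}
            )
            table = InterdependenceTable(net, ann)
            re_ij = table.real_edges("i", "j")
            ee_ij = table.expected("i", "j")
            diffs.append(re_ij - ee_ij)
            half_diffs.append(re_ij - ee_ij / 2)
        diffs, half_diffs = np.asarray(diffs), np.asarray(half_diffs)
        assert diffs.mean() < 0  # systematic conservatism
        se = half_diffs.std() / np.sqrt(len(half_diffs))
        assert abs(half_diffs.mean()) < 4 * se + 0.05


class TestDominantTerm:
    def test_majority_item_wins(self):
        ann = AnnotationMap({f"p{k}": {"X"} for k in range(4)}
                            | {"p4": {"Y"}, "p0": {"Y"}})
        assert dominant_term([f"p{k}" for k in range(5)], ann) == "X"

    def test_unannotated_members_give_none(self):
        assert dominant_term(["a", "b"], AnnotationMap()) is None

    def test_tie_breaks_to_smaller_item_id(self):
        ann = AnnotationMap({"a": {"B", "A"}, "b": {"A", "B"}, "c": {"B", "A"}})
        assert dominant_term(["a", "b", "c"], ann) == "A"
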