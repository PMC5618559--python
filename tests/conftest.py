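import pytest

from coreattach import AnnotationMap, PPINetwork


@pytest.fixture
def triangle_net() -> PPINetwork:
    """Isolated triangle A-B-C."""
    return PPINetwork(edges=[("A", "B"), ("A", "C"), ("B", "C")])


@pytest.fixture
def two_triangles_net() -> PPINetwork:
    """Two triangles sharing the edge B-C (cliques {A,B,C} and {B,C,D})."""
    return PPINetwork(edges=[("A", "B"), ("A", "C"), ("B", "C"), ("B", "D"), ("C", "D")])


@pytest.fixture
def merge_family_net() -> PPINetwork:
    """Union of the six triangles of the worked merge example.

    Cliques {A,B,C},{A,B,D},{A,B,H},{A,C,E},{B,C,F},{B,C,G} around the
    seed triangle {A,B,C}.
    """
    cliques = [frozenset(s) for s in ("ABC", "ABD", "ABH", "ACE", "BCF", "BCG")]
    edges = set()
    for c in cliques:
        cc = sorted(c)
        for i in range(3):
            for j in range(i + 1, 3):
                edges.add((cc[i], cc[j]))
    return PPINetwork(edges=sorted(edges))


@pytest.fixture
def merge_family_cliques() -> list[frozenset[str]]:
    return [frozenset(s) for s in ("ABC", "ABD", "ABH", "ACE", "BCF", "BCG")]


class StubInterdependence:
    """Interdependence oracle with a fixed set of interdependent pairs.

    Stands in for a fitted InterdependenceTable in tests where the fr
    relation itself is the given of the scenario.
    """

    def __init__(self, ann: AnnotationMap, pairs=()):
        self.ann = ann
        self._pairs = {frozenset(p) for p in pairs}

    def is_interdependent(self, i: str, j: str) -> bool:
        return i == j or frozenset((i, j)) in self._pairs


@pytest.fixture
def stub_table_factory():
    return StubInterdependence
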