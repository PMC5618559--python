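"""Graph data model and topological scoring primitives.

A protein–protein interaction (PPI) network is an undirected, unweighted
graph whose vertices are protein identifiers (opaque strings).  All the
scores used by the core-detection and attachment phases are defined here:

* ``density`` — edge richness of an induced subgraph, ``2|E'| / (|V'|(|V'|-1))``.
* ``closeness`` (cf) — density times the mean fraction of each member's
  neighbours that lie inside the subgraph.  This is the objective that
  complex cores locally maximise: it rewards subgraphs that are densely
  connected inside and sparsely connected to the rest of the network.
* ``neighborhood_affinity`` (NS) — overlap similarity ``|A∩B|² / (|A||B|)``
  between two vertex sets, used both to merge similar candidate cores and
  to match predictions against reference complexes.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "PPINetwork",
    "Cluster",
    "density",
    "closeness",
    "neighborhood_affinity",
    "external_boundary",
    "enumerate_maximal_cliques",
]


class PPINetwork:
    """An undirected PPI network backed by a :class:`networkx.Graph`.

    Self-loops are rejected and each unordered pair is stored once.
    Neighbour sets are cached as frozensets so the closeness function,
    which is evaluated many thousands of times during detection, does not
    repeatedly materialise networkx adjacency views.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = (), vertices: Iterable[str] = ()):
        g = nx.Graph()
        g.add_nodes_from(vertices)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r} not allowed")
            g.add_edge(u, v)
        self._g = g
        self._nbrs: dict[str, frozenset[str]] = {v: frozenset(g[v]) for v in g}

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "PPINetwork":
        net = cls.__new__(cls)
        h = nx.Graph()
        h.add_nodes_from(g.nodes)
        h.add_edges_from((u, v) for u, v in g.edges if u != v)
        net._g = h
        net._nbrs = {v: frozenset(h[v]) for v in h}
        return net

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def vertices(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str]]:
        return iter(self._g.edges)

    def degree(self, v: str) -> int:
        return len(self._nbrs[v])

    def neighbors(self, v: str) -> frozenset[str]:
        """The open neighbourhood N_v."""
        return self._nbrs[v]

    def has_vertex(self, v: str) -> bool:
        return v in self._nbrs

    def __contains__(self, v: str) -> bool:
        return v in self._nbrs

    def __len__(self) -> int:
        return self.n_vertices


class Cluster:
    """A nonempty vertex subset of a network (an induced subgraph G')."""

    __slots__ = ("members", "net")

    def __init__(self, members: Iterable[str], net: PPINetwork):
        ms = frozenset(members)
        if not ms:
            raise ValueError("cluster must be nonempty")
        missing = [v for v in ms if v not in net]
        if missing:
            raise ValueError(f"members not in network: {sorted(missing)[:5]}")
        self.members = ms
        self.net = net

    def __len__(self) -> int:
        return len(self.members)

    def internal_neighbors(self, v: str) -> frozenset[str]:
        """N_v^G' = N_v ∩ members."""
        return self.net.neighbors(v) & self.members

    def internal_edge_count(self) -> int:
        return sum(len(self.net.neighbors(v) & self.members) for v in self.members) // 2


def density(c: Cluster) -> float:
    """density(G') = 2|E'| / (|V'| (|V'|−1)); requires |G'| ≥ 2."""
    n = len(c)
    if n < 2:
        raise ValueError("density requires a cluster of size >= 2")
    return 2.0 * c.internal_edge_count() / (n * (n - 1))


def closeness(c: Cluster) -> float:
    """cf(G') = density(G') × mean_v |N_v^G'| / |N_v|.

    Every member must have degree ≥ 1 in the full network (callers only
    score connected candidate regions).
    """
    members = c.members
    net = c.net
    n = len(members)
    if n < 2:
        raise ValueError("closeness requires a cluster of size >= 2")
    inside = 0
    ratio_sum = 0.0
    for v in members:
        nv = net.neighbors(v)
        if not nv:
            raise ValueError(f"member {v!r} is isolated (degree 0)")
        k = len(nv & members)
        inside += k
        ratio_sum += k / len(nv)
    dens = inside / (n * (n - 1))  # inside double-counts edges: 2|E'| already
    return dens * (ratio_sum / n)


def closeness_of(members: frozenset[str] | set[str], net: PPINetwork) -> float:
    """cf over a raw member set; iteration is sorted so the float value is
    identical across processes regardless of hash seeding."""
    n = len(members)
    inside = 0
    ratio_sum = 0.0
    for v in sorted(members):
        nv = net.neighbors(v)
        k = len(nv & members)
        inside += k
        ratio_sum += k / len(nv)
    return (inside / (n * (n - 1))) * (ratio_sum / n)


def closeness_exact(members: frozenset[str] | set[str], net: PPINetwork) -> Fraction:
    """cf as an exact rational.

    Greedy pruning and growth compare cf values whose difference can be
    mathematically zero; exact arithmetic keeps those ties real instead
    of leaving them to float rounding, so every tie-break is principled
    and every run is reproducible.
    """
    n = len(members)
    inside = 0
    ratio_sum = Fraction(0)
    for v in members:
        nv = net.neighbors(v)
        k = len(nv & members)
        inside += k
        ratio_sum += Fraction(k, len(nv))
    return Fraction(inside, n * (n - 1)) * ratio_sum / n


def neighborhood_affinity(a: Iterable[str], b: Iterable[str]) -> float:
    """NS(A, B) = |A∩B|² / (|A|·|B|); symmetric, in [0, 1], 1 iff A = B."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("neighborhood affinity is undefined for empty sets")
    inter = len(sa & sb)
    return inter * inter / (len(sa) * len(sb))


def external_boundary(c: Cluster) -> set[str]:
    """Vob(G'): non-members with at least one edge into the cluster."""
    return boundary_of(c.members, c.net)


def boundary_of(members: frozenset[str] | set[str], net: PPINetwork) -> set[str]:
    out: set[str] = set()
    for v in members:
        out.update(net.neighbors(v))
    out -= set(members)
    return out


def enumerate_maximal_cliques(net: PPINetwork, min_size: int = 3) -> list[frozenset[str]]:
    """All maximal cliques of size ≥ ``min_size``, canonically ordered.

    Uses pivoting Bron–Kerbosch via networkx; the downstream merge phase
    consumes the *set* of maximal cliques, so any correct enumeration is
    equivalent.  Output is sorted by size then lexicographic member tuple
    so runs are reproducible regardless of hash ordering.
    """
    cliques = [frozenset(c) for c in nx.find_cliques(net.graph) if len(c) >= min_size]
    return sorted(cliques, key=canonical_key)


def canonical_key(members: frozenset[str]) -> tuple[int, tuple[str, ...]]:
    return (len(members), tuple(sorted(members)))


def brute_force_maximal_cliques(net: PPINetwork, min_size: int = 3) -> list[frozenset[str]]:
    """Independent oracle: maximal cliques by exhaustive subset enumeration.

    Exponential; only usable on graphs with at most ~15 vertices.  Kept in
    the library (not the test suite) so the equivalence check is reusable.
    """
    verts = sorted(net.vertices)
    if len(verts) > 16:
        raise ValueError("brute force limited to 16 vertices")
    cliques = []
    for r in range(1, len(verts) + 1):
        for sub in itertools.combinations(verts, r):
            if all(v in net.neighbors(u) for u, v in itertools.combinations(sub, 2)):
                cliques.append(frozenset(sub))
    maximal = [
        c for c in cliques
        if not any(c < d for d in cliques)
    ]
    return sorted((c for c in maximal if len(c) >= min_size), key=canonical_key)
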