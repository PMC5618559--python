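"""GO annotation storage and the functional-interdependence statistic.

Two GO items i and j are *functionally interdependent* when the number of
network edges joining an i-annotated protein to a j-annotated protein
exceeds what random placement would predict.  With

* ``re_ij`` — observed count of edges with one endpoint annotated i and the
  other annotated j (each edge counted once),
* ``m_i``  — number of edges with at least one endpoint annotated i,
* ``ee_ij = m_i · m_j / |E|`` — the expected cross-annotated edge count,

the statistic is::

    fr_ij = (re_ij − ee_ij) / [ ee_ij · (1 − Σ_k ee_ik/|E|) · (1 − Σ_k ee_kj/|E|) ]

with the sums running over every GO item present in the annotation map.
Items are declared interdependent when ``fr > 1.96`` (strict).  The printed
denominator carries no square root even though 1.96 is the two-sided 5%
normal critical value; a ``z_score`` variant that divides by the square
root of the same denominator is available for users who want the
conventional z-statistic reading.  Pairs whose denominator is zero or
negative are defined non-interdependent rather than raising mid-pipeline:
sparsely annotated items must not abort detection.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from typing import Iterable, Mapping, Optional

from .graph import PPINetwork

__all__ = [
    "AnnotationMap",
    "InterdependenceTable",
    "count_real_edges",
    "expected_edges",
    "dominant_term",
    "is_coherent",
    "coherence_rate",
]

logger = logging.getLogger(__name__)

#: two-sided 5% normal critical value used as the interdependence cutoff
DEFAULT_FR_THRESHOLD = 1.96


class AnnotationMap:
    """Protein → set of GO item IDs, with the inverse index kept in sync.

    Queries for unknown proteins return the empty set; they never fail.
    """

    def __init__(self, mapping: Optional[Mapping[str, Iterable[str]]] = None):
        self._by_protein: dict[str, frozenset[str]] = {}
        self._by_item: dict[str, set[str]] = {}
        if mapping:
            for protein, items in mapping.items():
                self.annotate(protein, items)

    def annotate(self, protein: str, items: Iterable[str]) -> None:
        new = frozenset(items) | self._by_protein.get(protein, frozenset())
        self._by_protein[protein] = new
        for item in new:
            self._by_item.setdefault(item, set()).add(protein)

    def terms_of(self, protein: str) -> frozenset[str]:
        return self._by_protein.get(protein, frozenset())

    def proteins_of(self, item: str) -> frozenset[str]:
        return frozenset(self._by_item.get(item, ()))

    @property
    def items(self) -> frozenset[str]:
        """GI — every GO item present in the map."""
        return frozenset(self._by_item)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self._by_protein)

    def __len__(self) -> int:
        return len(self._by_protein)

    def restrict_items(self, keep: Iterable[str]) -> "AnnotationMap":
        """A copy keeping only the given GO items (e.g. one namespace)."""
        keep = frozenset(keep)
        out = AnnotationMap()
        for protein, items in self._by_protein.items():
            kept = items & keep
            if kept:
                out.annotate(protein, kept)
        return out


def count_real_edges(net: PPINetwork, ann: AnnotationMap, i: str, j: str) -> int:
    """re_ij: edges (u,v) with i ∈ ann(u), j ∈ ann(v) or vice versa.

    Each edge contributes at most 1 regardless of how many annotation
    combinations realise the pair.
    """
    n = 0
    for u, v in net.edges():
        au, av = ann.terms_of(u), ann.terms_of(v)
        if (i in au and j in av) or (j in au and i in av):
            n += 1
    return n


def _edges_touching(net: PPINetwork, ann: AnnotationMap) -> Counter:
    """m_x for every item x: edges with ≥ 1 endpoint annotated with x."""
    m: Counter = Counter()
    for u, v in net.edges():
        for item in ann.terms_of(u) | ann.terms_of(v):
            m[item] += 1
    return m


def expected_edges(net: PPINetwork, ann: AnnotationMap, i: str, j: str) -> float:
    """ee_ij = m_i · m_j / |E|; requires a nonempty edge set."""
    if net.n_edges == 0:
        raise ValueError("expected edge count undefined on an empty edge set")
    m = _edges_touching(net, ann)
    return m[i] * m[j] / net.n_edges


def dominant_term(members: Iterable[str], ann: AnnotationMap) -> Optional[str]:
    """The GO item annotating the most members; ties → lexicographically
    smallest item ID; ``None`` when no member is annotated."""
    counts: Counter = Counter()
    for p in members:
        counts.update(ann.terms_of(p))
    if not counts:
        return None
    # max count first, then smallest item ID
    return min(counts, key=lambda item: (-counts[item], item))


class InterdependenceTable:
    """Lazy per-pair fr statistics over a network + annotation map.

    Only pairs actually queried (or co-occurring across an edge) are
    materialised; the full |GI|² table never exists.  The table is pure:
    the same network and annotations always produce identical values.
    """

    def __init__(
        self,
        net: PPINetwork,
        ann: AnnotationMap,
        threshold: float = DEFAULT_FR_THRESHOLD,
        variant: str = "as-printed",
    ):
        if variant not in ("as-printed", "z-score"):
            raise ValueError(f"unknown fr variant {variant!r}")
        if net.n_edges == 0:
            raise ValueError("interdependence table requires a nonempty edge set")
        self.net = net
        self.ann = ann
        self.threshold = threshold
        self.variant = variant
        self._m = _edges_touching(net, ann)          # m_x per item
        self._m_total = sum(self._m.values())        # Σ_k m_k
        self._re: dict[frozenset, int] = self._count_all_real_edges()
        self._fr_cache: dict[frozenset, Optional[float]] = {}

    def _count_all_real_edges(self) -> dict[frozenset, int]:
        re: dict[frozenset, int] = {}
        for u, v in self.net.edges():
            au, av = self.ann.terms_of(u), self.ann.terms_of(v)
            pairs = {frozenset((i, j)) for i in au for j in av}
            for pair in pairs:
                re[pair] = re.get(pair, 0) + 1
        return re

    def real_edges(self, i: str, j: str) -> int:
        return self._re.get(frozenset((i, j)), 0)

    def expected(self, i: str, j: str) -> float:
        return self._m[i] * self._m[j] / self.net.n_edges

    def _bracket(self, i: str) -> float:
        # 1 − Σ_k ee_ik/|E|  with  ee_ik = m_i·m_k/|E|
        e = self.net.n_edges
        return 1.0 - self._m[i] * self._m_total / (e * e)

    def fr(self, i: str, j: str) -> Optional[float]:
        """fr(i, j), or ``None`` when undefined (ee = 0 or a bracket ≤ 0)."""
        key = frozenset((i, j))
        if key in self._fr_cache:
            return self._fr_cache[key]
        ee = self.expected(i, j)
        bi, bj = self._bracket(i), self._bracket(j)
        if ee <= 0 or bi <= 0 or bj <= 0:
            logger.debug("fr undefined for (%s, %s): ee=%g brackets=(%g, %g)", i, j, ee, bi, bj)
            value: Optional[float] = None
        else:
            denom = ee * bi * bj
            if self.variant == "z-score":
                denom = math.sqrt(denom)
            value = (self.real_edges(i, j) - ee) / denom
        self._fr_cache[key] = value
        return value

    def is_interdependent(self, i: str, j: str) -> bool:
        """True iff i = j, or fr(i, j) is defined and exceeds the threshold
        (strict inequality: fr = 1.96 exactly is *not* interdependent)."""
        if i == j:
            return True
        value = self.fr(i, j)
        return value is not None and value > self.threshold


def is_coherent(members: Iterable[str], table: InterdependenceTable) -> bool:
    """Whether a member set passes the dominant-term coherence test.

    True when a dominant GO item m exists and every member is annotated by
    m or by some item interdependent with m.
    """
    members = list(members)
    m = dominant_term(members, table.ann)
    if m is None:
        return False
    for p in members:
        items = table.ann.terms_of(p)
        if m in items:
            continue
        if not any(table.is_interdependent(m, j) for j in items):
            return False
    return True


def coherence_rate(member_sets: Iterable[Iterable[str]], table: InterdependenceTable) -> float:
    """Fraction of the given member sets that are functionally coherent."""
    sets = [list(s) for s in member_sets]
    if not sets:
        return 0.0
    return sum(is_coherent(s, table) for s in sets) / len(sets)
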