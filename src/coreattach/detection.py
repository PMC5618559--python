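"""Complex-core detection: clique merging under the closeness objective.

Candidate cores start as the maximal cliques of the network (size ≥ 3).
Cores whose neighbourhood-affinity score against a seed core reaches the
merge threshold ``t`` form the seed's *family*; each family is collapsed
into a single candidate core by:

1. taking the union of all family members,
2. (GO mode) dropping every protein neither annotated by the union's
   dominant GO item nor by an item functionally interdependent with it,
3. greedily deleting the protein whose removal most increases the
   closeness function cf, while a strict increase exists and the core
   stays at the minimum size.

The family/merge loop runs to convergence first within each clique-size
stratum and then once more over the pooled strata — processing sizes
separately stops large cliques annexing small ones before the small ones
have consolidated.  Detected cores are pairwise dissimilar (NS < t),
size ≥ 3, locally cf-optimal under single removals, and (in GO mode)
functionally coherent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .annotation import InterdependenceTable, dominant_term
from .graph import (
    PPINetwork,
    canonical_key,
    closeness_exact,
    enumerate_maximal_cliques,
    neighborhood_affinity,
)

__all__ = ["DetectionParams", "CandidateCoreFamily", "build_family",
           "merge_similar_cores", "detect_cores"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the core-detection phase.

    t : NS merge threshold in (0, 1].  0.4 balances the number of
        predicted complexes against their quality; values above 4/9
        stop size-3 cores sharing two proteins from merging and flood
        the output with low-confidence triangles.
    min_core_size : cores smaller than this are discarded (≥ 3).
    fr_threshold : interdependence cutoff for the GO filter.
    use_go : False disables every GO-based filter (pure-topology mode).
    fr_variant : "as-printed" or "z-score" denominator for fr.
    max_iterations : safety cap on each merge loop.
    """

    t: float = 0.4
    min_core_size: int = 3
    fr_threshold: float = 1.96
    use_go: bool = True
    fr_variant: str = "as-printed"
    max_iterations: int = 100

    def __post_init__(self):
        if not (0.0 < self.t <= 1.0):
            raise ValueError(f"t must be in (0, 1], got {self.t}")
        if self.min_core_size < 3:
            raise ValueError(f"min_core_size must be >= 3, got {self.min_core_size}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


@dataclass
class CandidateCoreFamily:
    """A seed core plus every pool core with NS(seed, ·) ≥ t."""

    seed: frozenset[str]
    members: list[frozenset[str]] = field(default_factory=list)

    def union(self) -> set[str]:
        out: set[str] = set()
        for m in self.members:
            out |= m
        return out


def build_family(seed: frozenset[str], pool: Sequence[frozenset[str]], t: float) -> CandidateCoreFamily:
    """Family of ``seed``: itself plus every pool core with NS ≥ t.

    The comparison is ≥ (inclusive), so t = 4/9 still merges two
    triangles sharing two vertices while any larger t keeps them apart.
    """
    members = [seed]
    for cand in pool:
        if cand == seed:
            continue
        if neighborhood_affinity(seed, cand) >= t:
            members.append(cand)
    return CandidateCoreFamily(seed=seed, members=members)


def _go_filter(
    ps: set[str],
    table: InterdependenceTable,
    fr_threshold: float,
) -> set[str]:
    """Keep proteins annotated by the dominant item m of ``ps`` or by an
    item interdependent with m; keep everything if no member is annotated."""
    m = dominant_term(ps, table.ann)
    if m is None:
        logger.debug("no annotated member in candidate core %s; GO filter skipped", sorted(ps))
        return ps
    kept = set()
    for p in ps:
        items = table.ann.terms_of(p)
        if m in items or any(table.is_interdependent(m, j) for j in items):
            kept.add(p)
    return kept


def _prune_by_closeness(ps: set[str], net: PPINetwork, min_size: int) -> set[str]:
    """Greedily remove argmax_p cf(PS − {p}) while the removal strictly
    increases cf and the core stays at ``min_size``.

    cf comparisons are exact rationals; argmax ties break toward the
    lexicographically largest protein ID (this deterministic convention
    also reproduces the published worked merge trace).
    """
    ps = set(ps)
    while len(ps) > min_size:
        current = closeness_exact(ps, net)
        best_cf, best_p = max(
            ((closeness_exact(ps - {p}, net), p) for p in ps),
            key=lambda pair: (pair[0], pair[1]),
        )
        if best_cf <= current:
            break
        ps.remove(best_p)
    return ps


def merge_similar_cores(
    family: CandidateCoreFamily,
    net: PPINetwork,
    table: Optional[InterdependenceTable],
    params: DetectionParams,
) -> frozenset[str]:
    """Collapse a candidate-core family into one candidate core.

    Returns the empty frozenset when filtering leaves fewer than
    ``min_core_size`` proteins (the candidate is discarded).
    """
    ps = family.union()
    if params.use_go:
        if table is None:
            raise ValueError("GO mode requires an interdependence table")
        ps = _go_filter(ps, table, params.fr_threshold)
    if len(ps) < params.min_core_size:
        return frozenset()
    ps = _prune_by_closeness(ps, net, params.min_core_size)
    if len(ps) < params.min_core_size:
        return frozenset()
    return frozenset(ps)


def _any_similar_pair(cores: Sequence[frozenset[str]], t: float) -> bool:
    for i in range(len(cores)):
        for j in range(i + 1, len(cores)):
            if neighborhood_affinity(cores[i], cores[j]) >= t:
                return True
    return False


def _merge_loop(
    cores: Sequence[frozenset[str]],
    net: PPINetwork,
    table: Optional[InterdependenceTable],
    params: DetectionParams,
) -> list[frozenset[str]]:
    """The family→merge→dedupe loop, repeated until no pair has NS ≥ t.

    Do-while semantics: every candidate passes through the merge (and so
    through the GO filter and cf pruning) at least once, even when no
    pair in the pool is similar.
    """
    cs = sorted(set(cores), key=canonical_key)
    for _ in range(params.max_iterations):
        pool = cs
        seen: set[frozenset[str]] = set()
        nxt: list[frozenset[str]] = []
        for seed in pool:
            family = build_family(seed, pool, params.t)
            merged = merge_similar_cores(family, net, table, params)
            if merged and merged not in seen:
                seen.add(merged)
                nxt.append(merged)
        cs = sorted(nxt, key=canonical_key)
        if not _any_similar_pair(cs, params.t):
            return cs
        if cs == pool:
            # merging reproduced the same set while a similar pair remains:
            # no further progress is possible
            break
    if _any_similar_pair(cs, params.t):
        logger.warning("merge loop stopped with a similar core pair remaining (cap %d)",
                       params.max_iterations)
    return cs


def detect_cores(
    net: PPINetwork,
    ann_table: Optional[InterdependenceTable],
    params: DetectionParams = DetectionParams(),
) -> list[frozenset[str]]:
    """Detect complex cores from the maximal cliques of ``net``.

    Two-stage schedule: the merge loop first runs independently inside
    each clique-size stratum (ascending size), then once more over the
    pooled strata, so small cliques consolidate before they meet larger
    ones.  Output is canonically ordered (size, then member tuple).
    """
    if params.use_go and ann_table is None:
        raise ValueError("use_go=True requires an interdependence table")
    cliques = enumerate_maximal_cliques(net, min_size=params.min_core_size)
    if not cliques:
        return []

    by_size: dict[int, list[frozenset[str]]] = {}
    for c in cliques:
        by_size.setdefault(len(c), []).append(c)

    pooled: list[frozenset[str]] = []
    for size in sorted(by_size):
        pooled.extend(_merge_loop(by_size[size], net, ann_table, params))

    # the within-stratum loops run merge on every clique, but singleton
    # families can survive unfiltered when a stratum has one clique;
    # the pooled pass re-applies merge to everything
    seen = set()
    pooled_unique = []
    for c in pooled:
        if c not in seen:
            seen.add(c)
            pooled_unique.append(c)

    cores = _merge_loop(pooled_unique, net, ann_table, params)
    n_dropped = len(cliques) - len(cores)
    logger.info("detected %d cores from %d maximal cliques (net change %+d)",
                len(cores), len(cliques), -n_dropped)
    return cores
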