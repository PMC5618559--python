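"""Attachment screening: grow each detected core into a predicted complex.

A boundary protein joins a complex when admitting it strictly increases
the closeness function cf of the cluster — attachments must preserve the
dense-inside / sparse-outside topology of the core.  Growth is purely
topological: GO annotations play no role in this phase, so proteins that
were dropped from a core by the coherence filter can still re-enter a
complex as attachments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .annotation import InterdependenceTable
from .detection import DetectionParams, detect_cores
from .graph import PPINetwork, boundary_of, canonical_key, closeness_exact

__all__ = ["PredictedComplex", "grow_complex", "predict_complexes"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictedComplex:
    """A core plus the attachments admitted around it."""

    core: frozenset[str]
    attachments: frozenset[str]

    def __post_init__(self):
        if self.core & self.attachments:
            raise ValueError("core and attachments must be disjoint")
        if len(self.core) < 3:
            raise ValueError("complex core must have at least 3 members")

    @property
    def members(self) -> frozenset[str]:
        return self.core | self.attachments

    def __len__(self) -> int:
        return len(self.core) + len(self.attachments)


def grow_complex(core: frozenset[str], net: PPINetwork) -> PredictedComplex:
    """Greedy boundary accretion under the closeness objective.

    At each step every current external-boundary vertex is scored; the
    one maximising cf(c ∪ {v}) is admitted provided the maximum strictly
    exceeds cf(c) (ties → lexicographically smallest ID).  The boundary
    is recomputed after every admission.  cf is strictly increasing along
    the admission sequence; zero admissions is a valid outcome.
    """
    members = set(core)
    current = closeness_exact(members, net)
    while True:
        boundary = boundary_of(members, net)
        if not boundary:
            break
        best_v: Optional[str] = None
        best_cf = current
        for v in sorted(boundary):  # sorted: ties keep the smallest ID
            cf_with = closeness_exact(members | {v}, net)
            if cf_with > best_cf:
                best_cf = cf_with
                best_v = v
        if best_v is None:
            break
        members.add(best_v)
        current = best_cf
    return PredictedComplex(core=frozenset(core), attachments=frozenset(members) - frozenset(core))


def predict_complexes(
    net: PPINetwork,
    ann_table: Optional[InterdependenceTable],
    params: DetectionParams = DetectionParams(),
) -> list[PredictedComplex]:
    """Full two-phase pipeline: detect cores, then grow each one.

    The final list is deduplicated by full member set (first occurrence
    keeps its core/attachment split); complexes may overlap each other.
    """
    cores = detect_cores(net, ann_table, params)
    seen: set[frozenset[str]] = set()
    out: list[PredictedComplex] = []
    for core in sorted(cores, key=canonical_key):
        cx = grow_complex(core, net)
        if cx.members not in seen:
            seen.add(cx.members)
            out.append(cx)
    n_dup = len(cores) - len(out)
    if n_dup:
        logger.info("deduplicated %d complexes identical after growth", n_dup)
    return out
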