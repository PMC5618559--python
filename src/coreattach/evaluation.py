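"""Evaluation harness: match predictions to reference complexes by NS.

A predicted complex p matches a reference complex r when their
neighbourhood-affinity score NS(p, r) = |p∩r|²/(|p||r|) reaches the
matching threshold ω (0.2 by convention, loose enough to tolerate the
incompleteness of both PPI data and curated references).  With

* Np — predicted complexes matching ≥ 1 reference,
* Nb — reference complexes matched by ≥ 1 prediction,

precision = Np/|P|, recall = Nb/|R| and the F-measure is their harmonic
mean.  A single prediction may match many references and vice versa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .graph import neighborhood_affinity

__all__ = ["EvaluationReport", "evaluate"]

logger = logging.getLogger(__name__)

DEFAULT_OMEGA = 0.2


@dataclass(frozen=True)
class EvaluationReport:
    n_predicted: int
    n_reference: int
    np_matched: int      # predicted complexes matching >= 1 reference
    nb_matched: int      # reference complexes matched by >= 1 prediction
    precision: float
    recall: float
    f_measure: float
    omega: float

    def summary(self) -> str:
        return (
            f"predicted={self.n_predicted} reference={self.n_reference} "
            f"Np={self.np_matched} Nb={self.nb_matched} "
            f"P={self.precision:.4f} R={self.recall:.4f} F={self.f_measure:.4f} "
            f"(omega={self.omega})"
        )


def _dedupe(sets: Iterable[Iterable[str]], label: str) -> list[frozenset[str]]:
    seen: set[frozenset[str]] = set()
    out: list[frozenset[str]] = []
    dups = 0
    for s in sets:
        fs = frozenset(s)
        if not fs:
            raise ValueError(f"{label} list contains an empty member set")
        if fs in seen:
            dups += 1
            continue
        seen.add(fs)
        out.append(fs)
    if dups:
        logger.info("dropped %d duplicate %s sets before evaluation", dups, label)
    return out


def evaluate(
    predicted: Iterable[Iterable[str]],
    reference: Iterable[Iterable[str]],
    omega: float = DEFAULT_OMEGA,
) -> EvaluationReport:
    """Score a prediction list against a reference list at threshold ω.

    Both lists are deduplicated by member set before counting; either
    list being empty is an error.
    """
    pred = _dedupe(predicted, "predicted")
    ref = _dedupe(reference, "reference")
    if not pred:
        raise ValueError("predicted complex list is empty")
    if not ref:
        raise ValueError("reference complex list is empty")

    matched_ref: set[int] = set()
    n_p = 0
    for p in pred:
        hit = False
        for k, r in enumerate(ref):
            if neighborhood_affinity(p, r) >= omega:
                hit = True
                matched_ref.add(k)
        if hit:
            n_p += 1
    n_b = len(matched_ref)

    precision = n_p / len(pred)
    recall = n_b / len(ref)
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return EvaluationReport(
        n_predicted=len(pred),
        n_reference=len(ref),
        np_matched=n_p,
        nb_matched=n_b,
        precision=precision,
        recall=recall,
        f_measure=f,
        omega=omega,
    )
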