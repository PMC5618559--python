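"""File readers and writers for edge lists, annotations and complex sets.

Formats are the flat-text conventions of the complex-prediction
literature: two-column interaction pair lists, two-column protein→GO
TSVs or GAF 2.x annotation files, and one-complex-per-line benchmark
files with whitespace-separated protein IDs.  Written complex files
carry the core/attachment split as ``core... | attachments...``; the
reader accepts both that form and plain benchmark lines.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .annotation import AnnotationMap
from .attachment import PredictedComplex
from .evaluation import EvaluationReport
from .graph import PPINetwork

__all__ = [
    "read_edge_list", "read_annotations_tsv", "read_annotations_gaf",
    "read_annotations", "read_complexes", "write_complexes", "write_edge_list",
    "write_annotations_tsv", "write_report",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_edge_list(path: PathLike) -> PPINetwork:
    """Load an undirected network from a whitespace/TSV pair list.

    Lines starting with ``#`` are skipped; IDs are taken verbatim
    (case-sensitive).  Duplicate edges and self-loops are dropped with a
    logged count; a line with fewer than two columns is an error.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    n_dup = 0
    n_self = 0
    n_lines = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns, got {len(fields)}")
            n_lines += 1
            u, v = fields[0], fields[1]
            if u == v:
                n_self += 1
                continue
            key = (u, v) if u < v else (v, u)
            if key in edges:
                n_dup += 1
            else:
                edges.add(key)
    if n_lines == 0:
        raise ValueError(f"{path}: no interaction pairs found")
    if n_self:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self)
    if n_dup:
        logger.warning("%s: dropped %d duplicate edge(s)", path, n_dup)
    return PPINetwork(edges=sorted(edges))


def read_annotations_tsv(path: PathLike) -> AnnotationMap:
    """Minimal two-column reader: protein <tab/space> GO item."""
    path = Path(path)
    ann = AnnotationMap()
    n = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            ann.annotate(fields[0], [fields[1]])
            n += 1
    if n == 0:
        raise ValueError(f"{path}: no annotations found")
    return ann


def read_annotations_gaf(
    path: PathLike,
    evidence_codes: Optional[Iterable[str]] = None,
) -> AnnotationMap:
    """GAF 2.x reader: column 2 = object ID, column 5 = GO ID.

    Rows with a NOT qualifier (column 4) are skipped.  ``evidence_codes``
    restricts to the given codes (column 7); default accepts all.
    """
    path = Path(path)
    accept = set(evidence_codes) if evidence_codes is not None else None
    ann = AnnotationMap()
    n = 0
    n_not = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("!"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: GAF row has {len(fields)} columns, expected >= 7")
            obj_id, qualifier, go_id, evidence = fields[1], fields[3], fields[4], fields[6]
            if "NOT" in qualifier.split("|"):
                n_not += 1
                continue
            if accept is not None and evidence not in accept:
                continue
            ann.annotate(obj_id, [go_id])
            n += 1
    if n_not:
        logger.info("%s: skipped %d NOT-qualified row(s)", path, n_not)
    if n == 0:
        raise ValueError(f"{path}: no usable GAF rows found")
    return ann


def read_annotations(path: PathLike, fmt: str = "tsv", **kwargs) -> AnnotationMap:
    if fmt == "tsv":
        return read_annotations_tsv(path)
    if fmt == "gaf":
        return read_annotations_gaf(path, **kwargs)
    raise ValueError(f"unknown annotation format {fmt!r}")


def read_complexes(path: PathLike) -> list[frozenset[str]]:
    """One complex per line, whitespace-separated protein IDs.

    A ``|`` token (the core/attachment separator emitted by
    :func:`write_complexes`) is ignored, so written files round-trip.
    Duplicate IDs within a line collapse; singleton lines are kept but
    flagged in the log.
    """
    path = Path(path)
    out: list[frozenset[str]] = []
    n_singleton = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            ids = frozenset(tok for tok in line.split() if tok != "|")
            if not ids:
                raise ValueError(f"{path}:{lineno}: empty complex line")
            if len(ids) == 1:
                n_singleton += 1
            out.append(ids)
    if not out:
        raise ValueError(f"{path}: no complexes found")
    if n_singleton:
        logger.warning("%s: %d singleton complex line(s)", path, n_singleton)
    return out


def write_complexes(
    complexes: Sequence[Union[PredictedComplex, Iterable[str]]],
    path: PathLike,
) -> None:
    """Write complexes one per line as ``core... | attachments...``.

    The ``|`` separator is always present, even with no attachments, so
    the format is unambiguous.  Plain member sets (no core/attachment
    split) are written entirely on the core side.  Members are sorted,
    so output is byte-stable for identical inputs.
    """
    path = Path(path)
    with path.open("w") as fh:
        for cx in complexes:
            if isinstance(cx, PredictedComplex):
                core, att = sorted(cx.core), sorted(cx.attachments)
            else:
                core, att = sorted(set(cx)), []
            fh.write(" ".join(core) + " |" + ("" if not att else " " + " ".join(att)) + "\n")


def write_edge_list(net: PPINetwork, path: PathLike) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u}\t{v}\n")


def write_annotations_tsv(ann: AnnotationMap, path: PathLike) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for protein in sorted(ann.proteins):
            for item in sorted(ann.terms_of(protein)):
                fh.write(f"{protein}\t{item}\n")


def write_report(report: EvaluationReport, path: PathLike) -> None:
    """Evaluation report as a two-line TSV (header + values)."""
    path = Path(path)
    fields = [
        ("n_predicted", report.n_predicted),
        ("n_reference", report.n_reference),
        ("Np", report.np_matched),
        ("Nb", report.nb_matched),
        ("precision", f"{report.precision:.6f}"),
        ("recall", f"{report.recall:.6f}"),
        ("f_measure", f"{report.f_measure:.6f}"),
        ("omega", report.omega),
    ]
    with path.open("w") as fh:
        fh.write("\t".join(k for k, _ in fields) + "\n")
        fh.write("\t".join(str(v) for _, v in fields) + "\n")
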