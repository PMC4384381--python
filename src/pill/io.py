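"""Readers and writers for the standard text inputs and outputs.

Annotations arrive as two-column TSV (protein, label; ``#`` comments
allowed) or GAF 2.x; networks as three-column TSV edge lists; ontologies as
OBO 1.2 (see :func:`pill.ontology.parse_obo`).  Predictions and result
tables leave as TSV.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .ontology import AnnotationMatrix, OntologyError

__all__ = [
    "read_annotation_tsv",
    "read_gaf",
    "read_edge_tsv",
    "write_annotation_tsv",
    "write_predictions_tsv",
    "write_correlation_tsv",
]


def _data_lines(path: str) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_annotation_tsv(path: str) -> list[tuple[str, str]]:
    """Read (protein, label) pairs from a 2-column TSV."""
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise OntologyError(f"{path}:{lineno}: expected 'protein<TAB>label'")
        rows.append((fields[0], fields[1]))
    return rows


def read_gaf(path: str, exclude_evidence: tuple[str, ...] = ("IEA",)) -> list[tuple[str, str]]:
    """Read (protein, GO term) pairs from GAF 2.x, filtering evidence codes.

    Uses column 2 (DB object ID), column 5 (GO ID) and column 7 (evidence
    code); rows with a qualifier containing NOT (column 4) are skipped.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                continue
            if "NOT" in fields[3].split("|"):
                continue
            if fields[6] in exclude_evidence:
                continue
            rows.append((fields[1], fields[4]))
    return rows


def read_edge_tsv(path: str) -> list[tuple[str, str, float]]:
    """Read a weighted edge list (protein_a, protein_b, weight) TSV.

    A missing third column defaults to weight 1.0.
    """
    edges = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise OntologyError(f"{path}:{lineno}: expected at least 2 columns")
        w = 1.0
        if len(fields) >= 3 and fields[2]:
            try:
                w = float(fields[2])
            except ValueError:
                raise OntologyError(f"{path}:{lineno}: bad weight {fields[2]!r}") from None
        edges.append((fields[0], fields[1], w))
    return edges


def write_annotation_tsv(Y: AnnotationMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# protein\tlabel\n")
        for i, protein in enumerate(Y.proteins):
            for k in np.flatnonzero(Y.Y[i]):
                fh.write(f"{protein}\t{Y.labels[k]}\n")


def write_predictions_tsv(
    proteins: list[str],
    labels: list[str],
    scores: np.ndarray,
    path: str,
    known: np.ndarray | None = None,
    top: int | None = None,
) -> None:
    """Write (protein, label, score) sorted by protein then descending score.

    Entries flagged in *known* (already-annotated) are omitted; *top* keeps
    only the best-scoring candidates per protein.
    """
    with open(path, "w") as fh:
        fh.write("# protein\tlabel\tscore\n")
        for i, protein in enumerate(proteins):
            cols = np.arange(len(labels))
            if known is not None:
                cols = cols[~known[i, cols]]
            order = cols[np.argsort(-scores[i, cols], kind="stable")]
            if top is not None:
                order = order[:top]
            for k in order:
                fh.write(f"{protein}\t{labels[k]}\t{scores[i, k]:.8g}\n")


def write_correlation_tsv(labels: list[str], S: np.ndarray, path: str) -> None:
    pd.DataFrame(S, index=labels, columns=labels).to_csv(path, sep="\t")
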