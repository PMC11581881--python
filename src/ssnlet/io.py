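"""Readers and writers for the tabular formats the pipeline touches.

Matrices (expression, methylation, degree, fold change) travel as
tab-separated text with a header row of sample ids and gene ids in the first
column.  Floats are rendered with Python's shortest round-trip ``repr``, so a
write -> read cycle reproduces values bit-for-bit.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import networkx as nx
import numpy as np
import pandas as pd

from .types import GeneAnnotation, OmicsMatrix, PPINetwork, SampleMetadata

logger = logging.getLogger(__name__)


def _read_numeric_table(path, delimiter: str) -> pd.DataFrame:
    """Parse a genes x samples table, reporting the coordinates of any
    non-numeric cell.  'NA' and empty cells are deliberate hard errors: the
    pipeline's matrices carry explicit values only."""
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                      keep_default_na=False)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    cols = {}
    for col in raw.columns:
        strings = raw[col].to_numpy()
        try:
            # numpy's parser is correctly rounded, so written floats
            # round-trip bit-for-bit
            converted = strings.astype(np.float64)
        except ValueError:
            for row, cell in zip(raw.index, strings):
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at row {row!r}, "
                        f"column {col!r}") from None
            raise
        cols[col] = converted
    out = pd.DataFrame(cols, index=raw.index)
    out.index.name = "gene_id"
    return out


def read_expression_matrix(path, delimiter: str = "\t") -> OmicsMatrix:
    """Read an FPKM gene-by-sample table (first column gene ids, header row
    sample ids) into an expression-layer :class:`OmicsMatrix`."""
    return OmicsMatrix(_read_numeric_table(path, delimiter), layer="expression")


def read_methylation_matrix(path, layer: str, delimiter: str = "\t") -> OmicsMatrix:
    """Read a previously written promoter/body methylation-level matrix."""
    raw = pd.read_csv(path, sep=delimiter, index_col=0)
    raw.index.name = "gene_id"
    return OmicsMatrix(raw, layer=layer)


def read_matrix(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a generic numeric gene-by-sample table (degree or FC matrix)."""
    return _read_numeric_table(path, delimiter)


def write_matrix(frame, path) -> None:
    """Write a gene-by-sample table as TSV (shortest round-trip floats)."""
    if isinstance(frame, OmicsMatrix):
        frame = frame.frame
    frame.to_csv(path, sep="\t", index_label="gene_id")


def read_ppi(path, min_score: float = 0.0) -> PPINetwork:
    """Parse a STRING-style edge list into an undirected simple graph.

    Each line holds two gene ids and an optional confidence score; edges below
    ``min_score`` are discarded, self-loops are dropped with a warning, and
    reversed duplicates collapse onto a single undirected edge.
    """
    g = nx.Graph()
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: malformed edge line {line!r}")
            a, b = fields[0], fields[1]
            score = None
            if len(fields) >= 3:
                try:
                    score = float(fields[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric score {fields[2]!r}") from exc
            n_lines += 1
            if a == b:
                logger.warning("%s:%d: self-loop on %s dropped", path, lineno, a)
                continue
            if score is not None and score < min_score:
                continue
            if score is None:
                g.add_edge(a, b)
            else:
                g.add_edge(a, b, score=score)
    if n_lines == 0:
        logger.warning("%s: empty PPI file, returning empty graph", path)
    return g


def write_ppi(g: PPINetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b, data in sorted(g.edges(data=True)):
            score = data.get("score")
            if score is None:
                fh.write(f"{a}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{score:g}\n")


def read_metadata(path, delimiter: str = "\t") -> SampleMetadata:
    """Read the sample sheet (sample_id/group/let_value/stage).

    An empty ``let_value`` cell means "no LET measured" and is valid only for
    ground-control rows; an SF row must state its LET explicitly (0 for a
    flown-but-unhit plant).
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]
    if "let_value" in raw.columns:
        raw["let_value"] = raw["let_value"].replace("", None)
    return SampleMetadata(raw)


def write_metadata(meta: SampleMetadata, path) -> None:
    frame = meta.frame.copy()
    frame.to_csv(path, sep="\t", index=False)


def read_annotation_gff3(path) -> GeneAnnotation:
    """Extract gene spans from a GFF3 file.

    Only features of type ``gene`` are kept; a gene without a defined strand
    is a hard error because promoter orientation depends on it.
    """
    try:
        db = gffutils.create_db(str(path), ":memory:", merge_strategy="error",
                                keep_order=True)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    records = []
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            raise ValueError(f"{path}: gene {feat.id} has undefined strand")
        records.append((feat.id, feat.seqid, feat.strand, feat.start, feat.end))
    if not records:
        logger.warning("%s: no gene features found", path)
        frame = pd.DataFrame(columns=["chrom", "strand", "start", "end"])
        frame.index.name = "gene_id"
        return GeneAnnotation(frame)
    frame = pd.DataFrame(records, columns=["gene_id", "chrom", "strand",
                                           "start", "end"]).set_index("gene_id")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    return GeneAnnotation(frame)


def write_annotation_gff3(ann: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in ann.frame.itertuples():
            fh.write(f"{row.chrom}\tssnlet\tgene\t{row.start}\t{row.end}\t."
                     f"\t{row.strand}\t.\tID={row.Index}\n")
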