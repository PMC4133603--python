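"""Readers and writers for the formats the pipeline touches.

Formats: expression TSV (genes × conditions), BED3 intervals, gene-model TSV
(gene_id, chrom, start, end, strand), 2–3 column edge lists, and GMT-like
annotation files. All readers validate and reject malformed input rather
than silently coercing it. Internal coordinates are 1-based closed; BED is
0-based half-open and conversion happens here, at the boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from grffl.datatypes import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)


def read_expression_tsv(path: str | Path, log2_input: bool = False) -> ExpressionMatrix:
    """Read a genes × conditions expression table.

    The file must have a header row of condition ids and gene ids in the
    first column. If ``log2_input`` is true the stored values are
    ``2**cell`` so that the matrix is always on the linear scale.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ParseError(f"{path}: no condition columns")
    gene_ids = [str(g) for g in df.index]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise ValidationError(f"{path}: duplicate gene ids {dupes}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0]
            raise ParseError(
                f"{path}: malformed numeric cell at gene {row!r}, column {col!r}: "
                f"{bad.iloc[0]!r}"
            ) from None
    if log2_input:
        values = np.exp2(values)
    return ExpressionMatrix(gene_ids, [str(c) for c in df.columns], values)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(m.values, index=m.gene_ids, columns=m.condition_ids).to_csv(
        path, sep="\t", index_label="gene_id"
    )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals, converting to internal 1-based closed coordinates.

    BED is 0-based half-open: ``start_internal = start_bed + 1`` and
    ``end_internal = end_bed``. Empty/invalid BED intervals (end <= start)
    are rejected. A 4th column, when present, becomes the interval label.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start_bed, end_bed = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinates") from None
            if end_bed <= start_bed:
                raise ValidationError(
                    f"{path}:{lineno}: empty or inverted BED interval "
                    f"[{start_bed}, {end_bed})"
                )
            label = fields[3] if len(fields) > 3 else ""
            intervals.append(GenomicInterval(chrom, start_bed + 1, end_bed, label))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3 (or BED4 when labelled); exact inverse of read_bed."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start - 1), str(iv.end)]
            if iv.label:
                fields.append(iv.label)
            fh.write("\t".join(fields) + "\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a 2–3 column edge-list TSV into an undirected simple graph.

    Self-loops are dropped with a warning; a duplicate edge is stored once.
    A third column is parsed as a ``weight`` attribute but all partitioning
    and topology code ignores weights and uses only connectivity.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 columns")
            u, v = fields[0], fields[1]
            if u == v:
                logger.warning("%s:%d: self-loop %s-%s dropped", path, lineno, u, v)
                g.add_node(u)
                continue
            attrs = {}
            if len(fields) > 2 and fields[2] != "":
                try:
                    attrs["weight"] = float(fields[2])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: malformed weight {fields[2]!r}") from None
            g.add_edge(u, v, **attrs)
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(g.edges(data=True)):
            if "weight" in data:
                fh.write(f"{u}\t{v}\t{data['weight']}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a gene-model TSV: gene_id, chrom, start, end, strand (1-based closed)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    genes = [
        GeneModel(str(r.gene_id), str(r.chrom), int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples(index=False)
    ]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate gene ids")
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT-like annotation file: category, description, gene, gene..."""
    categories: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs category, "
                                 "description and >= 1 gene")
            categories[fields[0]] = set(fields[2:])
    return categories


def write_gmt(categories: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for cat in sorted(categories):
            desc = (descriptions or {}).get(cat, "na")
            genes = "\t".join(sorted(categories[cat]))
            fh.write(f"{cat}\t{desc}\t{genes}\n")
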