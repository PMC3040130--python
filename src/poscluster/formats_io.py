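"""Readers and writers for the package's text formats.

Two custom on-disk formats carry results between analysis steps:

GDF (gene data file) — one gene per line, tab-delimited on write::

    dset genename chrom start end strand expr1 expr2 ...

CLU (cluster file) — a ``nClusters N`` header, then per cluster its
numeric identifier, ``beginCluster``, one member line per gene, and
``endCluster``.  Member lines are space-delimited and, unlike GDF, put
the strand BEFORE the coordinates::

    dset genename chrom strand start stop exp1 exp2 ...

Both readers accept any run of whitespace as a delimiter and skip blank
lines and ``#`` comments.  Missing expression values are written as the
literal string ``NaN`` (case-sensitive).  Round-trips are identities on
valid objects.

The two raw input tables (Biomart-style gene positions, and per-gene
expression values) are read here as well; ``dialect`` selects tab, comma
or free whitespace splitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .datamodel import (
    Cluster,
    ClusterSet,
    GeneRecord,
    GeneTable,
    RandomRunSummary,
)

NAN_TOKEN = "NaN"

RANDOM_SUMMARY_HEADER = "run n.clusts n.tot.clust.genes n.genes per cluster"


class ParseError(ValueError):
    """A malformed line in a GDF/CLU/input table, with its line number."""

    def __init__(self, path: str | Path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass(frozen=True)
class PositionRow:
    """One line of a position table: name, chrom, start, end, strand."""

    name: str
    chrom: str
    start: int
    end: int
    strand: int


@dataclass(frozen=True)
class ExpressionRow:
    """One line of an expression table: name plus its value vector."""

    name: str
    values: tuple[float, ...]


def _split(line: str, dialect: str) -> list[str]:
    if dialect == "csv":
        return [f.strip() for f in line.split(",")]
    if dialect == "tab":
        return [f.strip() for f in line.split("\t")]
    if dialect == "whitespace":
        return line.split()
    raise ValueError(f"unknown dialect {dialect!r} (use tab, csv or whitespace)")


def _content_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _parse_strand(token: str) -> int:
    if token in ("1", "+1"):
        return 1
    if token == "-1":
        return -1
    raise ValueError(f"strand must be +1 or -1, got {token!r}")


def _parse_expr(token: str) -> float:
    """Expression cell -> float; blank or non-numeric cells become NaN."""
    if token == "" or token == NAN_TOKEN:
        return math.nan
    try:
        return float(token)
    except ValueError:
        return math.nan


def _format_expr(value: float) -> str:
    if math.isnan(value):
        return NAN_TOKEN
    return repr(value)


def read_position_table(path: str | Path, dialect: str = "whitespace") -> list[PositionRow]:
    """Read a gene position table (``name chrom start end strand``).

    The column order matches a Biomart export; strand is encoded ±1.
    """
    rows: list[PositionRow] = []
    for lineno, line in _content_lines(path):
        fields = _split(line, dialect)
        if len(fields) != 5:
            raise ParseError(path, lineno, f"expected 5 columns, got {len(fields)}")
        name, chrom, start_s, end_s, strand_s = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(path, lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
        try:
            strand = _parse_strand(strand_s)
        except ValueError as e:
            raise ParseError(path, lineno, str(e))
        rows.append(PositionRow(name=name, chrom=chrom, start=start, end=end, strand=strand))
    return rows


def read_expression_table(path: str | Path, dialect: str = "whitespace") -> list[ExpressionRow]:
    """Read a per-gene expression table (``name expr1 expr2 ...``).

    Blank or non-numeric cells become the missing marker; row lengths may
    differ here and are reconciled (NaN-padded) at merge time.
    """
    rows: list[ExpressionRow] = []
    for lineno, line in _content_lines(path):
        fields = _split(line, dialect)
        if not fields or not fields[0]:
            raise ParseError(path, lineno, "missing gene name")
        name = fields[0]
        values = tuple(_parse_expr(tok) for tok in fields[1:])
        rows.append(ExpressionRow(name=name, values=values))
    return rows


def write_gdf(table: GeneTable, path: str | Path) -> None:
    """Write a gene table as GDF (tab-delimited, NaN for missing cells)."""
    with open(path, "w", encoding="utf-8") as fh:
        for g in table.genes:
            fields = [g.dset, g.name, g.chrom, str(g.start), str(g.end), str(g.strand)]
            fields.extend(_format_expr(v) for v in g.expr)
            fh.write("\t".join(fields) + "\n")


def read_gdf(path: str | Path) -> GeneTable:
    """Read a GDF file; all genes must carry the same number of expressions."""
    genes: list[GeneRecord] = []
    n_expr: int | None = None
    for lineno, line in _content_lines(path):
        fields = line.split()
        if len(fields) < 6:
            raise ParseError(path, lineno, f"expected >= 6 columns, got {len(fields)}")
        if n_expr is None:
            n_expr = len(fields) - 6
        elif len(fields) != 6 + n_expr:
            raise ParseError(
                path, lineno, f"expected {6 + n_expr} columns, got {len(fields)}"
            )
        dset, name, chrom, start_s, end_s, strand_s = fields[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(path, lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
        try:
            strand = _parse_strand(strand_s)
        except ValueError as e:
            raise ParseError(path, lineno, str(e))
        expr = tuple(_parse_expr(tok) for tok in fields[6:])
        genes.append(GeneRecord(dset, name, chrom, start, end, strand, expr))
    return GeneTable(genes=genes, n_expr=n_expr or 0)


def _member_line(g: GeneRecord) -> str:
    # CLU member lines put strand before the coordinates, unlike GDF.
    fields = [g.dset, g.name, g.chrom, str(g.strand), str(g.start), str(g.end)]
    fields.extend(_format_expr(v) for v in g.expr)
    return " ".join(fields)


def write_clu(cs: ClusterSet, path: str | Path) -> None:
    """Write a cluster set as CLU."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"nClusters {len(cs.clusters)}\n")
        for c in cs.clusters:
            fh.write(f"{c.cid}\n")
            fh.write("beginCluster\n")
            for g in c.members:
                fh.write(_member_line(g) + "\n")
            fh.write("endCluster\n")


def read_clu(path: str | Path, threshold_bp: int = 0) -> ClusterSet:
    """Read a CLU file.

    ``threshold_bp`` is not stored in the format; pass it when known so
    downstream updates can reuse it (0 = unknown).
    """
    lines = list(_content_lines(path))
    if not lines:
        raise ParseError(path, 1, "empty CLU file (missing nClusters header)")
    lineno, header = lines[0]
    parts = header.split()
    if len(parts) != 2 or parts[0] != "nClusters":
        raise ParseError(path, lineno, f"bad header {header!r}")
    try:
        n_declared = int(parts[1])
    except ValueError:
        raise ParseError(path, lineno, f"bad cluster count {parts[1]!r}")

    clusters: list[Cluster] = []
    n_expr: int | None = None
    i = 1
    while i < len(lines):
        lineno, idline = lines[i]
        try:
            cid = int(idline.strip())
        except ValueError:
            raise ParseError(path, lineno, f"expected cluster id, got {idline!r}")
        i += 1
        if i >= len(lines) or lines[i][1].strip() != "beginCluster":
            raise ParseError(path, lineno, f"cluster {cid}: missing beginCluster")
        i += 1
        members: list[GeneRecord] = []
        closed = False
        while i < len(lines):
            lineno, line = lines[i]
            if line.strip() == "endCluster":
                closed = True
                i += 1
                break
            if line.strip() == "beginCluster":
                raise ParseError(path, lineno, "nested beginCluster")
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(path, lineno, f"expected >= 6 columns, got {len(fields)}")
            if n_expr is None:
                n_expr = len(fields) - 6
            elif len(fields) != 6 + n_expr:
                raise ParseError(
                    path, lineno, f"expected {6 + n_expr} columns, got {len(fields)}"
                )
            dset, name, chrom, strand_s, start_s, stop_s = fields[:6]
            try:
                strand = _parse_strand(strand_s)
            except ValueError as e:
                raise ParseError(path, lineno, str(e))
            try:
                start, end = int(start_s), int(stop_s)
            except ValueError:
                raise ParseError(path, lineno, f"non-integer coordinates {start_s!r}/{stop_s!r}")
            expr = tuple(_parse_expr(tok) for tok in fields[6:])
            members.append(GeneRecord(dset, name, chrom, start, end, strand, expr))
            i += 1
        if not closed:
            raise ParseError(path, lineno, f"cluster {cid}: missing endCluster")
        if not members:
            raise ParseError(path, lineno, f"cluster {cid}: no members")
        clusters.append(Cluster(cid=cid, chrom=members[0].chrom, members=members))
    if len(clusters) != n_declared:
        raise ParseError(
            path, 1, f"header declares {n_declared} clusters, file has {len(clusters)}"
        )
    return ClusterSet(clusters=clusters, threshold_bp=threshold_bp, n_expr=n_expr or 0)


def write_random_summary(runs: list[RandomRunSummary], path: str | Path) -> None:
    """Write the per-run randomization summary table.

    Header row, then one space-delimited row per run: run index, cluster
    count, total clustered genes, then the per-cluster sizes in ID order.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(RANDOM_SUMMARY_HEADER + "\n")
        for r in runs:
            fields = [str(r.run), str(r.n_clusters), str(r.n_clustered_genes)]
            fields.extend(str(s) for s in r.sizes)
            fh.write(" ".join(fields) + "\n")


def read_random_summary(path: str | Path) -> list[RandomRunSummary]:
    """Read back a randomization summary table (inverse of the writer)."""
    runs: list[RandomRunSummary] = []
    for lineno, line in _content_lines(path):
        if line.strip() == RANDOM_SUMMARY_HEADER:
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ParseError(path, lineno, f"expected >= 3 columns, got {len(fields)}")
        try:
            run, n_clusters, n_genes = (int(fields[0]), int(fields[1]), int(fields[2]))
            sizes = [int(s) for s in fields[3:]]
        except ValueError:
            raise ParseError(path, lineno, "non-integer field")
        runs.append(
            RandomRunSummary(run=run, n_clusters=n_clusters, n_clustered_genes=n_genes, sizes=sizes)
        )
    return runs
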