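"""Merging, repairing and filtering gene tables.

The entry point of an analysis: join a position table with an expression
table into a validated, position-sorted :class:`~poscluster.datamodel.GeneTable`,
optionally replace missing values, and select genes whose expression
passes a threshold.  Expression is only ever used here for *selection*;
the clustering step itself is purely positional.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .datamodel import GeneRecord, GeneTable, make_gene_table
from .formats_io import ExpressionRow, PositionRow


@dataclass(frozen=True)
class FilterSpec:
    """Expression-threshold filter settings.

    ``indices`` are 1-based expression indices to test (empty = all);
    ``combine`` says whether one (``any``) or every (``all``) tested value
    must pass; ``direction`` keeps genes at-or-above (``keep_ge``) or
    at-or-below (``keep_le``) the threshold.  Comparisons are inclusive;
    a NaN value never passes.
    """

    threshold: float
    indices: tuple[int, ...] = ()
    combine: str = "any"
    direction: str = "keep_ge"

    def __post_init__(self) -> None:
        if self.combine not in ("any", "all"):
            raise ValueError("combine must be 'any' or 'all'")
        if self.direction not in ("keep_ge", "keep_le"):
            raise ValueError("direction must be 'keep_ge' or 'keep_le'")
        object.__setattr__(self, "indices", tuple(self.indices))
        if any(i < 1 for i in self.indices):
            raise ValueError("expression indices are 1-based")


@dataclass
class MergeResult:
    table: GeneTable
    duplicates: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _keep_first(rows, seen: set[str], duplicates: list[str]):
    out = []
    for row in rows:
        if row.name in seen:
            duplicates.append(row.name)
            continue
        seen.add(row.name)
        out.append(row)
    return out


def merge_position_expression(
    positions: list[PositionRow],
    expressions: list[ExpressionRow] | None,
    dset_label: str,
) -> MergeResult:
    """Inner-join position and expression rows on gene name.

    Duplicate names (in either input) keep only their first instance and
    are reported; genes present in only one input are dropped with a
    warning.  Expression vectors are NaN-padded to the longest observed
    length.  ``expressions=None`` gives every gene a single zero
    expression for pure positional clustering.

    Raises ``ValueError`` if no gene name is shared by both inputs, or if
    the dataset label is empty / contains whitespace.
    """
    if not dset_label or any(ch.isspace() for ch in dset_label):
        raise ValueError("dset label must be non-empty and contain no whitespace")

    duplicates: list[str] = []
    warns: list[str] = []

    pos_unique = _keep_first(positions, set(), duplicates)
    if expressions is None:
        expressions = [ExpressionRow(name=p.name, values=(0.0,)) for p in pos_unique]
    expr_unique = _keep_first(expressions, set(), duplicates)
    if duplicates:
        warns.append(f"dropped {len(duplicates)} duplicate row(s): kept first instance")

    n_expr = max((len(e.values) for e in expr_unique), default=0)
    expr_by_name = {
        e.name: tuple(e.values) + (math.nan,) * (n_expr - len(e.values))
        for e in expr_unique
    }

    genes: list[GeneRecord] = []
    for p in pos_unique:
        if p.name not in expr_by_name:
            warns.append(f"gene {p.name} has no expression row: excluded")
            continue
        genes.append(
            GeneRecord(
                dset=dset_label,
                name=p.name,
                chrom=p.chrom,
                start=p.start,
                end=p.end,
                strand=p.strand,
                expr=expr_by_name[p.name],
            )
        )
    matched = {g.name for g in genes}
    for e in expr_unique:
        if e.name not in matched:
            warns.append(f"gene {e.name} has no position row: excluded")

    if not genes:
        raise ValueError("no overlapping genes between position and expression tables")

    for msg in warns:
        warnings.warn(msg, stacklevel=2)
    return MergeResult(table=make_gene_table(genes), duplicates=duplicates, warnings=warns)


def fix_nan(table: GeneTable, replacement: float) -> GeneTable:
    """Return a copy with every missing expression value replaced.

    A NaN replacement is a no-op (warned about, not an error).
    """
    if math.isnan(replacement):
        warnings.warn("replacement value is NaN: table is unchanged", stacklevel=2)
    genes = [
        g.with_expr(replacement if math.isnan(v) else v for v in g.expr)
        for g in table.genes
    ]
    return GeneTable(genes=genes, n_expr=table.n_expr)


def _passes(value: float, spec: FilterSpec) -> bool:
    if math.isnan(value):
        return False
    return value >= spec.threshold if spec.direction == "keep_ge" else value <= spec.threshold


def filter_by_expression(table: GeneTable, spec: FilterSpec) -> GeneTable:
    """Keep genes whose selected expression values pass the threshold test."""
    indices = spec.indices or tuple(range(1, table.n_expr + 1))
    for i in indices:
        if i > table.n_expr:
            raise ValueError(f"expression index {i} out of range (n_expr={table.n_expr})")
    agg = any if spec.combine == "any" else all
    genes = [
        g for g in table.genes if agg(_passes(g.expr[i - 1], spec) for i in indices)
    ]
    return GeneTable(genes=genes, n_expr=table.n_expr)
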