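"""Core domain types for gene positional clustering.

A *positional cluster* is a maximal run of two or more genes on one
chromosome in which every consecutive pair of gene start coordinates lies
within a base-pair distance threshold.  Everything else in the package —
file formats, the clustering algorithm, the randomization baseline and the
renderers — works in terms of the types defined here.

Coordinates are 1-based inclusive integers as exported by Biomart-style
position tables; the package never rescales them.  Strand is stored (±1)
but never used in distance computations: strand-restricted analyses are
achieved by pre-filtering the input gene list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator


def _position_sort_key(g: "GeneRecord") -> tuple[int, int, str]:
    # Tie-break (start, end, name) keeps output deterministic when two
    # genes share a start coordinate.
    return (g.start, g.end, g.name)


@dataclass(frozen=True)
class GeneRecord:
    """One gene: provenance label, name, position and expression vector.

    Parameters
    ----------
    dset
        Dataset-origin label ("origin"); distinguishes which input file a
        gene came from when tables are merged or clusters updated.  No
        whitespace (it is a whitespace-delimited field on disk).
    name
        Gene identifier, unique within a table.  No whitespace.
    chrom
        Chromosome or contig name.
    start, end
        Gene span in base pairs, ``start <= end``.
    strand
        Orientation, ``+1`` or ``-1``.
    expr
        Ordered expression values, one per experimental stage/condition;
        a missing value is ``float('nan')``.
    """

    dset: str
    name: str
    chrom: str
    start: int
    end: int
    strand: int
    expr: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "expr", tuple(float(v) for v in self.expr))

    def with_expr(self, expr: Iterable[float]) -> "GeneRecord":
        return replace(self, expr=tuple(expr))


@dataclass
class GeneTable:
    """Ordered collection of :class:`GeneRecord` — the in-memory GDF.

    Within each chromosome the records are expected in non-decreasing
    start order; :func:`validate_gene_table` checks this along with the
    other invariants (unique names, start<=end, strand in {+1,-1},
    homogeneous expression-vector length ``n_expr``).
    """

    genes: list[GeneRecord] = field(default_factory=list)
    n_expr: int = 0

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)

    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g.chrom, None)
        return list(seen)

    def by_chromosome(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out

    def names(self) -> set[str]:
        return {g.name for g in self.genes}

    def sorted_copy(self) -> "GeneTable":
        """Copy with each chromosome's genes sorted by (start, end, name).

        Chromosome blocks keep their order of first appearance.
        """
        groups = self.by_chromosome()
        genes: list[GeneRecord] = []
        for chrom in self.chromosomes():
            genes.extend(sorted(groups[chrom], key=_position_sort_key))
        return GeneTable(genes=genes, n_expr=self.n_expr)


def make_gene_table(genes: Iterable[GeneRecord], *, sort: bool = True) -> GeneTable:
    """Build a :class:`GeneTable`, inferring ``n_expr`` from the records."""
    genes = list(genes)
    n_expr = len(genes[0].expr) if genes else 0
    table = GeneTable(genes=genes, n_expr=n_expr)
    return table.sorted_copy() if sort else table


@dataclass(frozen=True)
class ClusteringParams:
    """Clustering parameters: the base-pair distance threshold D."""

    threshold_bp: int

    def __post_init__(self) -> None:
        if self.threshold_bp <= 0:
            raise ValueError("threshold_bp must be a positive integer")


@dataclass
class Cluster:
    """A positional cluster: numeric ID and ≥2 member genes on one chromosome."""

    cid: int
    chrom: str
    members: list[GeneRecord]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def first_start(self) -> int:
        return self.members[0].start

    @property
    def last_start(self) -> int:
        return self.members[-1].start

    def names(self) -> set[str]:
        return {g.name for g in self.members}


@dataclass
class ClusterSet:
    """All clusters from one clustering run — the in-memory CLU."""

    clusters: list[Cluster] = field(default_factory=list)
    threshold_bp: int = 0
    n_expr: int = 0

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self) -> Iterator[Cluster]:
        return iter(self.clusters)

    def get(self, cid: int) -> Cluster:
        for c in self.clusters:
            if c.cid == cid:
                return c
        raise KeyError(f"no cluster with id {cid}")

    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]

    def n_clustered_genes(self) -> int:
        return sum(self.sizes())

    def member_names(self) -> set[str]:
        out: set[str] = set()
        for c in self.clusters:
            out |= c.names()
        return out


@dataclass
class RandomRunSummary:
    """Per-run clustering summary used by the randomization baseline."""

    run: int
    n_clusters: int
    n_clustered_genes: int
    sizes: list[int]

    def __post_init__(self) -> None:
        if sum(self.sizes) != self.n_clustered_genes:
            raise ValueError("sum(sizes) must equal n_clustered_genes")
        if len(self.sizes) != self.n_clusters:
            raise ValueError("len(sizes) must equal n_clusters")
        if any(s < 2 for s in self.sizes):
            raise ValueError("every cluster size must be >= 2")


def _has_whitespace(s: str) -> bool:
    return any(ch.isspace() for ch in s)


def validate_gene_table(table: GeneTable) -> list[str]:
    """Check every :class:`GeneTable` invariant; return violation messages.

    Returns an empty list iff the table is valid.  Never raises: the
    function is meant for post-read validation where all problems should
    be reported at once.
    """
    violations: list[str] = []
    seen: set[str] = set()
    for g in table.genes:
        if g.name in seen:
            violations.append(f"duplicate name {g.name}")
        seen.add(g.name)
        if g.start > g.end:
            violations.append(f"start>end {g.name}")
        if g.start < 0:
            violations.append(f"negative start {g.name}")
        if g.strand not in (1, -1):
            violations.append(f"strand not +-1 {g.name}")
        if _has_whitespace(g.name) or not g.name:
            violations.append(f"bad name field {g.name!r}")
        if _has_whitespace(g.dset) or not g.dset:
            violations.append(f"bad dset field for {g.name}")
        if len(g.expr) != table.n_expr:
            violations.append(
                f"expression length {len(g.expr)} != n_expr {table.n_expr} for {g.name}"
            )
    for chrom, group in table.by_chromosome().items():
        for prev, cur in zip(group, group[1:]):
            if cur.start < prev.start:
                violations.append(
                    f"unsorted on {chrom}: {cur.name} (start {cur.start}) "
                    f"after {prev.name} (start {prev.start})"
                )
    return violations


def validate_cluster_set(cs: ClusterSet) -> list[str]:
    """Check ClusterSet invariants (unique 1..N IDs, sizes ≥ 2, gap rule)."""
    violations: list[str] = []
    if [c.cid for c in cs.clusters] != list(range(1, len(cs.clusters) + 1)):
        violations.append("cluster ids are not 1..N in order")
    seen: set[str] = set()
    for c in cs.clusters:
        if c.size < 2:
            violations.append(f"cluster {c.cid} has fewer than 2 members")
        for g in c.members:
            if g.chrom != c.chrom:
                violations.append(f"cluster {c.cid}: member {g.name} on wrong chromosome")
            if g.name in seen:
                violations.append(f"gene {g.name} appears in two clusters")
            seen.add(g.name)
        for prev, cur in zip(c.members, c.members[1:]):
            if cur.start < prev.start:
                violations.append(f"cluster {c.cid} members unsorted at {cur.name}")
            if cs.threshold_bp and cur.start - prev.start > cs.threshold_bp:
                violations.append(
                    f"cluster {c.cid}: gap {cur.start - prev.start} exceeds "
                    f"threshold {cs.threshold_bp} before {cur.name}"
                )
    return violations


def is_missing(value: float) -> bool:
    """True when an expression value is the missing marker (NaN)."""
    return math.isnan(value)
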