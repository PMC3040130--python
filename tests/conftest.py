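"""Shared test helpers: gene builders, random tables, and the clustering oracle.

The oracle deliberately ignores gene order: it unions ALL gene pairs on a
chromosome whose start distance is within the threshold (single linkage
at cutoff), then discards singleton groups.  The package's sequential
chaining must produce the identical partition.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from poscluster import Cluster, ClusterSet, GeneRecord, GeneTable, make_gene_table


def gene(name, chrom="chr1", start=0, end=None, strand=1, expr=(0.0,), dset="d1"):
    if end is None:
        end = start + 1000
    return GeneRecord(dset=dset, name=name, chrom=chrom, start=start,
                      end=end, strand=strand, expr=expr)


def table_from_starts(starts_by_chrom: dict[str, list[int]], expr=(0.0,)) -> GeneTable:
    """Build a table with one gene per start coordinate, named g1, g2, ..."""
    genes = []
    i = 0
    for chrom, starts in starts_by_chrom.items():
        for s in starts:
            i += 1
            genes.append(gene(f"g{i}", chrom=chrom, start=s, expr=expr))
    return make_gene_table(genes)


def random_table(rng: np.random.Generator, max_genes=50, max_chroms=4,
                 max_pos=1_000_000, n_expr=2) -> GeneTable:
    """A random valid gene table (unique names, sorted per chromosome)."""
    n_chroms = int(rng.integers(1, max_chroms + 1))
    genes = []
    i = 0
    for c in range(n_chroms):
        n = int(rng.integers(1, max_genes + 1))
        starts = sorted(int(s) for s in rng.integers(0, max_pos, size=n))
        for s in starts:
            i += 1
            length = int(rng.integers(100, 10_000))
            expr = tuple(float(v) for v in rng.normal(0, 1, size=n_expr))
            genes.append(gene(f"g{i}", chrom=f"chr{c + 1}", start=s,
                              end=s + length, strand=int(rng.choice((1, -1))),
                              expr=expr))
    return make_gene_table(genes)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def oracle_partition(table: GeneTable, threshold_bp: int) -> set[frozenset[str]]:
    """Brute-force single linkage at cutoff: all pairs, any order, then
    drop singleton groups.  Returns the set of clustered-name groups."""
    groups: set[frozenset[str]] = set()
    for chrom, genes in table.by_chromosome().items():
        uf = _UnionFind([g.name for g in genes])
        for a in genes:
            for b in genes:
                if a.name != b.name and abs(a.start - b.start) <= threshold_bp:
                    uf.union(a.name, b.name)
        comps: dict[str, set[str]] = {}
        for g in genes:
            comps.setdefault(uf.find(g.name), set()).add(g.name)
        for comp in comps.values():
            if len(comp) >= 2:
                groups.add(frozenset(comp))
    return groups


def cluster_partition(cs: ClusterSet) -> set[frozenset[str]]:
    return {frozenset(c.names()) for c in cs.clusters}


def tables_equal(a: GeneTable, b: GeneTable) -> bool:
    """Field-for-field equality with NaN-aware expression comparison."""
    if a.n_expr != b.n_expr or len(a) != len(b):
        return False
    for x, y in zip(a.genes, b.genes):
        if (x.dset, x.name, x.chrom, x.start, x.end, x.strand) != \
           (y.dset, y.name, y.chrom, y.start, y.end, y.strand):
            return False
        if len(x.expr) != len(y.expr):
            return False
        for u, v in zip(x.expr, y.expr):
            if math.isnan(u) != math.isnan(v):
                return False
            if not math.isnan(u) and u != v:
                return False
    return True


def cluster_sets_equal(a: ClusterSet, b: ClusterSet) -> bool:
    if len(a) != len(b):
        return False
    for ca, cb in zip(a.clusters, b.clusters):
        if ca.cid != cb.cid or ca.chrom != cb.chrom:
            return False
        ta = GeneTable(genes=ca.members, n_expr=a.n_expr)
        tb = GeneTable(genes=cb.members, n_expr=b.n_expr)
        if not tables_equal(ta, tb):
            return False
    return True


@pytest.fixture
def rng():
    return np.random.default_rng(20240115)
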