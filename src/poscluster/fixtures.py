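"""Deterministic synthetic gene tables with planted positional clusters.

The generator emulates the structure of real inputs — a Biomart-style
position table plus a multi-stage expression table — with a known ground
truth: groups of genes planted within a tight intra-cluster gap, and
isolated genes kept farther from every other gene than a stated
isolation gap.  Clustering at any threshold D with

    max intra-cluster gap  <=  D  <  min isolation gap

must then recover exactly the planted groups, which makes every module
in the package testable without downloading anything.

Planted members share one randomly chosen "hot" expression stage with
high values over a low-noise background, mimicking a developmental-stage
expression profile; isolated genes get background noise only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .formats_io import ExpressionRow, PositionRow


@dataclass(frozen=True)
class PlantedCluster:
    """One ground-truth cluster: where it sits and how tight it is."""

    chrom: str
    n_genes: int
    gap_min: int
    gap_max: int
    anchor: int

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("a planted cluster needs >= 2 genes")
        if not (0 < self.gap_min <= self.gap_max):
            raise ValueError("need 0 < gap_min <= gap_max")
        if self.anchor < 1:
            raise ValueError("anchor must be a positive coordinate")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic dataset.

    ``isolation_gap`` is the minimum start-to-start distance between an
    isolated gene and any other gene; it must exceed every planted
    cluster's ``gap_max`` so that a recovering threshold exists.
    """

    chromosomes: tuple[tuple[str, int], ...]
    clusters: tuple[PlantedCluster, ...]
    n_isolated: int = 0
    isolation_gap: int = 100_000
    n_expr: int = 1
    nan_rate: float = 0.0
    seed: int = 0
    gene_length: tuple[int, int] = (500, 5_000)
    hot_mean: float = 8.0
    background_mean: float = 0.5

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("need at least one chromosome")
        if not 0.0 <= self.nan_rate <= 1.0:
            raise ValueError("nan_rate must be in [0, 1]")
        if self.n_expr < 1:
            raise ValueError("n_expr must be >= 1")
        names = {name for name, _ in self.chromosomes}
        for c in self.clusters:
            if c.chrom not in names:
                raise ValueError(f"planted cluster on unknown chromosome {c.chrom}")
            if c.gap_max >= self.isolation_gap:
                raise ValueError(
                    "max intra-cluster gap must be smaller than the isolation gap"
                )

    @property
    def max_intra_gap(self) -> int:
        return max((c.gap_max for c in self.clusters), default=0)


@dataclass
class SyntheticData:
    """Generator output: the two input tables plus the planted truth."""

    positions: list[PositionRow]
    expressions: list[ExpressionRow]
    truth: list[set[str]]

    def write(self, out_dir: str | Path) -> None:
        """Write positions.tsv, expressions.tsv and truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "positions.tsv", "w", encoding="utf-8") as fh:
            for p in self.positions:
                fh.write(f"{p.name}\t{p.chrom}\t{p.start}\t{p.end}\t{p.strand}\n")
        with open(out / "expressions.tsv", "w", encoding="utf-8") as fh:
            for e in self.expressions:
                vals = "\t".join("" if np.isnan(v) else repr(v) for v in e.values)
                fh.write(f"{e.name}\t{vals}\n" if vals else f"{e.name}\n")
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump([sorted(s) for s in self.truth], fh, indent=1)
            fh.write("\n")


def _place_cluster(rng: np.random.Generator, spec: SyntheticSpec,
                   planted: PlantedCluster) -> list[int]:
    starts = [planted.anchor]
    for _ in range(planted.n_genes - 1):
        gap = int(rng.integers(planted.gap_min, planted.gap_max + 1))
        starts.append(starts[-1] + gap)
    return starts


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Generate position/expression tables and the planted truth sets.

    Deterministic given ``spec.seed``.  Raises ``ValueError`` when the
    layout cannot fit: overlapping planted clusters (closer than the
    isolation gap to each other counts as interleaving), or genes past a
    chromosome's end.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_len = dict(spec.chromosomes)
    # starts per chromosome, to enforce isolation and bounds
    occupied: dict[str, list[int]] = {name: [] for name, _ in spec.chromosomes}

    truth: list[set[str]] = []
    rows: list[tuple[str, str, int]] = []  # (name, chrom, start)
    gene_no = 0

    for planted in spec.clusters:
        starts = _place_cluster(rng, spec, planted)
        if starts[-1] > chrom_len[planted.chrom]:
            raise ValueError(
                f"planted cluster at {planted.anchor} on {planted.chrom} "
                f"overflows the chromosome"
            )
        for other in occupied[planted.chrom]:
            if starts[0] - spec.isolation_gap < other < starts[-1] + spec.isolation_gap:
                raise ValueError(
                    f"planted clusters interleave on {planted.chrom} near {other}"
                )
        members: set[str] = set()
        for s in starts:
            gene_no += 1
            name = f"g{gene_no:04d}"
            members.add(name)
            rows.append((name, planted.chrom, s))
        occupied[planted.chrom].extend(starts)
        truth.append(members)

    # Isolated genes: walk each chromosome right of everything placed so
    # far, stepping by at least the isolation gap.
    chrom_names = [name for name, _ in spec.chromosomes]
    cursor = {
        name: (max(occupied[name], default=0)) for name in chrom_names
    }
    placed = 0
    attempts = 0
    while placed < spec.n_isolated:
        chrom = chrom_names[attempts % len(chrom_names)]
        attempts += 1
        if attempts > 10 * spec.n_isolated * len(chrom_names) + 100:
            raise ValueError("cannot place isolated genes: chromosomes too short")
        step = spec.isolation_gap + int(rng.integers(0, spec.isolation_gap))
        pos = cursor[chrom] + step
        if pos > chrom_len[chrom]:
            cursor[chrom] = chrom_len[chrom] + 1  # chromosome full
            continue
        cursor[chrom] = pos
        gene_no += 1
        rows.append((f"g{gene_no:04d}", chrom, pos))
        placed += 1

    positions: list[PositionRow] = []
    for name, chrom, start in rows:
        length = int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
        strand = int(rng.choice((1, -1)))
        positions.append(PositionRow(name=name, chrom=chrom, start=start,
                                     end=start + length, strand=strand))

    # Expression: all members of one planted cluster share one hot stage,
    # drawn per cluster.
    hot_stage: dict[str, int] = {}
    for members in truth:
        stage = int(rng.integers(0, spec.n_expr))
        for name in members:
            hot_stage[name] = stage

    expressions: list[ExpressionRow] = []
    for p in positions:
        values = np.abs(rng.normal(spec.background_mean, 0.2, size=spec.n_expr))
        if p.name in hot_stage:
            values[hot_stage[p.name]] = abs(rng.normal(spec.hot_mean, 1.0))
        if spec.nan_rate > 0:
            mask = rng.random(spec.n_expr) < spec.nan_rate
            values[mask] = np.nan
        expressions.append(ExpressionRow(name=p.name, values=tuple(float(v) for v in values)))

    return SyntheticData(positions=positions, expressions=expressions, truth=truth)


def default_spec(seed: int = 0) -> SyntheticSpec:
    """A small, readable example dataset: 3 planted clusters, 6 loners."""
    return SyntheticSpec(
        chromosomes=(("chr2L", 5_000_000), ("chr2R", 6_000_000)),
        clusters=(
            PlantedCluster("chr2L", 3, 2_000, 10_000, 200_000),
            PlantedCluster("chr2L", 4, 2_000, 10_000, 900_000),
            PlantedCluster("chr2R", 5, 2_000, 10_000, 400_000),
        ),
        n_isolated=6,
        isolation_gap=100_000,
        n_expr=5,
        nan_rate=0.0,
        seed=seed,
    )


def genome_scale_spec(seed: int = 0, *, n_clusters: int = 400,
                      cluster_size_range: tuple[int, int] = (2, 8),
                      n_isolated: int = 2_000,
                      n_chromosomes: int = 4) -> SyntheticSpec:
    """A genome-scale stress spec: hundreds of clusters, thousands of genes.

    Clusters are laid out deterministically (given the seed) on evenly
    spaced anchors so they can never interleave.
    """
    rng = np.random.default_rng(seed)
    pitch = 400_000  # anchor spacing, comfortably above the isolation gap
    per_chrom = -(-n_clusters // n_chromosomes)  # ceil
    chroms = tuple(
        (f"chr{i + 1}", (per_chrom + n_isolated) * pitch) for i in range(n_chromosomes)
    )
    clusters = []
    for i in range(n_clusters):
        chrom = f"chr{i % n_chromosomes + 1}"
        anchor = (i // n_chromosomes + 1) * pitch
        size = int(rng.integers(cluster_size_range[0], cluster_size_range[1] + 1))
        clusters.append(PlantedCluster(chrom, size, 1_000, 15_000, anchor))
    return SyntheticSpec(
        chromosomes=chroms,
        clusters=tuple(clusters),
        n_isolated=n_isolated,
        isolation_gap=100_000,
        n_expr=5,
        nan_rate=0.0,
        seed=seed,
    )
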