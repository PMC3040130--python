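"""Randomization baseline and significance testing for clustering results.

Whether n selected genes cluster more than chance would predict is judged
against repeated clustering of n genes drawn uniformly (without
replacement) from a larger pool — typically all coding genes of the
genome.  Each run is summarized (cluster count, clustered-gene count,
per-cluster sizes) and the observed statistic is compared with the random
sample through a one-sample Student's t-test, the observed value serving
as the hypothesized mean.

Cluster-size distributions and the gene-weighted size summaries reported
alongside them live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .clustering import build_clusters
from .datamodel import (
    ClusteringParams,
    ClusterSet,
    GeneTable,
    RandomRunSummary,
    make_gene_table,
)

STATISTICS = ("n_clusters", "n_clustered_genes", "mean_cluster_size")


@dataclass(frozen=True)
class RandomizationParams:
    """n genes per draw, number of runs, and the RNG seed."""

    n: int
    runs: int
    seed: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


def random_clustering_runs(
    pool: GeneTable,
    rparams: RandomizationParams,
    cparams: ClusteringParams,
) -> list[RandomRunSummary]:
    """Cluster ``runs`` random n-gene subsets of ``pool``; summarize each.

    Deterministic given the seed.  Per-run RNG substreams are derived
    from one seed sequence, so results do not depend on execution order.
    """
    if rparams.n > len(pool):
        raise ValueError(f"n={rparams.n} exceeds pool size {len(pool)}")
    children = np.random.SeedSequence(rparams.seed).spawn(rparams.runs)
    summaries: list[RandomRunSummary] = []
    for run_index, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        idx = rng.choice(len(pool), size=rparams.n, replace=False)
        subset = make_gene_table(pool.genes[i] for i in sorted(idx))
        cs = build_clusters(subset, cparams)
        summaries.append(summarize_clusters(cs, run=run_index))
    return summaries


def summarize_clusters(cs: ClusterSet, run: int = 1) -> RandomRunSummary:
    """One-line summary of a clustering run (sizes in cluster-ID order)."""
    sizes = cs.sizes()
    return RandomRunSummary(
        run=run,
        n_clusters=len(sizes),
        n_clustered_genes=sum(sizes),
        sizes=sizes,
    )


@dataclass
class SizeDistribution:
    """Empirical distribution of cluster sizes, plus derived summaries.

    ``probs`` maps size -> fraction of clusters of that size (empty when
    there are no clusters).  The gene-weighted fractions mirror the
    summaries commonly reported for clustering runs: what share of the
    clustered genes sit in pairs versus in larger neighborhoods (pairs
    are often discounted as possible tandem duplications, so the ≥3 and
    ≥4 shares flag genuine hot-spots).
    """

    counts: dict[int, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return sum(self.counts.values())

    @property
    def n_clustered_genes(self) -> int:
        return sum(s * c for s, c in self.counts.items())

    @property
    def probs(self) -> dict[int, float]:
        n = self.n_clusters
        return {s: c / n for s, c in sorted(self.counts.items())} if n else {}

    def frac_clusters_of_size(self, size: int) -> float:
        return self.probs.get(size, 0.0)

    def frac_clusters_at_least(self, size: int) -> float:
        return sum(p for s, p in self.probs.items() if s >= size)

    def frac_genes_in_size(self, size: int) -> float:
        """Fraction of clustered genes lying in clusters of exactly this size."""
        total = self.n_clustered_genes
        if total == 0:
            return 0.0
        return size * self.counts.get(size, 0) / total

    def frac_genes_at_least(self, size: int) -> float:
        """Fraction of clustered genes lying in clusters of at least this size."""
        total = self.n_clustered_genes
        if total == 0:
            return 0.0
        return sum(s * c for s, c in self.counts.items() if s >= size) / total


def size_distribution(cs: ClusterSet) -> SizeDistribution:
    """Empirical cluster-size distribution of a cluster set."""
    counts: dict[int, int] = {}
    for s in cs.sizes():
        counts[s] = counts.get(s, 0) + 1
    return SizeDistribution(counts=counts)


def write_size_distribution(dist: SizeDistribution, path) -> None:
    """Write a size distribution as a two-column text table."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("size probability\n")
        for size, p in dist.probs.items():
            fh.write(f"{size} {p!r}\n")


def one_sample_t_test(sample: list[float], mu: float) -> tuple[float, int, float]:
    """One-sample Student's t-test of ``sample`` against mean ``mu``.

    Returns ``(t, df, p_two_sided)`` with t = (mean − mu)/(s/√k),
    df = k − 1 and s the sample standard deviation (ddof=1).

    Raises ``ValueError`` for samples smaller than 2 or with zero
    variance (report the degenerate sample directly instead).
    """
    x = np.asarray(sample, dtype=float)
    k = x.size
    if k < 2:
        raise ValueError("need at least 2 observations")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise ValueError(
            "zero sample variance: the t-test is undefined; report the "
            "degenerate sample (all runs identical) directly"
        )
    t = (float(x.mean()) - mu) / (sd / math.sqrt(k))
    df = k - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, min(p, 1.0)


@dataclass
class SignificanceReport:
    """Observed statistic versus the random baseline."""

    statistic: str
    observed: float
    random_mean: float
    random_sd: float
    t: float | None
    df: int
    p_value: float | None
    degenerate: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.degenerate:
            return (
                f"{self.statistic}: observed={self.observed:g}, random runs all equal "
                f"{self.random_mean:g} (zero variance; no t-test)"
            )
        return (
            f"{self.statistic}: observed={self.observed:g}, "
            f"random mean={self.random_mean:.4g} sd={self.random_sd:.4g}, "
            f"t={self.t:.4g} df={self.df} p={self.p_value:.4g}"
        )


def _extract_statistic(summary: RandomRunSummary, statistic: str) -> float:
    if statistic == "n_clusters":
        return float(summary.n_clusters)
    if statistic == "n_clustered_genes":
        return float(summary.n_clustered_genes)
    if statistic == "mean_cluster_size":
        # A run with no clusters contributes mean size 0.
        if summary.n_clusters == 0:
            return 0.0
        return summary.n_clustered_genes / summary.n_clusters
    raise ValueError(f"unknown statistic {statistic!r} (choose from {STATISTICS})")


def compare_observed_vs_random(
    observed: RandomRunSummary | ClusterSet,
    randoms: list[RandomRunSummary],
    statistic: str = "n_clusters",
) -> SignificanceReport:
    """t-test the random-run sample against the observed statistic as mean.

    The random runs form the sample; the observed clustering's statistic
    is the hypothesized mean mu.  With a zero-variance random sample the
    report is returned degenerate (no t or p) rather than erroring.
    """
    if isinstance(observed, ClusterSet):
        observed = summarize_clusters(observed)
    if len(randoms) < 2:
        raise ValueError("need at least 2 random runs")
    obs_value = _extract_statistic(observed, statistic)
    sample = [_extract_statistic(r, statistic) for r in randoms]
    arr = np.asarray(sample)
    mean, sd = float(arr.mean()), float(arr.std(ddof=1))
    if sd == 0.0:
        return SignificanceReport(
            statistic=statistic,
            observed=obs_value,
            random_mean=mean,
            random_sd=0.0,
            t=None,
            df=len(sample) - 1,
            p_value=None,
            degenerate=True,
        )
    t, df, p = one_sample_t_test(sample, mu=obs_value)
    return SignificanceReport(
        statistic=statistic,
        observed=obs_value,
        random_mean=mean,
        random_sd=sd,
        t=t,
        df=df,
        p_value=p,
    )
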