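"""Tests for the randomization baseline, size distributions and the t-test."""

import numpy as np
import pytest
from scipy import stats

from poscluster import (
    Cluster,
    ClusteringParams,
    ClusterSet,
    RandomizationParams,
    RandomRunSummary,
    compare_observed_vs_random,
    one_sample_t_test,
    random_clustering_runs,
    size_distribution,
    summarize_clusters,
)
from conftest import gene, table_from_starts

D = ClusteringParams(threshold_bp=20_000)


def _isolated_pool(n=30, gap=100_000):
    return table_from_starts({"chrA": [i * gap for i in range(n)]})


def _dense_pool(n=30, gap=100):
    # EVERY pairwise start distance <= D, so any subset chains fully
    return table_from_starts({"chrA": [i * gap for i in range(n)]})


class TestRandomRuns:
    def test_fixed_seed_is_bit_reproducible(self):
        pool = _dense_pool()
        rp = RandomizationParams(n=10, runs=5, seed=42)
        assert random_clustering_runs(pool, rp, D) == random_clustering_runs(pool, rp, D)

    def test_different_seeds_differ(self):
        pool = table_from_starts({"chrA": list(range(0, 3_000_000, 15_000))})
        a = random_clustering_runs(pool, RandomizationParams(n=20, runs=5, seed=1), D)
        b = random_clustering_runs(pool, RandomizationParams(n=20, runs=5, seed=2), D)
        assert a != b

    def test_all_isolated_pool_never_clusters(self):
        runs = random_clustering_runs(
            _isolated_pool(), RandomizationParams(n=10, runs=10, seed=0), D
        )
        assert all(r == RandomRunSummary(r.run, 0, 0, []) for r in runs)

    def test_all_within_threshold_pool_gives_one_full_cluster(self):
        runs = random_clustering_runs(
            _dense_pool(), RandomizationParams(n=8, runs=10, seed=0), D
        )
        assert all(r.n_clusters == 1 and r.sizes == [8] for r in runs)

    def test_summaries_satisfy_their_invariants(self):
        pool = table_from_starts({"chrA": list(range(0, 2_000_000, 15_000))})
        runs = random_clustering_runs(pool, RandomizationParams(n=30, runs=20, seed=3), D)
        for r in runs:  # RandomRunSummary.__post_init__ enforces; spot-check anyway
            assert sum(r.sizes) == r.n_clustered_genes
            assert all(s >= 2 for s in r.sizes)

    def test_oversized_draw_rejected(self):
        with pytest.raises(ValueError, match="pool size"):
            random_clustering_runs(
                _dense_pool(n=5), RandomizationParams(n=6, runs=1, seed=0), D
            )

    def test_run_mean_converges_with_more_runs(self):
        # standard error of the mean cluster count shrinks ~1/sqrt(R)
        pool = table_from_starts({"chrA": list(range(0, 6_000_000, 15_000))})
        small = random_clustering_runs(pool, RandomizationParams(n=60, runs=200, seed=7), D)
        large = random_clustering_runs(pool, RandomizationParams(n=60, runs=2000, seed=7), D)
        m_small = np.mean([r.n_clusters for r in small])
        m_large = np.mean([r.n_clusters for r in large])
        sd = np.std([r.n_clusters for r in large], ddof=1)
        assert abs(m_small - m_large) < 4 * sd / np.sqrt(200)


class TestSizeDistribution:
    def _cs(self, sizes):
        clusters = []
        pos = 0
        for i, s in enumerate(sizes, 1):
            members = [gene(f"c{i}g{j}", start=pos + j * 10) for j in range(s)]
            clusters.append(Cluster(cid=i, chrom="chrA", members=members))
            pos += 1_000_000
        return ClusterSet(clusters=clusters, threshold_bp=100, n_expr=1)

    def test_hand_counted_distribution(self):
        dist = size_distribution(self._cs([2, 2, 3]))
        assert dist.probs == {2: 2 / 3, 3: 1 / 3}
        assert dist.n_clustered_genes == 7
        assert dist.frac_clusters_of_size(2) == pytest.approx(2 / 3)

    def test_probabilities_sum_to_one(self):
        dist = size_distribution(self._cs([2, 3, 3, 4, 7]))
        assert sum(dist.probs.values()) == pytest.approx(1.0)

    def test_empty_set_gives_empty_distribution(self):
        dist = size_distribution(ClusterSet())
        assert dist.probs == {} and dist.n_clusters == 0

    def test_gene_weighted_fractions(self):
        # sizes [2,2,3]: 4 of 7 genes sit in pairs, 3 of 7 in >=3 clusters
        dist = size_distribution(self._cs([2, 2, 3]))
        assert dist.frac_genes_in_size(2) == pytest.approx(4 / 7)
        assert dist.frac_genes_at_least(3) == pytest.approx(3 / 7)
        assert dist.frac_genes_at_least(4) == 0.0


class TestOneSampleT:
    def test_worked_example(self):
        # closed form: mean 2, sd 1, se 1/sqrt(3) -> t = 2*sqrt(3) = 3.4641
        t, df, p = one_sample_t_test([1, 2, 3], mu=0)
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert df == 2
        assert p == pytest.approx(0.0742, abs=1e-3)

    def test_mean_equal_mu_gives_t_zero_p_one(self):
        t, df, p = one_sample_t_test([1.0, 2.0, 3.0], mu=2.0)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            one_sample_t_test([2.0, 2.0, 2.0], mu=0.0)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t_test([1.0], mu=0.0)

    def test_agrees_with_independent_reference(self, rng):
        for _ in range(100):
            k = int(rng.integers(3, 40))
            sample = rng.normal(rng.normal(0, 5), rng.uniform(0.5, 3), size=k)
            mu = float(rng.normal(0, 5))
            t, df, p = one_sample_t_test(list(sample), mu)
            ref = stats.ttest_1samp(sample, popmean=mu)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
            assert df == ref.df


class TestCompareObservedVsRandom:
    def _runs(self, counts):
        out = []
        for i, c in enumerate(counts, 1):
            out.append(RandomRunSummary(run=i, n_clusters=c,
                                        n_clustered_genes=2 * c, sizes=[2] * c))
        return out

    def test_t_computed_on_cluster_count_column(self):
        # the n.clusts column of a 7-run summary table
        randoms = self._runs([3, 3, 3, 1, 3, 2, 5])
        report = compare_observed_vs_random(
            RandomRunSummary(1, 3, 6, [2, 2, 2]), randoms, "n_clusters"
        )
        expected_t, _, expected_p = one_sample_t_test([3, 3, 3, 1, 3, 2, 5], mu=3.0)
        assert report.t == pytest.approx(expected_t)
        assert report.p_value == pytest.approx(expected_p)
        assert report.df == 6

    def test_observed_equal_to_random_mean_gives_p_one(self):
        randoms = self._runs([2, 4])
        report = compare_observed_vs_random(
            RandomRunSummary(1, 3, 6, [2, 2, 2]), randoms, "n_clusters"
        )
        assert report.t == 0.0 and report.p_value == pytest.approx(1.0)

    def test_degenerate_zero_variance_random_sample(self):
        randoms = self._runs([0, 0, 0])
        report = compare_observed_vs_random(
            RandomRunSummary(1, 5, 10, [2] * 5), randoms, "n_clusters"
        )
        assert report.degenerate and report.t is None and report.p_value is None
        assert report.observed == 5.0 and report.random_mean == 0.0

    def test_accepts_cluster_set_as_observed(self):
        cs = ClusterSet(clusters=[
            Cluster(cid=1, chrom="chrA",
                    members=[gene("a", start=0), gene("b", start=10)]),
        ], threshold_bp=100, n_expr=1)
        report = compare_observed_vs_random(cs, self._runs([1, 2, 3]), "n_clusters")
        assert report.observed == 1.0

    def test_mean_cluster_size_statistic_handles_empty_runs(self):
        randoms = self._runs([0, 2, 4])
        report = compare_observed_vs_random(
            RandomRunSummary(1, 2, 4, [2, 2]), randoms, "mean_cluster_size"
        )
        # runs contribute mean sizes 0, 2, 2
        assert report.random_mean == pytest.approx((0 + 2 + 2) / 3)

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError, match="statistic"):
            compare_observed_vs_random(
                RandomRunSummary(1, 1, 2, [2]), self._runs([1, 2]), "nope"
            )


def test_summarize_clusters_matches_sizes():
    cs = ClusterSet(clusters=[
        Cluster(cid=1, chrom="c", members=[gene("a", start=0), gene("b", start=1)]),
        Cluster(cid=2, chrom="c",
                members=[gene("x", start=100), gene("y", start=101), gene("z", start=102)]),
    ], threshold_bp=10, n_expr=1)
    s = summarize_clusters(cs, run=4)
    assert (s.run, s.n_clusters, s.n_clustered_genes, s.sizes) == (4, 2, 5, [2, 3])
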