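import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dgecompare.downsample import (
    downsample_matrix,
    downsample_paired,
    downsample_replicates,
    downsample_sample,
    downsample_to_common_depth,
)
from .conftest import make_matrix


class TestDownsampleSample:
    @pytest.mark.parametrize("variant", ["hypergeometric", "fixed_probability"])
    def test_full_depth_is_identity(self, variant):
        counts = np.array([10, 5, 85])
        out = downsample_sample(counts, 100, variant=variant, seed=0)
        assert np.array_equal(out, counts)

    @pytest.mark.parametrize("variant", ["hypergeometric", "fixed_probability"])
    def test_target_zero_empties(self, variant):
        out = downsample_sample(np.array([10, 5, 85]), 0, variant=variant, seed=0)
        assert np.array_equal(out, [0, 0, 0])

    def test_target_above_depth_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            downsample_sample(np.array([3, 1]), 5)

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            downsample_sample(np.array([3, 1]), -1)

    def test_two_gene_exhaustive_probability(self):
        # counts [3,1], target 2: P([2,0]) = C(3,2)C(1,0)/C(4,2) = 0.5
        rng = np.random.default_rng(123)
        n = 100_000
        hits = 0
        for _ in range(n):
            out = downsample_sample(np.array([3, 1]), 2, seed=rng)
            if out[0] == 2:
                hits += 1
        p_hat = hits / n
        assert abs(p_hat - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_marginal_matches_univariate_hypergeometric(self):
        # chi-square GOF for one gene's marginal on a 5-gene toy
        from scipy.stats import chisquare, hypergeom

        counts = np.array([10, 20, 5, 40, 25])
        target = 40
        rng = np.random.default_rng(7)
        draws = np.array([
            downsample_sample(counts, target, seed=rng)[0] for _ in range(10_000)
        ])
        support = np.arange(0, 11)
        expected = hypergeom.pmf(support, counts.sum(), counts[0], target) * draws.size
        observed = np.bincount(draws, minlength=11)[:11]
        keep = expected > 5
        stat, p = chisquare(observed[keep], expected[keep] * observed[keep].sum()
                            / expected[keep].sum())
        assert p > 0.001

    @pytest.mark.parametrize("variant", ["hypergeometric", "fixed_probability"])
    def test_expectation_linearity(self, variant):
        counts = np.array([50, 100, 250, 600])
        target = 500
        rng = np.random.default_rng(11)
        acc = np.zeros(4)
        n = 3000
        for _ in range(n):
            acc += downsample_sample(counts, target, variant=variant, seed=rng)
        expected = counts * target / counts.sum()
        # binomial-scale SE per gene
        se = np.sqrt(expected * (1 - target / counts.sum()) / n) + 1e-9
        assert np.all(np.abs(acc / n - expected) < 5 * se)

    def test_low_count_prefilter_zeroes_genes(self):
        counts = np.array([3, 2, 100])
        out = downsample_sample(counts, 50, seed=1, min_count=4)
        assert out[0] == 0 and out[1] == 0 and out[2] == 50

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 200), min_size=1, max_size=20),
        frac=st.floats(0.0, 1.0),
        variant=st.sampled_from(["hypergeometric", "fixed_probability"]),
        seed=st.integers(0, 2**20),
    )
    def test_conservation_and_dominance(self, counts, frac, variant, seed):
        counts = np.array(counts)
        target = int(frac * counts.sum())
        out = downsample_sample(counts, target, variant=variant, seed=seed)
        assert out.sum() == target
        assert np.all(out <= counts)
        assert np.all(out >= 0)


class TestDownsamplePaired:
    def test_ratio_one_locks_umis_to_reads(self):
        reads = np.array([50, 30, 20])
        nr, nu = downsample_paired(reads, reads.copy(), 40, seed=0)
        assert np.array_equal(nr, nu)

    def test_zero_umis_stay_zero(self):
        reads = np.array([100, 50])
        umis = np.array([0, 25])
        nr, nu = downsample_paired(reads, umis, 60, seed=1)
        assert nu[0] == 0

    def test_umi_exceeding_reads_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            downsample_paired(np.array([5]), np.array([6]), 3)

    @pytest.mark.parametrize("fixed_ratio", [False, True])
    def test_expected_umi_tracks_proportional_removal(self, fixed_ratio):
        # c=100, u=50, remove 50 reads -> E[final u] = 25
        rng = np.random.default_rng(5)
        n = 10_000
        acc = 0
        for _ in range(n):
            _, nu = downsample_paired(
                np.array([100]), np.array([50]), 50, seed=rng, fixed_ratio=fixed_ratio
            )
            acc += nu[0]
        mean = acc / n
        se = 4.0 / np.sqrt(n)  # sd(final u) < 4 here
        assert abs(mean - 25) < 4 * se

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 100), st.integers(0, 100)), min_size=1, max_size=15
        ),
        frac=st.floats(0.0, 1.0),
        fixed_ratio=st.booleans(),
        seed=st.integers(0, 2**20),
    )
    def test_invariants_on_random_inputs(self, data, frac, fixed_ratio, seed):
        reads = np.array([max(a, b) for a, b in data])
        umis = np.array([min(a, b) for a, b in data])
        target = int(frac * reads.sum())
        nr, nu = downsample_paired(reads, umis, target, seed=seed, fixed_ratio=fixed_ratio)
        assert nr.sum() == target
        assert np.all(nr <= reads)
        assert np.all(nu <= umis)
        assert np.all(nu <= nr)
        assert np.all(nu >= 0)


class TestMatrixLevel:
    def test_common_depth_equalizes_columns(self):
        m1 = make_matrix(np.array([[60, 50], [40, 30]]))  # depths 100, 80
        m2 = make_matrix(np.array([[70], [50]]))          # depth 120
        results = downsample_to_common_depth([m1, m2], seed=0, min_count=0)
        for res in results:
            assert np.all(res.counts_at_depth.column_sums() == 80)

    def test_single_sample_unchanged(self):
        m = make_matrix(np.array([[60], [40]]))
        (res,) = downsample_to_common_depth([m], seed=0, min_count=0)
        assert res.counts_at_depth == m

    def test_prefilter_records_removed_genes(self):
        m = make_matrix(np.array([[2, 3], [100, 100]]))
        res = downsample_matrix(m, 50, seed=0, min_count=4)
        assert res.removed_low_expression_genes == ["G000"]
        assert np.all(res.counts_at_depth.counts[0] == 0)

    def test_summed_filter_keeps_gene_above_threshold(self):
        # 2+3=5 >= 4 summed: survives the summed-mode filter but not per-sample
        m = make_matrix(np.array([[2, 3], [100, 100]]))
        res = downsample_matrix(m, 50, seed=0, min_count=4, summed_filter=True)
        assert res.removed_low_expression_genes == []


class TestReplicateVariability:
    def test_full_depth_gives_zero_cv(self):
        m = make_matrix(np.array([[50, 60], [50, 40]]))
        rep = downsample_replicates(m, 100, n_reps=4, seed=0)
        assert np.all(rep["cv_detected"] == 0)

    def test_half_depth_cv_is_small_at_16_reps(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(rng.lognormal(3, 1.5, 2000))[:, None]
        m = make_matrix(counts)
        rep = downsample_replicates(m, int(counts.sum() // 2), n_reps=16, seed=1)
        assert rep["n_reps"] == 16
        assert np.all(rep["cv_detected"] < 0.01)

    def test_requires_at_least_two_reps(self):
        m = make_matrix(np.array([[10]]))
        with pytest.raises(ValueError, match="n_reps"):
            downsample_replicates(m, 5, n_reps=1)
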