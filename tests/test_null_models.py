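import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from scvartools.genome_model import AnnotatedGenome, GeneRecord
from scvartools.null_models import (
    NEMENYI_Q_05,
    benjamini_hochberg,
    continuum_randomization,
    friedman_test,
    genes_with_min_hits,
    global_positions,
    max_per_gene_hits,
    nemenyi_posthoc,
    pascal_probability,
    shared_gene_count,
    two_sample_t,
    weighted_gene_hit_score,
)


class TestPascalProbability:
    def test_k_zero_is_certain(self):
        assert pascal_probability(100, 0) == 1.0

    def test_n10_k2_enumeration_oracle(self):
        # all 45 unordered position pairs from a 10 bp gene; exactly one
        # matches a fixed pair
        pairs = list(itertools.combinations(range(10), 2))
        assert len(pairs) == 45
        target = (3, 7)
        hits = sum(1 for p in pairs if p == target)
        assert pascal_probability(10, 2) == pytest.approx(hits / len(pairs), rel=1e-12)

    def test_big_integer_oracle(self):
        assert pascal_probability(1500, 5) == pytest.approx(1 / math.comb(1500, 5), rel=1e-12)

    def test_random_pairs_vs_math_comb(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 5001))
            k = int(rng.integers(0, min(n, 10) + 1))
            assert pascal_probability(n, k) == pytest.approx(
                1 / math.comb(n, k), rel=1e-12
            )

    def test_k_exceeds_n_errors(self):
        with pytest.raises(ValueError):
            pascal_probability(5, 6)

    @given(n=st.integers(4, 3000), k=st.integers(1, 10))
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_k(self, n, k):
        if n >= 2 * (k + 1):
            assert pascal_probability(n, k + 1) < pascal_probability(n, k)


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.01, 0.04, 0.03, 0.2, 0.5, 0.002]
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        assert benjamini_hochberg(p) == pytest.approx(expected)

    def test_empty(self):
        assert benjamini_hochberg([]) == []


def _flat_genome(length=10_000, gene_frac=0.5):
    genes = [GeneRecord("g1", "c1", 0, int(length * gene_frac), "+", "other")]
    return AnnotatedGenome({"c1": "A" * length}, genes)


class TestContinuumRandomization:
    def test_all_conditions_empty_p_is_one(self):
        genome = _flat_genome()
        res = continuum_randomization(genome, {"a": [], "b": []}, iterations=100, seed=0)
        assert res.observed == 0
        assert res.p_empirical == 1.0

    def test_half_genome_gene_hit_probability(self):
        """Analytic limit: 1 variant, 1 gene covering 50% -> empirical hit
        probability within 3 MC standard deviations of 0.5."""
        genome = _flat_genome(10_000, 0.5)
        res = continuum_randomization(genome, {"a": [100]}, iterations=10_000, seed=3)
        p_hit = res.null_mean  # statistic is 0/1 per iteration
        assert abs(p_hit - 0.5) <= 3 * math.sqrt(0.25 / 10_000)

    def test_reproducible_given_seed(self):
        genome = _flat_genome()
        a = continuum_randomization(genome, {"a": [10, 20]}, iterations=500, seed=9)
        b = continuum_randomization(genome, {"a": [10, 20]}, iterations=500, seed=9)
        assert a == b

    def test_p_empirical_never_zero(self):
        genome = _flat_genome(10_000, 0.001)
        obs = {"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]}
        res = continuum_randomization(genome, obs, iterations=200, seed=1)
        assert res.p_empirical >= 1 / 201

    def test_multi_contig_mapping(self):
        # gene on second contig: global positions must respect offsets
        genes = [GeneRecord("g1", "c2", 0, 100, "+", "other")]
        genome = AnnotatedGenome({"c1": "A" * 1000, "c2": "A" * 100}, genes)
        pos = global_positions(genome, [("c2", 50, "A", "G")])
        assert pos == [1050]
        res = continuum_randomization(genome, {"a": pos}, iterations=2000, seed=4)
        assert res.observed == 1.0
        # gene covers 100/1100 of the continuum
        assert res.null_mean == pytest.approx(100 / 1100, abs=3 * 0.009)

    def test_statistics_on_known_counts(self):
        counts = {
            "a": np.array([[1, 0, 2], [0, 0, 0]]),
            "b": np.array([[1, 1, 0], [1, 0, 0]]),
        }
        assert shared_gene_count(counts).tolist() == [1, 0]
        assert max_per_gene_hits(counts).tolist() == [2, 1]
        assert genes_with_min_hits(2)(counts).tolist() == [2, 0]
        w = np.array([1.0, 10.0, 100.0])
        assert weighted_gene_hit_score(w)(counts).tolist() == [111.0, 1.0]

    def test_overlapping_genes_rejected(self):
        genes = [GeneRecord("g1", "c1", 0, 60, "+", "other"),
                 GeneRecord("g2", "c1", 30, 90, "+", "other")]
        genome = AnnotatedGenome({"c1": "A" * 100}, genes)
        with pytest.raises(ValueError, match="non-overlapping"):
            continuum_randomization(genome, {"a": [5]}, iterations=10, seed=0)


class TestFriedman:
    def test_identical_conditions_zero(self):
        m = [[1.0, 1.0, 1.0], [2.0, 2.0, 2.0], [5.0, 5.0, 5.0]]
        chi2, df, p = friedman_test(m)
        assert chi2 == 0.0
        assert p == 1.0

    def test_matches_scipy(self, rng):
        for _ in range(20):
            m = rng.normal(size=(6, 4))
            chi2, df, p = friedman_test(m)
            expected = stats.friedmanchisquare(*m.T)
            assert chi2 == pytest.approx(expected.statistic)
            assert p == pytest.approx(expected.pvalue)
            assert df == 3

    def test_matches_scipy_with_ties(self):
        m = np.array([[1, 1, 2], [3, 2, 2], [1, 2, 3], [2, 2, 2]], dtype=float)
        chi2, _, p = friedman_test(m)
        expected = stats.friedmanchisquare(*m.T)
        assert chi2 == pytest.approx(expected.statistic)
        assert p == pytest.approx(expected.pvalue)

    def test_exact_permutation_oracle_n4_k3(self):
        """Brute-force within-block permutation distribution (3!)^4 = 1296."""
        m = np.array(
            [[10.0, 12.0, 14.0], [8.0, 9.0, 13.0], [7.0, 11.0, 12.0], [5.0, 6.0, 9.0]]
        )
        chi2, df, p_exact = friedman_test(m, method="exact")
        assert chi2 == pytest.approx(stats.friedmanchisquare(*m.T).statistic)
        # independent brute force: permute each block's raw values
        perms = list(itertools.permutations(range(3)))
        count = total = 0
        for combo in itertools.product(perms, repeat=4):
            pm = np.vstack([m[i, list(pp)] for i, pp in enumerate(combo)])
            s = stats.friedmanchisquare(*pm.T).statistic
            total += 1
            if s >= chi2 - 1e-12:
                count += 1
        assert total == 1296
        assert p_exact == pytest.approx(count / total)

    def test_two_condition_reduction(self):
        """k=2 Friedman equals the sign-test chi-square on the same data."""
        m = np.array([[1.0, 2.0], [3.0, 1.0], [2.0, 5.0], [0.0, 4.0], [9.0, 7.0]])
        chi2, df, p = friedman_test(m)
        wins_b = sum(1 for a, b in m if b > a)
        n = len(m)
        sign_chi2 = (2 * wins_b - n) ** 2 / n
        assert df == 1
        assert chi2 == pytest.approx(sign_chi2)

    def test_monotone_transform_invariance(self, rng):
        m = rng.normal(size=(5, 3))
        chi2_a, _, _ = friedman_test(m)
        chi2_b, _, _ = friedman_test(np.exp(m))
        assert chi2_a == pytest.approx(chi2_b)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            friedman_test([[1.0, 2.0]])


class TestNemenyi:
    def test_k2_not_applicable(self):
        cd, pairs = nemenyi_posthoc([[1.0, 2.0], [2.0, 1.0]])
        assert cd is None and pairs == []

    def test_identical_conditions_never_flagged(self, rng):
        col = rng.normal(size=8)
        m = np.column_stack([col, col, col + rng.normal(scale=5, size=8)])
        _, pairs = nemenyi_posthoc(m)
        pair_ab = next(p for p in pairs if (p.a, p.b) == (0, 1))
        assert not pair_ab.significant

    def test_boundary_threshold_semantics(self):
        # construct rank matrices with mean-rank gap just below / above CD
        n, k = 4, 3
        cd = NEMENYI_Q_05[k] * math.sqrt(k * (k + 1) / (6 * n))  # ~1.66
        # all blocks identical ordering: mean ranks are 1, 2, 3 -> gap(0,2)=2>CD
        m = np.array([[1.0, 2.0, 3.0]] * n)
        _, pairs = nemenyi_posthoc(m)
        p02 = next(p for p in pairs if (p.a, p.b) == (0, 2))
        p01 = next(p for p in pairs if (p.a, p.b) == (0, 1))
        assert p02.mean_rank_diff == pytest.approx(2.0)
        assert p02.significant  # 2.0 > 1.657
        assert not p01.significant  # 1.0 < 1.657
        assert 1.0 < cd < 2.0

    def test_flagging_matches_brute_force_table(self, rng):
        from scipy.stats import rankdata

        m = rng.normal(size=(6, 4))
        cd, pairs = nemenyi_posthoc(m)
        ranks = np.vstack([rankdata(r) for r in m])
        mean_ranks = ranks.mean(axis=0)
        n, k = m.shape
        cd_bf = NEMENYI_Q_05[k] * math.sqrt(k * (k + 1) / (6 * n))
        assert cd == pytest.approx(cd_bf)
        for p in pairs:
            expected = abs(mean_ranks[p.a] - mean_ranks[p.b]) > cd_bf
            assert p.significant == expected
            # p-value consistent with the flag at alpha = 0.05
            assert (p.p_value < 0.05) == expected


class TestTwoSampleT:
    def test_identical_groups(self):
        t, df, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_3v3(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        # pooled variance = ((2)*1 + (2)*4)/4 = 2.5; se = sqrt(2.5*(2/3))
        se = math.sqrt(2.5 * (2 / 3))
        expected_t = (2.0 - 4.0) / se
        t, df, p = two_sample_t(a, b)
        assert t == pytest.approx(expected_t, abs=1e-12)
        assert df == 4
        assert p == pytest.approx(2 * stats.t.sf(abs(expected_t), 4), abs=1e-12)

    def test_matches_scipy(self, rng):
        a, b = rng.normal(size=10), rng.normal(loc=0.5, size=12)
        t, df, p = two_sample_t(a, b)
        expected = stats.ttest_ind(a, b)
        assert t == pytest.approx(expected.statistic)
        assert p == pytest.approx(expected.pvalue)
        tw, dfw, pw = two_sample_t(a, b, equal_variance=False)
        expected_w = stats.ttest_ind(a, b, equal_var=False)
        assert tw == pytest.approx(expected_w.statistic)
        assert pw == pytest.approx(expected_w.pvalue)

    def test_swap_symmetry(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=7)
        t1, _, p1 = two_sample_t(a, b)
        t2, _, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_zero_variance(self):
        t, _, p = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_group_too_small_errors(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])
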