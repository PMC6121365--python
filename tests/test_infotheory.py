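"""MI, conditional MI, K-locus chi-square and Bonferroni correction,
checked against independent brute-force oracles."""
from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from epimic import (
    GenotypeMatrix,
    bonferroni_threshold,
    chi_square_test,
    conditional_mutual_information,
    mutual_information,
)
from epimic.infotheory import UndefinedScoreError, batch_chi2, mi_against, mi_matrix

from conftest import random_matrix


def mi_oracle(table: np.ndarray) -> float:
    """Direct double sum over the joint table, independent of the
    package's vectorised path."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    total = 0.0
    for u in range(table.shape[0]):
        for v in range(table.shape[1]):
            if table[u, v] > 0:
                total += (table[u, v] / n) * math.log(
                    (table[u, v] / n) / ((rows[u] / n) * (cols[v] / n))
                )
    return total


def matrix_from_joint(table, pheno_value=1):
    """Two-SNP matrix realising exactly the given 3x3 joint counts."""
    rows = []
    for u in range(3):
        for v in range(3):
            rows += [[u + 1, v + 1]] * int(table[u][v])
    geno = np.array(rows, dtype=np.uint8)
    pheno = np.full(len(rows), pheno_value, dtype=np.uint8)
    return GenotypeMatrix(geno, pheno)


class TestMutualInformation:
    def test_self_mi_is_uniform_entropy(self):
        g = GenotypeMatrix(
            np.repeat([[1], [2], [3]], 4, axis=0).astype(np.uint8), np.zeros(12, int)
        )
        assert mutual_information(g, 0, 0).value == pytest.approx(math.log(3), abs=1e-12)

    def test_exact_product_table_gives_zero(self):
        # joint = row * col / N for every cell -> independence
        g = matrix_from_joint([[1, 2, 3], [2, 4, 6], [3, 6, 9]])
        assert mutual_information(g, 0, 1).value == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_sum_oracle(self):
        table = [[2, 1, 0], [1, 2, 1], [0, 1, 2]]
        g = matrix_from_joint(table)
        score = mutual_information(g, 0, 1)
        assert score.n_effective == 10
        assert score.value == pytest.approx(mi_oracle(table), abs=1e-12)

    def test_symmetry_and_entropy_bound(self):
        g = random_matrix(n_samples=50, n_snps=6, seed=11, missing_rate=0.1)
        for i in range(g.n_snps):
            for j in range(i, g.n_snps):
                a = mutual_information(g, i, j).value
                b = mutual_information(g, j, i).value
                assert a == b
                assert a >= -1e-12
                hi = mutual_information(g, i, i).value
                hj = mutual_information(g, j, j).value
                assert a <= min(hi, hj) + 1e-12

    def test_no_joint_samples_raises(self):
        geno = np.array([[1, 0], [0, 2]], dtype=np.uint8)
        g = GenotypeMatrix(geno, np.array([0, 1]))
        with pytest.raises(UndefinedScoreError):
            mutual_information(g, 0, 1)


class TestConditionalMI:
    def test_independent_case_table_gives_zero(self):
        g = matrix_from_joint([[1, 2, 0], [2, 4, 0], [0, 0, 0]], pheno_value=1)
        assert conditional_mutual_information(g, 0, 1).value == pytest.approx(0, abs=1e-12)

    def test_ignores_control_samples_entirely(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(1, 4, size=(40, 2)).astype(np.uint8)
        pheno = np.repeat([1, 0], 20).astype(np.uint8)
        g = GenotypeMatrix(geno, pheno)
        base = conditional_mutual_information(g, 0, 1).value
        geno2 = geno.copy()
        geno2[20:] = rng.integers(1, 4, size=(20, 2))  # scramble controls
        assert conditional_mutual_information(GenotypeMatrix(geno2, pheno), 0, 1).value == base

    def test_matches_case_stratum_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.integers(1, 4, size=20)
        b = np.where(rng.random(20) < 0.7, a, rng.integers(1, 4, size=20))  # dependent
        geno = np.column_stack([a, b]).astype(np.uint8)
        g = GenotypeMatrix(
            np.vstack([geno, rng.integers(1, 4, size=(10, 2))]).astype(np.uint8),
            np.repeat([1, 0], [20, 10]),
        )
        table = np.zeros((3, 3))
        for u, v in zip(a, b):
            table[u - 1, v - 1] += 1
        got = conditional_mutual_information(g, 0, 1)
        assert got.value == pytest.approx(mi_oracle(table), abs=1e-12)
        assert got.n_effective == 20

    def test_no_cases_raises(self):
        g = GenotypeMatrix(np.ones((4, 2), dtype=np.uint8), np.zeros(4, int))
        with pytest.raises(UndefinedScoreError):
            conditional_mutual_information(g, 0, 1)


class TestChiSquare:
    def test_null_table_statistic_zero(self):
        # identical genotype distributions in cases and controls
        block = np.repeat([1, 2, 3], [5, 3, 2])
        geno = np.concatenate([block, block]).reshape(-1, 1).astype(np.uint8)
        g = GenotypeMatrix(geno, np.repeat([0, 1], 10))
        res = chi_square_test(g, [0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_single_locus_matches_hand_oracle(self):
        # cases (10, 20, 10) vs controls (20, 10, 10)
        cases = np.repeat([1, 2, 3], [10, 20, 10])
        controls = np.repeat([1, 2, 3], [20, 10, 10])
        geno = np.concatenate([controls, cases]).reshape(-1, 1).astype(np.uint8)
        g = GenotypeMatrix(geno, np.repeat([0, 1], 40))
        table = np.array([[20, 10], [10, 20], [10, 10]], dtype=float)
        expected = table.sum(1, keepdims=True) * table.sum(0) / table.sum()
        stat = ((table - expected) ** 2 / expected).sum()
        res = chi_square_test(g, [0])
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.df == 2

    def test_agrees_with_textbook_contingency_test(self):
        g = random_matrix(n_samples=120, n_snps=3, seed=2)
        from epimic import joint_counts

        table = joint_counts(g, [1], stratify_by_phenotype=True)
        ref = chi2_contingency(table.T, correction=False)
        res = chi_square_test(g, [1])
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_k3_default_df_26(self, small_random):
        assert chi_square_test(small_random, [0, 1, 2]).df == 26
        assert chi_square_test(small_random, [0, 1, 2], df_override=7).df == 7

    def test_invariant_to_sample_order_and_category_relabeling(self):
        g = random_matrix(n_samples=90, n_snps=4, seed=8)
        base = chi_square_test(g, [0, 1]).statistic
        perm = np.random.default_rng(3).permutation(g.n_samples)
        assert chi_square_test(g.subset(samples=perm), [0, 1]).statistic == pytest.approx(base)
        relabeled = g.genotypes.copy()
        swap = {1: 3, 2: 1, 3: 2}
        relabeled[:, 0] = np.vectorize(swap.get)(relabeled[:, 0])
        g2 = GenotypeMatrix(relabeled, g.phenotype)
        assert chi_square_test(g2, [0, 1]).statistic == pytest.approx(base, rel=1e-12)

    def test_single_phenotype_class_raises(self):
        g = GenotypeMatrix(np.ones((6, 2), dtype=np.uint8), np.ones(6, int))
        with pytest.raises(ValueError):
            chi_square_test(g, [0, 1])

    def test_batch_chi2_matches_single_tests(self):
        g = random_matrix(n_samples=100, n_snps=6, seed=4, missing_rate=0.05)
        from itertools import combinations

        combos = np.array(list(combinations(range(6), 3)))
        stats, pvals = batch_chi2(g, combos)
        for row, stat, p in zip(combos, stats, pvals):
            ref = chi_square_test(g, row.tolist())
            assert stat == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.p_value, rel=1e-9)


class TestBonferroni:
    def test_single_combination(self):
        assert bonferroni_threshold(0.05, 3, 3) == 0.05

    def test_exact_binomial(self):
        assert bonferroni_threshold(0.05, 1000, 3) == pytest.approx(0.05 / 166_167_000)

    @given(st.integers(1, 40), st.integers(1, 40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_never_exceeds_alpha0(self, m, k):
        if k <= m:
            assert bonferroni_threshold(0.05, m, k) <= 0.05

    def test_k_greater_than_m_raises(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 2, 3)


class TestBatchedKernels:
    def test_mi_matrix_and_mi_against_match_pairwise_calls(self):
        """Gram-matrix counting (mi_matrix) and bit-set counting
        (mi_against) must both agree with the single-pair path."""
        g = random_matrix(n_samples=70, n_snps=5, seed=6, missing_rate=0.1)
        idx = np.arange(5)
        full = mi_matrix(g, idx)
        against = mi_against(g, [0, 3])
        for i in range(5):
            for j in range(5):
                ref = mutual_information(g, i, j).value
                assert full[i, j] == pytest.approx(ref, abs=1e-10)
        for pos, t in enumerate([0, 3]):
            for i in range(5):
                assert against[i, pos] == pytest.approx(
                    mutual_information(g, i, t).value, abs=1e-10
                )

    def test_mi_matrix_cases_only_matches_cmi(self):
        g = random_matrix(n_samples=60, n_snps=4, seed=13)
        mat = mi_matrix(g, np.arange(4), cases_only=True)
        for i in range(4):
            for j in range(4):
                if i != j:
                    ref = conditional_mutual_information(g, i, j).value
                    assert mat[i, j] == pytest.approx(ref, abs=1e-10)
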