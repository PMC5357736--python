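"""Nonparametric layer: Skillings-Mack vs Friedman and permutation oracles,
exact Wilcoxon enumerations, Hommel closed-testing oracle, IQR rule."""

from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given, strategies as st

import metabodiet as md
from metabodiet.group_stats import BlockData


def friedman_statistic(table):
    """Friedman chi-square from the rank-sum closed form (no ties)."""
    n, k = table.shape
    ranks = np.argsort(np.argsort(table, axis=1), axis=1) + 1.0
    R = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * np.sum(R**2) - 3.0 * n * (k + 1)


def simes_p(pvals):
    p = np.sort(np.asarray(pvals))
    m = p.size
    return float(np.min(m * p / np.arange(1, m + 1)))


def hommel_oracle(pvals):
    """Closed testing with Simes local tests: adjusted p_i is the maximum
    Simes p over every subset containing i."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    adjusted = np.zeros(m)
    for i in range(m):
        worst = 0.0
        others = [j for j in range(m) if j != i]
        for r in range(len(others) + 1):
            for subset in combinations(others, r):
                worst = max(worst, simes_p(p[list(subset) + [i]]))
        adjusted[i] = min(worst, 1.0)
    return adjusted


class TestSkillingsMack:
    def test_identical_values_statistic_zero(self):
        table = np.full((4, 3), 7.0)
        res = md.skillings_mack(table)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_equals_friedman_on_complete_balanced(self, rng):
        """Exact equality with the Friedman rank-sum formula, 100 toys."""
        for _ in range(100):
            n = int(rng.integers(3, 8))
            k = int(rng.integers(3, 6))
            table = rng.permutation(n * k).reshape(n, k).astype(float)
            res = md.skillings_mack(table)
            assert res.statistic == pytest.approx(friedman_statistic(table),
                                                  abs=1e-9)
            assert res.df == k - 1

    def test_matches_permutation_null_on_incomplete(self, rng):
        """In the significance region the chi-square p agrees with the
        within-block permutation null to 0.02 (the asymptotic reference is
        loose only deep in the null bulk)."""
        table = rng.normal(size=(8, 3))
        table[:, 0] += 1.2  # treatment effect pulls p into the tail
        table[0, 2] = np.nan
        table[3, 0] = np.nan
        chi2_p = md.skillings_mack(table).p
        perm_p = md.skillings_mack(table, method="permutation",
                                   n_permutations=100_000, seed=1).p
        assert chi2_p < 0.2
        assert abs(chi2_p - perm_p) < 0.02

    def test_blocks_with_single_observation_dropped(self):
        table = np.array([
            [1.0, 2.0, 3.0],
            [2.0, np.nan, np.nan],  # dropped
            [3.0, 1.0, 2.0],
            [1.0, 3.0, 2.0],
        ])
        with pytest.warns(UserWarning, match="dropping"):
            res = md.skillings_mack(table)
        clean = md.skillings_mack(np.delete(table, 1, axis=0))
        assert res.statistic == pytest.approx(clean.statistic)

    def test_block_data_long_format(self):
        data = BlockData(
            blocks=["a", "a", "a", "b", "b", "b"],
            treatments=[1, 2, 3, 1, 2, 3],
            values=np.array([1.0, 2.0, 3.0, 2.0, 3.0, 1.0]),
        )
        res = md.skillings_mack(data)
        assert res.df == 2
        assert 0 <= res.p <= 1

    def test_monotone_transform_invariance(self, rng):
        table = rng.normal(size=(5, 4))
        a = md.skillings_mack(table).statistic
        b = md.skillings_mack(np.exp(table)).statistic
        assert a == pytest.approx(b, abs=1e-10)


class TestKruskalWallis:
    def test_hand_rank_sum_two_groups(self):
        """{1,2,3} vs {4,5,6}: H = 12/42 * (3*1.5^2 * 2) = 27/7."""
        res = md.kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(27 / 7, abs=1e-9)
        assert res.df == 1

    def test_identical_groups_zero(self):
        res = md.kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_shift_invariance(self, rng):
        groups = [rng.normal(size=6), rng.normal(size=5), rng.normal(size=7)]
        a = md.kruskal_wallis(groups).statistic
        b = md.kruskal_wallis([g + 100.0 for g in groups]).statistic
        assert a == pytest.approx(b, abs=1e-10)


class TestWilcoxon:
    def test_signed_rank_exact_n3_all_positive(self):
        """Enumerating all 2^3 sign assignments gives two-sided p = 0.25."""
        res = md.wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert res.p == pytest.approx(0.25)
        assert "exact" in res.method

    def test_signed_rank_balanced_pair(self):
        res = md.wilcoxon_signed_rank([-1.0, 1.0])
        assert res.p == pytest.approx(1.0)

    def test_signed_rank_all_zero_rejected(self):
        with pytest.raises(ValueError):
            md.wilcoxon_signed_rank([0.0, 0.0])

    def test_rank_sum_exact_enumeration(self):
        """{1,2} vs {3,4}: 1 of C(4,2)=6 labelings is as extreme, p = 1/3."""
        res = md.wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert res.p == pytest.approx(1 / 3)
        assert "exact" in res.method

    def test_rank_sum_large_samples_use_approximation(self, rng):
        res = md.wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30))
        assert "approximation" in res.method
        assert 0 <= res.p <= 1

    def test_signed_rank_exact_matches_enumeration(self, rng):
        """Exact p equals brute-force enumeration over sign assignments."""
        d = rng.normal(size=6)
        d = np.sign(d) * (np.abs(d) + np.linspace(0, 1e-3, 6))  # untie
        res = md.wilcoxon_signed_rank(d)
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = ranks[d > 0].sum()
        ws = np.array([
            float(np.sum(ranks[np.array(s, dtype=bool)]))
            for s in product([False, True], repeat=6)
        ])
        mu = ranks.sum() / 2
        p_exact = np.mean(np.abs(ws - mu) >= abs(w_obs - mu) - 1e-12)
        assert res.p == pytest.approx(p_exact)


class TestHommel:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(md.hommel_adjust([0.03]), [0.03])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(md.hommel_adjust([0.2, 0.2, 0.2]),
                                   [0.2, 0.2, 0.2])

    def test_matches_closed_testing_oracle(self, rng):
        """Exact agreement with subset-enumeration Simes closed testing."""
        for m in (3, 4, 5, 7):
            p = np.round(rng.random(m), 3)
            np.testing.assert_allclose(
                md.hommel_adjust(p), hommel_oracle(p), atol=1e-12
            )

    def test_spec_example_vector(self):
        p = np.array([0.01, 0.02, 0.04])
        np.testing.assert_allclose(md.hommel_adjust(p), hommel_oracle(p),
                                   atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2,
                    max_size=8))
    def test_dominance_relations(self, p):
        """Hommel is at least as powerful as Hochberg (adjusted p never
        larger) and never dips below the raw p-values."""
        from statsmodels.stats.multitest import multipletests
        p = np.asarray(p)
        hommel = md.hommel_adjust(p)
        hochberg = multipletests(p, method="simes-hochberg")[1]
        bonferroni = np.minimum(p * p.size, 1.0)
        assert np.all(hommel <= hochberg + 1e-12)
        assert np.all(hommel <= bonferroni + 1e-12)
        assert np.all(hommel >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            md.hommel_adjust([0.5, -0.1])


class TestIQROutliers:
    def test_constant_vector_no_outliers(self):
        assert not md.iqr_outliers([5.0] * 6).any()

    def test_hand_type7_quantiles(self):
        """{1..9, 100}: Q1=3.25, Q3=7.75, upper fence 14.5 -> only 100."""
        v = list(range(1, 10)) + [100]
        flags = md.iqr_outliers(v)
        assert flags.sum() == 1
        assert flags[-1]

    def test_value_on_fence_not_flagged(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        q1, q3 = np.quantile(v, [0.25, 0.75])
        fence = q3 + 1.5 * (q3 - q1)
        flags = md.iqr_outliers(np.append(v, fence))
        assert not flags[-1]

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            md.iqr_outliers([1.0, 2.0, 3.0])


def test_omnibus_type_one_error_controlled(rng):
    """Null rejection rates near nominal 5% for both omnibus tests."""
    n_sim, alpha = 400, 0.05
    rej_sm = rej_kw = 0
    for _ in range(n_sim):
        table = rng.normal(size=(8, 4))
        if md.skillings_mack(table).p < alpha:
            rej_sm += 1
        if md.kruskal_wallis(list(rng.normal(size=(3, 10)))).p < alpha:
            rej_kw += 1
    assert rej_sm / n_sim <= 0.07
    assert rej_kw / n_sim <= 0.07
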