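import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import enrichcord as ec
from enrichcord.degs import _ROW_ORDER
from enrichcord.exceptions import ParameterError


def make_stats(t_p, log2fc, sam_d=None, sam_p=None, genes=None):
    n = len(t_p)
    genes = genes or [f"g{i}" for i in range(1, n + 1)]
    table = pd.DataFrame({
        "t_stat": np.zeros(n), "t_p": t_p, "log2fc": log2fc,
        "sam_d": sam_d if sam_d is not None else np.zeros(n),
        "sam_p": sam_p if sam_p is not None else np.ones(n),
    }, index=pd.Index(genes, name="gene"))
    return ec.GeneStatistics(table, n_a=5, n_b=5)


class TestStudentT:
    def test_hand_worked_example(self):
        # pooled s^2 = 2.5, SE = 1 -> t = -1, df = 8
        t, p = ec.student_t([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert t == pytest.approx(-1.0, abs=1e-12)
        assert p == pytest.approx(0.34659, abs=1e-4)

    def test_identical_groups(self):
        assert ec.student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_zero_variance_unequal_means(self):
        t, p = ec.student_t([1, 1, 1], [2, 2, 2])
        assert math.isinf(t) and t < 0 and p == 0.0

    def test_matches_scipy_pooled_t(self, rng):
        for _ in range(50):
            a, b = rng.normal(size=5), rng.normal(size=7)
            t, p = ec.student_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_single_value_group_rejected(self):
        with pytest.raises(ParameterError):
            ec.student_t([1.0], [2.0, 3.0])


class TestFoldChange:
    @pytest.mark.parametrize("a,b,expected", [
        ([3, 3], [4, 4], -1.0),
        ([1.5, 2.5], [1.5, 2.5], 0.0),
        ([2, 4], [1, 1], 2.0),
    ])
    def test_mean_difference(self, a, b, expected):
        assert ec.log2_fold_change(a, b) == pytest.approx(expected)

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            ec.log2_fold_change([], [1.0])


class TestSamStatistic:
    def test_equals_t_when_s0_zero(self, rng):
        for _ in range(100):
            a, b = rng.normal(size=5), rng.normal(size=5)
            assert ec.sam_statistic(a, b, 0.0) == ec.student_t(a, b)[0]

    def test_zero_for_equal_means(self):
        assert ec.sam_statistic([1, 3], [2, 2], 5.0) == 0.0

    def test_shrinks_monotonically_with_s0(self, rng):
        a, b = rng.normal(1, 1, 5), rng.normal(0, 1, 5)
        ds = [abs(ec.sam_statistic(a, b, s0)) for s0 in (0.0, 0.5, 2.0, 10.0)]
        assert ds == sorted(ds, reverse=True)
        assert ds[-1] < 0.2 * ds[0]


class TestChooseS0:
    def test_constant_s_gives_zero(self):
        assert ec.choose_s0(np.ones(50), np.arange(50.0)) == 0.0

    def test_homoscedastic_data_damps_d_with_large_s0(self, rng):
        """One shared sigma: window spreads go as 1/(s_j + s0), so the CV of
        the window MADs falls monotonically in s0 and the rule picks a large
        fudge factor (d then tracks the raw mean difference, which is the
        right behaviour when variance carries no gene information)."""
        hits = 0
        for _ in range(10):
            x = rng.normal(size=(500, 10))
            from enrichcord.degs import _pooled_pieces
            r, s, _ = _pooled_pieces(x[:, :5], x[:, 5:], axis=1)
            hits += ec.choose_s0(s, r) >= np.median(s)
        assert hits >= 8

    def test_proportional_heteroscedastic_noise_keeps_s0_small(self, rng):
        """sigma_g ~ U(0.05, 2): the numerator spread scales with s, so d is
        already pivotal at s0 = 0 and any positive s0 re-introduces window
        differences; the rule keeps s0 at or near zero."""
        hits = 0
        for _ in range(10):
            sd = rng.uniform(0.05, 2.0, size=1000)
            x = rng.normal(size=(1000, 10)) * sd[:, None]
            from enrichcord.degs import _pooled_pieces
            r, s, _ = _pooled_pieces(x[:, :5], x[:, 5:], axis=1)
            hits += ec.choose_s0(s, r) <= np.percentile(s, 5) + 1e-12
        assert hits >= 8

    def test_too_few_genes_rejected(self):
        with pytest.raises(ParameterError):
            ec.choose_s0(np.ones(10), np.ones(10))


class TestSamPermutationP:
    def test_balanced_5v5_enumerates_252_assignments(self, rng):
        x = rng.normal(size=(20, 10))
        labels = ["A"] * 5 + ["B"] * 5
        p = ec.sam_permutation_p(x, labels, s0=0.1)
        steps = p * 252
        np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)
        assert p.min() >= 1 / 252

    def test_extreme_gene_gets_minimum_attainable_p(self, rng):
        x = rng.normal(size=(5, 10)) * 0.05
        x[0, :5] += 10.0          # overwhelming real difference
        labels = ["A"] * 5 + ["B"] * 5
        p = ec.sam_permutation_p(x, labels, s0=0.0)
        # the complement assignment always duplicates |d|, so the smallest
        # attainable p under full enumeration is 2/252
        assert p[0] == pytest.approx(2 / 252)

    def test_null_data_calibration(self, rng):
        x = rng.normal(size=(1000, 10))
        labels = ["A"] * 5 + ["B"] * 5
        p = ec.sam_permutation_p(x, labels, s0=0.0)
        assert 0.03 <= (p < 0.05).mean() <= 0.07

    def test_sampling_mode_requires_enough_perms(self, rng):
        x = rng.normal(size=(10, 14))
        labels = ["A"] * 7 + ["B"] * 7
        with pytest.raises(ParameterError):
            ec.sam_permutation_p(x, labels, s0=0.0, n_perm=10,
                                 enumerate_limit=100)


class TestSelectDegs:
    def test_three_gene_toy_fc_filter(self):
        stats = make_stats(t_p=[0.001, 0.02, 0.2], log2fc=[1.5, 0.5, 3.0])
        out = ec.select_degs(stats, ec.DEGCriterion("FC", 0.05, 1.0))
        assert out.genes == ["g1"]      # g2 fails FC, g3 fails p

    def test_all_insignificant_gives_empty_lists(self):
        stats = make_stats(t_p=[1.0] * 4, log2fc=[3, 2, 1, 0],
                           sam_p=[1.0] * 4)
        for m in ("FC", "SAM", "TTEST"):
            assert ec.select_degs(stats, ec.DEGCriterion(m, 0.05)).genes == []

    def test_ttest_superset_of_fc_at_same_cutoff(self, rng):
        stats = make_stats(t_p=rng.uniform(size=200),
                           log2fc=rng.normal(0, 1.5, 200))
        fc = set(ec.select_degs(stats, ec.DEGCriterion("FC", 0.05)).genes)
        tt = set(ec.select_degs(stats, ec.DEGCriterion("TTEST", 0.05)).genes)
        assert fc <= tt

    def test_monotone_cutoffs(self, desk_stats):
        for m in ("FC", "SAM", "TTEST"):
            n01 = len(ec.select_degs(desk_stats, ec.DEGCriterion(m, 0.01)))
            n05 = len(ec.select_degs(desk_stats, ec.DEGCriterion(m, 0.05)))
            assert n05 >= n01

    def test_tie_break_is_lexicographic(self):
        stats = make_stats(t_p=[0.001, 0.001], log2fc=[2.0, 2.0],
                           genes=["zz", "aa"])
        out = ec.select_degs(stats, ec.DEGCriterion("FC", 0.05))
        assert out.genes == ["aa", "zz"]


class TestSamTDivergence:
    def test_rank_agreement_decreases_with_heteroscedasticity(self, rng):
        """|spearman(d, t)| falls as the sigma_g range widens (10-seed median)."""
        from enrichcord.degs import _pooled_pieces

        def median_corr(lo, hi):
            cors = []
            for seed in range(10):
                g = np.random.default_rng(seed)
                sd = g.uniform(lo, hi, size=800)
                x = g.normal(size=(800, 10)) * sd[:, None]
                x[:200, :5] += g.normal(1.0, 0.3, size=(200, 1))
                r, s, _ = _pooled_pieces(x[:, :5], x[:, 5:], axis=1)
                t = r / s
                d = r / (s + ec.choose_s0(s, r))
                cors.append(abs(sps.spearmanr(t, d).statistic))
            return np.median(cors)

        assert median_corr(0.05, 2.0) < median_corr(0.45, 0.55)


def test_deg_count_table_layout_and_nesting(desk_stats):
    lists = {}
    for m, c in _ROW_ORDER:
        lists[("AFX", "1", m, c)] = ec.select_degs(
            desk_stats, ec.DEGCriterion(m, c))
    table = ec.deg_count_table(lists)
    assert list(table.columns) == ["AFX_1"]
    assert table.shape == (6, 1)
    col = table["AFX_1"]
    # column-wise nesting within a method, and FC <= t-test at equal cutoff
    assert col["t-test (p<0.05)"] >= col["t-test (p<0.01)"]
    assert col["|log2FC|>1 (p<0.01)"] <= col["t-test (p<0.01)"]
    assert col["|log2FC|>1 (p<0.05)"] <= col["t-test (p<0.05)"]
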