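"""From-scratch hypothesis tests checked against enumeration and scipy."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cnediv import anova_oneway, chi_square_2x2, fisher_one_tail, two_sample_t
from cnediv.stats import ContingencyTable2x2, DegenerateTableError

counts = st.integers(0, 60)


def pearson_loop(table):
    """Literal sum((O-E)^2/E) with expected counts from the margins."""
    (a, b), (c, d) = table
    n = a + b + c + d
    rows, cols = (a + b, c + d), (a + c, b + d)
    total = 0.0
    for i, row in enumerate(table):
        for j, obs in enumerate(row):
            exp = rows[i] * cols[j] / n
            total += (obs - exp) ** 2 / exp
    return total


class TestChiSquare:
    def test_perfect_independence(self):
        res = chi_square_2x2([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_symmetric_table(self):
        """[[20,10],[10,20]]: all expected counts are 15, statistic 20/3."""
        res = chi_square_2x2([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(20 / 3, rel=1e-12)
        assert res.df == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_square_2x2([[0, 0], [5, 5]])

    def test_matches_formula_and_scipy_on_random_tables(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 200:
            table = rng.integers(0, 50, size=(2, 2))
            if 0 in table.sum(0) or 0 in table.sum(1):
                continue
            res = chi_square_2x2(table.tolist())
            assert res.statistic == pytest.approx(pearson_loop(table.tolist()), rel=1e-12)
            stat, p, _, _ = sps.chi2_contingency(table, correction=False)
            assert res.statistic == pytest.approx(stat, rel=1e-10)
            assert res.p_value == pytest.approx(p, rel=1e-10)
            checked += 1

    def test_yates_matches_scipy_correction(self):
        table = [[12, 5], [7, 15]]
        res = chi_square_2x2(table, yates=True)
        stat, p, _, _ = sps.chi2_contingency(np.array(table), correction=True)
        assert res.statistic == pytest.approx(stat, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    @given(a=counts, b=counts, c=counts, d=counts)
    @settings(derandomize=True, max_examples=60)
    def test_invariant_under_simultaneous_row_col_swap(self, a, b, c, d):
        table = [[a + 1, b], [c, d + 1]]  # +1 keeps margins positive
        swapped = [[d + 1, c], [b, a + 1]]
        assert chi_square_2x2(table).statistic == pytest.approx(
            chi_square_2x2(swapped).statistic, rel=1e-12
        )


class TestFisherOneTail:
    def test_fully_concordant_table(self):
        """[[5,0],[0,5]] enrichment: the observed table is the unique extreme."""
        res = fisher_one_tail([[5, 0], [0, 5]], "greater")
        assert res.p_value == pytest.approx(1 / math.comb(10, 5), rel=1e-12)

    def test_zero_row_gives_p_one(self):
        assert fisher_one_tail([[0, 0], [3, 4]], "greater").p_value == 1.0

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(150):
            a, b, c, d = rng.integers(0, 15, size=4)
            if a + b + c + d == 0:
                continue
            table = [[int(a), int(b)], [int(c), int(d)]]
            for direction in ("greater", "less"):
                mine = fisher_one_tail(table, direction).p_value
                _, ref = sps.fisher_exact(table, alternative=direction)
                assert mine == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_one_tail_at_most_two_tail(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if a + b + c + d == 0:
                continue
            table = [[a, b], [c, d]]
            _, two = sps.fisher_exact(table, alternative="two-sided")
            observed_tail = min(
                fisher_one_tail(table, "greater").p_value,
                fisher_one_tail(table, "less").p_value,
            )
            assert observed_tail <= two + 1e-12

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_tail([[1, 2], [3, 4]], "sideways")


class TestTwoSampleT:
    def test_identical_samples(self):
        res = two_sample_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_separated_samples_against_permutation_oracle(self):
        """All 20 label permutations of the pooled data form the exact null."""
        xs, ys = [0.0, 0.0, 1.0], [10.0, 11.0, 9.0]
        res = two_sample_t(xs, ys)
        assert res.p_value < 0.01
        pooled = xs + ys
        observed = abs(np.mean(xs) - np.mean(ys))
        extreme = 0
        total = 0
        for idx in combinations(range(6), 3):
            group_a = [pooled[i] for i in idx]
            group_b = [pooled[i] for i in range(6) if i not in idx]
            total += 1
            if abs(np.mean(group_a) - np.mean(group_b)) >= observed - 1e-12:
                extreme += 1
        assert extreme / total <= 0.2  # observed split is among the most extreme

    def test_matches_scipy_welch_and_pooled(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            xs = rng.normal(0, 1, rng.integers(3, 12))
            ys = rng.normal(0.5, 2, rng.integers(3, 12))
            for welch in (True, False):
                res = two_sample_t(xs, ys, welch=welch)
                ref = sps.ttest_ind(xs, ys, equal_var=not welch)
                assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
                assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_welch_df_at_most_pooled_df(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            xs = rng.normal(0, 0.5, 5)
            ys = rng.normal(0, 3.0, 9)
            welch = two_sample_t(xs, ys, welch=True)
            pooled = two_sample_t(xs, ys, welch=False)
            assert welch.df <= pooled.df + 1e-9

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0], [2.0, 2.0])


class TestAnova:
    def test_identical_groups(self):
        res = anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_two_group_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            xs = rng.normal(0, 1, rng.integers(3, 10))
            ys = rng.normal(1, 1.5, rng.integers(3, 10))
            f = anova_oneway([xs, ys])
            t = two_sample_t(xs, ys, welch=False)
            assert f.statistic == pytest.approx(t.statistic**2, rel=1e-9)
            assert f.p_value == pytest.approx(t.p_value, rel=1e-9)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(13)
        groups = [rng.normal(m, 1, 8) for m in (0, 0.3, 1)]
        res = anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)
        assert res.df == (2.0, 21.0)

    def test_null_p_values_roughly_uniform_under_label_shuffles(self):
        """Shuffling labels of equal-mean data gives uniform p (KS sanity)."""
        rng = np.random.default_rng(17)
        data = rng.normal(0, 1, 24)
        pvals = []
        for _ in range(300):
            perm = rng.permutation(data)
            pvals.append(anova_oneway([perm[:8], perm[8:16], perm[16:]]).p_value)
        assert sps.kstest(pvals, "uniform").pvalue > 1e-3

    def test_single_group_or_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1, 2, 3]])
        with pytest.raises(ValueError):
            anova_oneway([[1, 2], [3]])


class TestContingencyTable:
    def test_margins(self):
        t = ContingencyTable2x2(1, 2, 3, 4)
        assert t.row_margins == (3, 7)
        assert t.col_margins == (4, 6)
        assert t.total == 10

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)

    @given(a=counts, b=counts, c=counts, d=counts)
    @settings(derandomize=True, max_examples=60)
    def test_all_p_values_in_unit_interval(self, a, b, c, d):
        table = [[a, b], [c, d]]
        if a + b + c + d == 0:
            return
        for direction in ("greater", "less"):
            assert 0.0 <= fisher_one_tail(table, direction).p_value <= 1.0
        if 0 not in (a + b, c + d, a + c, b + d):
            res = chi_square_2x2(table)
            assert res.statistic >= 0.0
            assert 0.0 <= res.p_value <= 1.0
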