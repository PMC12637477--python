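"""Composition, expressing fractions, rank-sum/permutation tests and the
Spearman quantile trend, each against an independent oracle."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from chronotime import (
    ChronotimeError,
    composition,
    expressing_fraction,
    gene_set_score,
    lognorm,
    quantile_trend,
    rank_sum_test,
    section_permutation_test,
    simulate_section,
    spearman_rho,
)
from chronotime.proximity import QuantileExpressionMatrix
import pandas as pd

from conftest import make_section


class TestComposition:
    def test_proportions(self):
        section = make_section(
            np.zeros((100, 2)), ["A"] * 30 + ["B"] * 70
        )
        table = composition([section], ["A", "B"])
        props = table.rows.set_index("cell_type")["proportion"]
        assert props["A"] == pytest.approx(0.3)
        assert props["B"] == pytest.approx(0.7)

    def test_others_collapsed_and_sum_to_one(self):
        section = make_section(
            np.zeros((10, 2)), ["A"] * 4 + ["B"] * 3 + ["C"] * 3
        )
        table = composition([section], ["A"])
        assert table.rows["proportion"].sum() == pytest.approx(1.0)
        assert set(table.rows["cell_type"]) == {"A", "other"}

    def test_empty_section_rejected(self):
        section = make_section(np.empty((0, 2)), [])
        with pytest.raises(ChronotimeError, match="empty"):
            composition([section], ["A"])

    def test_wilson_ci_attached(self):
        section = make_section(np.zeros((50, 2)), ["A"] * 20 + ["B"] * 30)
        table = composition([section], ["A", "B"], ci=True)
        row = table.rows.set_index("cell_type").loc["A"]
        assert row["ci_low"] < 0.4 < row["ci_high"]


class TestExpressingFraction:
    def section_with_ifng(self, counts):
        return make_section(
            np.zeros((len(counts), 2)), ["T"] * len(counts),
            np.array([counts]), ["Ifng"],
        )

    def test_singleton_set(self):
        section = self.section_with_ifng([0, 1, 5, 0])
        assert expressing_fraction(section, "T", ["Ifng"]) == 0.5

    def test_monotone_in_threshold(self):
        section = self.section_with_ifng([0, 1, 2, 3, 5, 8])
        fracs = [
            expressing_fraction(section, "T", ["Ifng"], threshold=t)
            for t in (1, 2, 3, 6)
        ]
        assert fracs == sorted(fracs, reverse=True)

    def test_any_gene_counts(self):
        section = make_section(
            np.zeros((2, 2)), ["T", "T"],
            np.array([[1, 0], [0, 1]]), ["Ifng", "Gzmb"],
        )
        assert expressing_fraction(section, "T", ["Ifng", "Gzmb"]) == 1.0

    def test_no_cells_of_type(self):
        section = self.section_with_ifng([1])
        with pytest.raises(ChronotimeError, match="no cells"):
            expressing_fraction(section, "myeloid", ["Ifng"])


class TestGeneSetScore:
    def test_singleton_equals_lognorm(self):
        counts = np.array([[4, 0], [6, 3]])
        section = make_section(
            np.zeros((2, 2)), ["T", "T"], counts, ["Ifng", "Actb"]
        )
        score = gene_set_score(section, ["Ifng"])
        expected = lognorm(counts)[0]
        np.testing.assert_allclose(score.to_numpy(), expected)

    def test_all_zero_cell_scores_zero(self):
        section = make_section(
            np.zeros((1, 2)), ["T"], np.array([[0], [0]]), ["Ifng", "Gzmb"]
        )
        assert gene_set_score(section, ["Ifng", "Gzmb"]).iloc[0] == 0.0

    def test_subset_by_type(self):
        section = make_section(
            np.zeros((3, 2)), ["T", "myeloid", "T"],
            np.array([[1, 2, 3]]), ["Ifng"],
        )
        score = gene_set_score(section, ["Ifng"], cell_subset="T")
        assert len(score) == 2


def enumeration_oracle(x, y, alternative):
    """Exact rank-sum p by enumerating all splits of the pooled sample."""
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return (xs[:, None] > ys[None, :]).sum() + 0.5 * (
            xs[:, None] == ys[None, :]
        ).sum()

    u_obs = u_of(range(n1))
    us = np.array([u_of(c) for c in combinations(range(n), n1)])
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2 * min(p_le, p_ge))


class TestRankSum:
    def test_worked_example(self):
        res = rank_sum_test([1, 2], [3, 4], "less")
        assert res.statistic == 0
        assert res.p_value == pytest.approx(1 / 6)
        assert res.exact

    def test_identical_samples_p_one(self):
        res = rank_sum_test([1, 2, 2, 3] * 6, [1, 2, 2, 3] * 6)
        assert res.p_value == 1.0

    def test_exact_path_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for n1 in (2, 3, 5):
            for n2 in (2, 4, 6):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                for alt in ("two-sided", "less", "greater"):
                    res = rank_sum_test(x, y, alt)
                    assert res.exact
                    assert res.p_value == pytest.approx(
                        enumeration_oracle(x, y, alt)
                    )

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=6), rng.normal(size=7)
        res = rank_sum_test(x, y, "two-sided")
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="exact")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_matches_scipy_asymptotic_with_ties(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 6, size=30).astype(float)
        y = rng.integers(1, 7, size=25).astype(float)
        res = rank_sum_test(x, y, "two-sided")
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic")
        assert not res.exact
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_empty_sample_rejected(self):
        with pytest.raises(ChronotimeError):
            rank_sum_test([], [1.0])

    @staticmethod
    def dp_exact_p(x, y):
        """Exact two-sided p for tie-free data by counting, for every
        possible rank sum, the subsets of {1..n} of size n1 achieving it."""
        n1, n2 = len(x), len(y)
        n = n1 + n2
        max_sum = n * (n + 1) // 2
        ways = np.zeros((n1 + 1, max_sum + 1), dtype=object)
        ways[0, 0] = 1
        for rank in range(1, n + 1):
            for k in range(min(rank, n1), 0, -1):
                ways[k, rank:] = ways[k, rank:] + ways[k - 1, :-rank or None]
        pooled = np.concatenate([x, y])
        r1 = scipy.stats.rankdata(pooled)[:n1].sum()
        u_obs = r1 - n1 * (n1 + 1) / 2
        total = comb(n, n1)
        sums = np.arange(max_sum + 1)
        us = sums - n1 * (n1 + 1) / 2
        p_le = sum(ways[n1, s] for s in range(max_sum + 1) if us[s] <= u_obs)
        p_ge = sum(ways[n1, s] for s in range(max_sum + 1) if us[s] >= u_obs)
        return min(1.0, 2 * min(p_le / total, p_ge / total))

    def test_normal_approximation_near_exact_at_n15(self):
        """For n1 = n2 = 15 on continuous data the tie-corrected normal
        approximation with continuity correction is within 0.01 of the
        exact enumeration."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            x, y = rng.normal(size=15), rng.normal(size=15)
            res = rank_sum_test(x, y, "two-sided")
            assert not res.exact
            assert abs(res.p_value - self.dp_exact_p(x, y)) < 0.01


def value_sections(values, labels):
    """Minimal sections whose permutation statistic is a stored value."""
    out = []
    for i, (v, lab) in enumerate(zip(values, labels)):
        out.append(make_section([[v, 0.0]], ["T"], section_id=f"s{i}",
                                condition=lab))
    return out


def xstat(section):
    return float(section.cells["x_um"].iloc[0])


class TestSectionPermutation:
    def test_exhaustive_3v3_multiple_of_20(self):
        sections = value_sections(
            [10, 11, 12, 1, 2, 3], ["ZT2"] * 3 + ["ZT18"] * 3
        )
        res = section_permutation_test(xstat, sections)
        assert res.exact
        assert res.n_permutations == comb(6, 3)
        assert res.p_value * 20 == pytest.approx(round(res.p_value * 20))
        assert res.p_value == pytest.approx(2 / 20)  # obs and its mirror

    def test_most_extreme_mc_p(self):
        # 8 vs 8 sections -> C(16,8) = 12870 assignments, Monte-Carlo path
        values = list(range(100, 108)) + list(range(8))
        sections = value_sections(values, ["ZT2"] * 8 + ["ZT18"] * 8)
        res = section_permutation_test(xstat, sections, n_perm=99, seed=0)
        assert not res.exact
        assert res.p_value == pytest.approx(1 / 100)

    def test_needs_two_sections_per_condition(self):
        sections = value_sections([1, 2, 3], ["ZT2", "ZT18", "ZT18"])
        with pytest.raises(ChronotimeError, match=">= 2 sections"):
            section_permutation_test(xstat, sections)

    def test_needs_two_conditions(self):
        sections = value_sections([1, 2, 3, 4], ["ZT2"] * 4)
        with pytest.raises(ChronotimeError, match="2 conditions"):
            section_permutation_test(xstat, sections)


def qem_from_rows(rows):
    index = pd.MultiIndex.from_tuples(
        [(f"G{i}", "T") for i in range(len(rows))],
        names=["gene", "measured_in_type"],
    )
    vals = pd.DataFrame(np.asarray(rows, float), index=index,
                        columns=range(1, len(rows[0]) + 1))
    return QuantileExpressionMatrix(values=vals, cell_counts=vals * 0)


class TestQuantileTrend:
    def test_strictly_decreasing_is_minus_one(self):
        trend = quantile_trend(qem_from_rows([np.arange(10, 0, -1)]))
        assert trend["rho"].iloc[0] == pytest.approx(-1.0)

    def test_constant_row_flagged_zero(self):
        trend = quantile_trend(qem_from_rows([[2.0] * 10]))
        assert trend["rho"].iloc[0] == 0.0
        assert trend["constant"].iloc[0]

    def test_needs_three_columns(self):
        with pytest.raises(ChronotimeError, match=">= 3"):
            quantile_trend(qem_from_rows([[1.0, 2.0]]))

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(7)
        idx = np.arange(10.0)
        for _ in range(200):
            row = np.round(rng.normal(size=10), 1)  # rounding makes ties
            if np.all(row == row[0]):
                continue
            got = spearman_rho(idx, row)
            ref = scipy.stats.spearmanr(idx, row).statistic
            assert got == pytest.approx(ref)


@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30),
       st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30))
@settings(derandomize=True, max_examples=60, deadline=None)
def test_rank_sum_p_in_unit_interval(x, y):
    res = rank_sum_test(x, y)
    assert 0 < res.p_value <= 1


def test_composition_recovers_planted_proportions(small_config):
    """On generated sections the true-label composition equals the
    configured per-type counts."""
    section, truth = simulate_section(small_config, "ZT18", seed=6)
    table = composition([section], ["T", "myeloid", "tumor", "other"])
    props = table.rows.set_index("cell_type")["proportion"]
    n = section.n_cells
    assert props["T"] == pytest.approx(
        truth.params["n_by_type"]["T"] / n
    )
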