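"""Contingency-table association tests and their published regression
values."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvassoc import (
    ContingencyTable,
    bonferroni,
    build_contingency,
    chi_squared,
    clinical_association,
    fisher_exact,
    odds_ratio,
    wilcoxon_rank_sum,
)
from cnvassoc.datasets import published_contingency


def brute_force_freeman_halton(table):
    """Independent oracle: exact rational enumeration of all 2xk tables
    with the observed margins; p = sum of probabilities <= observed."""
    t = np.asarray(table, dtype=int)
    cols = t.sum(axis=0)
    r1 = int(t[0].sum())
    n = int(t.sum())
    denom = comb(n, r1)

    def table_prob(row):
        num = 1
        for c, a in zip(cols, row):
            num *= comb(int(c), int(a))
        return num, denom

    obs_num, _ = table_prob(t[0])
    total = 0
    for row in itertools.product(*[range(c + 1) for c in cols]):
        if sum(row) != r1:
            continue
        num, _ = table_prob(row)
        if num <= obs_num:  # integer numerators: exact tie comparison
            total += num
    return total / denom


def calls_from_table(table: ContingencyTable, gene="G"):
    """Expand a count table back into a per-sample call frame."""
    rows = []
    i = 0
    for r, group in enumerate(("control", "case")):
        for label, count in zip(table.col_labels, table.counts[r]):
            dcn = int(str(label).split("-")[0].replace("+", ""))
            for _ in range(count):
                rows.append({"sample": f"s{i}", "gene": gene, "dCN": dcn,
                             "group": group})
                i += 1
    return pd.DataFrame(rows)


class TestContingencyTable:
    def test_validates_shape_and_counts(self):
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[1, 2]]))
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[1, -2], [3, 4]]))
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[0, 0], [3, 4]]))


class TestBuildContingency:
    def test_null_vs_rest_reproduces_published_ccl3l3_split(self):
        calls = calls_from_table(published_contingency("CCL3L3"))
        t = build_contingency(calls, "G", scheme="null_vs_rest")
        assert np.array_equal(t.counts, [[0, 338], [17, 310]])

    def test_low_vs_rest_reproduces_published_c4b_split(self):
        calls = calls_from_table(published_contingency("C4B"))
        t = build_contingency(calls, "G", scheme="low_vs_rest")
        assert np.array_equal(t.counts, [[43, 295], [62, 265]])

    def test_per_dcn_reproduces_published_count_rows(self):
        calls = calls_from_table(published_contingency("CCL3L3"))
        t = build_contingency(calls, "G", scheme="per_dcn", pool_from=4)
        assert np.array_equal(t.counts, [[0, 83, 141, 91, 23], [17, 74, 118, 84, 34]])

    def test_per_dcn_pools_high_copy_tail(self):
        calls = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(8)],
                "gene": "G",
                "dCN": [1, 2, 4, 6, 1, 2, 5, 2],
                "group": ["control"] * 4 + ["case"] * 4,
            }
        )
        t = build_contingency(calls, "G", scheme="per_dcn", pool_from=4)
        assert list(t.col_labels) == ["1", "2", "4-6"]  # empty bins dropped
        assert np.array_equal(t.counts, [[1, 1, 2], [1, 2, 1]])

    def test_all_diploid_cohort_is_degenerate(self):
        calls = pd.DataFrame(
            {"sample": ["a", "b"], "gene": "G", "dCN": [2, 2],
             "group": ["control", "case"]}
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            build_contingency(calls, "G", scheme="per_dcn")

    def test_unknown_gene_rejected(self):
        calls = pd.DataFrame({"sample": ["a"], "gene": "G", "dCN": [2],
                              "group": ["control"]})
        with pytest.raises(ValueError):
            build_contingency(calls, "NOPE")


class TestFisherExact:
    @pytest.mark.parametrize(
        "name,expected",
        [("IL12B", 0.1183), ("TBX21", 0.1183), ("TNIP1", 0.2414), ("TNFAIP3", 1.0000)],
    )
    def test_published_two_by_two_values(self, name, expected):
        res = fisher_exact(published_contingency(name))
        assert res.p == pytest.approx(expected, abs=1e-4)

    def test_proportional_rows_give_p_one(self):
        res = fisher_exact(np.array([[10, 20, 30], [20, 40, 60]]))
        assert res.p == pytest.approx(1.0)

    def test_matches_scipy_on_two_by_two(self, rng):
        from scipy import stats

        for _ in range(30):
            t = rng.integers(0, 15, size=(2, 2)) + [[1, 0], [0, 1]]
            ours = fisher_exact(t).p
            ref = stats.fisher_exact(t).pvalue
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_matches_brute_force_on_small_2x3_tables(self, rng):
        # the invariant: exact equals full enumeration for all margins <= 12
        for _ in range(25):
            t = rng.integers(0, 5, size=(2, 3))
            t[0, 0] += 1
            t[1, 1] += 1
            assert fisher_exact(t).p == pytest.approx(
                brute_force_freeman_halton(t), abs=1e-10
            )

    def test_monte_carlo_agrees_with_exact(self):
        t = published_contingency("C4A")
        exact = fisher_exact(t, method="exact")
        mc = fisher_exact(t, method="monte_carlo", B=200_000, seed=5)
        assert abs(mc.p - exact.p) < 3 * mc.mc_se

    def test_invariant_to_row_and_column_permutations(self):
        t = np.array([[5, 9, 2], [1, 7, 6]])
        base = fisher_exact(t).p
        assert fisher_exact(t[::-1]).p == pytest.approx(base, abs=1e-12)
        assert fisher_exact(t[:, ::-1]).p == pytest.approx(base, abs=1e-12)

    def test_ccl3l3_headline_table_is_highly_significant(self):
        res = fisher_exact(published_contingency("CCL3L3_null"))
        assert res.p <= 0.0001


class TestChiSquared:
    def test_proportional_rows_give_zero_statistic(self):
        stat, p, _ = chi_squared(np.array([[10, 20], [30, 60]]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_two_by_two_closed_form(self):
        t = np.array([[43, 295], [62, 265]])
        stat, _, _ = chi_squared(t)
        a, b, c, d = 43, 295, 62, 265
        n = a + b + c + d
        hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(hand, abs=1e-10)

    def test_low_expected_counts_flagged_not_switched(self):
        stat, p, warns = chi_squared(np.array([[1, 50], [3, 48]]))
        assert warns and np.isfinite(stat)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            chi_squared(np.array([[0, 5], [0, 7]]))


class TestOddsRatio:
    def test_published_c4b_value(self):
        res = odds_ratio(np.array([[43, 295], [62, 265]]))
        assert res.odds_ratio == pytest.approx(1.6051, abs=1e-4)
        assert not res.is_lower_bound
        assert res.ci95[0] < 1.6051 < res.ci95[1]

    def test_published_zero_cell_lower_bound(self):
        res = odds_ratio(np.array([[0, 338], [17, 310]]))
        assert res.odds_ratio == pytest.approx(18.5355, abs=1e-4)
        assert res.is_lower_bound
        assert res.ci95 is None

    def test_symmetric_table_gives_one(self):
        res = odds_ratio(np.array([[5, 5], [5, 5]]))
        assert res.odds_ratio == 1.0

    def test_haldane_policy_adds_half(self):
        res = odds_ratio(np.array([[0, 338], [17, 310]]), zero_cell_policy="haldane")
        assert res.odds_ratio == pytest.approx((17.5 * 338.5) / (310.5 * 0.5), abs=1e-9)

    def test_error_policy_raises(self):
        with pytest.raises(ValueError):
            odds_ratio(np.array([[0, 338], [17, 310]]), zero_cell_policy="error")

    def test_policy_has_no_effect_without_zero_cells(self):
        t = np.array([[5, 10], [8, 7]])
        a = odds_ratio(t, zero_cell_policy="substitute_one")
        b = odds_ratio(t, zero_cell_policy="haldane")
        assert a.odds_ratio == b.odds_ratio and not a.is_lower_bound


class TestWilcoxon:
    def test_identical_samples_not_significant(self):
        x = np.arange(10.0)
        _, p = wilcoxon_rank_sum(x, x)
        assert p >= 0.99

    def test_exact_enumeration_value(self):
        # fully separated samples of 3: the most extreme of C(6,3)=20
        # orderings in each direction -> two-sided p = 2/20 = 0.1
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_type_one_error_calibrated(self, rng):
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            x = rng.normal(size=120)
            y = rng.normal(size=120)
            _, p = wilcoxon_rank_sum(x, y)
            hits += p < 0.05
        assert 0.03 < hits / n_sim < 0.07


class TestBonferroni:
    def test_caps_at_one(self):
        assert bonferroni(0.5, 3) == 1.0

    def test_declared_family_size(self):
        assert bonferroni(0.0331, 11) == pytest.approx(0.3641, abs=1e-4)
        assert bonferroni(1e-5, 11) == pytest.approx(1.1e-4, abs=1e-9)

    def test_rejects_family_smaller_than_supplied(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)


class TestClinicalAssociation:
    def test_perfect_association_near_minimal_p(self, rng):
        status = pd.Series(np.r_[np.ones(15, bool), np.zeros(45, bool)],
                           index=[f"s{i}" for i in range(60)])
        flags = pd.DataFrame({"alopecia": status.to_numpy()}, index=status.index)
        out = clinical_association(status, flags)
        # minimum achievable for these margins
        assert out.loc[0, "p"] == pytest.approx(1 / comb(60, 15), rel=1e-6)

    def test_constant_variable_skipped_with_warning(self):
        status = pd.Series([True, False, True], index=list("abc"))
        flags = pd.DataFrame({"always": [1, 1, 1]}, index=list("abc"))
        with pytest.warns(UserWarning, match="skipped"):
            out = clinical_association(status, flags)
        assert out.empty

    def test_independent_variable_has_uniform_p(self, rng):
        # under the null, exact-test p-values are stochastically >= uniform;
        # check calibration via the rejection rate at alpha = 0.2
        n_sim, hits = 300, 0
        idx = [f"s{i}" for i in range(80)]
        for _ in range(n_sim):
            status = pd.Series(rng.random(80) < 0.3, index=idx)
            flags = pd.DataFrame({"v": rng.random(80) < 0.4}, index=idx)
            if status.nunique() < 2 or flags["v"].nunique() < 2:
                continue
            out = clinical_association(status, flags)
            hits += out.loc[0, "p"] < 0.2
        assert hits / n_sim < 0.25  # conservative, never anti-conservative
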