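import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from emuflux.expression import (
    ExpressionTable,
    classify_de,
    classify_fold_cutoff,
    gene_set_shift_test,
    mann_whitney_one_sided,
    normalize_signals,
    set_summary,
    volcano_table,
)


def brute_force_one_sided_p(a, b):
    """Independent oracle: enumerate all group reassignments of the pooled
    values and count, via pairwise comparisons (ties count one half), how
    often the U statistic of the second group reaches the observed one."""
    def u_stat(x, y):
        return sum(1.0 if yj > xi else 0.5 if yj == xi else 0.0
                   for xi in x for yj in y)

    pooled = list(a) + list(b)
    u_obs = u_stat(a, b)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), len(b)):
        grp_b = [pooled[i] for i in comb]
        grp_a = [pooled[i] for i in range(len(pooled)) if i not in set(comb)]
        hits += u_stat(grp_a, grp_b) >= u_obs - 1e-12
        total += 1
    return hits / total


def small_table():
    signals = pd.DataFrame(
        {"a_1": [1.0, 3.0, 10.0], "a_2": [2.0, 2.0, 11.0],
         "b_1": [4.0, 1.0, 10.0], "b_2": [5.0, 2.0, 12.0]},
        index=["g1", "g2", "g3"])
    conditions = {"a_1": "a", "a_2": "a", "b_1": "b", "b_2": "b"}
    return ExpressionTable(signals, conditions,
                           {"cmp": {"g1", "g2"}, "abrb": {"g2", "g3"}})


class TestNormalization:
    def test_two_gene_sample_scales_to_mean_500(self):
        table = ExpressionTable(pd.DataFrame({"s": [1.0, 3.0]}), {"s": "a"})
        out = normalize_signals(table)
        np.testing.assert_allclose(out.signals["s"], [250.0, 750.0])

    def test_sample_already_at_target_unchanged(self):
        table = ExpressionTable(pd.DataFrame({"s": [400.0, 600.0]}), {"s": "a"})
        out = normalize_signals(table)
        np.testing.assert_allclose(out.signals["s"], [400.0, 600.0])

    def test_every_sample_mean_exactly_500(self):
        rng = np.random.default_rng(0)
        signals = pd.DataFrame(rng.lognormal(5, 1, (100, 6)),
                               columns=[f"s{i}" for i in range(6)])
        table = ExpressionTable(signals, {f"s{i}": "a" for i in range(6)})
        out = normalize_signals(table)
        np.testing.assert_array_equal(out.signals.mean(axis=0).round(9),
                                      np.full(6, 500.0))

    def test_within_sample_ratios_preserved(self):
        table = ExpressionTable(pd.DataFrame({"s": [2.0, 8.0, 40.0]}),
                                {"s": "a"})
        out = normalize_signals(table)
        ratios = out.signals["s"].to_numpy()
        np.testing.assert_allclose(ratios[1:] / ratios[:-1], [4.0, 5.0])

    def test_all_zero_sample_rejected(self):
        table = ExpressionTable(pd.DataFrame({"s": [0.0, 0.0]}), {"s": "a"})
        with pytest.raises(ValueError, match="all-zero"):
            normalize_signals(table)


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        # all C(6,3)=20 assignments; only one reaches the maximal U
        assert mann_whitney_one_sided([1, 2, 3], [4, 5, 6]) == pytest.approx(
            1 / 20)

    def test_identical_groups_inclusive_convention(self):
        # with the inclusive tail P(U >= u_obs) and full ties, every
        # reassignment reaches the observed midpoint statistic
        p = mann_whitney_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(brute_force_one_sided_p(
            [1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert p > 0.5

    def test_direction_flip(self):
        p_greater = mann_whitney_one_sided([4, 5, 6], [1, 2, 3], "greater")
        p_less = mann_whitney_one_sided([4, 5, 6], [1, 2, 3], "less")
        assert p_less == pytest.approx(1 / 20)
        assert p_greater > 0.9

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.normal(size=rng.integers(3, 8))
            b = rng.normal(size=rng.integers(3, 8))
            ours = mann_whitney_one_sided(a, b)
            ref = mannwhitneyu(b, a, alternative="greater",
                               method="exact").pvalue
            assert ours == pytest.approx(float(ref), abs=1e-12)

    def test_asymptotic_close_to_exact_at_moderate_n(self):
        # exact enumeration at m = n = 9 (just above the exact cutoff
        # would be m+n=18; force comparability via the oracle)
        rng = np.random.default_rng(8)
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        exact = mann_whitney_one_sided(a, b)
        approx = float(mannwhitneyu(b, a, alternative="greater",
                                    method="asymptotic").pvalue)
        assert abs(exact - approx) < 0.01

    @given(st.lists(st.integers(0, 5), min_size=1, max_size=6),
           st.lists(st.integers(0, 5), min_size=1, max_size=6))
    @settings(deadline=None, max_examples=60)
    def test_exact_p_equals_brute_force(self, a, b):
        assert mann_whitney_one_sided(a, b) == pytest.approx(
            brute_force_one_sided_p(a, b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_sided([], [1.0])


class TestDEClassification:
    @pytest.mark.parametrize("log2fc,p,expected", [
        (1.2, 0.01, "up"),
        (-1.5, 0.04, "down"),
        (0.5, 0.001, "ns"),   # below the fold-change cutoff
        (2.0, 0.20, "ns"),    # not significant
        (1.0, 0.049, "up"),   # boundary: >= 1 is inclusive
        (-1.0, 0.049, "down"),
    ])
    def test_volcano_rule(self, log2fc, p, expected):
        assert classify_de(log2fc, p) == expected

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_de(float("nan"), 0.01)

    @pytest.mark.parametrize("fc,expected", [
        (1.6, "up"), (1.5, "up"), (1.0, "ns"), (0.7, "ns"),
        (0.6, "down"),  # 0.6 < 1/1.5
    ])
    def test_fold_cutoff_rule(self, fc, expected):
        assert classify_fold_cutoff(fc) == expected

    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(ValueError):
            classify_fold_cutoff(0.0)

    def test_classification_is_normalization_invariant(self):
        # scaling both conditions by a common factor leaves FC and p alone
        rng = np.random.default_rng(1)
        base = pd.DataFrame(rng.lognormal(5, 0.4, (20, 6)),
                            columns=[f"{c}_{r}" for c in "ab" for r in range(3)])
        conds = {c: c.split("_")[0] for c in base.columns}
        t1 = ExpressionTable(base, conds)
        t2 = ExpressionTable(base * 3.7, conds)
        r1 = volcano_table(t1, "a", "b", pseudo=0.0)
        r2 = volcano_table(t2, "a", "b", pseudo=0.0)
        assert [r.de_class for r in r1] == [r.de_class for r in r2]
        np.testing.assert_allclose([r.log2_fc for r in r1],
                                   [r.log2_fc for r in r2], atol=1e-12)


class TestSetSummary:
    def make_table(self, values_a, values_b, set_id="myset"):
        genes = [f"g{i}" for i in range(len(values_a))]
        signals = pd.DataFrame({
            "a_1": values_a, "a_2": values_a,
            "b_1": values_b, "b_2": values_b}, index=genes)
        conds = {c: c.split("_")[0] for c in signals.columns}
        return ExpressionTable(signals, conds, {set_id: set(genes)})

    def test_quartiles_match_hand_computation(self):
        # log2 signals 1..5 -> Q1 2, median 3, Q3 4 (linear interpolation)
        table = self.make_table([2.0, 4.0, 8.0, 16.0, 32.0],
                                [2.0, 4.0, 8.0, 16.0, 32.0])
        out = set_summary(table, "myset", "a", "b", pseudo=0.0)
        assert out["box_a"] == {"min": 1.0, "q1": 2.0, "median": 3.0,
                                "q3": 4.0, "max": 5.0}

    def test_constant_set_zero_width_box(self):
        table = self.make_table([8.0] * 4, [8.0] * 4)
        box = set_summary(table, "myset", "a", "b", pseudo=0.0)["box_a"]
        assert box["min"] == box["max"] == box["median"] == 3.0

    def test_uniform_doubling_detected(self):
        rng = np.random.default_rng(2)
        a = rng.lognormal(5, 0.5, 50)
        table = self.make_table(list(a), list(2.0 * a))
        out = set_summary(table, "myset", "a", "b", direction="greater",
                          pseudo=0.0)
        assert out["mann_whitney_p"] < 0.05
        assert out["median_shift"] == pytest.approx(1.0, abs=1e-9)

    def test_exclusion_rule_removes_dual_members(self):
        table = small_table()
        # g2 is in both 'cmp' and 'abrb' and must count for neither
        assert table.set_members("cmp") == ["g1"]
        assert table.set_members("abrb") == ["g3"]
        assert table.excluded_genes() == {"g2"}

    def test_empty_set_after_exclusion_raises(self):
        signals = pd.DataFrame({"a_1": [1.0], "a_2": [1.0],
                                "b_1": [1.0], "b_2": [1.0]}, index=["g1"])
        conds = {c: c.split("_")[0] for c in signals.columns}
        table = ExpressionTable(signals, conds,
                                {"cmp": {"g1"}, "abrb": {"g1"}})
        with pytest.raises(ValueError, match="empty"):
            set_summary(table, "cmp", "a", "b")


def test_gene_set_shift_test_directionality():
    low = [1.0, 1.2, 0.9, 1.1]
    high = [2.0, 2.2, 1.9, 2.1]
    assert gene_set_shift_test(low, high, "greater") < 0.05
    assert gene_set_shift_test(low, high, "less") > 0.9
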