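"""Category rank-shift enrichment: Mann-Whitney, BH FDR, classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from burdenkit import (
    CategoryMap,
    FoldChangeTable,
    UndefinedRatioError,
    ValidationError,
    between_condition_test,
    bh_fdr,
    category_shift_test,
    classify_response,
    condition_correlation,
    mann_whitney,
    partitioned_test,
    read_gmt,
)


def mw_enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney p via rank sums over all labelings.

    Independent of the implementation: works from the rank-sum statistic
    W of the first sample and enumerates every C(n, n_x) assignment.
    """
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n, n_x = pooled.size, len(x)
    mu_w = n_x * (n + 1) / 2.0
    obs = abs(ranks[:n_x].sum() - mu_w)
    hits = total = 0
    for combo in itertools.combinations(range(n), n_x):
        w = sum(ranks[i] for i in combo)
        if abs(w - mu_w) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def make_table(genes, **cond_values):
    """Build a FoldChangeTable; cond_values maps condition -> (fc, fdr) arrays."""
    data = {"gene_id": genes, "log10cpm": np.full(len(genes), 2.0)}
    for cond, (fc, fdr) in cond_values.items():
        data[f"log2fc_{cond}"] = fc
        data[f"fdr_{cond}"] = fdr
    return FoldChangeTable(pd.DataFrame(data))


class TestMannWhitney:
    def test_identical_multisets_symmetric(self):
        x = [1.0, 2.0, 3.0]
        u, p = mann_whitney(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_samples_exact_p(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 7.0])
        assert u == 0.0
        assert p == pytest.approx(2.0 / 35.0)

    @settings(deadline=None, max_examples=60)
    @given(
        n_x=st.integers(min_value=1, max_value=6),
        n_y=st.integers(min_value=1, max_value=6),
        data=st.data(),
    )
    def test_exact_path_matches_enumeration_oracle(self, n_x, n_y, data):
        # small integer values force ties often
        values = data.draw(
            st.lists(
                st.integers(min_value=0, max_value=4),
                min_size=n_x + n_y,
                max_size=n_x + n_y,
            )
        )
        x = np.asarray(values[:n_x], float)
        y = np.asarray(values[n_x:], float)
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(mw_enumeration_oracle(x, y), abs=1e-12)

    def test_large_sample_matches_scipy_asymptotic(self, rng):
        from scipy.stats import mannwhitneyu

        x = rng.normal(0.3, 1, 40)
        y = rng.normal(0.0, 1, 200)
        _, p = mann_whitney(x, y)
        ref = mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        ).pvalue
        assert p == pytest.approx(float(ref), rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.05]) == pytest.approx([0.05])

    def test_hand_computed_step_up(self):
        # p=(0.01,0.02,0.03,0.04), m=4: q_i = min over j>=i of p_j*4/j = 0.04
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        q = bh_fdr(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, ref, atol=1e-12)
        q_by = bh_fdr(p, by=True)
        ref_by = multipletests(p, method="fdr_by")[1]
        assert np.allclose(q_by, ref_by, atol=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(
        p=st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_permutation_invariance(self, p, seed):
        perm = np.random.default_rng(seed).permutation(len(p))
        q = bh_fdr(p)
        q_perm = bh_fdr(np.asarray(p)[perm])
        assert np.allclose(q_perm, q[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


class TestReadGMT:
    def test_two_sets_parsed_and_members_deduplicated(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text(
            "A\tdesc\tg1\tg2\tg3\n"
            "B\tdesc\t" + "\t".join(f"x{i}" for i in range(12)) + "\tx0\n"
        )
        cats = read_gmt(path)
        assert len(cats) == 2
        assert len(cats.sets["A"]) == 3
        assert len(cats.sets["B"]) == 12  # repeated x0 counted once

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("A\tdesc\tg1\nonlyonefield\n")
        with pytest.raises(ValidationError, match="line 2"):
            read_gmt(path)

    def test_duplicate_names_rejected_and_empty_skipped(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("A\td\tg1\nA\td\tg2\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_gmt(path)
        path2 = tmp_path / "empty.gmt"
        path2.write_text("A\td\tg1\nB\td\n")
        with pytest.warns(UserWarning, match="no members"):
            cats = read_gmt(path2)
        assert list(cats.sets) == ["A"]


class TestCategoryShiftTest:
    def test_small_category_fully_below_background(self):
        genes = [f"g{i}" for i in range(7)]
        fc = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        table = make_table(genes, c=(fc, np.ones(7)))
        cats = CategoryMap({"low": genes[:3], "rest": genes[3:]})
        results = category_shift_test(table, cats, "c", min_size=3)
        low = next(r for r in results if r.category_id == "low")
        assert low.u_statistic == 0.0
        assert low.p_value == pytest.approx(2.0 / 35.0)
        assert low.direction == -1

    def test_category_identical_to_background_not_significant(self, rng):
        genes = [f"g{i}" for i in range(60)]
        fc = np.tile(rng.normal(size=20), 3)
        table = make_table(genes, c=(fc, np.ones(60)))
        cats = CategoryMap({"a": genes[:20], "b": genes[20:40], "z": genes[40:]})
        results = category_shift_test(table, cats, "c", min_size=11)
        a = next(r for r in results if r.category_id == "a")
        # in-category multiset equals each background category's multiset
        assert a.p_value > 0.5

    def test_min_size_counted_after_table_intersection(self):
        genes = [f"g{i}" for i in range(30)]
        table = make_table(genes, c=(np.zeros(30), np.ones(30)))
        cats = CategoryMap(
            {"small": genes[:10] + ["absent1", "absent2"], "big": genes[10:30]}
        )
        results = category_shift_test(table, cats, "c", min_size=11)
        assert {r.category_id for r in results} == {"big"}

    def test_absent_condition_rejected(self):
        table = make_table(["g1", "g2"], c=(np.zeros(2), np.ones(2)))
        cats = CategoryMap({"a": ["g1", "g2"]})
        with pytest.raises(ValidationError, match="condition"):
            category_shift_test(table, cats, "nope")

    def test_background_excludes_unassigned_genes_by_default(self):
        # adding unassigned genes must not change the assigned-universe test
        genes = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(0)
        fc = rng.normal(size=40)
        table = make_table(genes, c=(fc, np.ones(40)))
        cats = CategoryMap({"a": genes[:15], "b": genes[15:30]})
        base = category_shift_test(table, cats, "c", min_size=11)

        extra_genes = genes + [f"u{i}" for i in range(25)]
        extra_fc = np.concatenate([fc, rng.normal(5.0, 1.0, 25)])
        bigger = make_table(extra_genes, c=(extra_fc, np.ones(65)))
        same = category_shift_test(bigger, cats, "c", min_size=11)
        for r0, r1 in zip(base, same):
            assert r0.category_id == r1.category_id
            assert r0.p_value == pytest.approx(r1.p_value, abs=1e-12)

        # with the full-table background the unassigned genes do matter
        changed = category_shift_test(
            bigger, cats, "c", min_size=11, assigned_only_background=False
        )
        assert any(
            c.p_value != pytest.approx(b.p_value, abs=1e-9)
            for b, c in zip(base, changed)
        )

    def test_gene_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(40)]
        fc = rng.normal(size=40)
        table = make_table(genes, c=(fc, np.ones(40)))
        cats = CategoryMap({"a": genes[:15], "b": genes[15:]})
        base = category_shift_test(table, cats, "c", min_size=11)

        renamed = {g: f"YAL{i:03d}W" for i, g in enumerate(genes)}
        table2 = make_table([renamed[g] for g in genes], c=(fc, np.ones(40)))
        cats2 = CategoryMap(
            {k: {renamed[g] for g in v} for k, v in cats.sets.items()}
        )
        other = category_shift_test(table2, cats2, "c", min_size=11)
        for r0, r1 in zip(base, other):
            assert r0.p_value == pytest.approx(r1.p_value, abs=1e-12)
            assert r0.u_statistic == pytest.approx(r1.u_statistic, abs=1e-9)


class TestBetweenConditionTest:
    def test_identical_conditions_give_p_one(self):
        genes = [f"g{i}" for i in range(15)]
        fc = np.arange(15.0)
        table = make_table(genes, a=(fc, np.ones(15)), b=(fc, np.ones(15)))
        cats = CategoryMap({"all": genes})
        results = between_condition_test(table, cats, "a", "b")
        assert results[0].p_value == pytest.approx(1.0)

    def test_fully_separated_conditions_match_oracle(self):
        genes = [f"g{i}" for i in range(11)]
        a = np.zeros(11)
        b = a + 1.0
        table = make_table(genes, a=(a, np.ones(11)), b=(b, np.ones(11)))
        cats = CategoryMap({"all": genes})
        results = between_condition_test(table, cats, "a", "b")
        from scipy.stats import mannwhitneyu

        ref = mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        ).pvalue
        assert results[0].p_value == pytest.approx(float(ref), rel=1e-9)
        assert results[0].direction == -1


class TestPartitionedTest:
    def _table_and_cats(self, rng, n=80):
        genes = [f"g{i}" for i in range(n)]
        fc = rng.normal(size=n)
        table = make_table(genes, c=(fc, np.ones(n)))
        cats = CategoryMap({"a": genes[: n // 2], "b": genes[n // 2 :]})
        return genes, table, cats

    def test_full_partition_equals_unpartitioned(self, rng):
        genes, table, cats = self._table_and_cats(rng)
        strat = partitioned_test(table, cats, set(genes), "c")
        base = category_shift_test(table, cats, "c")
        assert strat["complement"] == []
        assert [r.p_value for r in strat["partition"]] == pytest.approx(
            [r.p_value for r in base]
        )

    def test_empty_partition_tests_only_complement(self, rng):
        genes, table, cats = self._table_and_cats(rng)
        strat = partitioned_test(table, cats, set(), "c")
        assert strat["partition"] == []
        assert len(strat["complement"]) == 2

    def test_stratum_counts_reported(self, rng):
        genes, table, cats = self._table_and_cats(rng)
        # stratum holds 30 of category a's 40 members and 20 of b's 40
        partition = set(genes[:30]) | set(genes[40:60])
        strat = partitioned_test(table, cats, partition, "c")
        in_part = {r.category_id: r for r in strat["partition"]}
        assert in_part["a"].extra["n_stratum_of_total"] == "30/40"
        assert in_part["b"].extra["n_stratum_of_total"] == "20/40"
        assert all(r.extra["stratum"] == "partition" for r in strat["partition"])


class TestClassifyResponse:
    @pytest.mark.parametrize(
        "fc_a,fdr_a,fc_b,fdr_b,expected",
        [
            (2.0, 1.0, 1.0, 1.0, "ns"),
            (2.0, 0.01, 1.0, 0.01, "common_up"),
            (-2.0, 0.01, -1.0, 0.01, "common_down"),
            (2.0, 0.01, -1.0, 0.01, "opposite"),
            (2.0, 0.01, 1.0, 0.5, "a_specific"),
            (2.0, 0.5, 1.0, 0.01, "b_specific"),
        ],
    )
    def test_rule_application(self, fc_a, fdr_a, fc_b, fdr_b, expected):
        table = make_table(
            ["g1"], a=(np.array([fc_a]), np.array([fdr_a])), b=(np.array([fc_b]), np.array([fdr_b]))
        )
        labels = classify_response(table, "a", "b")
        assert labels.loc["g1"] == expected


class TestConditionCorrelation:
    def test_perfect_and_anti_correlation(self, rng):
        fc = rng.normal(size=10)
        table = make_table(
            [f"g{i}" for i in range(10)],
            a=(fc, np.ones(10)),
            b=(fc.copy(), np.ones(10)),
            c=(-fc, np.ones(10)),
        )
        assert condition_correlation(table, "a", "b") == pytest.approx(1.0)
        assert condition_correlation(table, "a", "c") == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self, rng):
        a = rng.normal(size=50)
        b = 0.6 * a + rng.normal(size=50)
        table = make_table(
            [f"g{i}" for i in range(50)], a=(a, np.ones(50)), b=(b, np.ones(50))
        )
        r = condition_correlation(table, "a", "b")
        # independent oracle: covariance formula
        expected = float(
            np.sum((a - a.mean()) * (b - b.mean()))
            / np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_undefined(self):
        table = make_table(
            ["g1", "g2", "g3"],
            a=(np.zeros(3), np.ones(3)),
            b=(np.arange(3.0), np.ones(3)),
        )
        with pytest.raises(UndefinedRatioError):
            condition_correlation(table, "a", "b")
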