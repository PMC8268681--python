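import numpy as np
import pandas as pd
import pytest

from isoswitch.switching import (
    AbundanceMatrix,
    bh_adjust,
    call_switch_pairs,
    delta_if,
    filter_low_expression,
    gene_switch_qvalue,
    isoform_fractions,
    per_sample_switch_calls,
    permutation_test_dtu,
)


def matrix(rows, samples, groups, tx2gene):
    values = pd.DataFrame(rows, columns=samples, index=list(tx2gene))
    return AbundanceMatrix(values, pd.Series(tx2gene), pd.Series(groups, index=samples))


class TestFilter:
    def test_zero_thresholds_identity(self, toy_abundance):
        out = filter_low_expression(toy_abundance, 0.0, 0.0)
        pd.testing.assert_frame_equal(out.values, toy_abundance.values)

    def test_mean_threshold(self):
        values = pd.DataFrame(
            [[0.1, 0.1], [5.0, 5.0], [20.0, 20.0]],
            index=["t1", "t2", "t3"], columns=["s1", "s2"],
        )
        m = AbundanceMatrix(
            values,
            pd.Series({"t1": "G1", "t2": "G2", "t3": "G2"}),
            pd.Series({"s1": "A", "s2": "B"}),
        )
        out = filter_low_expression(m, min_mean_abundance=1.0)
        assert list(out.values.index) == ["t2", "t3"]

    def test_gene_with_all_isoforms_failing_absent(self):
        values = pd.DataFrame(
            [[0.1, 0.1], [0.2, 0.2], [20.0, 20.0]],
            index=["t1", "t2", "t3"], columns=["s1", "s2"],
        )
        m = AbundanceMatrix(
            values,
            pd.Series({"t1": "G1", "t2": "G1", "t3": "G2"}),
            pd.Series({"s1": "A", "s2": "B"}),
        )
        out = filter_low_expression(m, min_mean_abundance=1.0)
        assert set(out.tx2gene) == {"G2"}

    def test_negative_threshold_rejected(self, toy_abundance):
        with pytest.raises(ValueError):
            filter_low_expression(toy_abundance, -1.0)

    def test_empty_result_is_error(self, toy_abundance):
        with pytest.raises(ValueError, match="no transcripts survive"):
            filter_low_expression(toy_abundance, 1e9)


class TestFractions:
    def test_normalization(self, toy_abundance):
        f = isoform_fractions(toy_abundance, eps=1.0)
        col = f.fractions["s0"]
        assert col["a1"] == pytest.approx(0.3) and col["a2"] == pytest.approx(0.7)
        assert col["b1"] == pytest.approx(1.0)

    def test_zero_gene_expression_gives_missing(self):
        m = matrix(
            [[0.0, 30.0], [0.0, 70.0]],
            ["s1", "s2"],
            ["A", "B"],
            {"t1": "G", "t2": "G"},
        )
        f = isoform_fractions(m, eps=1.0)
        assert f.fractions["s1"].isna().all()
        assert f.fractions["s2"].tolist() == pytest.approx([0.3, 0.7])

    def test_conservation_per_gene_sample(self, small_cohort):
        f = isoform_fractions(small_cohort["abundance"], eps=1.0)
        sums = f.fractions.groupby(f.tx2gene).sum(min_count=1)
        sums = sums.to_numpy()
        ok = np.isnan(sums) | (np.abs(sums - 1.0) < 1e-9)
        assert ok.all()


class TestDeltaIF:
    def test_arithmetic_and_antisymmetry(self, toy_abundance):
        f = isoform_fractions(toy_abundance, eps=1.0)
        d = delta_if(f, ("A", "B"))
        assert d.loc["a1", "dIF"] == pytest.approx(0.4)
        assert d.loc["a2", "dIF"] == pytest.approx(-0.4)
        assert d.loc["b1", "dIF"] == pytest.approx(0.0)
        # per-gene sum of dIF vanishes with complete data
        assert d.groupby("gene_id")["dIF"].sum().abs().max() < 1e-9

    def test_group_swap_negates(self, toy_abundance):
        f = isoform_fractions(toy_abundance, eps=1.0)
        d_ab = delta_if(f, ("A", "B"))["dIF"]
        d_ba = delta_if(f, ("B", "A"))["dIF"]
        pd.testing.assert_series_equal(d_ab, -d_ba)

    def test_gene_dif_sum_zero_on_cohort(self, small_cohort):
        f = isoform_fractions(small_cohort["abundance"], eps=1.0)
        d = delta_if(f, ("nevus", "melanoma"))
        complete = f.fractions.notna().all(axis=1)
        sums = d[complete].groupby("gene_id")["dIF"].sum()
        # only genes whose isoforms are all complete and testable
        full = d[complete].groupby("gene_id")["testable"].all()
        assert sums[full].abs().max() < 1e-9


class TestPermutationTest:
    def test_constant_isoform_p_is_one(self):
        rows = [[0.5] * 10, [0.5] * 10]
        m = matrix(rows, [f"s{i}" for i in range(10)], ["A"] * 5 + ["B"] * 5,
                   {"t1": "G", "t2": "G"})
        f = isoform_fractions(m, eps=0.1)
        p = permutation_test_dtu(f, ("A", "B"), n_perm=199, seed=5)
        assert (p == 1.0).all()

    def test_planted_switch_is_significant(self):
        rng = np.random.default_rng(42)
        n = 10
        fa = np.clip(rng.normal(0.2, 0.05, n), 0, 1)
        fb = np.clip(rng.normal(0.7, 0.05, n), 0, 1)
        top = np.concatenate([fa, fb])
        vals = np.vstack([top, 1 - top]) * 100.0
        m = matrix(vals, [f"s{i}" for i in range(2 * n)],
                   ["A"] * n + ["B"] * n, {"t1": "G", "t2": "G"})
        f = isoform_fractions(m, eps=0.1)
        p = permutation_test_dtu(f, ("A", "B"), n_perm=999, seed=7)
        assert p["t1"] <= 0.01 and p["t2"] <= 0.01

    def test_swap_leaves_p_unchanged(self, small_cohort):
        f = isoform_fractions(small_cohort["abundance"], eps=1.0)
        p1 = permutation_test_dtu(f, ("nevus", "melanoma"), n_perm=199, seed=3)
        p2 = permutation_test_dtu(f, ("melanoma", "nevus"), n_perm=199, seed=3)
        pd.testing.assert_series_equal(p1, p2)

    def test_small_n_perm_rejected(self, small_cohort):
        f = isoform_fractions(small_cohort["abundance"], eps=1.0)
        with pytest.raises(ValueError):
            permutation_test_dtu(f, ("nevus", "melanoma"), n_perm=10, seed=1)


class TestBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.03], [0.03]),
        ],
    )
    def test_examples(self, p, expected):
        assert bh_adjust(p).tolist() == pytest.approx(expected)

    def test_nan_passthrough_and_monotonicity(self):
        p = pd.Series([0.001, np.nan, 0.04, 0.9])
        q = bh_adjust(p)
        assert np.isnan(q[1])
        assert (q.dropna() >= p.dropna() - 1e-12).all()


class TestPairCalling:
    def test_single_pair(self):
        dif = pd.Series({"t1": 0.3, "t2": -0.3})
        q = pd.Series({"t1": 0.001, "t2": 0.2})
        pairs = call_switch_pairs(dif, q, pd.Series({"t1": "G", "t2": "G"}), 0.1, 0.05)
        assert len(pairs) == 1
        sp = pairs[0]
        assert (sp.up_isoform, sp.down_isoform) == ("t1", "t2")

    def test_no_pair_when_q_high(self):
        dif = pd.Series({"t1": 0.3, "t2": -0.3})
        q = pd.Series({"t1": 0.4, "t2": 0.2})
        assert call_switch_pairs(dif, q, pd.Series({"t1": "G", "t2": "G"})) == []

    def test_small_dif_member_excluded(self):
        dif = pd.Series({"t1": 0.3, "t2": -0.2, "t3": -0.05})
        q = pd.Series({"t1": 0.01, "t2": 0.01, "t3": 0.01})
        tx2gene = pd.Series({"t1": "G", "t2": "G", "t3": "G"})
        pairs = call_switch_pairs(dif, q, tx2gene, 0.1, 0.05)
        assert [(p.up_isoform, p.down_isoform) for p in pairs] == [("t1", "t2")]

    def test_input_order_invariance(self):
        dif = pd.Series({"t1": 0.3, "t2": -0.2, "t3": -0.15, "t4": 0.12})
        q = pd.Series({"t1": 0.01, "t2": 0.03, "t3": 0.2, "t4": 0.04})
        tx2gene = pd.Series({t: "G" for t in dif.index})
        ref = call_switch_pairs(dif, q, tx2gene, p=q)
        perm = ["t3", "t1", "t4", "t2"]
        shuffled = call_switch_pairs(dif[perm], q[perm], tx2gene[perm], p=q[perm])
        assert shuffled == ref


class TestGeneQ:
    def test_singleton_gene(self):
        p = pd.Series({"t1": 0.01})
        pairs, table = gene_switch_qvalue([], p, pd.Series({"t1": "G"}))
        assert table.loc["G", "gene_p"] == pytest.approx(0.01)
        assert table.loc["G", "gene_q"] == pytest.approx(0.01)

    def test_bonferroni_scaling(self):
        p = pd.Series({f"t{i}": x for i, x in enumerate([0.002, 0.5, 0.8, 0.9])})
        _, table = gene_switch_qvalue([], p, pd.Series({f"t{i}": "G" for i in range(4)}))
        assert table.loc["G", "gene_p"] == pytest.approx(0.008)


class TestPerSampleCalls:
    def _fit_pairs(self, toy_abundance):
        from isoswitch.model import IsoformSwitchModel

        return IsoformSwitchModel(
            toy_abundance, ("A", "B"), seed=1, n_perm=199, min_mean_abundance=0.0
        ).fit()

    def test_call_rules(self, toy_abundance):
        res = self._fit_pairs(toy_abundance)
        calls = res.per_sample_calls(tau_switch=0.1)
        # every B sample deviates by +0.4 for a1 (up) and -0.4 for a2 (down)
        assert calls.loc["a1"].all() and calls.loc["a2"].all()

    def test_sample_at_reference_mean_not_called(self):
        samples = [f"s{i}" for i in range(16)]
        groups = pd.Series(["A"] * 8 + ["B"] * 8, index=samples)
        vals = pd.DataFrame(
            {s: ([20.0, 80.0] if g == "A" or s == "s8" else [80.0, 20.0])
             for s, g in groups.items()},
            index=["t1", "t2"],
        )
        m = AbundanceMatrix(vals, pd.Series({"t1": "G", "t2": "G"}), groups)
        from isoswitch.model import IsoformSwitchModel

        res = IsoformSwitchModel(m, ("A", "B"), seed=2, n_perm=199).fit()
        calls = res.per_sample_calls(tau_switch=0.1)
        assert not calls.loc["t1", "s8"]  # equal to group-A mean
        assert calls.loc["t1", [f"s{i}" for i in range(9, 16)]].all()
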