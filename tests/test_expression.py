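"""Unordered-pair ratio statistics, DE, sex calling, similarity."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twinconcord.expression import (
    PairRatioTransformer,
    PairedExpressionMatrix,
    call_sex_by_xist,
    count_exceedance,
    differential_expression,
    group_similarity,
    pair_ratio,
    rank_for_gsea,
    ratio_table,
)

from conftest import make_matrix


class TestPairRatio:
    @pytest.mark.parametrize("a, b, expected", [(10, 5, 2.0), (5, 10, 2.0), (7, 7, 1.0), (0.3, 0.3, 1.0)])
    def test_examples_and_symmetry(self, a, b, expected):
        assert pair_ratio(a, b) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.floats(0.001, 1e6), st.floats(0.001, 1e6))
    def test_symmetric_and_at_least_one(self, a, b):
        r = pair_ratio(a, b)
        assert r >= 1.0
        assert r == pair_ratio(b, a)

    def test_double_zero_without_pseudocount_signalled(self):
        with pytest.raises(ValueError, match="undefined"):
            pair_ratio(0.0, 0.0)
        assert pair_ratio(0.0, 0.0, eps=1.0) == 1.0


def two_pair_matrix(gene_rows):
    """4 samples in 2 pairs; gene_rows maps gene -> 4 values."""
    genes = list(gene_rows)
    values = [gene_rows[g] for g in genes]
    return make_matrix(
        values,
        genes,
        ["p1a", "p1b", "p2a", "p2b"],
        {"p1a": "P1", "p1b": "P1", "p2a": "P2", "p2b": "P2"},
    )


class TestRatioTable:
    def test_hand_computed_two_pair_example(self):
        # gene with pair ratios {2, 4}: mean 3, sd sqrt(2), cv sqrt(2)/3
        mat = two_pair_matrix({"g1": [2, 1, 4, 1], "flat": [5, 5, 5, 5]})
        out = ratio_table(mat)
        assert out.loc["g1", "mean_ratio"] == pytest.approx(3.0)
        assert out.loc["g1", "sd_ratio"] == pytest.approx(np.sqrt(2), rel=1e-12)
        assert out.loc["g1", "cv"] == pytest.approx(np.sqrt(2) / 3, rel=1e-12)
        assert out.loc["flat"].tolist() == [1.0, 0.0, 0.0]

    def test_member_swap_leaves_statistics_unchanged(self):
        mat = two_pair_matrix({"g1": [2, 1, 4, 1], "g2": [3, 9, 1, 7]})
        swapped = two_pair_matrix({"g1": [1, 2, 1, 4], "g2": [9, 3, 7, 1]})
        pd.testing.assert_frame_equal(ratio_table(mat), ratio_table(swapped))

    def test_all_mean_ratios_at_least_one(self, study):
        out = ratio_table(study.expression)
        assert (out["mean_ratio"] >= 1.0).all()
        assert (out["cv"] >= 0.0).all()

    def test_housekeeping_quieter_than_epi_program(self, study):
        """Generator contract: the housekeeping panel shows smaller mean
        ratios and CVs than the epiblast-program genes."""
        out = ratio_table(study.expression)
        hk = [g for g in ("Actb", "Gapdh", "Hprt", "Ppia", "Ubc") if g in out.index]
        epi = [g for g in out.index if g.startswith("EpiProg") or g == "Nanog"]
        assert out.loc[hk, "mean_ratio"].mean() < out.loc[epi, "mean_ratio"].mean()
        assert out.loc[hk, "cv"].mean() < out.loc[epi, "cv"].mean()

    def test_transformer_wraps_table(self, study):
        tr = PairRatioTransformer().fit(study.expression)
        pd.testing.assert_frame_equal(tr.ratio_stats_, ratio_table(study.expression))
        pd.testing.assert_frame_equal(tr.transform(study.expression), ratio_table(study.expression))
        assert tr.n_pairs_ == len(study.expression.pairs)
        counts = tr.exceedance([2, 5, 10])
        assert counts[2.0] >= counts[5.0] >= counts[10.0]


class TestExceedance:
    def test_toy_counts(self):
        stats = pd.DataFrame({"mean_ratio": [1.5, 6.0, 12.0]}, index=["a", "b", "c"])
        assert count_exceedance(stats, [2, 5, 10]) == {2.0: 2, 5.0: 2, 10.0: 1}

    def test_empty_stats_give_zeros(self):
        stats = pd.DataFrame({"mean_ratio": []})
        assert count_exceedance(stats, [2, 5, 10]) == {2.0: 0, 5.0: 0, 10.0: 0}

    def test_strictly_greater_at_boundary(self):
        stats = pd.DataFrame({"mean_ratio": [2.0]}, index=["a"])
        assert count_exceedance(stats, [2])[2.0] == 0


class TestRanking:
    def test_high_cv_first_with_deterministic_ties(self):
        stats = pd.DataFrame(
            {"mean_ratio": [3.0, 1.2, 2.0], "sd_ratio": [0, 0, 0], "cv": [0.1, 0.9, 0.1]},
            index=pd.Index(["gA", "gB", "gC"], name="gene"),
        )
        ranked = rank_for_gsea(stats)
        # gB leads on CV; the 0.1 tie breaks by mean_ratio (gA > gC)
        assert ranked["gene"].tolist() == ["gB", "gA", "gC"]

    def test_symbol_breaks_remaining_ties(self):
        stats = pd.DataFrame(
            {"mean_ratio": [2.0, 2.0], "sd_ratio": [0, 0], "cv": [0.5, 0.5]},
            index=pd.Index(["gB", "gA"], name="gene"),
        )
        assert rank_for_gsea(stats)["gene"].tolist() == ["gA", "gB"]


class TestDifferentialExpression:
    def _grouped_matrix(self, xa, xb):
        n_a, n_b = xa.shape[1], xb.shape[1]
        samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
        genes = [f"g{i}" for i in range(xa.shape[0])]
        group = {s: ("A" if s.startswith("a") else "B") for s in samples}
        return make_matrix(np.hstack([xa, xb]), genes, samples, {}, group)

    def test_null_fraction_near_alpha(self):
        """Identical group distributions reject at roughly the nominal
        alpha = 0.05 rate (within 3 binomial SE over 2000 genes)."""
        rng = np.random.default_rng(17)
        mat = self._grouped_matrix(
            np.abs(rng.normal(10, 2, size=(2000, 8))) + 0.1,
            np.abs(rng.normal(10, 2, size=(2000, 8))) + 0.1,
        )
        de = differential_expression(mat, "A", "B")
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(de.attrs["frac_significant"] - 0.05) < 3 * se

    def test_large_shift_is_significant_and_label_swap_symmetric(self):
        rng = np.random.default_rng(3)
        xa = np.abs(rng.normal(10, 1, size=(5, 6))) + 0.1
        xb = np.abs(rng.normal(10, 1, size=(5, 6))) + 0.1
        xb[0] += 10  # 10-SD shift
        mat = self._grouped_matrix(xa, xb)
        de_ab = differential_expression(mat, "A", "B")
        de_ba = differential_expression(mat, "B", "A")
        assert de_ab.loc["g0", "p"] < 1e-6
        np.testing.assert_allclose(de_ab["p"], de_ba["p"])
        np.testing.assert_allclose(de_ab["t"], -de_ba["t"])

    def test_zero_variance_gene_flagged_with_p_one(self):
        xa = np.ones((2, 4)) * 5
        xb = np.ones((2, 4)) * 5
        xb[1] += np.array([0.1, -0.1, 0.2, -0.2])
        de = differential_expression(self._grouped_matrix(xa, xb), "A", "B")
        assert bool(de.loc["g0", "zero_variance"]) and de.loc["g0", "p"] == 1.0
        assert not bool(de.loc["g1", "zero_variance"])

    def test_bh_adjustment_column_optional(self):
        rng = np.random.default_rng(4)
        mat = self._grouped_matrix(
            np.abs(rng.normal(10, 2, size=(50, 4))) + 0.1,
            np.abs(rng.normal(10, 2, size=(50, 4))) + 0.1,
        )
        de = differential_expression(mat, "A", "B", adjust=True)
        assert "q" in de.columns and (de["q"] >= de["p"] - 1e-12).all()


class TestSexCalling:
    def _xist_matrix(self, xist_values):
        n = len(xist_values)
        samples = [f"s{i}" for i in range(n)]
        return make_matrix([xist_values, [5] * n], ["Xist", "other"], samples, {})

    def test_bimodal_toy_splits_three_two(self):
        calls = call_sex_by_xist(self._xist_matrix([1, 1, 1, 8, 8]))
        assert (calls == "male").sum() == 3
        assert (calls == "female").sum() == 2
        assert calls.loc["s4"] == "female"

    def test_constant_input_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            calls = call_sex_by_xist(self._xist_matrix([4, 4, 4, 4]))
        assert calls.nunique() == 1

    def test_scale_invariance(self):
        base = [1, 2, 1, 9, 8, 1]
        c1 = call_sex_by_xist(self._xist_matrix(base))
        c2 = call_sex_by_xist(self._xist_matrix([10 * v for v in base]))
        pd.testing.assert_series_equal(c1, c2)

    def test_simulated_twins_share_sex(self, study):
        calls = call_sex_by_xist(study.expression)
        for pid in study.expression.pairs:
            a, b = study.expression.pair_members(pid)
            assert calls[a] == calls[b]


class TestGroupSimilarity:
    def test_identical_groups_give_one(self):
        rng = np.random.default_rng(0)
        x = np.abs(rng.normal(8, 2, size=(100, 3))) + 0.1
        mat = make_matrix(
            np.hstack([x, x]),
            [f"g{i}" for i in range(100)],
            [f"s{i}" for i in range(6)],
            {},
            {f"s{i}": ("A" if i < 3 else "B") for i in range(6)},
        )
        assert group_similarity(mat, "A", "B") == pytest.approx(1.0)

    def test_independent_profiles_near_zero(self):
        rng = np.random.default_rng(1)
        x = np.abs(rng.normal(8, 2, size=(10000, 6))) + 0.1
        mat = make_matrix(
            x,
            [f"g{i}" for i in range(10000)],
            [f"s{i}" for i in range(6)],
            {},
            {f"s{i}": ("A" if i < 3 else "B") for i in range(6)},
        )
        assert group_similarity(mat, "A", "B") < 0.01

    def test_twin_vs_control_highly_similar_in_generator(self, study):
        assert group_similarity(study.expression, "MZ_twin", "control") > 0.9


class TestMatrixValidation:
    def test_nonpositive_linear_values_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            make_matrix([[1, -2]], ["g"], ["s1", "s2"], {"s1": "P1", "s2": "P1"})

    def test_incomplete_pair_rejected(self):
        with pytest.raises(ValueError, match="exactly two"):
            make_matrix([[1, 2, 3]], ["g"], ["s1", "s2", "s3"], {"s1": "P1", "s2": "P1", "s3": "P2"})

    def test_scale_conversion_roundtrip(self):
        mat = two_pair_matrix({"g1": [2, 4, 8, 16]})
        back = mat.to_log2().to_linear()
        pd.testing.assert_frame_equal(back.values, mat.values)
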