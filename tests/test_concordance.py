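"""DZ-derived thresholds and MZ concordance classification."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

from twinconcord.concordance import (
    ConcordanceClassifier,
    ConcordanceThresholds,
    LineageCounts,
    TwinPairRecord,
    classify_pair,
    concordance_summary,
    derive_thresholds,
    frame_from_pairs,
    lineage_correlation,
    pairs_from_frame,
)
from twinconcord.simulate import GeneratorConfig, simulate_lineage_pairs


def dz_pair(pid, a, b, condition=None):
    return TwinPairRecord(pid, "DZ", LineageCounts(*a), LineageCounts(*b), condition)


def mz_pair(pid, a, b, condition=None):
    return TwinPairRecord(pid, "MZ", LineageCounts(*a), LineageCounts(*b), condition)


def dz_pairs_with_diffs(te_diffs, epi_diffs, pend_diffs):
    """DZ pairs whose per-lineage absolute differences are as given."""
    base = (40, 15, 10)
    return [
        dz_pair(
            f"DZ{i}",
            base,
            (base[0] + te, base[1] + epi, base[2] + pend),
        )
        for i, (te, epi, pend) in enumerate(zip(te_diffs, epi_diffs, pend_diffs))
    ]


class TestDeriveThresholds:
    def test_dz_medians_18_4_4_halve_to_9_2_2(self):
        """The background DZ medians of 18/4/4 cells yield the 9-2-2 rule."""
        pairs = dz_pairs_with_diffs([10, 18, 30], [1, 4, 9], [2, 4, 7])
        th = derive_thresholds(pairs)
        assert th.as_tuple() == (9.0, 2.0, 2.0)

    def test_identical_members_give_zero_thresholds(self):
        pairs = [dz_pair(f"D{i}", (30, 10, 8), (30, 10, 8)) for i in range(4)]
        assert derive_thresholds(pairs).as_tuple() == (0.0, 0.0, 0.0)

    def test_odd_count_median_halved(self):
        # TE diffs {2, 6, 10}: median 6, halved to 3
        pairs = dz_pairs_with_diffs([2, 6, 10], [0, 0, 0], [0, 0, 0])
        assert derive_thresholds(pairs).te_max == 3.0

    def test_even_count_median_averages_central_pair(self):
        pairs = dz_pairs_with_diffs([2, 4, 8, 20], [0] * 4, [0] * 4)
        assert derive_thresholds(pairs).te_max == 3.0  # median (4+8)/2 = 6

    def test_rejects_mz_records_and_tiny_input(self):
        with pytest.raises(ValueError, match="non-DZ"):
            derive_thresholds([dz_pair("D1", (1, 1, 1), (1, 1, 1)), mz_pair("M1", (1, 1, 1), (2, 2, 2))])
        with pytest.raises(ValueError):
            derive_thresholds([])
        with pytest.raises(ValueError):
            derive_thresholds([dz_pair("D1", (1, 1, 1), (1, 1, 1))])


class TestClassifyPair:
    TH = ConcordanceThresholds(9, 2, 2)

    def test_boundary_equality_is_concordant(self):
        pair = mz_pair("M1", (20, 8, 5), (29, 10, 7))  # diffs exactly (9, 2, 2)
        assert classify_pair(pair, self.TH) == "concordant"

    def test_single_lineage_exceedance_is_discordant(self):
        pair = mz_pair("M1", (20, 8, 5), (30, 8, 5))  # diffs (10, 0, 0)
        assert classify_pair(pair, self.TH) == "discordant"

    def test_identical_members_concordant_for_any_thresholds(self):
        pair = mz_pair("M1", (20, 8, 5), (20, 8, 5))
        assert classify_pair(pair, ConcordanceThresholds(0, 0, 0)) == "concordant"

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.tuples(*[st.integers(0, 60)] * 6))
    def test_member_swap_invariance(self, counts):
        a, b = counts[:3], counts[3:]
        pair = mz_pair("M1", a, b)
        swapped = mz_pair("M1", b, a)
        assert classify_pair(pair, self.TH) == classify_pair(swapped, self.TH)

    def test_brute_force_recheck_on_random_pairs(self):
        """classify_pair agrees with direct evaluation of the three
        inequalities on 1000 random pairs."""
        rng = np.random.default_rng(0)
        th = ConcordanceThresholds(4.5, 2.0, 1.5)
        for _ in range(1000):
            a = tuple(int(v) for v in rng.integers(0, 40, 3))
            b = tuple(int(v) for v in rng.integers(0, 40, 3))
            pair = mz_pair("M", a, b)
            expected = (
                "concordant"
                if abs(a[0] - b[0]) <= 4.5 and abs(a[1] - b[1]) <= 2.0 and abs(a[2] - b[2]) <= 1.5
                else "discordant"
            )
            assert classify_pair(pair, th) == expected


class TestClassifierEstimator:
    def test_sklearn_conventions(self):
        clf = ConcordanceClassifier()
        assert clf.get_params() == {"thresholds": None}
        clone(clf)  # must be cloneable
        with pytest.raises(NotFittedError):
            clf.predict([mz_pair("M1", (1, 1, 1), (1, 1, 1))])

    def test_fit_predict_with_supplied_thresholds(self):
        clf = ConcordanceClassifier(ConcordanceThresholds(9, 2, 2)).fit(None)
        labels = clf.predict(
            [mz_pair("M1", (20, 8, 5), (29, 10, 7)), mz_pair("M2", (20, 8, 5), (30, 8, 5))]
        )
        assert list(labels) == ["concordant", "discordant"]

    def test_fit_derives_from_dz(self):
        clf = ConcordanceClassifier().fit(dz_pairs_with_diffs([10, 18, 30], [1, 4, 9], [2, 4, 7]))
        assert clf.thresholds_.as_tuple() == (9.0, 2.0, 2.0)
        assert clf.n_dz_pairs_ == 3


class TestSummary:
    TH = ConcordanceThresholds(9, 2, 2)

    def test_printed_partition_36_of_100(self):
        pairs = [mz_pair(f"M{i}", (20, 8, 5), (20, 8, 5)) for i in range(36)]
        pairs += [mz_pair(f"M{i + 36}", (20, 8, 5), (40, 8, 5)) for i in range(64)]
        out = concordance_summary(pairs, self.TH)
        row = out.iloc[0]
        assert row["prop_concordant"] == pytest.approx(0.36)
        assert row["prop_discordant"] == pytest.approx(0.64)
        assert row["sd"] == pytest.approx(np.sqrt(0.36 * 0.64 / 100))

    def test_all_concordant_has_zero_sd(self):
        pairs = [mz_pair(f"M{i}", (20, 8, 5), (20, 8, 5)) for i in range(10)]
        assert concordance_summary(pairs, self.TH).iloc[0]["sd"] == 0.0

    def test_condition_grouping_and_low_n_flag(self):
        pairs = [mz_pair(f"M{i}", (20, 8, 5), (20, 8, 5), condition="mediumA") for i in range(6)]
        pairs += [mz_pair("M9", (20, 8, 5), (40, 8, 5), condition="SCNT")]
        out = concordance_summary(pairs, self.TH, group_by_condition=True)
        out = out.set_index("group")
        assert not out.loc["mediumA", "low_n"]
        assert out.loc["SCNT", "low_n"]
        assert np.allclose(out["prop_concordant"] + out["prop_discordant"], 1.0)


class TestLineageCorrelation:
    def test_equal_members_give_r_one(self):
        pairs = [mz_pair(f"M{i}", (t, 8, 5), (t, 8, 5)) for i, t in enumerate([10, 20, 30])]
        assert lineage_correlation(pairs, "te") == pytest.approx(1.0)

    def test_antisymmetric_toy_gives_minus_one(self):
        # doubled set of {(0,10),(10,0)} is 4 points with exact r = -1
        pairs = [mz_pair("M1", (0, 0, 0), (10, 0, 0)), mz_pair("M2", (10, 0, 0), (0, 0, 0))]
        assert lineage_correlation(pairs, "te") == pytest.approx(-1.0)

    def test_zero_variance_signalled(self):
        pairs = [mz_pair(f"M{i}", (5, 8, 5), (5, 8, 5)) for i in range(3)]
        with pytest.raises(ValueError, match="variance"):
            lineage_correlation(pairs, "te")

    def test_epi_correlation_lower_than_te_on_discordant_data(self):
        """EPI drives discordance in the generator, so its within-pair
        correlation falls below TE's."""
        cfg = GeneratorConfig(seed=21, n_mz_pairs=200, n_dz_pairs=2)
        pairs, _ = simulate_lineage_pairs(cfg)
        mz = [p for p in pairs if p.zygosity == "MZ"]
        assert lineage_correlation(mz, "epi") < lineage_correlation(mz, "te")


class TestPipelineProperties:
    def test_half_of_dz_pairs_fall_within_unhalved_median(self):
        """Sanity of the halving rule's input: by definition of the
        median, about half the DZ pairs differ by at most the unhalved
        median in each lineage."""
        cfg = GeneratorConfig(seed=31, n_mz_pairs=1, n_dz_pairs=200)
        pairs, _ = simulate_lineage_pairs(cfg)
        dz = [p for p in pairs if p.zygosity == "DZ"]
        th = derive_thresholds(dz)  # halved medians
        for lineage, halved in zip(("te", "epi", "pend"), th.as_tuple()):
            med = 2 * halved
            frac = np.mean([p.abs_diff(lineage) <= med for p in dz])
            assert 0.4 <= frac  # at least half (ties can push it above)
            assert frac <= 0.75

    def test_roundtrip_through_long_frame(self):
        pairs = [mz_pair("M1", (20, 8, 5), (29, 10, 7), "mediumA"), dz_pair("D1", (40, 15, 10), (50, 12, 9))]
        back = pairs_from_frame(frame_from_pairs(pairs))
        assert sorted(back, key=lambda p: p.pair_id) == sorted(pairs, key=lambda p: p.pair_id)

    def test_frame_with_singleton_member_rejected(self):
        df = frame_from_pairs([mz_pair("M1", (1, 1, 1), (2, 2, 2))]).iloc[:1]
        with pytest.raises(ValueError, match="M1"):
            pairs_from_frame(df)
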