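"""Metadata binning, two/multi-group tests and trend summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import microcompare as mc
from microcompare.metadata_stats import multi_group_test, two_group_test


def meta_frame(ages, bmis):
    return pd.DataFrame(
        {"age": ages, "bmi": bmis}, index=[f"S{i}" for i in range(len(ages))]
    )


class TestBinning:
    def test_bmi_boundaries(self):
        meta = meta_frame([30, 30, 30], [18.5, 25.0, 18.49])
        out = mc.bin_metadata(meta)
        assert list(out["bmi_bin"]) == ["normal", "obese", "underweight"]

    def test_six_age_bins_with_closed_last(self):
        meta = meta_frame([20, 24.9, 45, 50, 33, 49.9], [22] * 6)
        out = mc.bin_metadata(meta, age_start=20)
        assert list(out["age_bin"].cat.categories) == [
            "[20,25)", "[25,30)", "[30,35)", "[35,40)", "[40,45)", "[45,50]",
        ]
        assert out.loc["S0", "age_bin"] == "[20,25)"
        assert out.loc["S3", "age_bin"] == "[45,50]"  # closed right edge
        assert not out["age_out_of_range"].any()

    def test_out_of_range_age_flagged(self):
        meta = meta_frame([20, 90], [22, 22])
        out = mc.bin_metadata(meta, age_start=20)
        assert out.loc["S1", "age_out_of_range"]
        assert pd.isna(out.loc["S1", "age_bin"])

    def test_default_anchor_is_floored_minimum(self):
        meta = meta_frame([23, 31, 44], [22] * 3)
        out = mc.bin_metadata(meta)
        assert out["age_bin"].cat.categories[0] == "[20,25)"


class TestTwoGroup:
    def test_identical_groups(self, rng):
        v = rng.normal(size=8)
        values = np.concatenate([v, v])
        labels = ["A"] * 8 + ["B"] * 8
        for method in ("wilcoxon", "whites"):
            res = two_group_test(values, labels, method=method, seed=0)
            assert res.p > 0.8
            assert res.ci[0] <= 0 <= res.ci[1]

    def test_whites_p_bounded_below(self, rng):
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(50, 1, 10)])
        labels = ["A"] * 10 + ["B"] * 10
        res = two_group_test(values, labels, method="whites", n_perm=1000, seed=0)
        # a 50-sigma shift: only (near-)identity permutations can match it
        assert 1 / 1001 <= res.p <= 3 / 1001
        assert res.direction == "B"

    def test_power_for_large_shift(self, rng):
        hits = 0
        for s in range(20):
            r = np.random.default_rng(s)
            values = np.concatenate([r.normal(0, 1, 20), r.normal(3, 1, 20)])
            labels = ["A"] * 20 + ["B"] * 20
            res = two_group_test(values, labels, method="whites", seed=s)
            hits += res.p < 0.01
        assert hits >= 19

    def test_type_i_calibration(self):
        # null: both groups iid; empirical rejection rate ~ alpha
        rejections = 0
        reps = 200
        for s in range(reps):
            r = np.random.default_rng(10_000 + s)
            values = r.normal(size=24)
            labels = ["A"] * 12 + ["B"] * 12
            res = two_group_test(values, labels, method="whites", n_perm=400, n_boot=10, seed=s)
            rejections += res.p < 0.05
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se + 0.01

    def test_label_relabeling_invariance(self, rng):
        values = rng.normal(size=20)
        labels = ["A"] * 10 + ["B"] * 10
        renamed = ["grp1"] * 10 + ["grp2"] * 10
        a = two_group_test(values, labels, seed=1)
        b = two_group_test(values, renamed, seed=1)
        assert a.p == b.p and a.statistic == b.statistic


class TestMultiGroup:
    def test_identical_groups_eta_squared_near_zero(self, rng):
        v = rng.normal(size=10)
        values = np.concatenate([v, v, v])
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        h, p, eta2, pairs = multi_group_test(values, groups)
        # the (H-k+1)/(n-k) estimator is slightly negative when H ~ 0
        assert eta2 < 0.02 and p > 0.9

    def test_kw_statistic_matches_manual_ranks(self):
        # 9-value fixture, 3 groups of 3
        values = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0, 20.0, 21.0, 22.0])
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        h, p, eta2, _ = multi_group_test(values, groups)
        ranks = stats.rankdata(values)
        n = 9
        manual = 12 / (n * (n + 1)) * sum(
            3 * (ranks[i : i + 3].mean() - (n + 1) / 2) ** 2 for i in (0, 3, 6)
        )
        assert h == pytest.approx(manual, rel=1e-12)
        assert eta2 == pytest.approx((h - 3 + 1) / (n - 3))

    def test_shifted_group_flagged_in_both_pairs(self, rng):
        values = np.concatenate(
            [rng.normal(0, 1, 15), rng.normal(0, 1, 15), rng.normal(8, 1, 15)]
        )
        groups = ["a"] * 15 + ["b"] * 15 + ["c"] * 15
        _, _, _, pairs = multi_group_test(values, groups)
        sig = pairs[pairs["p"] < 0.01]
        flagged = {frozenset((r.group1, r.group2)) for r in sig.itertuples()}
        assert flagged == {frozenset(("a", "c")), frozenset(("b", "c"))}

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            multi_group_test([1, 2, 3, 4, 5], ["a", "a", "b", "b", "c"])


class TestTrend:
    def bins_series(self, labels, columns):
        return pd.Series(
            pd.Categorical(labels, categories=sorted(set(labels)), ordered=True),
            index=columns,
        )

    def test_strictly_increasing_rho_one(self):
        features = pd.DataFrame(
            [[1.0, 1.1, 2.0, 2.1, 3.0, 3.2]], index=["f"],
            columns=[f"S{i}" for i in range(6)],
        )
        bins = self.bins_series(["a", "a", "b", "b", "c", "c"], features.columns)
        out = mc.trend_summary(features, bins)
        assert out.loc["f", "rho"] > 0.9
        assert out.loc["f", "direction"] == "increasing"

    def test_constant_feature_none(self):
        features = pd.DataFrame(
            [[2.0] * 6, [1, 2, 3, 4, 5, 6]], index=["const", "inc"],
            columns=[f"S{i}" for i in range(6)],
        )
        bins = self.bins_series(["a", "a", "b", "b", "c", "c"], features.columns)
        out = mc.trend_summary(features, bins)
        assert out.loc["const", "direction"] == "none"

    def test_planted_metadata_link_recovered(self):
        from microcompare.simulate import MetadataLink, lognormal_component, CohortSpec, generate_cohorts

        spec = CohortSpec(
            n_samples={"TR": 150},
            n_features=40,
            components=[lognormal_component(40, seed=2)],
            component_weights={"TR": np.array([1.0])},
            metadata_links=[MetadataLink(0, "bmi", "decreasing", rho=0.6)],
            seed=8,
        )
        table, meta = generate_cohorts(spec)
        binned = mc.bin_metadata(meta)
        rel = mc.to_relative(table)
        out = mc.trend_summary(rel.data, binned["bmi_bin"])
        assert out.loc["OTU_1", "direction"] == "decreasing"

    def test_shuffled_bins_not_flagged(self, rng):
        features = pd.DataFrame(
            rng.normal(size=(5, 60)), index=[f"f{i}" for i in range(5)],
            columns=[f"S{i}" for i in range(60)],
        )
        bins = self.bins_series(list("abc") * 20, features.columns)
        out = mc.trend_summary(features, bins)
        assert (out["direction"] == "none").all()
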