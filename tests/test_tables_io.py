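"""Table I/O, rarefaction and the sparsity/prevalence filters."""

import numpy as np
import pandas as pd
import pytest

import microcompare as mc
from microcompare import AbundanceTable


class TestReadWrite:
    def test_roundtrip_counts_exact(self, rng, tmp_path):
        data = pd.DataFrame(
            rng.integers(0, 500, size=(50, 20)),
            index=[f"F{i}" for i in range(50)],
            columns=[f"S{j}" for j in range(20)],
        )
        table = AbundanceTable(data=data, kind="counts")
        path = tmp_path / "t.tsv"
        mc.write_abundance(table, path)
        back = mc.read_abundance(path)
        assert (back.data.to_numpy() == data.to_numpy()).all()
        assert back.sample_ids == table.sample_ids
        assert back.feature_ids == table.feature_ids

    def test_roundtrip_preserves_taxonomy(self, counts_table, tmp_path):
        path = tmp_path / "t.tsv"
        mc.write_abundance(counts_table, path)
        back = mc.read_abundance(path)
        assert back.taxonomy == counts_table.taxonomy

    def test_negative_value_names_cell(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("feature_id\tS1\tS2\nF1\t3\t4\nF2\t-1\t0\n")
        with pytest.raises(ValueError, match=r"line 3.*F2.*S1"):
            mc.read_abundance(path)

    def test_ragged_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("feature_id\tS1\tS2\nF1\t3\t4\nF2\t1\n")
        with pytest.raises(ValueError, match="line 3"):
            mc.read_abundance(path)

    def test_duplicate_feature_id_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("feature_id\tS1\nF1\t3\nF1\t4\n")
        with pytest.raises(ValueError, match="duplicate feature ids"):
            mc.read_abundance(path)

    def test_comments_skipped(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("# comment\nfeature_id\tS1\n# another\nF1\t3\n")
        assert mc.read_abundance(path).data.loc["F1", "S1"] == 3


class TestRarefy:
    def test_default_depth_is_minimum_column_sum(self, counts_table):
        rare = mc.rarefy(counts_table, seed=1)
        depth = counts_table.data.sum(axis=0).min()
        assert (rare.data.sum(axis=0) == depth).all()

    def test_column_at_depth_unchanged(self, counts_table):
        totals = counts_table.data.sum(axis=0)
        rare = mc.rarefy(counts_table, depth=int(totals.min()), seed=0)
        shallow = totals.idxmin()
        assert (rare.data[shallow] == counts_table.data[shallow]).all()

    def test_error_names_shallow_sample(self, counts_table):
        # S1 and S4 both hold 1000 reads, the minimum; depth 1100 excludes them
        with pytest.raises(ValueError, match="S1"):
            mc.rarefy(counts_table, depth=1100)

    def test_hypergeometric_expectation(self):
        # counts (900,100) subsampled to 100: expected feature-2 count is 10
        data = pd.DataFrame({"S1": [900, 100]}, index=["A", "B"])
        table = AbundanceTable(data=data)
        draws = [
            mc.rarefy(table, depth=100, seed=s).data.loc["B", "S1"] for s in range(600)
        ]
        # hypergeometric variance: n*p*q*(N-n)/(N-1)
        se = np.sqrt(100 * 0.1 * 0.9 * 900 / 999 / len(draws))
        assert abs(np.mean(draws) - 10.0) < 3 * se

    def test_reorder_invariance(self, counts_table):
        rare = mc.rarefy(counts_table, seed=7)
        shuffled = counts_table.select_samples(["S3", "S1", "S6", "S2", "S5", "S4"])
        rare2 = mc.rarefy(shuffled, seed=7)
        assert (rare2.data[rare.sample_ids] == rare.data).all().all()

    def test_per_feature_expectation_matches_proportion(self, counts_table):
        depth = 200
        reps = 400
        col = counts_table.data["S1"]
        acc = np.zeros(len(col))
        for s in range(reps):
            acc += mc.rarefy(counts_table, depth=depth, seed=s).data["S1"].to_numpy()
        expected = depth * col.to_numpy() / col.sum()
        p = col.to_numpy() / col.sum()
        se = np.sqrt(depth * p * (1 - p) / reps) + 1e-9
        assert (np.abs(acc / reps - expected) < 3 * se + 0.05).all()


class TestFilters:
    def test_sparse_filter_drops_below_fraction(self):
        data = pd.DataFrame({"S1": [10**6 - 1, 1]}, index=["big", "tiny"])
        table = AbundanceTable(data=data)
        kept, dropped = mc.filter_sparse(table, min_total_fraction=0.00002)
        assert dropped == ["tiny"]

    def test_sparse_threshold_zero_keeps_all(self, counts_table):
        kept, dropped = mc.filter_sparse(counts_table, min_total_fraction=0.0)
        assert dropped == [] and kept.n_features == counts_table.n_features

    def test_sparse_small_grand_total(self):
        # grand total 10,000 at 0.002% => cutoff 0.2 reads: only zero-total drops
        data = pd.DataFrame(
            {"S1": [9998, 1, 0], "S2": [0, 1, 0]}, index=["a", "b", "c"]
        )
        kept, dropped = mc.filter_sparse(AbundanceTable(data=data))
        assert dropped == ["c"]

    def test_to_relative(self, counts_table):
        rel = mc.to_relative(counts_table)
        assert np.allclose(rel.data.sum(axis=0), 1.0)
        col = mc.to_relative(
            AbundanceTable(pd.DataFrame({"S": [2, 3, 5]}, index=list("abc")))
        )
        assert np.allclose(col.data["S"], [0.2, 0.3, 0.5])

    def test_collapse_sums_same_genus(self, counts_table):
        genus = mc.collapse(counts_table, "genus")
        expect = counts_table.data.loc["OTU_1"] + counts_table.data.loc["OTU_2"]
        assert (genus.data.loc["Prevotella"] == expect).all()
        assert genus.n_features == 4

    def test_collapse_commutes_with_to_relative(self, counts_table):
        a = mc.to_relative(mc.collapse(counts_table, "phylum"))
        b = mc.collapse(mc.to_relative(counts_table), "phylum")
        assert np.allclose(a.data.to_numpy(), b.data.loc[a.data.index].to_numpy(), atol=1e-12)

    def test_collapse_requires_taxonomy(self, counts_table):
        bare = AbundanceTable(data=counts_table.data.copy())
        with pytest.raises(ValueError, match="taxonomy"):
            mc.collapse(bare, "genus")

    def test_prevalence_filter_per_group(self):
        # feature non-zero in 5/10 of group A (50% < 51%) must be removed
        data = pd.DataFrame(
            [[1] * 5 + [0] * 5 + [1] * 10, [1] * 20],
            index=["borderline", "everywhere"],
            columns=[f"S{i}" for i in range(20)],
        )
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=data.columns)
        kept = mc.prevalence_filter(AbundanceTable(data=data), 0.51, groups=groups)
        assert kept.feature_ids == ["everywhere"]

    def test_prevalence_filter_global(self):
        data = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 1, 0]], index=["half", "most"],
            columns=list("abcd"),
        )
        kept = mc.prevalence_filter(AbundanceTable(data=data), 0.51)
        assert kept.feature_ids == ["most"]


class TestMetadata:
    def test_roundtrip(self, tmp_path):
        meta = pd.DataFrame(
            {"cohort": ["TR", "UR"], "age": [30.0, 40.0], "bmi": [22.0, 27.5]},
            index=pd.Index(["a", "b"], name="sample_id"),
        )
        path = tmp_path / "meta.tsv"
        mc.write_metadata(meta, path)
        back = mc.read_metadata(path)
        assert (back["age"] == meta["age"]).all()

    def test_validation_flags_problems(self, counts_table):
        meta = pd.DataFrame(
            {"cohort": ["TR"] * 5, "age": [30, -1, 25, np.nan, 50]},
            index=["S1", "S2", "S3", "S4", "S5"],
        )
        issues = mc.validate_metadata(meta, counts_table)
        assert any("S6" in i for i in issues)  # missing sample
        assert any("age" in i and "S2" in i for i in issues)

    def test_validation_clean(self, counts_table):
        meta = pd.DataFrame(
            {"cohort": ["TR"] * 6, "age": [30.0] * 6},
            index=counts_table.sample_ids,
        )
        assert mc.validate_metadata(meta, counts_table) == []
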