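"""Count ingestion, size factors, group summaries, fold changes."""

import math

import numpy as np
import pandas as pd
import pytest
from helpers import design_frame, make_matrix, random_matrix

from regenpath.expression import (
    CountMatrix,
    FormatError,
    fold_change,
    normalized_counts,
    read_counts,
    size_factors,
    summarize_groups,
    write_counts,
)


class TestReadCounts:
    def test_round_trip(self, tmp_path):
        m = make_matrix({"g1": [10] * 15, "g2": [0, 5] + [1] * 13})
        write_counts(m, tmp_path / "c.tsv", tmp_path / "d.tsv")
        m2 = read_counts(tmp_path / "c.tsv", tmp_path / "d.tsv")
        pd.testing.assert_frame_equal(m.counts, m2.counts)
        pd.testing.assert_frame_equal(m.design, m2.design)

    def test_sample_missing_from_design_names_the_column(self, tmp_path):
        m = make_matrix({"g1": [10] * 15})
        write_counts(m, tmp_path / "c.tsv", tmp_path / "d.tsv")
        d = pd.read_csv(tmp_path / "d.tsv", sep="\t")
        d = d[d["sample_id"] != "MI_P7_r2"]
        d.to_csv(tmp_path / "d.tsv", sep="\t", index=False)
        with pytest.raises(FormatError, match="MI_P7_r2"):
            read_counts(tmp_path / "c.tsv", tmp_path / "d.tsv")

    def test_non_integer_count_rejected(self, tmp_path):
        m = make_matrix({"g1": [10] * 15})
        write_counts(m, tmp_path / "c.tsv", tmp_path / "d.tsv")
        text = (tmp_path / "c.tsv").read_text().replace("\t10", "\t3.7", 1)
        (tmp_path / "c.tsv").write_text(text)
        with pytest.raises(FormatError, match="non-integer"):
            read_counts(tmp_path / "c.tsv", tmp_path / "d.tsv")

    def test_negative_and_duplicate_rejected(self):
        d = design_frame()
        counts = pd.DataFrame([[-1] * 15], index=["g1"], columns=list(d.index))
        with pytest.raises(FormatError, match="negative"):
            CountMatrix.from_frames(counts, d)
        dup = pd.DataFrame([[1] * 15, [2] * 15], index=["g1", "g1"],
                           columns=list(d.index))
        with pytest.raises(FormatError, match="duplicate gene"):
            CountMatrix.from_frames(dup, d)

    def test_mi_at_p1_rejected(self):
        d = design_frame()
        d.loc["CTL_P1_r1", "condition"] = "MI"
        counts = pd.DataFrame([[1] * 15], index=["g1"], columns=list(d.index))
        with pytest.raises(FormatError, match="P7 and P28"):
            CountMatrix.from_frames(counts, d)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = make_matrix({"g1": [7] * 15, "g2": [100] * 15})
        assert np.allclose(size_factors(m), 1.0)

    def test_doubled_sample_has_double_factor(self):
        d = design_frame(1)  # 5 samples
        base = np.array([100, 10, 1000])
        cols = {s: base for s in d.index}
        cols["MI_P7_r1"] = base * 2
        counts = pd.DataFrame(cols, index=["a", "b", "c"])
        m = CountMatrix.from_frames(counts, d)
        s = size_factors(m)
        assert s["MI_P7_r1"] / s["CTL_P1_r1"] == pytest.approx(2.0)
        norm = normalized_counts(m, s)
        assert np.allclose(norm["MI_P7_r1"], norm["CTL_P1_r1"])

    def test_hand_computed_two_sample_factors(self):
        # counts [[100,200],[10,20],[1000,2000]] -> factors (1/sqrt2, sqrt2)
        d = design_frame(1).iloc[:2]
        counts = pd.DataFrame(
            [[100, 200], [10, 20], [1000, 2000]],
            index=["a", "b", "c"], columns=list(d.index),
        )
        m = CountMatrix.from_frames(counts, d)
        s = size_factors(m)
        assert s.iloc[0] == pytest.approx(1 / math.sqrt(2))
        assert s.iloc[1] == pytest.approx(math.sqrt(2))

    def test_empty_reference_set_raises(self):
        m = make_matrix({"g1": [0] + [1] * 14, "g2": [1] * 14 + [0]})
        with pytest.raises(ValueError, match="pseudocount|reference"):
            size_factors(m)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_scale_invariance(self, seed):
        """Scaling one sample's counts by c raises its factor c-fold
        relative to the others; normalized values change only by the common
        geometric-mean-1 renormalization constant, so every ratio-based
        quantity (summary ratios, fold changes) is unchanged."""
        rng = np.random.default_rng(seed)
        m = random_matrix(rng)
        c = int(rng.integers(2, 7))
        scaled_counts = m.counts.copy()
        sample = m.sample_ids[int(rng.integers(len(m.sample_ids)))]
        scaled_counts[sample] *= c
        m2 = CountMatrix.from_frames(scaled_counts, m.design)
        s1, s2 = size_factors(m), size_factors(m2)
        ratio = (s2 / s1) / (s2 / s1).drop(sample).iloc[0]
        assert ratio[sample] == pytest.approx(c, rel=1e-9)
        n1 = normalized_counts(m, s1)
        n2 = normalized_counts(m2, s2)
        common = (n2 / n1).to_numpy()
        assert np.allclose(common, common.flat[0], rtol=1e-9)
        f1 = fold_change(summarize_groups(m, s1), "G000", "P7", 0.0)
        f2 = fold_change(summarize_groups(m2, s2), "G000", "P7", 0.0)
        assert f2.fold == pytest.approx(f1.fold, rel=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng)
        perm = list(rng.permutation(m.gene_ids))
        m2 = CountMatrix.from_frames(m.counts.loc[perm], m.design)
        s1 = summarize_groups(m)
        s2 = summarize_groups(m2)
        pd.testing.assert_frame_equal(s1, s2.sort_index())


class TestSummaries:
    def test_equal_replicates_sem_zero(self):
        m = make_matrix({"g1": [4] * 15})
        s = summarize_groups(m)
        row = s.loc[("g1", "CTL", "P7")]
        assert row["mean_norm"] == pytest.approx(4)
        assert row["sem_norm"] == 0

    def test_one_two_three_sem(self):
        m = make_matrix({"g1": [2] * 6 + [2] * 3 + [1, 2, 3] + [2] * 3,
                         "ref": [50] * 15, "ref2": [80] * 15})
        # two constant reference genes pin the per-sample ratio median at 1,
        # so normalized values equal raw values exactly
        s = summarize_groups(m)
        row = s.loc[("g1", "MI", "P7")]
        assert row["mean_norm"] == pytest.approx(2.0)
        assert row["sem_norm"] == pytest.approx(1 / math.sqrt(3))
        assert row["raw_total"] == 6

    def test_single_replicate_group(self):
        m = make_matrix({"g1": [5, 5, 5, 5, 5]}, n_reps=1)
        s = summarize_groups(m)
        row = s.loc[("g1", "MI", "P7")]
        assert row["n"] == 1 and row["sem_norm"] == 0 and row["mean_norm"] == 5


class TestFoldChange:
    def test_simple_ratio_without_pseudocount(self):
        m = make_matrix({"g1": [4] * 9 + [8] * 6, "ref": [100] * 15,
                         "ref2": [30] * 15})
        s = summarize_groups(m)
        rec = fold_change(s, "g1", "P7", pseudocount=0.0)
        assert rec.fold == pytest.approx(2.0)
        assert rec.log2fc == pytest.approx(1.0)

    def test_zero_means_pseudocount_floor(self):
        m = make_matrix({"g1": [0] * 15, "ref": [100] * 15})
        s = summarize_groups(m)
        rec = fold_change(s, "g1", "P7", pseudocount=0.5)
        assert rec.fold == pytest.approx(1.0)
        assert rec.log2fc == pytest.approx(0.0)

    def test_pseudocount_arithmetic(self):
        # MI mean 10, CTL mean 2.5, pc .5 -> fold 3.5
        m = make_matrix(
            {"g1": [3, 2, 4, 2, 3, 1, 3, 2, 4, 10, 10, 10, 5, 5, 5]})
        s = summarize_groups(m)
        # factors are 1 only if columns tie; compute from the summaries instead
        mi = s.loc[("g1", "MI", "P7"), "mean_norm"]
        ctl = s.loc[("g1", "CTL", "P7"), "mean_norm"]
        rec = fold_change(s, "g1", "P7", pseudocount=0.5)
        assert rec.fold == pytest.approx((mi + 0.5) / (ctl + 0.5))

    def test_missing_group_raises(self):
        m = make_matrix({"g1": [1] * 15})
        s = summarize_groups(m).drop(("g1", "MI", "P7"))
        with pytest.raises(KeyError, match="g1"):
            fold_change(s, "g1", "P7")
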