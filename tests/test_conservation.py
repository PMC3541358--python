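"""Ancestry calling, score aggregation, alignment identity, group tests."""

import io

import numpy as np
import pytest

from cnediv import (
    AlignmentBlock,
    ScoreTrack,
    accel_constraint_counts,
    classify_ancestral,
    group_ratio_comparison,
    mean_pairwise_identity,
    mean_track_score,
    stratified_score_comparison,
    two_sample_t,
)
from cnediv.annotations import CNERecord
from cnediv.conservation import (
    read_alignment_fasta,
    read_bedgraph,
    read_fixed_step_wiggle,
    read_hits_table,
    tracks_from_coverage,
)


def track(values, cne="HsX", kind="phyloP"):
    return ScoreTrack(cne, kind, tuple(float(v) for v in values))


class TestAncestry:
    def test_threshold_is_strict(self):
        calls = classify_ancestral([("Hs608", 1e-8), ("Hs999", 1e-3), ("HsEq", 1e-5)])
        by_id = {c.cne_id: c for c in calls}
        assert by_id["Hs608"].ancestral
        assert not by_id["Hs999"].ancestral
        assert not by_id["HsEq"].ancestral  # exactly at threshold is negative

    def test_best_hit_wins(self):
        (call,) = classify_ancestral([("HsA", 1e-2), ("HsA", 1e-9)])
        assert call.best_evalue == 1e-9
        assert call.ancestral

    def test_missing_element_is_not_ancestral(self):
        calls = classify_ancestral([("HsA", 1e-9)], all_ids=["HsA", "HsB"])
        by_id = {c.cne_id: c for c in calls}
        assert by_id["HsB"].best_evalue is None
        assert not by_id["HsB"].ancestral

    def test_negative_evalue_rejected(self):
        with pytest.raises(ValueError):
            classify_ancestral([("HsA", -1.0)])


class TestScoreAggregation:
    @pytest.mark.parametrize(
        "values,expected",
        [([0.5, 0.5, 0.5], 0.5), ([1, 0], 0.5), ([-2, 1], -0.5)],
    )
    def test_mean(self, values, expected):
        assert mean_track_score(track(values)) == pytest.approx(expected)

    def test_mean_order_invariant(self):
        values = [0.3, -1.2, 2.4, 0.0, 1.1]
        assert mean_track_score(track(values)) == pytest.approx(
            mean_track_score(track(values[::-1]))
        )

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            ScoreTrack("HsX", "phyloP", ())

    def test_phastcons_range_enforced(self):
        with pytest.raises(ValueError):
            track([0.5, 1.2], kind="phastCons")

    @pytest.mark.parametrize(
        "values,expected",
        [
            ([-2, -1.5, 0, 1.2, 1.5, 2], (2, 3)),
            ([-1, 1], (0, 0)),  # boundary values count in neither bin
            ([0, 0, 0], (0, 0)),
        ],
    )
    def test_accel_constraint_counts(self, values, expected):
        assert accel_constraint_counts(track(values)) == expected

    def test_counts_bounded_by_length(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 2, 100)
        n_low, n_high = accel_constraint_counts(track(values))
        assert n_low + n_high <= len(values)

    def test_counts_require_phylop(self):
        with pytest.raises(ValueError):
            accel_constraint_counts(track([0.5], kind="phastCons"))


class TestGroupRatio:
    def test_arithmetic(self):
        a = [track([-2] * 50 + [2] * 10, "A1")]
        b = [track([-2] * 20 + [2] * 10, "B1")]
        res = group_ratio_comparison(a, b)
        assert res.counts_a == (50, 10)
        assert res.counts_b == (20, 10)
        assert (res.ratio_a, res.ratio_b) == (5.0, 2.0)
        assert res.fold == pytest.approx(2.5)

    def test_identical_groups_show_no_association(self):
        values = [-2] * 30 + [2] * 10
        res = group_ratio_comparison([track(values, "A")], [track(values, "B")])
        assert res.fold == pytest.approx(1.0)
        assert res.test.p_value == pytest.approx(1.0)

    def test_chi_square_matches_hand_pearson(self):
        """[[30,10],[10,30]]: all expected 20, statistic 4*(100/20) = 20."""
        a = [track([-2] * 30 + [2] * 10, "A")]
        b = [track([-2] * 10 + [2] * 30, "B")]
        res = group_ratio_comparison(a, b)
        assert res.test.statistic == pytest.approx(20.0, rel=1e-12)

    def test_pooling_across_elements(self):
        a = [track([-2] * 25 + [2] * 5, "A1"), track([-2] * 25 + [2] * 5, "A2")]
        b = [track([-2] * 20 + [2] * 10, "B1")]
        res = group_ratio_comparison(a, b)
        assert res.counts_a == (50, 10)

    def test_zero_constrained_positions_rejected(self):
        with pytest.raises(ValueError):
            group_ratio_comparison([track([-2, -2])], [track([-2, 2])])


class TestPairwiseIdentity:
    def test_identical_ungapped(self):
        block = AlignmentBlock(("ACGT", "ACGT"), ("hg", "mm"))
        assert mean_pairwise_identity(block) == pytest.approx(100.0)

    def test_three_of_four(self):
        block = AlignmentBlock(("ACGT", "ACGA"), ("hg", "mm"))
        assert mean_pairwise_identity(block) == pytest.approx(75.0)

    def test_gap_columns_excluded(self):
        block = AlignmentBlock(("AC-T", "ACGT"), ("hg", "mm"))
        assert mean_pairwise_identity(block) == pytest.approx(100.0)

    def test_mean_over_pairs(self):
        block = AlignmentBlock(("ACGT", "ACGT", "ACGA"), ("hg", "mm", "gg"))
        # pairs: 100, 75, 75
        assert mean_pairwise_identity(block) == pytest.approx(250 / 3)

    def test_case_and_order_invariant(self):
        upper = AlignmentBlock(("ACGT", "acga"), ("hg", "mm"))
        flipped = AlignmentBlock(("ACGA", "ACGT"), ("mm", "hg"))
        assert mean_pairwise_identity(upper) == mean_pairwise_identity(flipped)

    def test_disjoint_gap_pair_excluded(self):
        block = AlignmentBlock(("AA--", "--TT", "AATT"), ("a", "b", "c"))
        # (a,b) has no gap-free column; (a,c) 100, (b,c) 100
        assert mean_pairwise_identity(block) == pytest.approx(100.0)

    def test_all_pairs_excluded_rejected(self):
        block = AlignmentBlock(("AA--", "--TT"), ("a", "b"))
        with pytest.raises(ValueError):
            mean_pairwise_identity(block)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            AlignmentBlock(("ACGT", "ACG"), ("a", "b"))


class TestStratifiedComparison:
    def test_identical_groups(self):
        a = [track([0.5] * 10, f"A{i}") for i in range(3)]
        b = [track([0.5] * 10, f"B{i}") for i in range(3)]
        res = stratified_score_comparison(a, b, "phyloP")
        assert res.test.statistic == 0.0
        assert res.test.p_value == pytest.approx(1.0)

    def test_separated_groups_reject(self):
        rng = np.random.default_rng(2)
        a = [track(0.0 + rng.normal(0, 0.01, 10), f"A{i}") for i in range(4)]
        b = [track(1.0 + rng.normal(0, 0.01, 10), f"B{i}") for i in range(4)]
        res = stratified_score_comparison(a, b, "phyloP")
        assert res.test.p_value < 0.001
        assert res.mean_a == pytest.approx(0.0, abs=0.05)
        assert res.mean_b == pytest.approx(1.0, abs=0.05)

    def test_f_equals_pooled_t_squared_on_element_means(self):
        rng = np.random.default_rng(4)
        a = [track(rng.normal(0.1, 1, 50), f"A{i}") for i in range(6)]
        b = [track(rng.normal(0.2, 1, 50), f"B{i}") for i in range(5)]
        res = stratified_score_comparison(a, b, "phyloP")
        t = two_sample_t(res.element_means_a, res.element_means_b, welch=False)
        assert res.test.statistic == pytest.approx(t.statistic**2, rel=1e-9)

    def test_small_group_rejected(self):
        a = [track([0.5], "A1")]
        b = [track([0.5], "B1"), track([0.5], "B2")]
        with pytest.raises(ValueError):
            stratified_score_comparison(a, b, "phyloP")


class TestReaders:
    def test_bedgraph_tracks(self):
        bedgraph = io.StringIO(
            "chr1\t0\t2\t0.5\nchr1\t2\t5\t-1.5\nchr2\t0\t3\t0.25\n"
        )
        coverage = read_bedgraph(bedgraph)
        cnes = [CNERecord("HsA", "hg19", "chr1", 1, 4)]
        (t,) = tracks_from_coverage(coverage, cnes, "phyloP")
        assert t.values == (0.5, -1.5, -1.5)

    def test_missing_bases_rejected(self):
        coverage = read_bedgraph(io.StringIO("chr1\t0\t2\t0.5\n"))
        cnes = [CNERecord("HsA", "hg19", "chr1", 0, 5)]
        with pytest.raises(ValueError, match="lack"):
            tracks_from_coverage(coverage, cnes, "phyloP")

    def test_fixed_step_wiggle_is_one_based(self):
        wig = io.StringIO(
            "fixedStep chrom=chr1 start=1 step=1\n0.1\n0.2\n0.3\n"
        )
        coverage = read_fixed_step_wiggle(wig)
        assert coverage["chr1"][0] == (0, 1, 0.1)
        cnes = [CNERecord("HsA", "hg19", "chr1", 0, 3)]
        (t,) = tracks_from_coverage(coverage, cnes, "phyloP")
        assert t.values == (0.1, 0.2, 0.3)

    def test_wiggle_matches_equivalent_bedgraph(self):
        values = [0.5, -1.0, 2.0, 0.0]
        wig = "fixedStep chrom=chr3 start=11 step=1\n" + "\n".join(map(str, values))
        bedgraph = "".join(
            f"chr3\t{10 + i}\t{11 + i}\t{v}\n" for i, v in enumerate(values)
        )
        cnes = [CNERecord("HsA", "hg19", "chr3", 10, 14)]
        from_wig = tracks_from_coverage(read_fixed_step_wiggle(io.StringIO(wig)), cnes, "phyloP")
        from_bg = tracks_from_coverage(read_bedgraph(io.StringIO(bedgraph)), cnes, "phyloP")
        assert from_wig[0].values == from_bg[0].values

    def test_alignment_fasta(self):
        fasta = io.StringIO(">hg19\nACGT\n>mm9\nAC-T\n")
        block = read_alignment_fasta(fasta)
        assert block.labels == ("hg19", "mm9")
        assert mean_pairwise_identity(block) == pytest.approx(100.0)

    def test_hits_table_with_header(self):
        hits = read_hits_table(io.StringIO("cne_id\tevalue\nHsA\t1e-8\nHsB\t0.2\n"))
        assert hits == [("HsA", 1e-8), ("HsB", 0.2)]
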