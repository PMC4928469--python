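import numpy as np
import pytest

from plastcomp import (
    Alignment,
    GeneFeature,
    PlastomeRecord,
    WindowParams,
    project_regions,
    rank_markers,
    region_variation,
    sliding_window_pi,
)
from plastcomp.diversity import RegionSpan
from plastcomp.errors import IdentityError, PlastcompError

from conftest import random_dna


class TestSlidingWindowPi:
    def test_identical_rows_give_zero_everywhere(self):
        aln = Alignment(["a", "b"], ["ACGT" * 200] * 2)
        assert all(w.pi == 0.0 for w in sliding_window_pi(aln))

    def test_three_row_worked_example(self):
        # pairwise diffs: (a,b)=1, (a,c)=2, (b,c)=1 over 4 sites -> 4/12
        aln = Alignment(["a", "b", "c"], ["AAAA", "AAAT", "AATT"])
        (w,) = sliding_window_pi(aln, WindowParams(window=4, step=4))
        assert w.ungapped_sites == 4
        assert w.pi == pytest.approx(4 / 12)

    def test_pairwise_eight_mismatches_in_400(self):
        rng = np.random.default_rng(17)
        row1 = random_dna(rng, 400)
        row2 = list(row1)
        for pos in rng.choice(400, size=8, replace=False):
            row2[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[row2[pos]]
        aln = Alignment(["a", "b"], [row1, "".join(row2)])
        (w,) = sliding_window_pi(aln, WindowParams(window=400, step=100))
        assert w.pi == pytest.approx(0.02)

    def test_gap_and_n_columns_excluded(self):
        aln = Alignment(["a", "b"], ["ACGT-A", "ACNTCC"])
        (w,) = sliding_window_pi(aln, WindowParams(window=6, step=6))
        # col 2 has N, col 4 a gap -> 4 usable sites, 1 difference (col 5)
        assert w.ungapped_sites == 4
        assert w.pi == pytest.approx(1 / 4)

    def test_all_gap_window_flagged_undefined_not_zero(self):
        aln = Alignment(["a", "b"], ["AAAA----", "AAAA----"])
        wins = sliding_window_pi(aln, WindowParams(window=4, step=4))
        assert wins[0].pi == 0.0
        assert wins[1].pi is None and wins[1].undefined

    def test_window_layout_last_window_short(self):
        aln = Alignment(["a", "b"], ["A" * 1050] * 2)
        wins = sliding_window_pi(aln, WindowParams(window=400, step=100))
        assert wins[0].start == 0 and wins[0].end == 400
        assert wins[-1].end == 1050
        assert all(w2.start - w1.start == 100 for w1, w2 in zip(wins, wins[1:]))

    def test_row_order_invariance(self):
        aln1 = Alignment(["a", "b", "c"], ["AAAA", "AAAT", "AATT"])
        aln2 = Alignment(["c", "b", "a"], ["AATT", "AAAT", "AAAA"])
        pis1 = [w.pi for w in sliding_window_pi(aln1)]
        pis2 = [w.pi for w in sliding_window_pi(aln2)]
        assert pis1 == pis2


class TestRegionVariation:
    def test_identical_region_zero_pic(self):
        aln = Alignment(["a", "b"], ["ACGTACGT"] * 2)
        (r,) = region_variation(aln, [RegionSpan("x", 0, 8)])
        assert r.pic == 0

    def test_substitutions_plus_one_gap_run(self):
        # 3 mismatches and a single 5-column gap run in row 2 -> PIC 4
        row1 = "ACGTACGTACGTACGTACGT"
        row2 = "ATGTACCTAC-----TACCT"
        aln = Alignment(["a", "b"], [row1, row2])
        (r,) = region_variation(aln, [RegionSpan("x", 0, 20)])
        assert r.substitutions == 3
        assert r.indel_events == 1
        assert r.pic == 4

    def test_abutting_gap_runs_in_different_rows_count_twice(self):
        row1 = "AAAAAAAAAA---AAAAAAA"
        row2 = "AAAAAAAAAAAAA---AAAA"
        aln = Alignment(["a", "b"], [row1, row2])
        (r,) = region_variation(aln, [RegionSpan("x", 0, 20)])
        assert r.indel_events == 2

    def test_gap_run_split_by_region_boundary_counts_in_both(self):
        row1 = "AAAAAAAAAAAAAAAAAAAA"
        row2 = "AAAAAAAA----AAAAAAAA"
        aln = Alignment(["a", "b"], [row1, row2])
        whole = region_variation(aln, [RegionSpan("w", 0, 20)])[0]
        halves = region_variation(
            aln, [RegionSpan("l", 0, 10), RegionSpan("r", 10, 20)])
        assert whole.indel_events == 1
        assert sum(h.indel_events for h in halves) == 2  # runs merge when joined

    def test_substitutions_are_additive_over_partitions(self):
        rng = np.random.default_rng(31)
        row1 = random_dna(rng, 300)
        row2 = "".join(
            c if rng.integers(0, 10) else "ACGT"[rng.integers(0, 4)] for c in row1)
        aln = Alignment(["a", "b"], [row1, row2])
        whole = region_variation(aln, [RegionSpan("w", 0, 300)])[0]
        parts = region_variation(
            aln, [RegionSpan(f"p{i}", i * 50, (i + 1) * 50) for i in range(6)])
        assert whole.substitutions == sum(p.substitutions for p in parts)

    def test_out_of_range_region_rejected(self):
        aln = Alignment(["a", "b"], ["ACGT", "ACGT"])
        with pytest.raises(PlastcompError):
            region_variation(aln, [RegionSpan("x", 0, 5)])


class TestProjectRegions:
    def _record_with_genes(self, seq, genes):
        feats = [GeneFeature(n, "CDS", "+", [(s, e)]) for n, s, e in genes]
        return PlastomeRecord("g", seq, features=feats)

    def test_gap_free_projection_is_identity(self):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 400)
        rec = self._record_with_genes(seq, [("geneA", 100, 200)])
        aln = Alignment(["g", "h"], [seq, seq])
        spans = project_regions(rec, aln, 0)
        named = {s.name: (s.start, s.end) for s in spans}
        assert named["geneA"] == (100, 200)

    def test_prefix_gaps_shift_columns(self):
        rng = np.random.default_rng(6)
        seq = random_dna(rng, 300)
        rec = self._record_with_genes(seq, [("geneA", 100, 200)])
        gapped = seq[:50] + "-" * 10 + seq[50:]
        other = random_dna(rng, 310)
        aln = Alignment(["g", "h"], [gapped, other])
        spans = {s.name: (s.start, s.end) for s in project_regions(rec, aln, 0)}
        assert spans["geneA"] == (110, 210)

    def test_igs_named_by_flanking_genes(self):
        rng = np.random.default_rng(7)
        seq = random_dna(rng, 500)
        rec = self._record_with_genes(seq, [("trnH", 10, 80), ("psbA", 150, 400)])
        aln = Alignment(["g", "h"], [seq, seq])
        names = [s.name for s in project_regions(rec, aln, 0)]
        assert names == ["trnH", "trnH-psbA", "psbA"]

    def test_row_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        seq = random_dna(rng, 100)
        rec = self._record_with_genes(seq, [("geneA", 10, 20)])
        aln = Alignment(["g", "h"], [random_dna(rng, 100), seq])
        with pytest.raises(IdentityError):
            project_regions(rec, aln, 0)


class TestRankMarkers:
    def _rv(self, name, pic, length=300, pi=0.01):
        from plastcomp.diversity import RegionVariation
        return RegionVariation(name, 0, length, length, pic, 0, pic, pi)

    def test_short_regions_filtered_out(self):
        regions = [self._rv("a", 9, length=150), self._rv("b", 9, length=200)]
        assert rank_markers(regions) == []  # filter is strictly > 200

    def test_rank_by_variable_sites_descending(self):
        regions = [self._rv("A", 7), self._rv("B", 3), self._rv("C", 9)]
        assert [r.name for r in rank_markers(regions)] == ["C", "A", "B"]

    def test_fewer_than_top_n_returns_all(self):
        regions = [self._rv("A", 7), self._rv("B", 3)]
        assert len(rank_markers(regions, top_n=40)) == 2

    def test_tie_broken_by_pi_then_name(self):
        regions = [
            self._rv("B", 5, pi=0.01),
            self._rv("A", 5, pi=0.01),
            self._rv("C", 5, pi=0.05),
        ]
        assert [r.name for r in rank_markers(regions)] == ["C", "A", "B"]
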