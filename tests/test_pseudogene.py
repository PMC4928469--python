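import numpy as np
import pytest

from plastcomp import (
    AlignScoring,
    assess_integrity,
    find_longest_orf,
    global_align,
)
from plastcomp.errors import InputError, SizeCapError
from plastcomp.synth import random_cds

from conftest import random_dna
from oracles import brute_force_affine_score, brute_force_longest_orf


class TestGlobalAlign:
    def test_identical_strings_align_gap_free(self):
        aln, score = global_align("ACGTACGT", "ACGTACGT")
        assert aln.rows == ["ACGTACGT", "ACGTACGT"]
        assert score == 8

    def test_single_gap_worked_example(self):
        aln, score = global_align(
            "ACGT", "ACT",
            AlignScoring(match=1, mismatch=-1, gap_open=-2, gap_extend=-1))
        assert aln.rows == ["ACGT", "AC-T"]
        assert score == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            global_align("", "ACGT")

    def test_size_cap(self):
        with pytest.raises(SizeCapError):
            global_align("A" * 50_001, "ACGT")

    @pytest.mark.parametrize("seed", range(12))
    def test_score_matches_plain_dp(self, seed):
        rng = np.random.default_rng(seed)
        a = random_dna(rng, int(rng.integers(10, 45)))
        b = random_dna(rng, int(rng.integers(10, 45)))
        s = AlignScoring(match=2, mismatch=-3, gap_open=-5, gap_extend=-2)
        aln, score = global_align(a, b, s)
        assert score == brute_force_affine_score(a, b, 2, -3, -5, -2)
        # and the emitted alignment actually achieves the reported score
        achieved = 0
        in_gap = None
        for ca, cb in zip(*aln.rows):
            if ca == "-" or cb == "-":
                gap_row = 0 if ca == "-" else 1
                achieved += s.gap_extend if in_gap == gap_row else s.gap_open
                in_gap = gap_row
            else:
                achieved += s.match if ca == cb else s.mismatch
                in_gap = None
        assert achieved == score

    def test_affine_prefers_one_long_gap_over_two_short(self):
        # deleting 2 adjacent bases should cost open+extend, not 2 opens
        a = "AAACCGGTTT"
        b = "AAAGGTTT"
        aln, _ = global_align(
            a, b, AlignScoring(match=1, mismatch=-2, gap_open=-3, gap_extend=-1))
        gaps = aln.rows[1].count("-")
        assert gaps == 2
        assert "--" in aln.rows[1]


class TestFindLongestOrf:
    def test_minimal_orf(self):
        orf = find_longest_orf("ATGAAATAA")
        assert (orf.start, orf.end, orf.aa_length) == (0, 9, 2)

    def test_no_stop_means_no_complete_orf(self):
        orf = find_longest_orf("ATGAAAAAAAAAAAAAAA")
        assert orf.aa_length == 0

    def test_orf_found_in_any_forward_frame(self):
        seq = "CC" + "ATG" + "GCT" * 30 + "TAG"
        orf = find_longest_orf(seq)
        assert orf.frame == 2 and orf.aa_length == 31

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 300)
        orf = find_longest_orf(seq)
        expected = brute_force_longest_orf(seq)
        if expected is None:
            assert orf.aa_length == 0
        else:
            assert (orf.start, orf.end, orf.aa_length) == expected


@pytest.fixture(scope="module")
def ref():
    return random_cds(np.random.default_rng(77), 200)  # 600 bp CDS


class TestAssessIntegrity:

    def test_self_is_intact(self, ref):
        rep = assess_integrity(ref, ref)
        assert rep.verdict == "intact"
        assert rep.identity == 1.0
        assert rep.deletion_spans == [] and rep.insertion_spans == []
        assert not rep.frameshift and rep.premature_stops == 0

    def test_synonymous_substitution_stays_intact(self, ref):
        # GGA -> GGG (both glycine), pick a GGx codon or make one
        q = ref[:99] + "GGG" + ref[102:]
        ref2 = ref[:99] + "GGA" + ref[102:]
        rep = assess_integrity(q, ref2)
        assert rep.verdict == "intact"

    def test_frameshifting_deletion_called_pseudogene(self, ref):
        # remove 100 bp (not a multiple of 3) from the middle
        q = ref[:150] + ref[250:]
        rep = assess_integrity(q, ref)
        assert rep.verdict == "pseudogene"
        assert rep.frameshift
        assert sum(e - s for s, e in rep.deletion_spans) == 100

    def test_large_inframe_deletion_reported_with_exact_span(self, ref):
        q = ref[:150] + ref[300:]  # 150 bp, multiple of 3
        rep = assess_integrity(q, ref)
        assert not rep.frameshift
        assert sum(e - s for s, e in rep.deletion_spans) == 150

    def test_premature_stop_flips_verdict(self, ref):
        q = ref[:90] + "TAA" + ref[93:]
        rep = assess_integrity(q, ref)
        assert rep.premature_stops >= 1
        assert rep.verdict == "pseudogene"

    def test_insertion_spans_in_query_coordinates(self, ref):
        q = ref[:120] + "GGGGGG" + ref[120:]
        rep = assess_integrity(q, ref)
        assert rep.insertion_spans and not rep.frameshift
        s, e = rep.insertion_spans[0]
        assert e - s == 6

    def test_invalid_reference_rejected(self):
        with pytest.raises(InputError):
            assess_integrity("ATGAAATAA", "CCCAAATAA")  # no start codon
        with pytest.raises(InputError):
            assess_integrity("ATGAAATAA", "ATGAATAA")  # length not /3

    def test_n_terminal_peptide_exported(self, ref):
        rep = assess_integrity(ref, ref)
        assert rep.n_terminal_peptide.startswith("M")
        assert len(rep.n_terminal_peptide) == 72
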