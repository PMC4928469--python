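import numpy as np
import pytest

from plastcomp import (
    GeneFeature,
    PlastomeRecord,
    base_composition,
    find_inverted_repeats,
    junction_report,
    partition,
    revcomp,
)
from plastcomp.errors import AmbiguousPartitionError

from conftest import random_dna
from oracles import brute_force_max_inverted_pair


class TestFindInvertedRepeats:
    def test_repeat_free_sequence_yields_nothing(self):
        rng = np.random.default_rng(41)
        rec = PlastomeRecord("r", random_dna(rng, 5000), circular=False)
        assert find_inverted_repeats(rec, min_len=1000) is None

    def test_planted_repeat_recovered_and_matches_brute_force(self):
        rng = np.random.default_rng(42)
        x, r, y, z = (random_dna(rng, n) for n in (2000, 1200, 800, 500))
        g = x + r + y + revcomp(r) + z
        rec = PlastomeRecord("planted", g, circular=False)
        pair = find_inverted_repeats(rec, min_len=1000)
        oracle = brute_force_max_inverted_pair(g, 1000)
        assert oracle is not None
        assert (pair.first, pair.second) == oracle[1]
        # the planted coordinates, allowing chance single-base extension
        assert abs(pair.first[0] - 2000) <= 2
        assert abs(pair.first[1] - 3200) <= 2
        assert abs(pair.second[0] - 4000) <= 2
        assert abs(pair.second[1] - 5200) <= 2

    def test_wrapped_repeat_found_on_circular_record(self, toy_genome):
        rec, truth = toy_genome
        # rotate so IRa straddles the origin
        n = rec.length
        shift = n - (truth.partition.ira[0] + truth.partition.ir_length // 2)
        rotated = PlastomeRecord("rot", rec.sequence[-shift:] + rec.sequence[:-shift])
        pair = find_inverted_repeats(rotated, min_len=100)
        assert pair is not None and pair.length == truth.partition.ir_length

    def test_linear_record_cannot_wrap(self, toy_genome):
        rec, truth = toy_genome
        pair = find_inverted_repeats(
            PlastomeRecord("lin", rec.sequence, circular=False), min_len=100)
        assert (pair.first, pair.second) == (truth.partition.irb, truth.partition.ira)


class TestPartition:
    def test_planted_lengths_recovered_exactly(self, toy_genome):
        rec, truth = toy_genome
        pair = find_inverted_repeats(rec, min_len=100)
        part = partition(rec, pair)
        assert part.lsc_length == 3000
        assert part.ssc_length == 700
        assert part.ir_length == 1200

    def test_tiling_identity(self, toy_genome):
        rec, _ = toy_genome
        part = partition(rec, find_inverted_repeats(rec, min_len=100))
        assert part.lsc_length + part.ssc_length + 2 * part.ir_length == rec.length

    def test_ir_copies_are_exact_reverse_complements(self, toy_genome):
        rec, _ = toy_genome
        part = partition(rec, find_inverted_repeats(rec, min_len=100))
        assert revcomp(rec.subseq(*part.irb)) == rec.subseq(*part.ira)

    def test_equal_arcs_are_ambiguous(self):
        rng = np.random.default_rng(43)
        r = random_dna(rng, 300)
        # y starts and ends with A so the repeat cannot chance-extend into it
        y = "A" + random_dna(rng, 498) + "A"
        g = random_dna(rng, 500) + r + y + revcomp(r)
        rec = PlastomeRecord("amb", g, circular=False)
        pair = find_inverted_repeats(rec, min_len=200)
        with pytest.raises(AmbiguousPartitionError):
            partition(rec, pair)

    def test_irb_is_the_copy_upstream_of_ssc(self, toy_genome):
        rec, truth = toy_genome
        part = partition(rec, find_inverted_repeats(rec, min_len=100))
        assert part.irb == truth.partition.irb
        assert part.junctions == truth.partition.junctions


class TestJunctionReport:
    def test_crossing_gene_flanks_sum_to_span(self, toy_genome):
        rec, truth = toy_genome
        part = truth.partition
        j = part.junctions["J(LSC-IRb)"]
        feats = rec.features + [GeneFeature("crossA", "CDS", "+", [(j - 120, j + 60)])]
        rec2 = PlastomeRecord(rec.id, rec.sequence, features=feats)
        rows = junction_report(rec2, part)
        hit = [r for r in rows if r.gene_name == "crossA" and r.note == "crosses"]
        assert len(hit) == 1
        assert hit[0].bases_in_each_flank == (120, 60)
        assert sum(hit[0].bases_in_each_flank) == 180

    def test_interior_gene_reported_near_only_if_nearest(self, toy_genome):
        rec, truth = toy_genome
        part = truth.partition
        j = part.junctions["J(LSC-IRb)"]
        interior = GeneFeature("deep", "CDS", "+", [(j - 520, j - 500)])
        closer = GeneFeature("close", "CDS", "+", [(j - 110, j - 100)])
        rec2 = PlastomeRecord(rec.id, rec.sequence, features=[interior, closer])
        rows = [r for r in junction_report(rec2, part)
                if r.junction == "J(LSC-IRb)"]
        crosses = [r for r in rows if r.note == "crosses"]
        near_up = [r for r in rows if r.note == "near" and r.side == "upstream"]
        assert not crosses
        assert [r.gene_name for r in near_up] == ["close"]
        assert near_up[0].distance == 100

    def test_near_distance_counts_strictly_between(self, toy_genome):
        # a gene starting 10 bp downstream of the junction reports distance 10
        rec, truth = toy_genome
        part = truth.partition
        j = part.junctions["J(IRb-SSC)"]
        g = GeneFeature("ndhF-like", "CDS", "-", [(j + 10, j + 400)])
        rec2 = PlastomeRecord(rec.id, rec.sequence, features=[g])
        rows = [r for r in junction_report(rec2, part)
                if r.junction == "J(IRb-SSC)" and r.note == "near"]
        down = [r for r in rows if r.side == "downstream"]
        assert down and down[0].distance == 10

    def test_empty_features_empty_report(self, toy_genome):
        rec, truth = toy_genome
        bare = PlastomeRecord(rec.id, rec.sequence)
        assert junction_report(bare, truth.partition) == []


class TestBaseComposition:
    def test_simple_sequence(self):
        rows = base_composition(PlastomeRecord("x", "ATGC"))
        assert rows[0].gc_percent == 50.0

    def test_n_bases_excluded(self):
        rows = base_composition(PlastomeRecord("x", "ATGCNNNN"))
        assert rows[0].a + rows[0].c + rows[0].g + rows[0].t == 4
        assert rows[0].gc_percent == 50.0

    def test_rounding_is_half_up_to_one_decimal(self):
        # 5 G/C out of 8 -> 62.5; half-up keeps 62.5; 1/3 GC -> 33.3
        rows = base_composition(PlastomeRecord("x", "GGGCCTAT"))
        assert rows[0].gc_percent == 62.5

    def test_partition_rows_cover_all_regions(self, toy_genome):
        rec, truth = toy_genome
        rows = base_composition(rec, truth.partition)
        assert [r.region for r in rows] == ["total", "LSC", "SSC", "IR"]
        total = rows[0]
        assert total.a + total.c + total.g + total.t == rec.length
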