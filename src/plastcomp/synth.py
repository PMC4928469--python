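"""Synthetic plastomes with planted ground truth.

Every other stage of the toolkit is testable offline against genomes built
here: a circular quadripartite genome (LSC + IRb + SSC + IRa, the IRa an
exact reverse complement of the IRb), planted gene features (CDS/tRNA/rRNA,
some intron-containing, some IR-duplicated, an optional trans-spliced
rps12 analogue, optional junction-crossing genes), planted perfect SSR
tracts in a repeat-sanitised background, and a sister genome diverged by
known substitution and indel processes with the true alignment retained.

Default dimensions and gene plan follow a real Primula-type plastome
(150,859 bp: LSC 82,064 / SSC 17,725 / IR 25,535; 78 + 30 + 4 genes with
7/7/4 IR duplicates, 15 one-intron and 2 two-intron genes); the default
divergence (substitution rate 0.02/site, indel rate 0.002/site with mean
length 4, IR rates scaled by 0.2) mimics the empirical pattern that
variation concentrates in the single-copy regions while the IRs stay
nearly invariant.  Use :meth:`SynthParams.toy` for fast small genomes.

All random draws are integer-based (numpy PCG64), so a seed reproduces the
same genome on any platform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CapacityError, PlastcompError
from .seqio import Alignment, GeneFeature, PlastomeRecord, revcomp
from .ssr import SSRHit, SSRParams, scan_ssrs, _is_primitive
from .structure import (
    QuadripartitePartition,
    all_inverted_pairs,
    find_inverted_repeats,
    partition as derive_partition,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_R = 10 ** 9  # resolution of integer Bernoulli draws


@dataclass(frozen=True)
class SSRRequest:
    """A perfect SSR to plant: motif repeated ``units`` times in ``region``."""

    motif: str
    units: int
    region: str = "LSC"  # LSC | SSC | IR

    def __post_init__(self) -> None:
        if not _is_primitive(self.motif.upper()):
            raise ValueError(f"motif {self.motif!r} is not primitive")
        if self.region not in ("LSC", "SSC", "IR"):
            raise ValueError(f"unknown region {self.region!r}")


@dataclass(frozen=True)
class SynthParams:
    # structure
    lsc_len: int = 82_064
    ssc_len: int = 17_725
    ir_len: int = 25_535
    # gene plan
    n_cds: int = 78
    n_trna: int = 30
    n_rrna: int = 4
    n_ir_dup_cds: int = 7
    n_ir_dup_trna: int = 7
    n_ir_dup_rrna: int = 4
    n_one_intron: int = 15
    n_two_intron: int = 2
    trans_spliced: bool = True
    junction_genes: bool = True
    # gene dimensioning (drawn uniformly per gene)
    cds_codon_range: tuple[int, int] = (100, 400)
    intron_range: tuple[int, int] = (300, 700)
    gap_range: tuple[int, int] = (20, 120)
    rrna_range: tuple[int, int] = (800, 2400)
    # planted repeats
    planted_ssrs: tuple[SSRRequest, ...] = ()
    # divergence process
    sub_rate: float = 0.02
    indel_rate: float = 0.002
    indel_mean_len: float = 4.0
    ir_rate_multiplier: float = 0.2
    # bookkeeping
    seed: int = 0
    sanitize: bool = True
    ssr_params: SSRParams = field(default_factory=SSRParams)
    min_unplanted_ir: int = 50

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.indel_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must be in [0, 1)")
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise ValueError("region lengths must be positive")
        if self.indel_mean_len < 1:
            raise ValueError("mean indel length must be >= 1")

    @classmethod
    def toy(cls, seed: int = 0, **kw) -> "SynthParams":
        """A small fast genome (LSC 3000 / IR 1200 / SSC 700) for tests."""
        defaults = dict(
            lsc_len=3000, ssc_len=700, ir_len=1200,
            n_cds=4, n_trna=2, n_rrna=1,
            n_ir_dup_cds=1, n_ir_dup_trna=1, n_ir_dup_rrna=1,
            n_one_intron=1, n_two_intron=1,
            trans_spliced=False, junction_genes=False,
            cds_codon_range=(40, 120), intron_range=(80, 150),
            gap_range=(10, 40), rrna_range=(200, 400),
            seed=seed,
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class MutationEvent:
    position: int  # genome-A coordinate (anchor position for insertions)
    kind: str      # 'sub' | 'ins' | 'del'
    length: int


@dataclass
class SyntheticTruth:
    """Planted parameters: everything a test needs as ground truth."""

    partition: QuadripartitePartition | None = None
    features: list[GeneFeature] = field(default_factory=list)
    ssr_inventory: list[SSRHit] = field(default_factory=list)
    mutation_log: list[MutationEvent] = field(default_factory=list)
    alignment: Alignment | None = None


def _rand_arr(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, length)]


def _arr_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _reroll(rng: np.random.Generator, arr: np.ndarray, idx: int) -> None:
    old = int(np.where(_BASES == arr[idx])[0][0])
    arr[idx] = _BASES[(old + 1 + int(rng.integers(0, 3))) % 4]


def random_cds(rng: np.random.Generator, n_codons: int, code_stops=("TAA", "TAG", "TGA")) -> str:
    """A valid CDS: ATG, ``n_codons - 2`` random non-stop codons, TAA."""
    if n_codons < 2:
        raise ValueError("need at least start + stop")
    middle = []
    while len(middle) < n_codons - 2:
        codon = _arr_to_str(_rand_arr(rng, 3))
        if codon not in code_stops:
            middle.append(codon)
    return "ATG" + "".join(middle) + "TAA"


# ---------------------------------------------------------------------------
# gene placement


def _place_in_region(rng, names_kinds, region_len, margin, p: SynthParams,
                     end_margin=None):
    """Lay out genes left to right inside one region; returns local features."""
    feats = []
    cursor = margin
    if end_margin is None:
        end_margin = margin
    for name, kind, n_parts in names_kinds:
        cursor += int(rng.integers(*p.gap_range))
        if kind == "CDS":
            total = int(rng.integers(*p.cds_codon_range)) * 3
            per = max(3, total // n_parts // 3 * 3)
            exon_lens = [per] * (n_parts - 1) + [total - per * (n_parts - 1)]
        elif kind == "tRNA":
            exon_lens = [75 // n_parts + 1] * n_parts
        else:
            exon_lens = [int(rng.integers(*p.rrna_range)) for _ in range(n_parts)]
        parts = []
        pos = cursor
        for k, el in enumerate(exon_lens):
            parts.append((pos, pos + el))
            pos += el
            if k < len(exon_lens) - 1:
                pos += int(rng.integers(*p.intron_range))  # intron
        cursor = pos
        if cursor > region_len - end_margin:
            raise CapacityError(
                f"genes do not fit: need > {cursor} bp in a {region_len} bp region"
            )
        strand = "+" if int(rng.integers(0, 2)) == 0 else "-"
        if strand == "-":
            parts = parts[::-1]
        feats.append(GeneFeature(name, kind, strand, parts))
    return feats


def _offset_feature(f: GeneFeature, offset: int) -> GeneFeature:
    return GeneFeature(
        f.gene_name, f.kind, f.strand,
        [(s + offset, e + offset) for s, e in f.parts], f.is_pseudo,
    )


def _mirror_into_ira(f: GeneFeature, ira_start: int, ir_len: int) -> GeneFeature:
    """Map an IR-unit-local feature onto the IRa copy (reverse complement)."""
    parts = [(ira_start + ir_len - e, ira_start + ir_len - s) for s, e in f.parts]
    strand = "-" if f.strand == "+" else "+"
    return GeneFeature(f.gene_name, f.kind, strand, parts, f.is_pseudo)


def _build_features(p: SynthParams, rng) -> list[GeneFeature]:
    L, I, S = p.lsc_len, p.ir_len, p.ssc_len
    margin_l = min(300, L // 10)
    margin_i = min(300, I // 10)
    margin_s = min(300, S // 10)

    n_sc_cds = (p.n_cds - p.n_ir_dup_cds - (1 if p.trans_spliced else 0)
                - (3 if p.junction_genes else 0))
    n_sc_trna = p.n_trna - p.n_ir_dup_trna
    n_sc_rrna = p.n_rrna - p.n_ir_dup_rrna
    if min(n_sc_cds, n_sc_trna, n_sc_rrna) < 0:
        raise CapacityError("more IR-duplicated genes requested than genes")

    # intron genes drawn from the single-copy CDS pool
    if p.n_one_intron + p.n_two_intron > n_sc_cds:
        raise CapacityError("more intron genes requested than single-copy CDS")

    plan_sc = []
    idx = 0
    for _ in range(p.n_two_intron):
        idx += 1
        plan_sc.append((f"cds{idx:02d}", "CDS", 3))
    for _ in range(p.n_one_intron):
        idx += 1
        plan_sc.append((f"cds{idx:02d}", "CDS", 2))
    for _ in range(n_sc_cds - p.n_one_intron - p.n_two_intron):
        idx += 1
        plan_sc.append((f"cds{idx:02d}", "CDS", 1))
    for t in range(n_sc_trna):
        plan_sc.append((f"trn{t + 1:02d}", "tRNA", 1))
    for r in range(n_sc_rrna):
        plan_sc.append((f"rrn{r + 1:02d}", "rRNA", 1))

    # roughly an eighth of the single-copy genes go to the SSC; take them
    # from the tail of the plan (single-exon genes) so the intron-bearing
    # CDS stay in the roomier LSC
    n_to_ssc = max(0, len(plan_sc) // 8)
    plan_lsc = plan_sc[:len(plan_sc) - n_to_ssc]
    plan_ssc = plan_sc[len(plan_sc) - n_to_ssc:]

    plan_ir = []
    for d in range(p.n_ir_dup_cds):
        plan_ir.append((f"cdsIR{d + 1:02d}", "CDS", 1))
    for d in range(p.n_ir_dup_trna):
        plan_ir.append((f"trnIR{d + 1:02d}", "tRNA", 1))
    for d in range(p.n_ir_dup_rrna):
        plan_ir.append((f"rrnIR{d + 1:02d}", "rRNA", 1))

    # junction genes reach into the SSC from both sides; reserve room there
    ssc_start_margin = max(margin_s, 900) if p.junction_genes else margin_s
    ssc_end_margin = max(margin_s, 950) if p.junction_genes else margin_s

    feats: list[GeneFeature] = []
    feats += _place_in_region(rng, plan_lsc, L, margin_l, p)
    ir_local = _place_in_region(rng, plan_ir, I, margin_i, p)
    feats += [_offset_feature(f, L) for f in ir_local]          # IRb copies
    feats += [_mirror_into_ira(f, L + I + S, I) for f in ir_local]  # IRa copies
    feats += [_offset_feature(f, L + I) for f in
              _place_in_region(rng, plan_ssc, S, ssc_start_margin, p,
                               ssc_end_margin)]

    if p.trans_spliced:
        # rps12 analogue: exon 1 late in the LSC, exons 2-3 in both IRs
        # (placed in the reserved IR start margin, clear of junction genes)
        if margin_i < 270 or margin_l < 150:
            raise CapacityError("regions too small for a trans-spliced gene")
        e1 = (L - margin_l, L - margin_l + 114)
        ex23 = GeneFeature("rps12", "CDS", "+", [(150, 230), (240, 266)])
        feats.append(GeneFeature("rps12", "CDS", "+", [e1]))
        feats.append(_offset_feature(ex23, L))
        feats.append(_mirror_into_ira(ex23, L + I + S, I))

    if p.junction_genes:
        n = L + 2 * I + S
        feats.append(GeneFeature("rps19", "CDS", "+", [(L - 160, L + 119)]))
        feats.append(GeneFeature("ndhF", "CDS", "-", [(L + I - 50, L + I + 850)]))
        feats.append(GeneFeature("ycf1", "CDS", "+", [(L + I + S - 900, L + I + S + 240)]))
        for f in feats[-3:]:
            for s, e in f.parts:
                if e > n:
                    raise CapacityError("junction gene spills past the genome end")
    return feats


# ---------------------------------------------------------------------------
# genome assembly and repeat sanitation


class _Cores:
    """The three independent sequence cores (LSC, IR unit, SSC)."""

    def __init__(self, rng, p: SynthParams):
        self.p = p
        self.lsc = _rand_arr(rng, p.lsc_len)
        self.ir = _rand_arr(rng, p.ir_len)
        self.ssc = _rand_arr(rng, p.ssc_len)
        self.protected: list[tuple[str, int, int]] = []  # (core, start, end)

    def assemble(self) -> str:
        ira = _arr_to_str(self.ir)
        return (_arr_to_str(self.lsc) + _arr_to_str(self.ir)
                + _arr_to_str(self.ssc) + revcomp(ira))

    def locate(self, pos: int) -> tuple[str, int]:
        """Map a genome position to (core name, core-local index)."""
        p = self.p
        L, I, S = p.lsc_len, p.ir_len, p.ssc_len
        pos %= L + 2 * I + S
        if pos < L:
            return "lsc", pos
        if pos < L + I:
            return "ir", pos - L
        if pos < L + I + S:
            return "ssc", pos - L - I
        return "ir", I - 1 - (pos - L - I - S)  # IRa mirrors the unit

    def is_protected(self, core: str, idx: int) -> bool:
        return any(c == core and s <= idx < e for c, s, e in self.protected)

    def reroll_genome_pos(self, rng, pos: int) -> bool:
        core, idx = self.locate(pos)
        if self.is_protected(core, idx):
            return False
        _reroll(rng, getattr(self, core), idx)
        return True


def _plant_ssrs(rng, cores: _Cores, p: SynthParams) -> list[SSRHit]:
    L, I, S = p.lsc_len, p.ir_len, p.ssc_len
    inventory: list[SSRHit] = []
    for req in p.planted_ssrs:
        motif = req.motif.upper()
        span = len(motif) * req.units
        core = {"LSC": cores.lsc, "SSC": cores.ssc, "IR": cores.ir}[req.region]
        if span + 20 > len(core):
            raise CapacityError(f"SSR {motif}x{req.units} does not fit in {req.region}")
        name = {"LSC": "lsc", "SSC": "ssc", "IR": "ir"}[req.region]
        for _ in range(100):
            start = int(rng.integers(10, len(core) - span - 10))
            if not any(c == name and not (start + span <= s or e <= start)
                       for c, s, e in cores.protected):
                break
        else:
            raise CapacityError(f"no free slot for SSR {motif}x{req.units}")
        tract = (motif * req.units).encode()
        core[start:start + span] = np.frombuffer(tract, dtype=np.uint8)
        cores.protected.append((name, start, start + span))
        offset = {"lsc": 0, "ir": L, "ssc": L + I}[name]
        inventory.append(SSRHit(motif, len(motif), req.units,
                                offset + start, offset + start + span))
        if name == "ir":  # the tract also appears reverse-complemented in IRa
            ira_start = L + I + S + (I - start - span)
            rc_tract = revcomp(motif * req.units)
            inventory.append(SSRHit(rc_tract[:len(motif)], len(motif), req.units,
                                    ira_start, ira_start + span))
    inventory.sort(key=lambda h: h.start)
    return inventory


def _sanitize(rng, cores: _Cores, p: SynthParams,
              inventory: list[SSRHit]) -> str:
    """Re-randomise until no unplanted SSR or inverted repeat >= 50 bp remains."""
    L, I, S = p.lsc_len, p.ir_len, p.ssc_len
    n = L + 2 * I + S
    expected_first = (L, L + I)
    expected_second = (L + I + S, n)
    planted_keys = {(h.start, h.end, h.motif) for h in inventory}
    for _ in range(100):
        genome = cores.assemble()
        dirty = False
        for h in scan_ssrs(genome, p.ssr_params):
            if (h.start, h.end, h.motif) in planted_keys:
                continue
            dirty = True
            fixed = False
            for pos in range(h.start - 1, h.end + 1):
                if 0 <= pos < n and cores.reroll_genome_pos(rng, pos):
                    fixed = True
            if not fixed:
                raise PlastcompError(
                    f"cannot sanitise SSR at {h.start}: all bases protected"
                )
        rec = PlastomeRecord("tmp", genome, circular=True)
        for pr in all_inverted_pairs(rec, p.min_unplanted_ir):
            if (pr.first, pr.second) == (expected_first, expected_second):
                continue
            dirty = True
            contains_planted = (
                pr.first[0] <= expected_first[0]
                and pr.first[1] >= expected_first[1]
            )
            if contains_planted:
                # chance extension of the planted IR: break the flanks
                flanks = (list(range(pr.first[0], expected_first[0]))
                          + list(range(expected_first[1], pr.first[1])))
                for pos in flanks:
                    cores.reroll_genome_pos(rng, pos)
            else:
                cores.reroll_genome_pos(rng, pr.first[0] + pr.length // 2)
        if not dirty:
            return genome
    raise PlastcompError("repeat sanitation did not converge in 100 iterations")


def generate_plastome(p: SynthParams) -> tuple[PlastomeRecord, SyntheticTruth]:
    """Build a synthetic quadripartite plastome with planted ground truth.

    The background is i.i.d. uniform ACGT, then re-randomised until no
    unplanted SSR meets the screening thresholds and no unplanted inverted
    repeat of >= 50 bp exists; IRa is inserted as the exact reverse
    complement of IRb.  Reproducible from ``p.seed``.
    """
    rng = np.random.default_rng(p.seed)
    L, I, S = p.lsc_len, p.ir_len, p.ssc_len
    n = L + 2 * I + S
    cores = _Cores(rng, p)
    inventory = _plant_ssrs(rng, cores, p)
    genome = _sanitize(rng, cores, p, inventory) if p.sanitize else cores.assemble()
    features = _build_features(p, rng)
    record = PlastomeRecord(f"synthetic-{p.seed}", genome, circular=True,
                            features=features)
    part = QuadripartitePartition(
        lsc=(0, L), irb=(L, L + I), ssc=(L + I, L + I + S), ira=(L + I + S, n),
        genome_length=n,
        junctions={
            "J(LSC-IRb)": L, "J(IRb-SSC)": L + I,
            "J(SSC-IRa)": L + I + S, "J(IRa-LSC)": 0,
        },
    )
    truth = SyntheticTruth(partition=part, features=features,
                           ssr_inventory=inventory)
    return record, truth


# ---------------------------------------------------------------------------
# divergence


def _geometric(rng, mean: float) -> int:
    """Geometric length with the given mean, from integer draws only."""
    m = int(round(mean))
    if m <= 1:
        return 1
    k = 1
    while int(rng.integers(0, m)) != 0 and k < 100:
        k += 1
    return k


def _mutate_segment(rng, seq: str, sub_rate: float, indel_rate: float,
                    mean_len: float):
    """Mutate one region; returns (row_a, row_b, local events).

    Successive indel events always leave at least one unmutated anchor
    column between them (and stay off the region edges) so that each event
    remains one distinct gap run in the true alignment.
    """
    Lr = len(seq)
    sub_thr = int(sub_rate * _R)
    ind_thr = int(indel_rate * _R)
    sub_draw = rng.integers(0, _R, Lr) < sub_thr
    ind_draw = rng.integers(0, _R, Lr) < ind_thr
    is_ins = rng.integers(0, 2, Lr).astype(bool)
    sub_choice = rng.integers(0, 3, Lr)
    alts = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    a_parts: list[str] = []
    b_parts: list[str] = []
    events: list[MutationEvent] = []
    i = 0
    no_del_until = 1  # keep indels off the first/last base of the region
    while i < Lr:
        if ind_draw[i] and 1 <= i < Lr - 1 and i >= no_del_until:
            length = _geometric(rng, mean_len)
            if is_ins[i]:
                ins = _arr_to_str(_rand_arr(rng, length))
                a_parts.append("-" * length)
                b_parts.append(ins)
                events.append(MutationEvent(i, "ins", length))
            else:
                length = min(length, Lr - 1 - i)
                if length > 0:
                    a_parts.append(seq[i:i + length])
                    b_parts.append("-" * length)
                    events.append(MutationEvent(i, "del", length))
                    i += length
                    no_del_until = i + 1
                    continue
        base = seq[i]
        if sub_draw[i] and base in alts:
            b_parts.append(alts[base][int(sub_choice[i])])
            events.append(MutationEvent(i, "sub", 1))
        else:
            b_parts.append(base)
        a_parts.append(base)
        i += 1
    return "".join(a_parts), "".join(b_parts), events


def _rc_row(row: str) -> str:
    """Reverse complement of a gapped row (gaps preserved in place)."""
    comp = str.maketrans("ACGTN-", "TGCAN-")
    return row.translate(comp)[::-1]


def mutate_genome(
    record: PlastomeRecord, p: SynthParams,
    part: QuadripartitePartition | None = None,
) -> tuple[PlastomeRecord, SyntheticTruth]:
    """Derive a diverged sister genome with mutation log and true alignment.

    Substitutions are drawn per site (uniform among the 3 alternatives) and
    indels initiated per site with geometric lengths, insertions and
    deletions equiprobable.  The two IR copies receive identical draws (one
    process applied to the IR unit, mirrored into IRa) so the sister genome
    keeps an exact IR pair; IR rates are scaled by ``p.ir_rate_multiplier``.
    Events are logged once per genome-A copy in genome-A coordinates.
    """
    rng = np.random.default_rng([p.seed, 1])
    n = record.length
    if part is None:
        ir = find_inverted_repeats(record, min_len=min(1000, max(p.min_unplanted_ir, n // 20)))
        if ir is not None:
            part = derive_partition(record, ir)
    canonical = (
        part is not None and part.lsc[0] == 0
        and part.irb[0] == part.lsc[1] and part.ssc[0] == part.irb[1]
        and part.ira[0] == part.ssc[1] and part.ira[1] == n
    )
    if part is not None and not canonical:
        warnings.warn("partition not in canonical LSC-IRb-SSC-IRa order from "
                      "position 0; mutating without IR coupling")
    events: list[MutationEvent] = []
    if part is None or not canonical:
        a_row, b_row, local = _mutate_segment(
            rng, record.sequence, p.sub_rate, p.indel_rate, p.indel_mean_len)
        events = local
    else:
        L, I, S = part.lsc_length, part.ir_length, part.ssc_length
        mult = p.ir_rate_multiplier
        a_l, b_l, ev_l = _mutate_segment(
            rng, record.subseq(*part.lsc), p.sub_rate, p.indel_rate, p.indel_mean_len)
        a_i, b_i, ev_i = _mutate_segment(
            rng, record.subseq(*part.irb), p.sub_rate * mult,
            p.indel_rate * mult, p.indel_mean_len)
        a_s, b_s, ev_s = _mutate_segment(
            rng, record.subseq(*part.ssc), p.sub_rate, p.indel_rate, p.indel_mean_len)
        a_row = a_l + a_i + a_s + _rc_row(a_i)
        b_row = b_l + b_i + b_s + _rc_row(b_i)
        events += [replace(e, position=e.position) for e in ev_l]
        events += [replace(e, position=L + e.position) for e in ev_i]
        events += [replace(e, position=L + I + e.position) for e in ev_s]
        ira0 = L + I + S
        for e in ev_i:  # mirrored occurrences in the IRa copy
            if e.kind == "ins":
                events.append(MutationEvent(ira0 + I - e.position, "ins", e.length))
            else:
                events.append(MutationEvent(
                    ira0 + I - e.position - e.length, e.kind, e.length))
    mutated_seq = b_row.replace("-", "")
    aln = Alignment([record.id, record.id + "-sister"], [a_row, b_row])
    if a_row.replace("-", "") != record.sequence:
        raise PlastcompError("true alignment does not reproduce genome A")
    mutated = PlastomeRecord(record.id + "-sister", mutated_seq,
                             circular=record.circular)
    events.sort(key=lambda e: e.position)
    truth = SyntheticTruth(partition=part, mutation_log=events, alignment=aln)
    return mutated, truth


def generate_pair(
    p: SynthParams,
) -> tuple[PlastomeRecord, PlastomeRecord, SyntheticTruth]:
    """Generate a genome and its diverged sister; truth carries everything."""
    rec_a, truth_a = generate_plastome(p)
    rec_b, truth_b = mutate_genome(rec_a, p, truth_a.partition)
    truth = SyntheticTruth(
        partition=truth_a.partition,
        features=truth_a.features,
        ssr_inventory=truth_a.ssr_inventory,
        mutation_log=truth_b.mutation_log,
        alignment=truth_b.alignment,
    )
    return rec_a, rec_b, truth
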