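"""Gene accounting: category counts, IR duplicates, introns, pseudogenes.

Reproduces the classic plastome gene-content table: unique genes by category
(protein-coding / tRNA / rRNA), genes present twice because they lie in the
inverted repeats, intron-containing genes derived from exon counts, the
trans-spliced rps12 case, overlapping reading frames, and pseudogenes kept
out of the functional totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .seqio import GeneFeature, PlastomeRecord
from .structure import QuadripartitePartition, _gene_span

#: Parts separated by more than this many bases are treated as trans-spliced
#: pieces rather than exons of one cis-spliced transcript (plastid introns
#: are well under this size).
TRANS_SPLICE_GAP = 5000

_CODING_KINDS = {"CDS": "protein_coding", "tRNA": "trna", "rRNA": "rrna"}


@dataclass
class GeneCensus:
    total_genes: int = 0
    protein_coding: int = 0
    trna: int = 0
    rrna: int = 0
    duplicated_in_ir: dict[str, set[str]] = field(default_factory=dict)
    one_intron: set[str] = field(default_factory=set)
    two_intron: set[str] = field(default_factory=set)
    trans_spliced: set[str] = field(default_factory=set)
    pseudogenes: set[str] = field(default_factory=set)


@dataclass
class OverlapPair:
    gene_a: str
    gene_b: str
    overlap_length: int
    frame_offset: int  # difference of reading frames at the overlap, mod 3


def _in_region(span: tuple[int, int], region: tuple[int, int], n: int) -> bool:
    """Is the gene span entirely inside the (possibly wrapped) region?"""
    s, e = span
    rs, re_ = region
    off = (s - rs) % n
    return off + (e - s) <= re_ - rs


def _is_trans_spliced(feats: list[GeneFeature], n: int) -> bool:
    """Parts split across distant loci (e.g. rps12: exon 1 in the LSC, exons
    2-3 in the IRs) signal trans-splicing."""
    parts: list[tuple[int, int]] = []
    for f in feats:
        parts.extend(f.parts)
    if len(parts) < 2:
        return False
    parts = sorted((s % n, s % n + ((e - s) % n or (e - s))) for s, e in parts)
    gaps = []
    for (s1, e1), (s2, e2) in zip(parts, parts[1:]):
        gaps.append(s2 - e1)
    gaps.append(n - parts[-1][1] + parts[0][0])  # wrap-around gap
    # distant pieces: more than one large inter-part gap around the circle
    large = sum(1 for g in gaps if g > TRANS_SPLICE_GAP)
    return large >= 2


def census(
    record: PlastomeRecord, part: QuadripartitePartition | None = None
) -> GeneCensus:
    """Count genes once per unique name, classify introns and IR duplicates.

    Pseudogenes are excluded from the category counts and listed separately,
    so ``total_genes = protein_coding + trna + rrna``.  A gene is duplicated
    in the IR when two same-name features lie one in each IR copy (requires
    a partition).  Intron classes follow exon counts of cis-spliced genes:
    2 parts = one intron, 3 parts = two introns.
    """
    n = record.length
    out = GeneCensus(duplicated_in_ir={k: set() for k in _CODING_KINDS.values()})
    by_name: dict[str, list[GeneFeature]] = {}
    for f in record.features:
        by_name.setdefault(f.gene_name, []).append(f)
    for name, feats in sorted(by_name.items()):
        if any(f.is_pseudo for f in feats):
            out.pseudogenes.add(name)
            continue
        kinds = {f.kind for f in feats}
        kind = next(iter(kinds & _CODING_KINDS.keys()), "other")
        if kind == "other":
            continue
        category = _CODING_KINDS[kind]
        # two identical-structure copies are an IR duplication; same-name
        # features with differing exon structure are trans-spliced pieces
        copies = len({tuple(sorted(e - s for s, e in f.parts)) for f in feats})
        is_trans = len(feats) > 1 and copies > 1 and _is_trans_spliced(feats, n)
        if len(feats) > 2 and not is_trans:
            warnings.warn(f"{name}: {len(feats)} same-name copies; counted once")
        setattr(out, category, getattr(out, category) + 1)
        out.total_genes += 1
        if part is not None and len(feats) >= 2 and not is_trans:
            spans = [_gene_span(f, n) for f in feats]
            in_irb = any(_in_region(sp, part.irb, n) for sp in spans)
            in_ira = any(_in_region(sp, part.ira, n) for sp in spans)
            if in_irb and in_ira:
                out.duplicated_in_ir[category].add(name)
        if is_trans:
            out.trans_spliced.add(name)
        else:
            exons = max(f.exon_count for f in feats)
            if exons == 2:
                out.one_intron.add(name)
            elif exons == 3:
                out.two_intron.add(name)
    return out


def overlap_report(record: PlastomeRecord) -> list[OverlapPair]:
    """All unordered CDS pairs sharing genomic sequence, with overlap length
    and reading-frame offset (0 means same frame)."""
    n = record.length
    cds = [f for f in record.features if f.kind == "CDS" and not f.is_pseudo]
    out: list[OverlapPair] = []
    for i, fa in enumerate(cds):
        sa, ea = _gene_span(fa, n)
        for fb in cds[i + 1:]:
            if fa.gene_name == fb.gene_name:
                continue
            sb, eb = _gene_span(fb, n)
            lo = max(sa, sb)
            hi = min(ea, eb)
            if hi <= lo:
                continue
            out.append(OverlapPair(
                fa.gene_name, fb.gene_name, hi - lo, (sb - sa) % 3
            ))
    return out
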