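"""Sliding-window nucleotide diversity (Pi) and PIC-based marker ranking.

Pi is the average per-site pairwise difference between aligned sequences.
Columns containing a gap or an N in any row are excluded (per-column
exclusion; for pairwise alignments this coincides with pairwise deletion).
The default window of 400 alignment columns advancing by 100 (i.e. adjacent
windows overlap by 300) matches common DnaSP practice for plastome scans.

Potentially informative characters (PIC) of a region are counted as
nucleotide substitutions plus indel events, where one indel event is one
maximal run of gap characters in a single row -- a 1 bp and a 400 bp gap
each count once.  Candidate markers are ranked by that count, requiring a
minimum aligned length so that very short spacers do not outrank usable
loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IdentityError, PlastcompError
from .seqio import Alignment, PlastomeRecord


@dataclass(frozen=True)
class WindowParams:
    window: int = 400
    step: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window:
            raise ValueError("need 0 < step <= window")


@dataclass
class WindowDiversity:
    start: int
    end: int
    ungapped_sites: int
    diff_sites: int
    pi: float | None  # None when no ungapped site exists in the window

    @property
    def undefined(self) -> bool:
        return self.pi is None


@dataclass
class RegionSpan:
    name: str
    start: int  # alignment columns, 0-based half-open
    end: int


@dataclass
class RegionVariation:
    name: str
    start: int
    end: int
    aligned_length: int
    substitutions: int
    indel_events: int
    pic: int
    pi: float | None

    def bed_fields(self):
        return ("aln", self.start, self.end, self.name, self.pic, "+")


def _column_matrix(aln: Alignment) -> np.ndarray:
    return np.vstack([
        np.frombuffer(row.encode(), dtype=np.uint8) for row in aln.rows
    ])


def _pair_stats(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column: validity mask, any-difference mask, pairwise-diff counts."""
    gap, nn = ord("-"), ord("N")
    valid = ~np.any((mat == gap) | (mat == nn), axis=0)
    k = mat.shape[0]
    pair_diffs = np.zeros(mat.shape[1], dtype=np.int64)
    for i in range(k):
        for j in range(i + 1, k):
            pair_diffs += (mat[i] != mat[j])
    differs = pair_diffs > 0
    return valid, differs, pair_diffs


def sliding_window_pi(
    aln: Alignment, p: WindowParams | None = None
) -> list[WindowDiversity]:
    """Nucleotide diversity in overlapping windows of alignment columns.

    For two rows pi is the fraction of differing ungapped sites; for n rows
    it is Nei's average pairwise difference per ungapped site.  A window
    with no ungapped site is emitted with ``pi=None`` rather than dropped,
    so window counts are predictable.
    """
    p = p or WindowParams()
    mat = _column_matrix(aln)
    valid, differs, pair_diffs = _pair_stats(mat)
    npairs = aln.n_rows * (aln.n_rows - 1) // 2
    out: list[WindowDiversity] = []
    s = 0
    while True:
        e = min(s + p.window, aln.n_cols)
        v = valid[s:e]
        ungapped = int(v.sum())
        diffs = int((differs[s:e] & v).sum())
        if ungapped == 0:
            pi = None
        else:
            pi = float(pair_diffs[s:e][v].sum()) / (npairs * ungapped)
        out.append(WindowDiversity(s, e, ungapped, diffs, pi))
        if s + p.window >= aln.n_cols:
            break
        s += p.step
    return out


def region_variation(
    aln: Alignment, regions: list[RegionSpan]
) -> list[RegionVariation]:
    """Substitutions, indel events and PIC per labelled alignment span.

    Substitutions are ungapped mismatching columns within the span
    (N-containing columns excluded); indel events are maximal per-row gap
    runs within the span, each counted once regardless of length.
    """
    mat = _column_matrix(aln)
    valid, differs, pair_diffs = _pair_stats(mat)
    gap = ord("-")
    is_gap = mat == gap
    npairs = aln.n_rows * (aln.n_rows - 1) // 2
    out: list[RegionVariation] = []
    for reg in regions:
        if not (0 <= reg.start <= reg.end <= aln.n_cols):
            raise PlastcompError(
                f"region {reg.name!r} [{reg.start},{reg.end}) outside alignment "
                f"of {aln.n_cols} columns"
            )
        v = valid[reg.start:reg.end]
        subs = int((differs[reg.start:reg.end] & v).sum())
        events = 0
        for r in range(aln.n_rows):
            g = is_gap[r, reg.start:reg.end]
            padded = np.concatenate(([False], g, [False]))
            events += int(np.count_nonzero(padded[1:] & ~padded[:-1]))
        ungapped = int(v.sum())
        if ungapped:
            pi = float(pair_diffs[reg.start:reg.end][v].sum()) / (npairs * ungapped)
        else:
            pi = None
        out.append(RegionVariation(
            reg.name, reg.start, reg.end, reg.end - reg.start,
            subs, events, subs + events, pi,
        ))
    return out


def project_regions(
    record: PlastomeRecord, aln: Alignment, row: int = 0
) -> list[RegionSpan]:
    """Map one genome's gene/IGS annotation onto alignment columns.

    Each gene becomes a span named by its symbol; each intergenic interval
    becomes a span named ``geneA-geneB`` after its flanking genes.  The
    named alignment row must reproduce the record's sequence exactly.
    """
    seq = aln.ungapped(row)
    if seq != record.sequence:
        raise IdentityError(
            f"alignment row {row} does not match record {record.id!r}"
        )
    row_str = aln.rows[row]
    col_of = np.flatnonzero(
        np.frombuffer(row_str.encode(), dtype=np.uint8) != ord("-")
    )  # col_of[pos] = alignment column of sequence position pos

    def span_cols(s: int, e: int) -> tuple[int, int]:
        return int(col_of[s]), int(col_of[e - 1]) + 1

    n = record.length
    genes = []
    for f in record.features:
        s, e = f.span(n)
        if e > n:  # wrapped gene: cannot be projected on a linear alignment
            continue
        genes.append((s, e, f.gene_name))
    genes.sort()
    out: list[RegionSpan] = []
    prev_end, prev_name = None, None
    for s, e, name in genes:
        if prev_end is not None and s > prev_end:
            cs, ce = span_cols(prev_end, s)
            out.append(RegionSpan(f"{prev_name}-{name}", cs, ce))
        cs, ce = span_cols(s, e)
        out.append(RegionSpan(name, cs, ce))
        if prev_end is None or e > prev_end:
            prev_end, prev_name = e, name
    return out


def rank_markers(
    regions: list[RegionVariation], top_n: int = 40, min_aligned_len: int = 200
) -> list[RegionVariation]:
    """Rank candidate marker regions by variable sites.

    Regions with aligned length > ``min_aligned_len`` are ranked by
    substitutions + indel events (descending), ties broken by pi
    (descending) then name; at most ``top_n`` are returned.
    """
    survivors = [r for r in regions if r.aligned_length > min_aligned_len]
    survivors.sort(key=lambda r: (-r.pic, -(r.pi or 0.0), r.name))
    return survivors[:top_n]
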