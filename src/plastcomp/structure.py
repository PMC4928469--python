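"""Quadripartite structure: inverted-repeat detection, partition, junctions.

A canonical plastome is circular with two exact reverse-complement copies of
an inverted repeat (IRa/IRb, typically 20-30 kb) separating a large and a
small single-copy region (LSC, SSC).  This module detects the IR pair de
novo by exact matching, derives the LSC/IRb/SSC/IRa partition and its four
junctions, computes per-region base composition, and reports the genes that
cross or flank each single-copy/IR junction.

IR detection anchors k-mer matches (default k = 25) between the sequence and
its reverse complement, extends each anchor to a maximal exact match, and
keeps the longest pair of disjoint intervals.  Circular records are searched
on the doubled sequence so repeats spanning the origin are found, with
coordinates normalised back to the circle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .errors import AmbiguousPartitionError, PlastcompError
from .seqio import GeneFeature, PlastomeRecord, revcomp

DEFAULT_MIN_IR_LEN = 1000
_ANCHOR_K = 25

Interval = tuple[int, int]  # 0-based half-open; end may exceed n when wrapped


def _interval_len(iv: Interval) -> int:
    return iv[1] - iv[0]


@dataclass(frozen=True)
class IRPair:
    """A pair of disjoint intervals that are exact reverse complements."""

    first: Interval   # smaller normalised start
    second: Interval
    length: int


@dataclass
class QuadripartitePartition:
    """The four regions and four junction positions of a plastome.

    Intervals are 0-based half-open on the deposited strand; an interval with
    ``end > genome_length`` wraps the origin.  A junction position is the
    index of the first base of the downstream region, so the physical
    boundary lies between ``position - 1`` and ``position``.
    """

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    genome_length: int
    junctions: dict[str, int] = field(default_factory=dict)

    @property
    def ir_length(self) -> int:
        return _interval_len(self.irb)

    @property
    def lsc_length(self) -> int:
        return _interval_len(self.lsc)

    @property
    def ssc_length(self) -> int:
        return _interval_len(self.ssc)

    def region_of(self, pos: int) -> str:
        """Name of the region containing genomic position ``pos``."""
        pos %= self.genome_length
        for name in ("lsc", "irb", "ssc", "ira"):
            s, e = getattr(self, name)
            if s <= pos < e or (e > self.genome_length and pos < e - self.genome_length):
                return name.upper().replace("IRB", "IRb").replace("IRA", "IRa")
        raise PlastcompError("partition does not tile the genome")


@dataclass
class JunctionGene:
    """A gene crossing, or nearest to, one SC-IR junction."""

    gene_name: str
    junction: str
    note: str  # 'crosses' | 'near'
    bases_in_each_flank: tuple[int, int] | None = None
    distance: int | None = None
    side: str | None = None  # 'upstream' | 'downstream' for near genes


@dataclass
class BaseComposition:
    region: str
    a: int
    c: int
    g: int
    t: int
    gc_percent: float


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# IR detection


def _maximal_inverted_matches(t: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal exact matches (i, j, L) between ``t`` and ``revcomp(t)``.

    Every maximal match of length >= min_len is reported at least once.
    N never matches.
    """
    m = len(t)
    k = min(_ANCHOR_K, min_len)
    rc = revcomp(t)
    index: dict[str, list[int]] = {}
    for j in range(m - k + 1):
        kmer = rc[j:j + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(j)
    step = max(1, min_len - k + 1)
    seen: dict[int, list[tuple[int, int]]] = {}  # diagonal -> covered i-extents
    runs: list[tuple[int, int, int]] = []
    for q in range(0, m - k + 1, step):
        kmer = t[q:q + k]
        if "N" in kmer:
            continue
        for j in index.get(kmer, ()):
            d = q - j
            covered = seen.setdefault(d, [])
            if any(s <= q < e for s, e in covered):
                continue
            i0, j0 = q, j
            while i0 > 0 and j0 > 0 and t[i0 - 1] == rc[j0 - 1] != "N":
                i0 -= 1
                j0 -= 1
            i1, j1 = q + k, j + k
            while i1 < m and j1 < m and t[i1] == rc[j1] != "N":
                i1 += 1
                j1 += 1
            covered.append((i0, i1))
            if i1 - i0 >= min_len:
                runs.append((i0, j0, i1 - i0))
    return runs


def _circular_overlap(a: Interval, b: Interval, n: int) -> bool:
    """Do two (possibly wrapped) intervals share any position on the circle?"""
    (s1, e1), (s2, e2) = a, b
    if (s2 - s1) % n < e1 - s1:
        return True
    if (s1 - s2) % n < e2 - s2:
        return True
    return False


def all_inverted_pairs(record: PlastomeRecord, min_len: int) -> list[IRPair]:
    """Every maximal pair of disjoint exact inverted repeats >= ``min_len``."""
    s = record.sequence
    n = len(s)
    t = s + s if record.circular else s
    m = len(t)
    pairs: set[tuple[Interval, Interval]] = set()
    rejected_overlapping = 0
    for i0, j0, L in _maximal_inverted_matches(t, min_len):
        # rc[j] is the complement of t[m-1-j]; the partner copy is:
        b0, b1 = m - j0 - L, m - j0
        a = (i0 % n, i0 % n + L)
        b = (b0 % n, b0 % n + L)
        if record.circular and 2 * L > n:
            continue  # copies cannot both fit disjointly on the circle
        if _circular_overlap(a, b, n):
            rejected_overlapping += 1
            continue
        first, second = sorted((a, b))
        pairs.add((first, second))
    if rejected_overlapping and not pairs:
        warnings.warn(
            f"{record.id}: rejected {rejected_overlapping} overlapping "
            "inverted-repeat candidate(s)"
        )
    return [IRPair(a, b, _interval_len(a)) for a, b in sorted(pairs)]


def find_inverted_repeats(
    record: PlastomeRecord, min_len: int = DEFAULT_MIN_IR_LEN
) -> IRPair | None:
    """Longest pair of disjoint intervals that are exact reverse complements.

    Each copy is at least ``min_len`` bases and extended maximally on both
    ends; the search respects circularity.  Returns ``None`` when no such
    pair exists.  Among co-maximal pairs the one with the leftmost start
    wins (with a warning).
    """
    if record.length < 2 * min_len:
        raise PlastcompError(
            f"sequence length {record.length} < 2*min_len ({2 * min_len})"
        )
    pairs = all_inverted_pairs(record, min_len)
    if not pairs:
        return None
    best_len = max(p.length for p in pairs)
    best = [p for p in pairs if p.length == best_len]
    if len(best) > 1:
        warnings.warn(
            f"{record.id}: {len(best)} co-maximal inverted-repeat pairs; "
            "keeping the leftmost"
        )
    return min(best, key=lambda p: p.first[0])


# ---------------------------------------------------------------------------
# partition


def partition(record: PlastomeRecord, ir_pair: IRPair) -> QuadripartitePartition:
    """Derive the LSC/IRb/SSC/IRa partition from a detected IR pair.

    The longer inter-IR arc becomes the LSC, the shorter the SSC; IRb is the
    IR copy immediately upstream of the SSC on the deposited strand,
    matching the conventional LSC-IRb-SSC-IRa layout.
    """
    n = record.length
    a, b = ir_pair.first, ir_pair.second
    arc_after_a = ((a[1] % n), (a[1] % n) + (b[0] - a[1] % n) % n)
    arc_after_b = ((b[1] % n), (b[1] % n) + (a[0] - b[1] % n) % n)
    if _interval_len(arc_after_a) == _interval_len(arc_after_b):
        raise AmbiguousPartitionError(
            "the two single-copy arcs have equal length; cannot name LSC/SSC"
        )
    if _interval_len(arc_after_a) > _interval_len(arc_after_b):
        lsc, ssc = arc_after_a, arc_after_b
        irb, ira = b, a  # SSC follows b
    else:
        ssc, lsc = arc_after_a, arc_after_b
        irb, ira = a, b
    part = QuadripartitePartition(
        lsc=lsc, irb=irb, ssc=ssc, ira=ira, genome_length=n,
        junctions={
            "J(LSC-IRb)": irb[0] % n,
            "J(IRb-SSC)": ssc[0] % n,
            "J(SSC-IRa)": ira[0] % n,
            "J(IRa-LSC)": lsc[0] % n,
        },
    )
    total = part.lsc_length + part.ssc_length + 2 * part.ir_length
    if total != n:
        raise PlastcompError(
            f"partition does not tile the genome ({total} != {n})"
        )
    if revcomp(record.subseq(*irb)) != record.subseq(*ira):
        raise PlastcompError("IRb is not the exact reverse complement of IRa")
    return part


# ---------------------------------------------------------------------------
# junction report


def _gene_span(f: GeneFeature, n: int) -> tuple[int, int]:
    s, e = f.span(n)
    return s % n, s % n + (e - s)


def junction_report(
    record: PlastomeRecord, part: QuadripartitePartition
) -> list[JunctionGene]:
    """Genes crossing each SC-IR junction, plus the nearest gene on each side.

    A gene crosses a junction when its span contains bases on both sides of
    the boundary; its two flank lengths then sum to the span length.  For
    each side of each junction the nearest non-crossing gene is reported
    with its distance (bases strictly between the boundary and the closer
    gene end).
    """
    n = record.length
    out: list[JunctionGene] = []
    for label, j in part.junctions.items():
        nearest_up: tuple[int, str] | None = None
        nearest_down: tuple[int, str] | None = None
        for f in record.features:
            s, e = _gene_span(f, n)
            length = e - s
            d = (j - s) % n
            if 1 <= d <= length - 1:
                out.append(JunctionGene(
                    f.gene_name, label, "crosses",
                    bases_in_each_flank=(d, length - d),
                ))
                continue
            dist_up = (j - (e % n)) % n       # gene ends before the boundary
            dist_down = (s - j) % n           # gene starts after the boundary
            if dist_up <= dist_down:
                if nearest_up is None or dist_up < nearest_up[0]:
                    nearest_up = (dist_up, f.gene_name)
            else:
                if nearest_down is None or dist_down < nearest_down[0]:
                    nearest_down = (dist_down, f.gene_name)
        if nearest_up is not None:
            out.append(JunctionGene(
                nearest_up[1], label, "near",
                distance=nearest_up[0], side="upstream",
            ))
        if nearest_down is not None:
            out.append(JunctionGene(
                nearest_down[1], label, "near",
                distance=nearest_down[0], side="downstream",
            ))
    return out


# ---------------------------------------------------------------------------
# base composition


def _composition_row(region: str, seq: str) -> BaseComposition:
    a, c, g, t = (seq.count(ch) for ch in "ACGT")
    denom = a + c + g + t
    gc = _round_half_up(100.0 * (g + c) / denom, 1) if denom else 0.0
    return BaseComposition(region, a, c, g, t, gc)


def base_composition(
    record: PlastomeRecord, part: QuadripartitePartition | None = None
) -> list[BaseComposition]:
    """Per-region A/C/G/T counts and GC percentage (one decimal, half-up).

    N bases are excluded from all tallies.  With a partition, rows for the
    total, LSC, SSC and IR (one copy) are produced; otherwise total only.
    """
    rows = [_composition_row("total", record.sequence)]
    if part is not None:
        rows.append(_composition_row("LSC", record.subseq(*part.lsc)))
        rows.append(_composition_row("SSC", record.subseq(*part.ssc)))
        rows.append(_composition_row("IR", record.subseq(*part.irb)))
    return rows
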