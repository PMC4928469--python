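"""Coding-integrity assessment of a locus against a functional ortholog.

Plastid loci such as accD and infA lose function through deletions,
frameshifts and premature stop codons.  Given a query locus and an intact
reference CDS, this module aligns the two with an affine-gap global
aligner, derives deletion/insertion spans, translates the query in the
reference frame (so indels propagate frame shifts downstream), counts
premature stops, measures the longest remaining ORF, and calls a verdict:

    pseudogene  iff  premature stops > 0, or a frameshift (net indel length
    not divisible by 3), or the longest ORF falls below a configurable
    fraction (default 50%) of the reference protein length.

The plastid/bacterial genetic code (NCBI table 11) is the default.
Reverse-strand ORFs are not searched: loci are supplied in annotated
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .errors import InputError, SizeCapError
from .seqio import Alignment

_NEG = -(10 ** 9)
_SIZE_CAP = 50_000


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap scores; a gap of length L costs open + (L-1)*extend."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.mismatch >= self.match:
            raise ValueError("mismatch score must be below match score")


@dataclass
class LongestORF:
    start: int = 0
    end: int = 0  # includes the stop codon
    aa_length: int = 0
    frame: int | None = None


@dataclass
class IntegrityReport:
    gene_name: str
    ref_length: int
    identity: float
    deletion_spans: list[tuple[int, int]] = field(default_factory=list)
    insertion_spans: list[tuple[int, int]] = field(default_factory=list)
    frameshift: bool = False
    premature_stops: int = 0
    longest_orf_aa: int = 0
    verdict: str = "intact"
    n_terminal_peptide: str = ""  # first 72 query codons, for external predictors


def _codon_sets(code: int) -> tuple[set[str], set[str]]:
    table = CodonTable.unambiguous_dna_by_id[code]
    return set(table.start_codons), set(table.stop_codons)


def _translate(seq: str, code: int) -> str:
    table = CodonTable.unambiguous_dna_by_id[code]
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        if codon in table.stop_codons:
            out.append("*")
        else:
            out.append(table.forward_table.get(codon, "X"))
    return "".join(out)


# ---------------------------------------------------------------------------
# affine-gap global alignment (Gotoh), vectorised over alignment rows


def global_align(
    a: str, b: str, s: AlignScoring | None = None,
    names: tuple[str, str] = ("a", "b"),
) -> tuple[Alignment, int]:
    """Optimal affine-gap global alignment of two DNA strings.

    Traceback is deterministic: on ties prefer the diagonal (match state),
    then up (gap in ``b``), then left (gap in ``a``).  Returns the
    alignment and its score.
    """
    s = s or AlignScoring()
    if not a or not b:
        raise InputError("global_align requires two non-empty sequences")
    if len(a) > _SIZE_CAP or len(b) > _SIZE_CAP:
        raise SizeCapError(
            f"sequences above {_SIZE_CAP} bp; use an external aligner"
        )
    m, n = len(a), len(b)
    bo = np.frombuffer(b.encode(), dtype=np.uint8)
    open_, ext = s.gap_open, s.gap_extend

    # state 0 = M (diagonal), 1 = X (up, gap in b), 2 = Y (left, gap in a)
    ptrM = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrX = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrY = np.zeros((m + 1, n + 1), dtype=np.int8)

    Mprev = np.full(n + 1, _NEG, dtype=np.int64)
    Xprev = np.full(n + 1, _NEG, dtype=np.int64)
    Yprev = np.full(n + 1, _NEG, dtype=np.int64)
    Mprev[0] = 0
    if n:
        Yprev[1:] = open_ + ext * np.arange(n, dtype=np.int64)
        ptrY[0, 1:] = 2
        ptrY[0, 1] = 0
    js = np.arange(1, n + 1, dtype=np.int64)

    for i in range(1, m + 1):
        ai = ord(a[i - 1])
        subs = np.where(bo == ai, s.match, s.mismatch).astype(np.int64)

        best_prev = np.maximum(Mprev, np.maximum(Xprev, Yprev))
        M = np.full(n + 1, _NEG, dtype=np.int64)
        M[1:] = best_prev[:-1] + subs
        pm = np.full(n + 1, 2, dtype=np.int8)
        pm[1:] = np.where(
            Mprev[:-1] == best_prev[:-1], 0,
            np.where(Xprev[:-1] == best_prev[:-1], 1, 2),
        )
        ptrM[i] = pm

        x_open_m = Mprev + open_
        x_ext = Xprev + ext
        x_open_y = Yprev + open_
        X = np.maximum(x_open_m, np.maximum(x_ext, x_open_y))
        X[0] = open_ + ext * (i - 1)
        px = np.where(x_open_m == X, 0, np.where(x_ext == X, 1, 2)).astype(np.int8)
        px[0] = 0 if i == 1 else 1
        ptrX[i] = px

        # Y has an in-row recurrence; solve with a running maximum:
        #   Y[j] = j*ext + max_{k<j} (W[k] - (k+1)*ext),  W = max(M, X) + open
        W = np.maximum(M, X) + open_
        Y = np.full(n + 1, _NEG, dtype=np.int64)
        if n:
            shifted = (W - (np.arange(n + 1, dtype=np.int64) + 1) * ext)[:-1]
            Y[1:] = js * ext + np.maximum.accumulate(shifted)
            y_from_m = M[:-1] + open_
            y_from_x = X[:-1] + open_
            py = np.full(n + 1, 2, dtype=np.int8)
            py[1:] = np.where(
                y_from_m == Y[1:], 0, np.where(y_from_x == Y[1:], 1, 2)
            )
            ptrY[i] = py

        Mprev, Xprev, Yprev = M, X, Y

    finals = (Mprev[n], Xprev[n], Yprev[n])
    score = max(finals)
    state = finals.index(score)  # ties: M, then X, then Y

    ra, rb = [], []
    i, j = m, n
    while i > 0 or j > 0:
        if i == 0:
            state = 2
        elif j == 0:
            state = 1
        if state == 0:
            ra.append(a[i - 1]); rb.append(b[j - 1])
            state = int(ptrM[i, j]); i -= 1; j -= 1
        elif state == 1:
            ra.append(a[i - 1]); rb.append("-")
            state = int(ptrX[i, j]); i -= 1
        else:
            ra.append("-"); rb.append(b[j - 1])
            state = int(ptrY[i, j]); j -= 1
    aln = Alignment(list(names), ["".join(reversed(ra)), "".join(reversed(rb))])
    return aln, int(score)


# ---------------------------------------------------------------------------
# ORF finding


def find_longest_orf(
    seq: str, code: int = 11, start_codons: tuple[str, ...] = ("ATG",)
) -> LongestORF:
    """Longest start-to-stop ORF over the three forward frames.

    The amino-acid length excludes the stop codon; ties are broken by the
    leftmost start.  Returns a zero-length result when no complete ORF
    exists.
    """
    seq = seq.upper()
    _, stops = _codon_sets(code)
    best = LongestORF()
    for frame in range(3):
        orf_start = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos:pos + 3]
            if orf_start is None:
                if codon in start_codons:
                    orf_start = pos
            elif codon in stops:
                aa = (pos - orf_start) // 3
                if aa > best.aa_length or (
                    aa == best.aa_length and best.frame is not None
                    and orf_start < best.start
                ):
                    best = LongestORF(orf_start, pos + 3, aa, frame)
                orf_start = None
    return best


# ---------------------------------------------------------------------------
# integrity assessment


def _validate_ref_cds(ref: str, code: int) -> None:
    starts, stops = _codon_sets(code)
    if len(ref) % 3 != 0 or len(ref) < 6:
        raise InputError("reference CDS length must be a positive multiple of 3")
    if ref[:3] not in starts:
        raise InputError(f"reference CDS does not begin with a start codon ({ref[:3]})")
    if ref[-3:] not in stops:
        raise InputError("reference CDS does not end with a stop codon")
    aa = _translate(ref[:-3], code)
    if "*" in aa:
        raise InputError("reference CDS contains an internal stop codon")


def assess_integrity(
    query_locus: str,
    ref_cds: str,
    code: int = 11,
    gene_name: str = "locus",
    orf_fraction: float = 0.5,
    scoring: AlignScoring | None = None,
) -> IntegrityReport:
    """Assess whether a locus still encodes an intact protein.

    Aligns the query against the reference CDS, reports deletion spans in
    reference coordinates and insertion spans in query coordinates, flags a
    frameshift when the net indel length is not divisible by 3, counts
    in-frame stop codons arising before the reference stop, and measures
    the longest ORF remaining in the query.
    """
    query = query_locus.upper()
    ref = ref_cds.upper()
    _validate_ref_cds(ref, code)
    aln, _ = global_align(ref, query, scoring, names=("ref", "query"))
    ref_row, q_row = aln.rows

    matches = both = 0
    deletions: list[tuple[int, int]] = []
    insertions: list[tuple[int, int]] = []
    rpos = qpos = 0
    del_start = ins_start = None
    q_at_ref_stop = None
    ref_stop_start = len(ref) - 3
    for rc, qc in zip(ref_row, q_row):
        if rpos == ref_stop_start and rc != "-" and q_at_ref_stop is None:
            q_at_ref_stop = qpos
        if rc != "-" and qc != "-":
            both += 1
            if rc == qc:
                matches += 1
        if qc == "-" and rc != "-":
            if del_start is None:
                del_start = rpos
        elif del_start is not None:
            deletions.append((del_start, rpos))
            del_start = None
        if rc == "-" and qc != "-":
            if ins_start is None:
                ins_start = qpos
        elif ins_start is not None:
            insertions.append((ins_start, qpos))
            ins_start = None
        if rc != "-":
            rpos += 1
        if qc != "-":
            qpos += 1
    if del_start is not None:
        deletions.append((del_start, rpos))
    if ins_start is not None:
        insertions.append((ins_start, qpos))
    if q_at_ref_stop is None:
        q_at_ref_stop = qpos

    net = sum(e - s for s, e in insertions) - sum(e - s for s, e in deletions)
    frameshift = net % 3 != 0
    coding_prefix = query[: q_at_ref_stop - (q_at_ref_stop % 3)]
    premature_stops = _translate(coding_prefix, code).count("*")
    orf = find_longest_orf(query, code)
    pseudo = (
        premature_stops > 0
        or frameshift
        or orf.aa_length < orf_fraction * len(ref) / 3
    )
    return IntegrityReport(
        gene_name=gene_name,
        ref_length=len(ref),
        identity=matches / both if both else 0.0,
        deletion_spans=deletions,
        insertion_spans=insertions,
        frameshift=frameshift,
        premature_stops=premature_stops,
        longest_orf_aa=orf.aa_length,
        verdict="pseudogene" if pseudo else "intact",
        n_terminal_peptide=_translate(query[: 3 * 72], code),
    )
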