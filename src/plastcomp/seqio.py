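"""Sequence/feature data model and readers/writers for the standard formats.

The toolkit works on plastid (chloroplast) genomes: circular molecules of
roughly 120-160 kb carrying of the order of a hundred genes.  Everything
downstream consumes the :class:`PlastomeRecord` defined here.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open ``[start, end)``.  Human-facing
report dialects convert on output: BED stays 0-based half-open, GFF3 and any
GenBank-style text are 1-based inclusive.  A feature part that wraps the
origin of a circular molecule is stored as a single ``(start, end)`` pair with
``end < start``; its length is computed modulo the genome length.

GenBank and FASTA parsing is delegated to Biopython; this module only adapts
its objects into the small dataclasses below and enforces their invariants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import (
    EmptyInputError,
    FormatError,
    RaggedAlignmentError,
    UsageError,
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Gene-symbol synonyms normalised on input (newer names preferred).
GENE_SYNONYMS = {"ycf3": "pafI", "ycf4": "pafII"}

FASTA_WRAP = 70


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """One annotated gene: name, kind, strand and its exon intervals.

    ``parts`` are ordered along the direction of transcription; for a gene on
    the minus strand the first part is therefore the one with the largest
    coordinates.  ``exon_count`` equals ``len(parts)`` for cis-spliced genes.
    """

    gene_name: str
    kind: str  # CDS | tRNA | rRNA | other
    strand: str  # '+' | '-'
    parts: list[tuple[int, int]]
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError(f"feature {self.gene_name!r} has no parts")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def exon_count(self) -> int:
        return len(self.parts)

    def span(self, genome_length: int | None = None) -> tuple[int, int]:
        """Overall genomic interval covered by the feature.

        For a feature wrapping the origin the returned ``end`` exceeds the
        genome length (un-normalised), so ``end - start`` is always the span
        length; callers take coordinates modulo the genome length as needed.
        """
        starts = [s for s, _ in self.parts]
        ends = [e for _, e in self.parts]
        lo, hi = min(starts), max(ends)
        if genome_length is not None:
            for s, e in self.parts:
                if e < s:  # wrapped part
                    return s, e + genome_length
        return lo, hi

    def length(self, genome_length: int | None = None) -> int:
        total = 0
        for s, e in self.parts:
            if e >= s:
                total += e - s
            else:
                if genome_length is None:
                    raise ValueError("wrapped part needs genome length")
                total += genome_length - s + e
        return total


@dataclass
class PlastomeRecord:
    """A plastome sequence plus its gene annotation."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )
        if not self.sequence:
            raise EmptyInputError(f"record {self.id!r} has an empty sequence")
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.parts:
                if not (0 <= s < n and 0 <= e <= n):
                    raise FormatError(
                        f"feature {f.gene_name!r} part ({s},{e}) outside [0,{n})"
                    )
                if e < s and not self.circular:
                    raise FormatError(
                        f"feature {f.gene_name!r} wraps origin of a linear record"
                    )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """Extract ``[start, end)``; ``end`` may exceed length on circular records."""
        n = self.length
        if end <= n and start >= 0:
            return self.sequence[start:end]
        if not self.circular:
            raise ValueError("interval outside a linear record")
        start %= n
        end = start + (end - start)
        if end <= n:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[: end - n]


@dataclass
class Alignment:
    """A gapped multiple alignment; rows are equal-length strings."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if len(self.rows) < 2:
            raise RaggedAlignmentError("an alignment needs at least 2 rows")
        n = len(self.rows[0])
        for name, row in zip(self.names, self.rows):
            if len(row) != n:
                raise RaggedAlignmentError(
                    f"row {name!r} has length {len(row)}, expected {n}"
                )

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


# ---------------------------------------------------------------------------
# readers


def _feature_from_biopython(feat, locus: str) -> GeneFeature | None:
    kind = feat.type if feat.type in ("CDS", "tRNA", "rRNA") else None
    quals = feat.qualifiers
    is_pseudo = "pseudo" in quals or "pseudogene" in quals
    if kind is None:
        # pseudogenes are often annotated only as `gene` features
        if feat.type == "gene" and is_pseudo:
            kind = "other"
        else:
            return None
    name = quals.get("gene", quals.get("locus_tag", ["?"]))[0]
    name = GENE_SYNONYMS.get(name, name)
    strand = "-" if feat.location.strand == -1 else "+"
    try:
        parts = [(int(p.start), int(p.end)) for p in feat.location.parts]
    except Exception as exc:  # pragma: no cover - biopython internals
        raise FormatError(f"locus {locus}: unparseable location for {name}") from exc
    # order along transcription
    parts.sort()
    if strand == "-":
        parts.reverse()
    return GeneFeature(name, kind, strand, parts, is_pseudo=is_pseudo)


def read_plastome(path: str | Path, format: str = "genbank") -> PlastomeRecord:
    """Read a plastome from a GenBank flat file or plain FASTA.

    GenBank supplies the gene annotation (CDS/tRNA/rRNA features, with
    join/complement locations converted to ordered parts plus a strand, and
    ``/pseudo`` flags honoured); FASTA yields an empty feature set.
    """
    path = Path(path)
    if format not in ("genbank", "fasta"):
        raise UsageError(f"unknown format {format!r}")
    if not path.exists():
        raise EmptyInputError(f"no such file: {path}")
    try:
        rec = next(SeqIO.parse(str(path), format), None)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if rec is None:
        raise EmptyInputError(f"{path}: no record found")
    seq = str(rec.seq).upper()
    if not seq:
        raise EmptyInputError(f"{path}: record {rec.id!r} has an empty sequence")
    circular = "circular" in rec.annotations.get("topology", "circular")
    features: list[GeneFeature] = []
    if format == "genbank":
        for feat in rec.features:
            gf = _feature_from_biopython(feat, rec.id)
            if gf is not None:
                features.append(gf)
    return PlastomeRecord(rec.id, seq, circular=circular, features=features)


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA (>=2 equal-length rows, identifiers in file order)."""
    path = Path(path)
    if not path.exists():
        raise EmptyInputError(f"no such file: {path}")
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(str(rec.seq).upper())
    if len(rows) < 2:
        raise RaggedAlignmentError(f"{path}: need >=2 aligned rows, got {len(rows)}")
    return Alignment(names, rows)


# ---------------------------------------------------------------------------
# writers


def write_fasta(records: Iterable[tuple[str, str]] | PlastomeRecord,
                path: str | Path) -> None:
    """Write sequences as FASTA with fixed 70-column wrapping."""
    if isinstance(records, PlastomeRecord):
        records = [(records.id, records.sequence)]
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i:i + FASTA_WRAP] + "\n")


def write_alignment(aln: Alignment, path: str | Path) -> None:
    write_fasta(list(zip(aln.names, aln.rows)), path)


def _tsv_fields(row) -> dict:
    if dataclasses.is_dataclass(row):
        d = {}
        for f in dataclasses.fields(row):
            v = getattr(row, f.name)
            d[f.name] = v
        return d
    if isinstance(row, dict):
        return row
    raise UsageError(f"cannot serialise row of type {type(row).__name__}")


def write_table(rows: Sequence, path: str | Path, dialect: str = "tsv",
                header_comments: Sequence[str] = ()) -> None:
    """Write report rows as TSV (with header), BED (0-based half-open) or
    GFF3 (1-based inclusive).

    BED/GFF3 rows must provide ``bed_fields()`` returning
    ``(chrom, start, end, name, score, strand)`` in internal 0-based
    half-open coordinates; the GFF3 dialect converts to 1-based inclusive.
    """
    rows = list(rows)
    if dialect == "tsv":
        with open(path, "w") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            if rows:
                fields = list(_tsv_fields(rows[0]))
            else:
                fields = []
            fh.write("\t".join(fields) + "\n")
            for row in rows:
                d = _tsv_fields(row)
                fh.write("\t".join(str(d[f]) for f in fields) + "\n")
    elif dialect in ("bed", "gff3"):
        with open(path, "w") as fh:
            if dialect == "gff3":
                fh.write("##gff-version 3\n")
            for line in header_comments:
                fh.write(f"# {line}\n")
            for row in rows:
                try:
                    chrom, start, end, name, score, strand = row.bed_fields()
                except AttributeError as exc:
                    raise UsageError(
                        f"row type {type(row).__name__} has no interval fields "
                        f"for dialect {dialect!r}"
                    ) from exc
                if dialect == "bed":
                    fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
                else:
                    fh.write(
                        f"{chrom}\tplastcomp\tregion\t{start + 1}\t{end}\t{score}"
                        f"\t{strand}\t.\tName={name}\n"
                    )
    else:
        raise UsageError(f"unknown table dialect {dialect!r}")
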