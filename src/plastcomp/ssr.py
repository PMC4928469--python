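"""Perfect microsatellite (SSR) scanner.

Finds every maximal perfect tandem repeat of a primitive 1-6 bp motif,
with the period-class thresholds used for plastome SSR screens: at least
eight units for mononucleotide runs and at least four units for di- through
hexanucleotide motifs.  Only perfect repeats are reported: a partial
trailing unit is excluded from the span, and a run is never re-reported at
a multiple of its true period (an AAAA... tract is a mononucleotide hit,
never AAx4).  N matches nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import InputError


@dataclass(frozen=True)
class SSRParams:
    """Screening thresholds: minimum complete units per period class."""

    min_units_mono: int = 8
    min_units_multi: int = 4
    max_period: int = 6

    def __post_init__(self) -> None:
        if self.min_units_mono < 1 or self.min_units_multi < 2:
            raise ValueError("unit thresholds too small")
        if not 1 <= self.max_period <= 6:
            raise ValueError("max_period must be in 1..6")

    def min_units(self, period: int) -> int:
        return self.min_units_mono if period == 1 else self.min_units_multi


@dataclass(frozen=True)
class SSRHit:
    """One maximal perfect tandem repeat."""

    motif: str
    period: int
    units: int
    start: int
    end: int  # start + period*units (partial trailing unit excluded)

    @property
    def canonical_motif(self) -> str:
        """Lexicographically minimal rotation of the motif."""
        m = self.motif
        return min(m[i:] + m[:i] for i in range(len(m)))

    def bed_fields(self):
        return ("seq", self.start, self.end,
                f"{self.motif}x{self.units}", self.units, "+")


@dataclass
class SSRSummary:
    counts_by_period: dict[int, int] = field(default_factory=dict)
    total: int = 0
    at_only_fraction: float = 0.0  # percent of hits using only A/T


def _is_primitive(motif: str) -> bool:
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return False
    return True


def scan_ssrs(sequence: str, params: SSRParams | None = None) -> list[SSRHit]:
    """All maximal perfect SSRs in ``sequence``, sorted by start position.

    A hit at period p covers ``units`` complete copies of a primitive motif
    and cannot be extended by a full or partial unit on either side.
    Overlapping hits of different periods are each reported independently.
    """
    params = params or SSRParams()
    sequence = sequence.upper()
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise InputError(f"non-DNA characters in sequence: {sorted(bad)}")
    n = len(sequence)
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    n_code = ord("N")
    hits: list[SSRHit] = []
    for p in range(1, params.max_period + 1):
        if n < 2 * p:
            continue
        m = (arr[:-p] == arr[p:]) & (arr[:-p] != n_code)
        # maximal runs of True in m
        padded = np.concatenate(([False], m, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        starts, ends = edges[::2], edges[1::2]
        threshold = params.min_units(p)
        for s, e in zip(starts, ends):
            tandem_len = (e - s) + p  # run of matches plus one period
            units = tandem_len // p
            if units < threshold:
                continue
            motif = sequence[s:s + p]
            if not _is_primitive(motif):
                continue
            hits.append(SSRHit(motif, p, int(units), int(s), int(s + units * p)))
    hits.sort(key=lambda h: (h.start, h.period))
    return hits


def ssr_summary(hits: list[SSRHit]) -> SSRSummary:
    """Per-period-class tallies and the A/T-only percentage (two decimals)."""
    out = SSRSummary()
    for h in hits:
        out.counts_by_period[h.period] = out.counts_by_period.get(h.period, 0) + 1
    out.total = len(hits)
    if hits:
        at_only = sum(1 for h in hits if set(h.motif) <= {"A", "T"})
        frac = Decimal(100 * at_only) / Decimal(len(hits))
        out.at_only_fraction = float(
            frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
        )
    return out
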