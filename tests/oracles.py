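"""Independent brute-force oracles used to validate the fast implementations.

These deliberately re-derive each quantity from first principles (exhaustive
enumeration, quadratic scans, plain dynamic programming) and share no code
with the package internals they check.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# SSRs: test every (start, period) pair


def brute_force_ssrs(seq: str, min_units_mono: int = 8, min_units_multi: int = 4,
                     max_period: int = 6) -> set[tuple]:
    """Every maximal perfect primitive tandem repeat, as (motif, start, end)."""
    n = len(seq)
    hits = set()
    for p in range(1, max_period + 1):
        thr = min_units_mono if p == 1 else min_units_multi
        for start in range(n - p + 1):
            motif = seq[start:start + p]
            if "N" in motif:
                continue
            # primitivity
            if any(p % d == 0 and motif == motif[:d] * (p // d)
                   for d in range(1, p)):
                continue
            # left-maximality of the period-p run through `start`
            if start > 0 and start + p - 1 < n and \
                    seq[start - 1] == seq[start + p - 1] != "N":
                continue
            # extend right while the tandem continues
            end = start + p
            while end < n and seq[end] == seq[end - p] != "N":
                end += 1
            units = (end - start) // p
            if units >= thr:
                hits.add((motif, start, start + units * p))
    return hits


# ---------------------------------------------------------------------------
# inverted repeats: scan every diagonal of the (seq x revcomp) match matrix


def brute_force_max_inverted_pair(s: str, min_len: int):
    """Longest disjoint pair of exact reverse-complement intervals.

    Linear (non-circular) quadratic scan.  Returns (length, (first, second))
    or None; co-maximal ties resolved to the leftmost pair.
    """
    n = len(s)
    a = np.frombuffer(s.encode(), dtype=np.uint8)
    b = np.frombuffer(rc(s).encode(), dtype=np.uint8)
    nn = ord("N")
    candidates = []
    for d in range(-(n - 1), n):
        ai, bi = (d, 0) if d >= 0 else (0, -d)
        span = n - abs(d)
        if span < min_len:
            continue
        eq = (a[ai:ai + span] == b[bi:bi + span]) & (a[ai:ai + span] != nn)
        pad = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(pad[1:] != pad[:-1])
        for s0, e0 in zip(edges[::2], edges[1::2]):
            run = int(e0 - s0)
            if run < min_len:
                continue
            i0, j0 = ai + int(s0), bi + int(s0)
            c1 = (i0, i0 + run)
            c2 = (n - j0 - run, n - j0)
            first, second = sorted([c1, c2])
            if first[1] > second[0]:  # overlapping copies (incl. palindromes)
                continue
            candidates.append((run, first, second))
    if not candidates:
        return None
    best = max(c[0] for c in candidates)
    first, second = min((f, s) for r, f, s in candidates if r == best)
    return best, (first, second)


# ---------------------------------------------------------------------------
# ORFs: enumerate every start codon and find its in-frame stop


def brute_force_longest_orf(seq: str, stops=("TAA", "TAG", "TGA")):
    """(start, stop_end, aa_length) of the longest ATG..stop ORF, ties to the
    leftmost start; None when no complete ORF exists."""
    best = None
    for start in range(len(seq) - 2):
        if seq[start:start + 3] != "ATG":
            continue
        for pos in range(start + 3, len(seq) - 2, 3):
            if seq[pos:pos + 3] in stops:
                aa = (pos - start) // 3
                if best is None or aa > best[2] or (aa == best[2] and start < best[0]):
                    best = (start, pos + 3, aa)
                break
    return best


# ---------------------------------------------------------------------------
# affine-gap alignment score: plain dictionary DP, no vectorisation


def brute_force_affine_score(a: str, b: str, match: int, mismatch: int,
                             gap_open: int, gap_extend: int) -> int:
    """Optimal global affine-gap score (gap length L costs open+(L-1)*extend)."""
    NEG = float("-inf")
    m, n = len(a), len(b)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0
    for i in range(1, m + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, n + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sc = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sc
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return int(max(M[m][n], X[m][n], Y[m][n]))
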