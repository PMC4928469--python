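# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Coordinates and data model

All internal coordinates are 0-based half-open; BED output keeps that
convention, GFF3 and other human-facing reports are 1-based inclusive. A
feature part wrapping the origin of a circular molecule is stored as one
`(start, end)` pair with `end < start` and its length computed modulo the
genome length; records are never rotated silently. Gene symbols are
normalised through a small synonym table (`ycf3 → pafI`, `ycf4 → pafII`).
N bases are legal in sequences but excluded from composition tallies,
diversity columns and SSR matching.

## Inverted-repeat detection and partition

Plastid IRs are exact (or very nearly exact) reverse-complement copies of
20–30 kb, so detection is framed as an exact-matching problem: k-mer
anchors (k = 25, reduced to `min_len` for small problems) between the
sequence and its reverse complement are extended to maximal exact matches,
and the longest pair of disjoint intervals wins, each copy at least
`min_len` (default 1000 bp — well below any true plastid IR, above
spurious repeats). Ties are broken to the leftmost start, with a warning;
candidate pairs whose copies overlap (palindromes) are rejected. Circular
records are searched on the doubled sequence with coordinates normalised
back to the circle, so an IR straddling the origin is found.

The partition names the longer inter-IR arc LSC and the shorter SSC
(equal arcs raise an explicit ambiguity error — a synthetic pathological
case); IRb is the IR copy immediately upstream of the SSC on the
deposited strand, matching the conventional LSC–IRb–SSC–IRa reading. A
junction position is the index of the first base of the downstream
region. The partition is only accepted when the tiling identity
`lsc + ssc + 2·ir = n` holds and the IRb subsequence reverse-complements
exactly onto IRa. Whether a published IR length includes the junction
base on either side varies between papers; any off-by-one disagreement
with printed tables would localise to this convention.

A gene *crosses* a junction when its span has bases on both sides of the
boundary; its two flank lengths sum to the span length. For each side of
each junction the nearest non-crossing gene is also reported, with the
distance counted as bases strictly between the boundary and the closer
gene end — so a gene starting 10 bp into the SSC is at distance 10 from
the IRb–SSC junction.

GC percentages are rounded half-up to one decimal; the IR composition row
uses one copy (IRb — both copies are identical by construction).

## Gene census

Genes are counted once per unique name; pseudogene-flagged loci are
excluded from the category counts and listed separately, so
`total = protein_coding + tRNA + rRNA`. A gene is IR-duplicated when two
same-name features of identical exon structure lie one in each IR copy.
Same-name features with *different* exon structures whose pieces are
separated by more than 5 kb (far above any plastid intron) are classified
trans-spliced — the *rps12* situation, with exon 1 in the LSC and exons
2–3 in the IRs — and counted once, outside the intron classes. Otherwise
intron classes derive from exon counts: 2 parts = one intron, 3 = two.
Three or more identical copies trigger a warning and count once.

The overlap report lists unordered CDS pairs with intersecting spans,
with the overlap length and the difference of reading frames (mod 3) —
the *psbD*/*psbC*-type arrangement.

## Perfect SSR scanning

For each period p = 1..6 the scanner finds maximal runs of the predicate
`s[i] == s[i+p]` (N never matches), which correspond exactly to maximal
perfect tandem tracts. A tract is reported when its motif is primitive
(not a power of a shorter motif), its complete-unit count meets the
period-class threshold (defaults: ≥ 8 for mono, ≥ 4 for periods 2–6, the
"at least eight / four repeat units" convention of GMATo-style screens),
and the partial trailing unit is excluded from the span. Primitivity is
what makes class counts well-defined: a poly-A tract is one
mononucleotide hit, never AA×n. Overlapping hits of different periods are
each reported if independently maximal; compound/imperfect SSRs are out
of scope. The genome is scanned as deposited — a flat string with both IR
copies present and no wrap-around joining — and on the given strand only.
The A/T-only percentage is rounded half-up to two decimals.

## Diversity, PIC and marker ranking

π is Nei's average pairwise difference per site. Columns containing a gap
or N in any row are excluded (per-column exclusion; identical to pairwise
deletion for the two-genome case this pipeline targets). Windows are 400
alignment columns advancing by 100 — i.e. adjacent windows overlap by
300 columns, standard DnaSP-style practice — starting at column 0, the
last window may be short, and a window with zero usable sites is emitted
with π flagged undefined rather than dropped, so window counts are
predictable.

Per region, substitutions are the ungapped mismatching columns and one
indel event is one maximal per-row gap run, counted once regardless of
length (the Shaw-style convention); PIC = substitutions + indel events.
Because runs merge across region boundaries, indel events can only
decrease or stay equal when regions are merged, while substitutions are
additive over any column partition — both properties are tested.

Region projection maps one genome's annotation onto alignment columns via
that row's gap structure; intergenic spacers are named by their flanking
genes (`trnH-psbA`). Genes wrapping the origin cannot be projected onto a
linear alignment and are skipped. Ranking filters regions with aligned
length strictly greater than 200 columns and sorts by PIC descending,
ties by π then name; the top-40 cut and both thresholds are parameters,
since published analyses vary between "top 40" and "41 regions".

## Pseudogene integrity

The reference must be a valid CDS (start codon, length divisible by 3,
single terminal stop, bacterial/plastid code — NCBI table 11). Query and
reference are aligned with an affine-gap global aligner (Gotoh; a gap of
length L costs `open + (L−1)·extend`, defaults +1/−1/−2/−1). The
traceback is deterministic: diagonal preferred over up over left on ties.
The DP is vectorised per row; the in-row gap-state recurrence is solved
with a running maximum, so gene-scale problems (≤ a few kb) align in well
under a second; inputs above 50 kb are refused with advice to use an
external aligner. When equal flanking bases make the gap placement
ambiguous the reported span can shift by a base or two, but the total
deleted length is always exact.

Deletion spans are reported in reference coordinates, insertions in query
coordinates. A frameshift is a net indel length not divisible by 3.
Premature stops are counted by translating the query from its start up to
the position aligned with the reference stop codon — indels shift the
frame downstream, which is exactly what makes decayed loci accumulate
stops. The longest ORF searches the three forward frames only (loci are
supplied in annotated orientation), ATG starts, ties to the leftmost.
The verdict is `pseudogene` iff premature stops > 0, or a frameshift, or
the longest ORF is below half the reference protein length; the 50 %
threshold encodes the qualitative "extremely reduced ORF" criterion and
is configurable. The report also exposes the first 72 query codons
translated, the region external transit-peptide predictors consume.

## The synthetic generator

Defaults are the dimensions and gene plan of a real Primula-type
plastome: LSC 82,064 / SSC 17,725 / IR 25,535 (150,859 bp total); 78
protein-coding + 30 tRNA + 4 rRNA genes with 7/7/4 duplicated in the IR,
15 one-intron and 2 two-intron genes, a trans-spliced *rps12* analogue,
and three junction-crossing genes (rps19/ndhF/ycf1-like). The background
is i.i.d. uniform ACGT, then *sanitised*: the assembled genome is
rescanned and offending windows re-randomised (bounded at 100 iterations)
until no unplanted SSR meets the screening thresholds, no unplanted
inverted repeat of ≥ 50 bp exists, and the planted IR pair is exactly
maximal (chance single-base extensions at its flanks are broken). Planted
SSR tracts are protected from re-randomisation; a tract planted in the IR
unit appears twice in the genome, reverse-complemented in IRa, and the
truth inventory lists both occurrences.

Divergence: substitutions are per-site Bernoulli draws (uniform over the
three alternatives), indels per-site initiations with geometric lengths
(mean 4 by default), insertion/deletion equiprobable. Defaults
(substitution rate 0.02/site, indel rate 0.002/site, IR rates scaled by
0.2) were chosen once to mimic the empirical pattern in congeneric
plastome pairs — windowed π spanning 0 to a few percent with variation
concentrated outside the IRs. The two IR copies receive identical draws
(the process runs on the IR unit and is mirrored, complemented, into
IRa), so the sister genome keeps an exact IR pair, emulating real IR
homogenisation; the mutation log records each event once per copy.
Successive indels always leave at least one unmutated column between them
and stay off region edges, so each logged event is exactly one gap run in
the true alignment and the log count equals what the diversity module
measures. All draws are integer-based (numpy PCG64), making a seed
reproducible across platforms.

What the generator does **not** emulate: codon structure and selective
constraint inside genes (gene "sequences" are just background DNA under
annotations), transition/transversion bias, rate heterogeneity beyond the
per-region multipliers, tandem-repeat slippage, and IR
expansion/contraction. Passing tests therefore demonstrate algorithmic
correctness on structurally faithful genomes, not biological realism of
the sequence content itself.

## Problem sizes in the test and acceptance runs

The oracle suites use 100 random 2 kb sequences (SSR), 200 planted-repeat
genomes of ~1–2.5 kb (inverted repeats, against a quadratic
diagonal-scan oracle), and 50 random 300 bp sequences (ORFs). Parameter
recovery runs on a 100 kb synthetic pair (LSC 55 kb / IR 17.5 kb / SSC
10 kb): pooled windowed π must fall within three binomial standard errors
of the planted substitution rate — computed over the count of
*independent* sites, i.e. excluding one IR copy, since the copies share
draws — and the indel events measured on the true alignment must equal
the mutation-log count exactly. The acceptance script runs the full-scale
(150,859 bp) genome pair. These sizes keep the whole suite and the
script each within a couple of minutes on one CPU while leaving every
statistical check well-powered.

## Known limitations

- IR detection assumes exact repeats; a `max_mismatch` relaxation is not
  implemented (real plastid IRs are overwhelmingly exact, and detection
  equality against the brute-force oracle is only defined at 0
  mismatches).
- Genome-scale alignments are consumed, not computed: MAFFT or similar is
  upstream; the built-in aligner is for gene-scale integrity work only.
- The marker ranking reflects whatever alignment it is given — alignment
  artefacts in hard regions propagate into PIC counts.
- `read_plastome` takes the first record of a multi-record file.
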