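# plastcomp

Comparative analysis of chloroplast genomes (plastomes): quadripartite
structure, SC–IR junctions, gene content, perfect microsatellites,
sliding-window nucleotide diversity with marker ranking, and pseudogene
integrity — with a synthetic plastome generator so the whole pipeline is
testable without downloading a single accession.

## The problem

A typical angiosperm plastome is a circular molecule of 120–160 kb with a
conserved quadripartite layout: a large and a small single-copy region
(LSC, SSC) separated by two identical inverted repeats (IRa, IRb).
Comparative studies of newly assembled plastomes answer a standard set of
questions — where are the IR boundaries and which genes straddle them, how
many genes of each class does the genome carry, where are the perfect
microsatellites (SSRs) useful for population genetics, which intergenic
spacers are variable enough to serve as phylogenetic markers, and which
loci (classically *accD* and *infA*) have decayed into pseudogenes.
`plastcomp` implements each of those analyses as a tested, reusable
library with a thin command-line interface.

## Methods at the core

- **IR detection & partition.** Anchored k-mer matching (k = 25) between
  the sequence and its reverse complement, extended to maximal exact
  matches; the longest pair of disjoint reverse-complement intervals
  (each ≥ 1000 bp by default) is the IR. The longer inter-IR arc becomes
  the LSC, the shorter the SSC, and the four junctions follow. Invariant:
  `LSC + SSC + 2·IR = genome length`, exactly.
- **Perfect SSRs.** All maximal perfect tandem repeats of a primitive
  1–6 bp motif, with ≥ 8 units for mononucleotides and ≥ 4 units for
  periods 2–6; partial trailing units are excluded and a tract is never
  re-reported at a multiple of its true period.
- **Nucleotide diversity.** π = average pairwise difference per site,
  columns containing a gap or N excluded, computed in 400-column windows
  advancing by 100 (adjacent windows overlap by 300 columns).
- **Marker ranking.** For each gene and intergenic spacer projected onto
  the alignment: PIC = substitutions + indel events, where one indel
  event is one maximal per-row gap run (a 1 bp and a 400 bp gap each
  count once). Regions longer than 200 aligned columns are ranked by PIC.
- **Pseudogene calls.** Affine-gap global alignment (Gotoh) of a locus
  against an intact reference CDS; verdict `pseudogene` iff there is a
  premature in-frame stop, a frameshift (net indel length ∤ 3), or the
  longest remaining ORF is below 50 % of the reference protein.
- **Synthetic truth.** The generator plants IRs, genes (IR duplicates,
  introns, a trans-spliced *rps12* analogue, junction-crossing genes) and
  SSRs in a repeat-sanitised background, then derives a sister genome by
  a known substitution/indel process (IR copies co-mutated so the repeat
  stays exact) and keeps the true alignment and mutation log.

## Worked example

```bash
python examples/01_structure_and_census.py
```

prints, for a full-scale synthetic plastome (seed 42):

```
synthetic plastome: 150,859 bp, 132 features
LSC 82,064 bp | IR 25,535 bp x2 | SSC 17,725 bp
genes: 112 total = 78 protein-coding + 30 tRNA + 4 rRNA
IR-duplicated: 18; one intron: 15; two introns: 2; trans-spliced: ['rps12']
  rps19 crosses J(LSC-IRb), flanks (160, 119)
  ndhF crosses J(IRb-SSC), flanks (50, 850)
  ycf1 crosses J(SSC-IRa), flanks (900, 240)
```

The region lengths and gene counts are *recovered by detection and
counting*, not read from the generator — the genome was built to those
dimensions, so any discrepancy would expose a defect in the detector or
census. The other examples cover the SSR screen
(`02_ssr_screen.py`), diversity + marker ranking
(`03_diversity_and_markers.py`, which also cross-checks the measured
indel events against the generator's mutation log), and the pseudogene
verdict for a 400 bp deletion near the start of a 1.5 kb CDS
(`04_pseudogene_assessment.py`).

The same analyses are available from the shell:

```bash
plastcomp structure --in genome.gb --min-ir-len 1000 --out partition.tsv
plastcomp ssr --in genome.fasta --mono 8 --multi 4 --out ssrs.tsv
plastcomp markers --aln pair.fasta --genome genome.gb --top 40 --out markers.tsv
plastcomp pseudo --query locus.fasta --ref refcds.fasta --out report.tsv
plastcomp synth --toy --seed 42 --out-prefix sim/
```

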