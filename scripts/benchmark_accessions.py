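#!/usr/bin/env python
"""Re-run the pipeline on real GenBank plastomes (requires network).

Fetches the Primula sinensis plastome (KU321892) and relatives
(NC_024543, NC_026197, KC465962), runs structure detection, base
composition, gene census and the SSR screen, and prints the published
values next to the recomputed ones.  If MAFFT is on PATH it also aligns
the two Primula genomes and reports windowed diversity and the top
variable regions.

This script is a convenience for users with internet access; nothing in
the test suite depends on it.

Usage:  python scripts/benchmark_accessions.py [--workdir scratch/bench]
"""

from __future__ import annotations

import argparse
import shutil
import subprocess
import sys
import urllib.request
from pathlib import Path

from plastcomp import (
    WindowParams,
    base_composition,
    census,
    find_inverted_repeats,
    junction_report,
    partition,
    project_regions,
    rank_markers,
    read_alignment,
    read_plastome,
    region_variation,
    scan_ssrs,
    sliding_window_pi,
    ssr_summary,
    write_fasta,
)

EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nucleotide&id={acc}&rettype=gbwithparts&retmode=text")

# published values for quick visual comparison (Table-style)
PUBLISHED = {
    "KU321892": dict(total=150_859, lsc=82_064, ssc=17_725, ir=25_535,
                     gc=37.2, genes=112, ssr_total=193),
    "NC_024543": dict(total=151_664, lsc=83_444, ssc=17_822, ir=25_199,
                      gc=37.0, ssr_total=177),
    "NC_026197": dict(total=155_386, lsc=85_229, ssc=17_951, ir=26_103, gc=37.1),
    "KC465962": dict(total=156_506, lsc=86_078, ssc=18_328, ir=26_050, gc=37.1),
}


def fetch(acc: str, workdir: Path) -> Path:
    path = workdir / f"{acc}.gb"
    if not path.exists():
        print(f"fetching {acc} ...", file=sys.stderr)
        urllib.request.urlretrieve(EFETCH.format(acc=acc), path)
    return path


def analyse(acc: str, workdir: Path):
    rec = read_plastome(fetch(acc, workdir), "genbank")
    pub = PUBLISHED.get(acc, {})
    pair = find_inverted_repeats(rec, min_len=1000)
    part = partition(rec, pair) if pair else None
    comp = base_composition(rec, part)
    print(f"\n== {acc} ({rec.id})")
    print(f"  total length {rec.length:,} (published {pub.get('total', '?'):,})")
    if part:
        print(f"  LSC {part.lsc_length:,} / SSC {part.ssc_length:,} / "
              f"IR {part.ir_length:,}  (published {pub.get('lsc', '?')}/"
              f"{pub.get('ssc', '?')}/{pub.get('ir', '?')})")
    print(f"  GC {comp[0].gc_percent}% (published {pub.get('gc', '?')})")
    c = census(rec, part)
    print(f"  genes: {c.total_genes} total, {c.protein_coding} CDS, "
          f"{c.trna} tRNA, {c.rrna} rRNA; pseudogenes {sorted(c.pseudogenes)}")
    hits = scan_ssrs(rec.sequence)
    s = ssr_summary(hits)
    print(f"  SSRs: {s.total} total (published {pub.get('ssr_total', '?')}); "
          f"by period {s.counts_by_period}; A/T-only {s.at_only_fraction}%")
    if part and rec.features:
        crossing = [r for r in junction_report(rec, part) if r.note == "crosses"]
        print(f"  junction-crossing genes: "
              f"{sorted({r.gene_name for r in crossing})}")
    return rec


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--workdir", type=Path, default=Path("scratch/bench"))
    args = ap.parse_args()
    args.workdir.mkdir(parents=True, exist_ok=True)

    records = {}
    for acc in PUBLISHED:
        try:
            records[acc] = analyse(acc, args.workdir)
        except Exception as exc:  # network or parse failure: keep going
            print(f"  {acc}: FAILED ({exc})", file=sys.stderr)

    if "KU321892" in records and "NC_024543" in records and shutil.which("mafft"):
        print("\n== pairwise diversity P. sinensis vs P. poissonii (MAFFT)")
        pair_fa = args.workdir / "pair.fasta"
        write_fasta([(a, records[a].sequence) for a in ("KU321892", "NC_024543")],
                    pair_fa)
        aln_fa = args.workdir / "pair.aln.fasta"
        with open(aln_fa, "w") as fh:
            subprocess.run(["mafft", "--retree", "2", str(pair_fa)],
                           stdout=fh, check=True)
        aln = read_alignment(aln_fa)
        wins = sliding_window_pi(aln, WindowParams(400, 100))
        defined = [w for w in wins if w.pi is not None]
        print(f"  Pi range {min(w.pi for w in defined):.3f}-"
              f"{max(w.pi for w in defined):.3f} (published 0-0.47)")
        spans = project_regions(records["KU321892"], aln, 0)
        ranked = rank_markers(region_variation(aln, spans),
                              top_n=40, min_aligned_len=200)
        print("  top variable regions:",
              ", ".join(r.name for r in ranked[:8]))
        print("  (published top four: rpl36-rps8, rps16-trnQ, trnH-psbA, "
              "ndhC-trnV)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
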