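"""Call a pseudogene from a deletion-bearing locus.

Recreates the classic plastid accD situation: a ~400 bp deletion near the
start of an otherwise intact CDS shifts the reading frame, introduces a
premature stop, and leaves only a short residual ORF.  The integrity
report shows each line of evidence and the resulting verdict.
"""

import numpy as np

from plastcomp import assess_integrity, find_longest_orf
from plastcomp.synth import random_cds

rng = np.random.default_rng(42)
ref = random_cds(rng, 498)          # a healthy 1,494 bp CDS (497 aa + stop)
query = ref[:150] + ref[550:]       # 400 bp deleted near the 5' end

report = assess_integrity(query, ref, gene_name="accD-like")
print(f"reference CDS: {report.ref_length} bp")
print(f"aligned identity: {report.identity:.3f}")
print(f"deletions (ref coords): {report.deletion_spans}")
print(f"frameshift: {report.frameshift} "
      f"(net indel length not divisible by 3)")
print(f"premature stops before the reference stop: {report.premature_stops}")
print(f"longest remaining ORF: {report.longest_orf_aa} aa "
      f"(reference encodes {report.ref_length // 3 - 1} aa)")
print(f"verdict: {report.verdict}")

orf = find_longest_orf(query)
print(f"longest ORF span in the query: [{orf.start}, {orf.end}), "
      f"frame {orf.frame}")
# The verdict is 'pseudogene' because any one of the three criteria fires:
# premature stops, a frameshift, or an ORF below half the reference length.
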