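"""Scan a genome fragment for candidate mobile ORFs.

Builds a small synthetic plastome fragment with one long reading frame hidden
in noncoding sequence, then runs the six-frame scanner with the conventional
500 nt floor (stop codon included).  Each reported row is an ATG...stop frame
with no internal stop; mobile-ORF candidates in real plastomes are nominated
exactly this way before homology checks.
"""

import numpy as np

from morffokit.io_formats import find_orfs, orfs_to_frame

rng = np.random.default_rng(1)
# stop-dense flanks: no reading frame can run far outside the planted ORF
flank = "".join(rng.choice(["TAA", "TGA", "CTA", "TTA"], 130))
orf = "ATG" + "".join(rng.choice(["GCT", "GAA", "TGT", "CCA"], 180)) + "TAA"
genome = flank + orf + "".join(rng.choice(["TAA", "TGA", "CTA", "TTA"], 130))

hits = find_orfs(genome, min_len=500, contig_id="fragment")
print(orfs_to_frame(hits).to_string(index=False))
print(f"\n{len(hits)} ORF(s) of >= 500 nt; the planted frame is {len(orf)} nt long.")
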