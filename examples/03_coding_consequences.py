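"""Classify the coding consequences of splicing events.

For each simulated event: CDS/UTR localization, frame preservation
(segment length mod 3), premature stop codons in the minor isoform, and
NMD candidacy under the 50-nt junction rule.
"""

from collections import Counter

from splicedelta import SimConfig, classify_frame
from splicedelta.synthdata import make_transcriptome

cfg = SimConfig(n_genes=30, seed=5)
txome = make_transcriptome(cfg)

tally = Counter()
for ev in txome.events:
    ann = classify_frame(ev, txome.host(ev), txome.genome)
    tally[ann.localization] += 1
    if ann.localization == "CDS":
        tally["frame_preserving" if ann.frame_preserving else "frameshift"] += 1
        if ann.premature_stop:
            tally["premature_stop"] += 1
        if ann.nmd_candidate:
            tally["nmd_candidate"] += 1

for k in ("CDS", "UTR5", "UTR3", "frame_preserving", "frameshift",
          "premature_stop", "nmd_candidate"):
    print(f"{k:>18}: {tally[k]}")
# CDS events split into frame-preserving (protein gains/loses residues) and
# frameshift/PTC events (NMD targets or novel C-termini).
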