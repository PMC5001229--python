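"""Scan the 7 regulatory regions of cassette events for RBP motifs.

Plants a strong PWM consensus in Region 3 (acceptor-adjacent end of the
upstream intron) of up-regulated events and recovers it with exact
p-values and BH FDR — the motif shows up concentrated in Region 3 of
up-regulated events only.
"""

import numpy as np

from splicedelta import SimConfig
from splicedelta.motifs import extract_regions, motif_enrichment
from splicedelta.quant import DiffSplicingCall
from splicedelta.synthdata import (
    assign_truth,
    make_transcriptome,
    plant_motif,
    planted_pwm,
)

cfg = SimConfig(n_genes=60, seed=51, frac_affected=0.6,
                delta_psi_effects=(0.3, -0.3))
txome = make_transcriptome(cfg)
truth = assign_truth(txome.events, cfg)
pwm = planted_pwm()
planted = plant_motif(txome, truth, pwm, region_index=3, direction="up")

# idealized calls straight from the truth table (quantification is
# demonstrated in example 02)
calls = [
    DiffSplicingCall(t.event_id, t.true_psi_control, t.true_psi_treated,
                     t.true_psi_treated - t.true_psi_control, 100.0,
                     float(np.log(100.0)), passes=t.is_differential)
    for t in truth.values()
]
region_sets = {
    e.event_id: extract_regions(e, planted.genome)
    for e, c in zip(txome.events, calls)
    if c.passes and e.event_type.value == "cassette"
}
res = motif_enrichment(calls, region_sets, [pwm], p_cut=1e-4, fdr_cut=0.1)
print(res.table.to_string(index=False))
print("motifs exclusive to up-regulated events:", sorted(res.up_only))
# n_hits counts surviving motif occurrences per region; the planted motif
# appears only in region 3 of the up direction.
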