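"""Domain overlap of spliced peptides and the dual-evidence PPI join.

Translates frame-preserving AS segments with 30-nt exon flanks, intersects
them with a protein-domain table, then finds interaction partners with
BOTH experimental (PPI edge) and structural (domain-domain pair) support.
"""

from splicedelta import SimConfig, build_flanked_peptide, overlap_domains
from splicedelta.domains import domains_from_frame
from splicedelta.ppi import dual_evidence_join, merge_ppi
from splicedelta.synthdata import make_annotation_fixtures, make_transcriptome

cfg = SimConfig(n_genes=40, seed=11)
txome = make_transcriptome(cfg)
fx = make_annotation_fixtures(txome, cfg)
dom_table = domains_from_frame(fx.domains)

n_pep = n_ov = 0
for ev in txome.events:
    try:
        pep = build_flanked_peptide(ev, txome.host(ev), txome.genome)
    except ValueError:
        continue  # not a frame-preserving CDS segment
    n_pep += 1
    for ov in overlap_domains(pep, dom_table):
        n_ov += 1
        print(f"{ev.gene_id}: {ov.name} overlap {ov.overlap_aa} aa ({ov.which_part})")
print(f"{n_pep} flanked peptides translated, {n_ov} domain overlaps")

merged = merge_ppi(fx.ppi_edges)
hits = dual_evidence_join(fx.as_genes_with_domains, fx.ddi, fx.gene_domains,
                          merged, expressed_genes=fx.expressed_genes)
print(f"\n{len(hits)} interactions with both experimental and structural evidence:")
for h in hits:
    print(f"  {h.as_gene} [{h.as_domain}] -- {h.partner_gene} [{h.partner_domain}]")
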