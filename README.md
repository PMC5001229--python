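# splicedelta

Differential alternative-splicing analysis for two-condition bulk RNA-seq
designs, with a fully synthetic test bed. The package re-implements, as a
reusable and tested library, the classic event-level workflow used to
study stimulus-induced splicing changes (e.g., LPS-treated vs control
bone-marrow stromal cells): Bayesian estimation of exon inclusion (Ψ),
Bayes-factor calling of differential events across four event classes
(cassette exon, alternative 5′/3′ splice site, intron retention), and the
downstream characterization of what those events do to the protein —
coding-frame and NMD consequences, disrupted protein domains, protein
interactions supported by both experimental and structural evidence, and
RNA-binding-protein motifs in the regulatory regions flanking cassette
exons.

It is a library first: import it from Python, or drive the whole pipeline
with the thin `splicedelta` CLI. All inputs can be simulated, so every
stage runs and is testable with no downloads.

## The model

Reads over an event locus fall into three observable classes — compatible
only with the inclusion isoform, only with the exclusion isoform, or with
both. With effective sizes `e_inc`, `e_exc`, `e_sh` (the number of read
start positions diagnostic for each class at the given read length,
counted by exact enumeration over both isoforms), the class probabilities
at inclusion level Ψ are

```
Z(Ψ)      = Ψ·(e_inc + e_sh) + (1−Ψ)·(e_exc + e_sh)
p_inc(Ψ)  = Ψ·e_inc / Z        p_exc(Ψ) = (1−Ψ)·e_exc / Z
p_sh(Ψ)   = e_sh / Z
```

and the likelihood of counts (n_inc, n_exc, n_sh) is multinomial. With a
Uniform(0,1) prior, the posterior over Ψ is computed on a fixed 1,001-point
grid (Simpson quadrature), giving the posterior mean Ψ̂ and a central 95%
credible interval. Differential splicing between conditions is scored with
a Bayes factor

```
BF = P(D_ctrl, D_trt | Ψ_ctrl ⊥ Ψ_trt, each ~ U(0,1))
     ─────────────────────────────────────────────────
     P(D_ctrl, D_trt | Ψ_ctrl = Ψ_trt ~ U(0,1))
```

and an event is called differential when **BF > 5 and |ΔΨ| > 0.05**, with
ΔΨ = Ψ̂_treated − Ψ̂_control. Replicates are pooled per condition before
inference.

Downstream stages: segment length mod 3 decides frame preservation;
translating the minor isoform from the annotated start codon detects
premature termination codons, with NMD candidacy under the 50-nt final
junction rule; frame-preserving CDS segments plus 30 nt of each flanking
exon are translated and intersected with protein-domain intervals;
interactions are reported only with both an experimental PPI edge and a
structural domain–domain pair; and seven regulatory regions per cassette
exon (150-nt exon flanks, 300-nt intron ends, the exon itself) are scanned
with PWMs using exact dynamic-programming p-values and Benjamini–Hochberg
FDR (p < 1e-4, FDR < 0.1).

## Worked example

```python
from splicedelta import EffectiveSizes, EventCounts, bayes_factor, psi_posterior

sizes = EffectiveSizes(eff_inc=220, eff_exc=74, eff_shared=150)
control = EventCounts("Abi1_cassette", "control", 180, 95, 140, sizes)
treated = EventCounts("Abi1_cassette", "treated", 310, 48, 150, sizes)
for c in (control, treated):
    p = psi_posterior(c)
    print(f"{c.condition}: psi = {p.mean:.3f} [{p.ci_low:.3f}, {p.ci_high:.3f}]")
call = bayes_factor(control, treated)
print(f"delta_psi = {call.delta_psi:+.3f}, BF = {call.bayes_factor:.1f}, passes: {call.passes}")
```

prints

```
control: psi = 0.468 [0.408, 0.528]
treated: psi = 0.748 [0.690, 0.801]
delta_psi = +0.280, BF = 107909227.0, passes: True
```

i.e., an exon included in ~47% of transcripts in control and ~75% after
treatment; the data are overwhelmingly better explained by two different
inclusion levels than by one, so the event is called differential.

The `examples/` directory has one short script per capability (event
quantification, simulate-and-call, coding consequences, domains + PPI,
motif scanning). A full synthetic study runs from the shell with

```sh
splicedelta run-all -o out/ --seed 7 --n-genes 50
```

which writes per-stage TSVs (`calls.tsv`, `annotation.tsv`,
`domain_overlaps.tsv`, `interactions.tsv`, `motif_table.tsv`, …) and JSON
summaries under `out/`.

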