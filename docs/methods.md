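# Methods

## Two-isoform splicing model

Every event — cassette exon, alternative 5′ or 3′ splice site, retained
intron — is reduced to a pair of isoforms over its locus: the inclusion
form carries the *alternative segment* (the cassette exon, the splice-site
extension, or the intron) and the exclusion form does not. Percent spliced
in (Ψ) is the fraction of the gene's transcripts carrying the segment.

A read of length L maps to one of three classes: inclusion-specific,
exclusion-specific, or shared. The *effective size* of a class is the
number of read start positions producing such a read, counted by exhaustive
enumeration of all contiguous windows on both isoform chains over the
locus; reads with less than the minimum junction overhang (default 1 nt)
on either side of a junction are discarded as unmappable. A footprint is
"compatible" with an isoform when it is a contiguous spliced window of
that isoform, so a read skipping an exon is incompatible with the
inclusion chain even though all its bases are exonic there. Events with
zero inclusion-specific or zero exclusion-specific positions are flagged
untestable and skipped with a logged reason.

Given Ψ, a read comes from the inclusion isoform with probability
proportional to Ψ times that isoform's informative length, leading to

    Z(Ψ)     = Ψ(e_inc + e_sh) + (1−Ψ)(e_exc + e_sh)
    p_inc    = Ψ e_inc / Z,   p_exc = (1−Ψ) e_exc / Z,   p_sh = e_sh / Z

and a multinomial likelihood for the observed class counts. This is the
single-event, single-end special case of mixture-of-isoforms inference;
paired-end insert modeling and >2 isoforms are out of scope.

## Posterior and Bayes factor

The prior on Ψ is Uniform(0,1); no pseudocounts are added anywhere — a
zero count simply leaves the corresponding likelihood factor out. The
posterior is evaluated on a fixed equispaced grid of 1,001 points with
composite-Simpson quadrature weights. Grid inference was chosen over MCMC
because it is deterministic and directly checkable against adaptive
quadrature; tests require the posterior mean within 1e-3 and the log Bayes
factor within 0.01 of a `scipy.integrate.quad` oracle, and Simpson weights
are needed to hold the log-BF tolerance at counts of a few hundred
(trapezoid error reaches ~0.02 there). The 95% interval is the central
credible interval read off the cumulative grid mass by linear
interpolation; with all counts zero, the posterior is the prior and is
flagged low-information.

The differential-splicing score is a Bayes factor comparing a model with
independent Ψ per condition (each uniform) against a shared-Ψ null, both
marginal likelihoods computed on the same grid in log space. The source
study defines only the BF's interpretation, not its construction; the
shared-Ψ null is this package's choice, documented here rather than
attributed. ΔΨ is the difference of posterior means (posterior means, not
MAP — also a choice). An event passes when BF > 5 and |ΔΨ| > 0.05, both
strict inequalities.

Replicates are pooled per condition before inference, mirroring the common
practice of merging replicate alignments by biological condition; a
per-replicate mode is retained in the simulator for dispersion
experiments, but no overdispersion term is modeled.

## Synthetic study generator

The generator emulates the study design the analysis assumes: two
conditions (control/treated), three replicates, 75-nt reads, one event per
gene on its own chromosome, and an event-type mix defaulting to
(cassette 0.42, alt-5′ 0.14, alt-3′ 0.23, retained-intron 0.21) — the
observed taxonomy of differential events in the emulated study. Exons are
drawn 60–300 nt and segment lengths are multiples of 3 with probability
0.5 so both frame branches are exercised; introns are ~1,000 nt (never
below 400 around cassette exons, so the 300-nt motif regions fit); half
the genes are mirrored to the minus strand. About 45% of cassette exons
are placed in UTRs (split between 5′ and 3′), matching the roughly even
CDS/UTR split reported for this kind of screen; a quarter of CDS cassettes
are "poison-exon" style, annotated on the skipped form so that inclusion
can introduce a premature stop. Annotated CDSs are built from random
non-stop codons with a proper start and stop, so the annotated isoform is
always a clean ORF.

True Ψ values: a configurable fraction of events (default 0.3) receives a
ΔΨ drawn from {±0.1, ±0.2, ±0.3}; control Ψ is uniform on the widest
interval keeping both conditions inside [0.02, 0.98]. Read counts are
multinomial over the three classes using the *quantifier's own* class
probabilities at the true Ψ — simulation and inference share one formula
by design, so empirical class frequencies converge to the model
(law-of-large-numbers tests at depth 1e5). `depth_per_event` is the
expected number of informative (inclusion- plus exclusion-specific) reads
per condition, split evenly over replicates with Poisson totals. What the
generator does **not** emulate: mapping error, positional bias,
overdispersion between replicates, multi-isoform genes, shared chromosomes.
Passing tests therefore demonstrate correctness of the inference and the
downstream logic under the stated model, not robustness to alignment
artifacts.

Statistical checks run at depth 1,000 with 200–1,000 events — sizes at
which the bands (mean |Ψ̂−Ψ| < 0.02, CI coverage 93–97%, null BF>5 rate
≤ 5%, sensitivity ≥ 0.9 at |ΔΨ| = 0.3) are comfortably resolved while the
whole suite stays fast.

## Coding consequences

Localization is by genomic overlap of the segment with the CDS span (start
through stop codon): any overlap → CDS, otherwise 5′ or 3′ UTR by position
relative to the CDS in transcript orientation. A segment touching both CDS
and UTR counts as CDS, since the protein-level consequence dominates.

Frame preservation is segment length ≡ 0 (mod 3). Premature-stop detection
translates the *minor* isoform (the one differing from the annotated
transcript) from the annotated start codon; a stop ending strictly before
the annotated stop's position on that isoform is premature. The annotated
isoform's status is recorded alongside. NMD candidacy uses the standard
50-nt rule: the premature stop must lie more than 50 nt upstream of the
isoform's final exon–exon junction. A frameshift without NMD is flagged as
a novel C-terminus. Disorder categories over the AS peptide use strict
boundaries (fraction 1 → totally disordered, 0 → structured, else
partial); the per-residue calls and PTM site tables are inputs — the
predictors themselves are external tools and out of scope. PTM intervals
are closed on both ends in protein coordinates; peptides shorter than 9
residues are excluded from disorder classification as unreliable
predictor input.

## Domain overlap

Frame-preserving CDS segments are extended by up to 30 nt into each
neighboring exon (truncated at short exons), the window is snapped inward
to codon boundaries of the annotated frame (never crossing the start or
stop codon), translated, and intersected with a table of protein-domain
intervals (1-based inclusive protein coordinates, minimum reported overlap
1 aa). Overlaps are labeled AS_only / flank_only / both so that overlap
with the alternative residues proper is distinguishable from flank-only
contact. Domain coordinates are consumed as a table; running an HMM search
is deliberately out of scope since only coordinates enter the procedure.
The stage applies only to events whose annotated isoform contains the
segment — for retained introns annotated on the spliced form there is no
segment on the annotated protein, and such events are skipped with a
logged reason.

## Dual-evidence interactions

Experimental edge lists are merged into one undirected network
(case-insensitive canonical gene pairs, duplicate edges accumulate a
source count, self-loops kept for homodimers). Structural candidates of a
disrupted domain are all genes carrying a domain paired with it in the
domain–domain interaction table, including the gene itself when the domain
self-pairs. An interaction is emitted only when the partner is both a
structural candidate and an experimental neighbor; an optional expression
filter drops partners absent from a supplied expressed-gene list (the
default fixture wires one unexpressed dual-evidence partner to exercise
it). No ortholog mapping is attempted.

## Motif regions and scanning

Seven regions per cassette event, in transcript orientation: R1/R7 the
3′-most/5′-most 150 nt of the flanking exons, R2/R3 the first/last 300 nt
of the upstream intron, R4 the cassette exon, R5/R6 the first/last 300 nt
of the downstream intron. Introns shorter than 600 nt are split at the
midpoint (first half rounded up) so R2/R3 and R5/R6 never overlap; regions
truncate to their source feature. The donor-adjacent/acceptor-adjacent
orientation of the intron halves is a fixed, strand-symmetric convention.

PWMs get a 1e-3 pseudocount and are scored as log2 odds against a 0-order
background estimated jointly from all scanned regions (configurable).
Scores are discretized to 0.01-bit bins; the null distribution of the
discretized score under the i.i.d. background is built by
dynamic-programming convolution, making every reported p-value the exact
tail mass at the hit's score (verified bit-for-bit against enumeration of
all 4^w words). Scanning is sense-strand only, as appropriate for RNA
motifs; T and U are equivalent.

Enrichment partitions passing calls by ΔΨ sign, filters hits at p < 1e-4
and controls Benjamini–Hochberg FDR at 0.1 within each (direction, motif)
stratum. The BH correction uses *all* scanned offsets of the stratum as
the test family — the stricter of the two readings of "filter then
adjust" — and a hit must satisfy both thresholds. Occurrences are tallied
per region and direction, and motifs exclusive to one direction are
reported both as motif identifiers and RBP names.

## Pipeline

Stages (simulate → quantify → classify → domains → ppi → motifs)
communicate through files (GFF3, FASTA, TSV, minimal MEME text) in one
output directory, each writing a JSON summary; a missing upstream file
raises a dependency error naming the stage. Coordinates are 0-based
half-open internally and 1-based inclusive in GFF3. All randomness flows
from a single seed, and identical configuration reproduces byte-identical
outputs. Differential-expression calling and annotation-enrichment
analysis are out of scope; DE gene lists are inputs, and
`intersect_de` performs the exact set intersection with the
alternatively spliced gene list.

## Known limitations

- The generator's multinomial noise understates replicate variability of
  real RNA-seq; calibration statements hold under the stated model.
- Single annotated transcript per gene; overlapping events per gene are
  not modeled.
- BF construction and FDR stratification are reasonable conventions, not
  uniquely determined by the emulated study's description.
- The grid CI is linearly interpolated between grid points, so interval
  endpoints are only grid-resolution accurate (~1e-3).
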