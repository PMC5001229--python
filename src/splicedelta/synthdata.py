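"""Synthetic two-condition splicing study generator.

Emulates the structure of a bulk RNA-seq splicing experiment: a toy
transcriptome of multi-exon genes, one alternative-splicing event per gene
over the four event classes (cassette exon, alternative 5'/3' splice site,
retained intron), true Ψ values per condition for control vs treated with
three replicates each, and event-level read-class counts drawn from the
same mixture model the quantifier inverts — so empirical class frequencies
converge to the model's class probabilities by construction.

Annotation fixtures (protein domains, PPI/DDI evidence tables, PTM sites,
per-residue disorder calls, RBP position-weight matrices) are generated
alongside so every downstream characterization stage is testable without
any external database.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import quant
from .events import (
    EventType,
    Interval,
    SplicingEvent,
    Transcript,
    chain_len,
)

_STOPS = ("TAA", "TAG", "TGA")
_NT = np.array(list("ACGT"))

_DEFAULT_MIX = {
    EventType.CASSETTE: 0.42,
    EventType.ALT5: 0.14,
    EventType.ALT3: 0.23,
    EventType.RETAINED_INTRON: 0.21,
}


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic experiment.

    Defaults mirror the emulated study: two conditions in triplicate,
    75-nt reads, and an event-type mix matching the observed taxonomy of
    differential events (cassette 0.42, alt-5' 0.14, alt-3' 0.23, retained
    intron 0.21). ``depth_per_event`` is the expected number of informative
    (inclusion- plus exclusion-specific) reads per condition, split evenly
    across replicates.
    """

    n_genes: int = 50
    event_type_mix: dict = field(default_factory=lambda: dict(_DEFAULT_MIX))
    read_length: int = 75
    depth_per_event: float = 1000.0
    n_replicates: int = 3
    delta_psi_effects: tuple = (0.1, 0.2, 0.3, -0.1, -0.2, -0.3)
    frac_affected: float = 0.3
    seed: int = 0
    # structural knobs
    intron_length: int = 1000
    min_flank_intron: int = 400
    exon_len_range: tuple = (60, 300)
    cassette_utr_fraction: float = 0.45
    minus_strand_fraction: float = 0.5
    poison_exon_fraction: float = 0.25  # CDS cassettes annotated on the skipped form

    def __post_init__(self) -> None:
        self.event_type_mix = {EventType(k): v for k, v in self.event_type_mix.items()}
        total = sum(self.event_type_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"event_type_mix must sum to 1 (got {total})")
        if any(v < 0 for v in self.event_type_mix.values()):
            raise ValueError("event_type_mix proportions must be non-negative")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20 nt")
        if self.depth_per_event < 0:
            raise ValueError("depth_per_event must be >= 0")
        if not 0.0 <= self.frac_affected <= 1.0:
            raise ValueError("frac_affected must be in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth splicing parameters for one event."""

    event_id: str
    true_psi_control: float
    true_psi_treated: float
    is_differential: bool

    def __post_init__(self) -> None:
        diff = abs(self.true_psi_treated - self.true_psi_control) > 0
        if diff != self.is_differential:
            raise ValueError("is_differential inconsistent with Ψ values")


@dataclass
class Transcriptome:
    transcripts: dict[str, Transcript]  # annotated isoform per gene
    genome: dict[str, str]
    events: list[SplicingEvent]

    def host(self, event: SplicingEvent) -> Transcript:
        return self.transcripts[event.transcript_id]


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def _random_cds(rng: np.random.Generator, n_nt: int) -> str:
    """ATG + random non-stop codons + one stop codon; n_nt must be a
    multiple of 3 and >= 9."""
    assert n_nt % 3 == 0 and n_nt >= 9
    codons = ["ATG"]
    for _ in range(n_nt // 3 - 2):
        while True:
            c = _random_seq(rng, 3)
            if c not in _STOPS:
                break
        codons.append(c)
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


def _mixed_mod3(rng: np.random.Generator, lo: int, hi: int) -> int:
    """Draw a length in [lo, hi], a multiple of 3 with probability 1/2."""
    n = int(rng.integers(lo, hi + 1))
    if rng.random() < 0.5:
        n -= n % 3
    elif n % 3 == 0:
        n += 1 + int(rng.integers(0, 2))
    return n


def _intron_len(rng: np.random.Generator, cfg: SimConfig, flanking: bool) -> int:
    n = int(rng.integers(cfg.intron_length - 100, cfg.intron_length + 101))
    if flanking:
        n = max(n, cfg.min_flank_intron)
    return n


@dataclass
class _Layout:
    """Plus-strand gene layout: named pieces laid left-to-right."""

    pieces: list = field(default_factory=list)  # (name, length)
    seqs: dict = field(default_factory=dict)

    def add(self, name: str, length: int, seq: str | None = None):
        self.pieces.append((name, length))
        if seq is not None:
            assert len(seq) == length
            self.seqs[name] = seq

    def intervals(self) -> dict[str, Interval]:
        out, pos = {}, 0
        for name, length in self.pieces:
            out[name] = (pos, pos + length)
            pos += length
        return out

    def fill_random(self, rng: np.random.Generator):
        for name, length in self.pieces:
            if name not in self.seqs:
                self.seqs[name] = _random_seq(rng, length)

    def chrom_seq(self) -> str:
        return "".join(self.seqs[name] for name, _ in self.pieces)


def _spread_mrna(layout: _Layout, exon_names: list[str], mrna: str) -> None:
    """Slice a designed mRNA across the named exonic pieces (in order)."""
    pos = 0
    lens = dict((n, l) for n, l in layout.pieces)
    for name in exon_names:
        layout.seqs[name] = mrna[pos : pos + lens[name]]
        pos += lens[name]
    assert pos == len(mrna)


def _design_mrna(
    rng: np.random.Generator, total: int, utr5: int, utr3_min: int
) -> tuple[str, int, int]:
    """mRNA with a maximal in-frame CDS between utr5 and >=utr3_min tail.

    Returns (sequence, cds_off_start, cds_off_end) in spliced coordinates.
    """
    cds_len = 3 * ((total - utr5 - utr3_min) // 3)
    assert cds_len >= 9, "gene too short for a CDS"
    utr3 = total - utr5 - cds_len
    seq = _random_seq(rng, utr5) + _random_cds(rng, cds_len) + _random_seq(rng, utr3)
    return seq, utr5, utr5 + cds_len


def _build_gene(
    gtype: EventType, idx: int, rng: np.random.Generator, cfg: SimConfig
) -> tuple[Transcript, SplicingEvent, str]:
    """One gene on its own chromosome with a single AS event (plus strand;
    the caller may mirror the whole chromosome for minus-strand genes)."""
    gene_id = f"gene{idx:04d}"
    tx_id = f"{gene_id}.t1"
    chrom = f"chr_{gene_id}"
    lo, hi = cfg.exon_len_range
    exl = lambda: int(rng.integers(max(lo, 120), hi + 1))  # flanks comfortably > 60
    lay = _Layout()
    lay.add("padL", 100)

    if gtype is EventType.CASSETTE:
        lens = dict(E1=exl(), E2=exl(), C=_mixed_mod3(rng, lo, hi), E4=exl(), E5=exl())
        lay.add("E1", lens["E1"]); lay.add("I1", _intron_len(rng, cfg, False))
        lay.add("E2", lens["E2"]); lay.add("I2", _intron_len(rng, cfg, True))
        lay.add("C", lens["C"]);   lay.add("I3", _intron_len(rng, cfg, True))
        lay.add("E4", lens["E4"]); lay.add("I4", _intron_len(rng, cfg, False))
        lay.add("E5", lens["E5"])
        u = rng.random()
        if u < cfg.cassette_utr_fraction / 2:
            loc, annotated = "UTR5", "inclusion"
        elif u < cfg.cassette_utr_fraction:
            loc, annotated = "UTR3", "inclusion"
        elif rng.random() < cfg.poison_exon_fraction:
            loc, annotated = "CDS", "exclusion"
        else:
            loc, annotated = "CDS", "inclusion"
        ann_exons = ["E1", "E2", "C", "E4", "E5"]
        if annotated == "exclusion":
            ann_exons = ["E1", "E2", "E4", "E5"]
        total = sum(lens[e] for e in ann_exons)
        if loc == "CDS":
            mrna, off_s, off_e = _design_mrna(rng, total, 30, 60)
        elif loc == "UTR5":
            utr5 = lens["E1"] + lens["E2"] + lens["C"] + 20
            mrna, off_s, off_e = _design_mrna(rng, total, utr5, 40)
        else:  # UTR3: CDS confined to E1+E2
            head = lens["E1"] + lens["E2"]
            m_head, off_s, off_e = _design_mrna(rng, head, 30, 20)
            mrna = m_head + _random_seq(rng, total - head)
        _spread_mrna(lay, ann_exons, mrna)
        lay.fill_random(rng)
        iv = lay.intervals()
        inc_chain = (iv["E2"], iv["C"], iv["E4"])
        exc_chain = (iv["E2"], iv["E4"])
        seg, up, down = iv["C"], iv["E2"], iv["E4"]
        full_exons = tuple(iv[e] for e in ["E1", "E2", "C", "E4", "E5"])
        if annotated == "exclusion":
            full_exons = tuple(iv[e] for e in ["E1", "E2", "E4", "E5"])

    elif gtype in (EventType.ALT5, EventType.ALT3):
        ext = _mixed_mod3(rng, 30, 120)
        lens = dict(E1=exl(), E2=exl(), E3=exl(), E4=exl())
        lay.add("E1", lens["E1"]); lay.add("I1", _intron_len(rng, cfg, False))
        if gtype is EventType.ALT5:  # donor-side extension of E2
            lay.add("E2", lens["E2"]); lay.add("S", ext)
            lay.add("I2", _intron_len(rng, cfg, False))
            lay.add("E3", lens["E3"])
        else:  # acceptor-side extension of E3
            lay.add("E2", lens["E2"]); lay.add("I2", _intron_len(rng, cfg, False))
            lay.add("S", ext); lay.add("E3", lens["E3"])
        lay.add("I3", _intron_len(rng, cfg, False)); lay.add("E4", lens["E4"])
        annotated, loc = "inclusion", "CDS"
        ann_exons = ["E1", "E2", "S", "E3", "E4"]
        total = lens["E1"] + lens["E2"] + ext + lens["E3"] + lens["E4"]
        mrna, off_s, off_e = _design_mrna(rng, total, 30, 60)
        _spread_mrna(lay, ann_exons, mrna)
        lay.fill_random(rng)
        iv = lay.intervals()
        seg = iv["S"]
        if gtype is EventType.ALT5:
            long2 = (iv["E2"][0], iv["S"][1])
            inc_chain, exc_chain = (long2, iv["E3"]), (iv["E2"], iv["E3"])
            up, down = iv["E2"], iv["E3"]
            full_exons = (iv["E1"], long2, iv["E3"], iv["E4"])
        else:
            long3 = (iv["S"][0], iv["E3"][1])
            inc_chain, exc_chain = (iv["E2"], long3), (iv["E2"], iv["E3"])
            up, down = iv["E2"], iv["E3"]
            full_exons = (iv["E1"], iv["E2"], long3, iv["E4"])

    elif gtype is EventType.RETAINED_INTRON:
        lens = dict(E1=exl(), E2=exl(), E3=exl(), E4=exl())
        ri_len = _mixed_mod3(rng, cfg.intron_length - 100, cfg.intron_length + 100)
        lay.add("E1", lens["E1"]); lay.add("I1", _intron_len(rng, cfg, False))
        lay.add("E2", lens["E2"]); lay.add("I2", ri_len)
        lay.add("E3", lens["E3"]); lay.add("I3", _intron_len(rng, cfg, False))
        lay.add("E4", lens["E4"])
        annotated, loc = "exclusion", "CDS"
        ann_exons = ["E1", "E2", "E3", "E4"]
        total = sum(lens[e] for e in ann_exons)
        mrna, off_s, off_e = _design_mrna(rng, total, 30, 60)
        _spread_mrna(lay, ann_exons, mrna)
        lay.fill_random(rng)
        iv = lay.intervals()
        seg = iv["I2"]
        inc_chain = ((iv["E2"][0], iv["E3"][1]),)
        exc_chain = (iv["E2"], iv["E3"])
        up, down = iv["E2"], iv["E3"]
        full_exons = tuple(iv[e] for e in ann_exons)
    else:  # pragma: no cover
        raise ValueError(gtype)

    lay.add("padR", 100)
    lay.fill_random(rng)
    chrom_seq = lay.chrom_seq()
    # CDS genomic bounds from spliced offsets on the annotated chain
    from .events import spliced_to_genomic

    cds_start = spliced_to_genomic(full_exons, "+", off_s)
    cds_end = spliced_to_genomic(full_exons, "+", off_e - 1) + 1
    tx = Transcript(tx_id, gene_id, chrom, "+", full_exons, cds_start, cds_end)
    ev = SplicingEvent(
        event_id=f"ev_{gene_id}",
        event_type=gtype,
        gene_id=gene_id,
        transcript_id=tx_id,
        chrom=chrom,
        strand="+",
        alt_segment=seg,
        upstream_exon=up,
        downstream_exon=down,
        inclusion_chain=inc_chain,
        exclusion_chain=exc_chain,
        annotated_isoform=annotated,
    )
    if rng.random() < cfg.minus_strand_fraction:
        tx, ev, chrom_seq = mirror_gene(tx, ev, chrom_seq)
    return tx, ev, chrom_seq


def _flip_iv(iv: Interval, L: int) -> Interval:
    return (L - iv[1], L - iv[0])


def mirror_gene(
    tx: Transcript, ev: SplicingEvent, chrom_seq: str
) -> tuple[Transcript, SplicingEvent, str]:
    """Reverse-complement a whole chromosome and flip all annotations.

    The mirrored gene expresses the identical mRNA on the opposite strand,
    which makes this the canonical strand-invariance oracle as well as the
    generator's minus-strand path.
    """
    L = len(chrom_seq)
    flip = lambda ch: tuple(sorted(_flip_iv(iv, L) for iv in ch))
    new_strand = "-" if tx.strand == "+" else "+"
    tx2 = Transcript(
        tx.transcript_id, tx.gene_id, tx.chrom, new_strand, flip(tx.exons),
        L - tx.cds_end if tx.has_cds else None,
        L - tx.cds_start if tx.has_cds else None,
    )
    ev2 = SplicingEvent(
        event_id=ev.event_id, event_type=ev.event_type, gene_id=ev.gene_id,
        transcript_id=ev.transcript_id, chrom=ev.chrom, strand=new_strand,
        alt_segment=_flip_iv(ev.alt_segment, L),
        upstream_exon=_flip_iv(ev.upstream_exon, L),
        downstream_exon=_flip_iv(ev.downstream_exon, L),
        inclusion_chain=flip(ev.inclusion_chain),
        exclusion_chain=flip(ev.exclusion_chain),
        annotated_isoform=ev.annotated_isoform,
    )
    return tx2, ev2, str(Seq(chrom_seq).reverse_complement())


def make_transcriptome(config: SimConfig) -> Transcriptome:
    """Build the toy transcriptome: one gene/chromosome per event."""
    rng = np.random.default_rng(config.seed)
    types = list(config.event_type_mix)
    probs = np.array([config.event_type_mix[t] for t in types], dtype=float)
    draws = rng.choice(len(types), size=config.n_genes, p=probs)
    transcripts, genome, events = {}, {}, []
    for i, ti in enumerate(draws):
        tx, ev, seq = _build_gene(types[int(ti)], i, rng, config)
        transcripts[tx.transcript_id] = tx
        genome[tx.chrom] = seq
        events.append(ev)
    return Transcriptome(transcripts, genome, events)


# ---------------------------------------------------------------------------
# truth and counts
# ---------------------------------------------------------------------------

def assign_truth(
    events: list[SplicingEvent], config: SimConfig, rng: np.random.Generator | None = None
) -> dict[str, SimTruth]:
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    truth = {}
    for ev in events:
        if rng.random() < config.frac_affected and config.delta_psi_effects:
            delta = float(rng.choice(np.asarray(config.delta_psi_effects, dtype=float)))
            lo = max(0.02, 0.02 - delta)
            hi = min(0.98, 0.98 - delta)
            psi_c = float(rng.uniform(lo, hi))
            truth[ev.event_id] = SimTruth(ev.event_id, psi_c, psi_c + delta, True)
        else:
            psi = float(rng.uniform(0.05, 0.95))
            truth[ev.event_id] = SimTruth(ev.event_id, psi, psi, False)
    return truth


def simulate_counts(
    events: list[SplicingEvent],
    truth: dict[str, SimTruth],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    sizes: dict[str, quant.EffectiveSizes] | None = None,
) -> pd.DataFrame:
    """Multinomial read-class counts per event, condition and replicate.

    Reads are allocated to {inclusion-specific, exclusion-specific, shared}
    with the quantifier's own class probabilities at the true Ψ, so the
    simulation is model-consistent by construction. The replicate total is
    Poisson around depth_per_event / n_replicates informative reads.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if sizes is None:
        sizes = {
            ev.event_id: quant.effective_sizes(ev, config.read_length) for ev in events
        }
    rows = []
    for ev in events:
        if ev.event_id not in truth:
            raise KeyError(f"no truth record for event {ev.event_id}")
        t = truth[ev.event_id]
        sz = sizes[ev.event_id]
        if not sz.testable:
            continue
        for cond, psi in (("control", t.true_psi_control), ("treated", t.true_psi_treated)):
            p = np.array(quant.class_probabilities(psi, sz), dtype=float)
            p_inf = p[0] + p[1]
            mean_total = (config.depth_per_event / config.n_replicates) / max(p_inf, 1e-12)
            for rep in range(1, config.n_replicates + 1):
                n = rng.poisson(mean_total)
                n_inc, n_exc, n_sh = rng.multinomial(n, p)
                rows.append((ev.event_id, cond, rep, int(n_inc), int(n_exc), int(n_sh)))
    return pd.DataFrame(
        rows, columns=["event_id", "condition", "replicate", "n_inc", "n_exc", "n_shared"]
    )


def counts_frame_to_event_counts(
    df: pd.DataFrame, sizes: dict[str, quant.EffectiveSizes]
) -> dict[str, dict[str, list[quant.EventCounts]]]:
    """Regroup a counts table into quant's event → condition → replicates map."""
    out: dict[str, dict[str, list[quant.EventCounts]]] = {}
    for row in df.itertuples(index=False):
        if row.event_id not in sizes or not sizes[row.event_id].testable:
            continue
        out.setdefault(row.event_id, {}).setdefault(row.condition, []).append(
            quant.EventCounts(
                row.event_id, row.condition, row.n_inc, row.n_exc, row.n_shared,
                sizes[row.event_id],
            )
        )
    return out


# ---------------------------------------------------------------------------
# annotation fixtures
# ---------------------------------------------------------------------------

_DOMAIN_NAMES = [
    ("PF00069", "Pkinase", "Protein kinase domain"),
    ("PF03528", "Rabaptin", "Rabaptin GTPase binding"),
    ("PF00104", "Hormone_recep", "Nuclear hormone receptor ligand-binding"),
    ("PF00076", "RRM_1", "RNA recognition motif"),
    ("PF00595", "PDZ", "PDZ domain"),
    ("PF00018", "SH3_1", "SH3 domain"),
    ("PF00169", "PH", "Pleckstrin homology domain"),
]


@dataclass
class AnnotationFixtures:
    domains: pd.DataFrame          # protein_id, accession, name, description, start_aa, end_aa
    ppi_edges: list[pd.DataFrame]  # >= 2 experimental edge lists (gene_a, gene_b, source)
    ddi: pd.DataFrame              # dom_a, dom_b
    gene_domains: pd.DataFrame     # gene, accession (protein→domain map)
    ptm: pd.DataFrame              # protein_id, position, type, source
    disorder: pd.DataFrame         # protein_id, residue_index, call
    pwms: list                     # motifs.PWM objects
    expressed_genes: set
    as_genes_with_domains: list    # (gene, accession) used in the PPI wiring


def make_annotation_fixtures(
    transcriptome: Transcriptome,
    config: SimConfig,
    n_domain_overlaps: int = 7,
    include_unexpressed_partner: bool = True,
    rng: np.random.Generator | None = None,
) -> AnnotationFixtures:
    """Annotation tables wired so downstream stages have known answers.

    Three AS genes carrying disrupted domains are connected to eight
    expressed partners with both experimental (PPI) and structural (DDI)
    evidence, plus one unexpressed dual-evidence partner, one
    structural-only and one experimental-only distractor, and one
    self-interacting domain pair (a homodimerization pattern).
    """
    from . import domains as dom_mod
    from .motifs import PWM

    if rng is None:
        rng = np.random.default_rng(config.seed + 3)

    # protein intervals of AS segments on eligible events
    eligible = []
    for ev in transcriptome.events:
        host = transcriptome.host(ev)
        try:
            iv = dom_mod.as_protein_interval(ev, host)
        except ValueError:
            continue
        if iv is not None:
            eligible.append((ev, host, iv))

    dom_rows, ddi_rows, gd_rows = [], [], []
    as_wiring = []
    for k, (ev, host, (aa_s, aa_e)) in enumerate(eligible[:n_domain_overlaps]):
        acc, name, desc = _DOMAIN_NAMES[k % len(_DOMAIN_NAMES)]
        prot = host.transcript_id + "_prot"
        dom_rows.append((prot, acc, name, desc, max(1, aa_s - 5), aa_e + 5))
        gd_rows.append((ev.gene_id, acc))
        if len(as_wiring) < 3:
            as_wiring.append((ev.gene_id, acc))

    # PPI / DDI wiring around the first three AS genes
    edges_a, edges_b = [], []  # two experimental datasets to merge
    expressed = {g for g, _ in as_wiring}
    partner_alloc = [3, 3, 2]
    pi = 0
    for (gene, acc), n_part in zip(as_wiring, partner_alloc):
        for _ in range(n_part):
            pi += 1
            partner, pdom = f"partner{pi}", f"PD{pi:04d}"
            ddi_rows.append((acc, pdom))
            gd_rows.append((partner, pdom))
            (edges_a if pi % 2 else edges_b).append((gene, partner, f"ds{pi % 2 + 1}"))
            expressed.add(partner)
    if as_wiring:
        g0, a0 = as_wiring[0]
        ddi_rows.append((a0, a0))  # homodimerization: structural self-pair
        if include_unexpressed_partner:
            partner, pdom = "partner_unexpr", "PD9999"
            ddi_rows.append((a0, pdom))
            gd_rows.append((partner, pdom))
            edges_a.append((g0, partner, "ds1"))
        # distractors
        gd_rows.append(("struct_only", "PDS001"))
        ddi_rows.append((a0, "PDS001"))          # structural but no PPI edge
        edges_b.append((g0, "exp_only", "ds2"))  # experimental but no DDI
        expressed.update({"struct_only", "exp_only"})

    domains_df = pd.DataFrame(
        dom_rows, columns=["protein_id", "accession", "name", "description", "start_aa", "end_aa"]
    )
    ddi_df = pd.DataFrame(ddi_rows, columns=["dom_a", "dom_b"])
    gd_df = pd.DataFrame(gd_rows, columns=["gene", "accession"])
    ppi_lists = [
        pd.DataFrame(edges_a, columns=["gene_a", "gene_b", "source"]),
        pd.DataFrame(edges_b, columns=["gene_a", "gene_b", "source"]),
    ]

    # PTM sites: 14 cleavage sites across AS intervals (a proteolytic-
    # cleavage tally fixture), a handful of phosphosites, plus off-region sites
    ptm_rows = []
    if eligible:
        for j in range(14):
            ev, host, (aa_s, aa_e) = eligible[j % len(eligible)]
            pos = aa_s + (j % max(1, aa_e - aa_s + 1))
            ptm_rows.append((host.transcript_id + "_prot", pos, "cleavage", "predicted"))
        for j in range(5):
            ev, host, (aa_s, aa_e) = eligible[j % len(eligible)]
            ptm_rows.append((host.transcript_id + "_prot", aa_s, "phosphorylation", "known"))
        ev, host, (aa_s, aa_e) = eligible[0]
        ptm_rows.append((host.transcript_id + "_prot", max(1, aa_s - 50), "acetylation", "known"))
    ptm_df = pd.DataFrame(ptm_rows, columns=["protein_id", "position", "type", "source"])

    # per-residue disorder over each AS peptide, with category mix 52/33/15
    dis_rows = []
    for ev, host, (aa_s, aa_e) in eligible:
        u = rng.random()
        prot = host.transcript_id + "_prot"
        for pos in range(aa_s, aa_e + 1):
            if u < 0.52:
                call = 1
            elif u < 0.85:
                call = int(rng.random() < 0.5)
            else:
                call = 0
            dis_rows.append((prot, pos, call))
    disorder_df = pd.DataFrame(dis_rows, columns=["protein_id", "residue_index", "call"])

    pwms = [planted_pwm()]
    for i in range(8):
        w = int(rng.integers(6, 9))
        mat = rng.dirichlet(np.ones(4), size=w)
        pwms.append(PWM(f"M{i:03d}", f"RBP{i:03d}", np.asarray(mat)))

    return AnnotationFixtures(
        domains=domains_df, ppi_edges=ppi_lists, ddi=ddi_df, gene_domains=gd_df,
        ptm=ptm_df, disorder=disorder_df, pwms=pwms,
        expressed_genes=expressed, as_genes_with_domains=as_wiring,
    )


def planted_pwm(width: int = 8, strength: float = 0.97, motif_id: str = "PLANTED",
                rbp: str = "PLANTED_RBP"):
    """A near-deterministic PWM whose consensus can be planted and recovered."""
    from .motifs import PWM

    rng = np.random.default_rng(12345)
    cons = rng.integers(0, 4, size=width)
    mat = np.full((width, 4), (1.0 - strength) / 3)
    mat[np.arange(width), cons] = strength
    return PWM(motif_id, rbp, mat)


def plant_motif(
    transcriptome: Transcriptome,
    truth: dict[str, SimTruth],
    pwm,
    region_index: int = 3,
    direction: str = "up",
    config: SimConfig | None = None,
) -> Transcriptome:
    """Write a PWM's consensus into one regulatory region of every
    differential cassette event of the given ΔΨ direction.

    Returns a new Transcriptome sharing annotations but with edited genome
    sequences; used for plant-and-recover tests of the motif scanner.
    """
    from .motifs import extract_regions

    consensus = "".join("ACGT"[i] for i in np.argmax(pwm.matrix, axis=1))
    genome = dict(transcriptome.genome)
    for ev in transcriptome.events:
        if ev.event_type is not EventType.CASSETTE:
            continue
        t = truth.get(ev.event_id)
        if t is None or not t.is_differential:
            continue
        d = t.true_psi_treated - t.true_psi_control
        if (direction == "up") != (d > 0):
            continue
        regions = extract_regions(ev, genome)
        reg = regions.regions[region_index - 1]
        s, e = reg.interval
        if e - s < len(consensus):
            continue
        mid = s + (e - s - len(consensus)) // 2
        insert = consensus
        if ev.strand == "-":
            insert = str(Seq(consensus).reverse_complement())
        seq = genome[ev.chrom]
        genome[ev.chrom] = seq[:mid] + insert + seq[mid + len(insert):]
    return Transcriptome(transcriptome.transcripts, genome, transcriptome.events)
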