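"""Shared fixtures: a hand-controllable toy cassette gene and a small
simulated study reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from splicedelta.events import (
    EventType,
    SplicingEvent,
    Transcript,
    spliced_to_genomic,
)
from splicedelta.synthdata import (
    SimConfig,
    assign_truth,
    make_transcriptome,
    mirror_gene,
    simulate_counts,
)

_STOPS = {"TAA", "TAG", "TGA"}
_NT = "ACGT"


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[i] for i in rng.integers(0, 4, size=n))


def _nonstop_codons(rng: np.random.Generator, n_codons: int) -> str:
    out = []
    while len(out) < n_codons:
        c = _rand_seq(rng, 3)
        if c not in _STOPS:
            out.append(c)
    return "".join(out)


def toy_cassette_gene(
    cassette_len: int = 72,
    cassette_seq: str | None = None,
    annotated: str = "inclusion",
    cds_mode: str = "CDS",  # CDS | UTR5 | UTR3
    e_lens: tuple = (90, 60, 60, 120),
    introns: tuple = (200, 450, 450, 200),
    utr5: int = 30,
    seed: int = 0,
    mirror: bool = False,
):
    """Build one cassette gene with full control over the cassette content.

    Returns (transcript, event, genome). The chromosome is laid out
    pad-E1-I1-E2-I2-C-I3-E4-I4-E5-pad on the plus strand; *mirror* flips the
    whole chromosome to the minus strand.
    """
    rng = np.random.default_rng(seed)
    l1, l2, l4, l5 = e_lens
    lc = len(cassette_seq) if cassette_seq is not None else cassette_len
    lens = dict(E1=l1, E2=l2, C=lc, E4=l4, E5=l5)
    ann_names = ["E1", "E2", "C", "E4", "E5"]
    if annotated == "exclusion":
        ann_names = ["E1", "E2", "E4", "E5"]
    total = sum(lens[n] for n in ann_names)
    if cds_mode == "CDS":
        cds_len = 3 * ((total - utr5 - 60) // 3)
        head, tail = utr5, total - utr5 - cds_len
        mrna = (_rand_seq(rng, head) + "ATG" + _nonstop_codons(rng, cds_len // 3 - 2)
                + "TAA" + _rand_seq(rng, tail))
        off_s, off_e = head, head + cds_len
    elif cds_mode == "UTR5":
        head = lens["E1"] + lens["E2"] + (lc if "C" in ann_names else 0) + 20
        cds_len = 3 * ((total - head - 40) // 3)
        mrna = (_rand_seq(rng, head) + "ATG" + _nonstop_codons(rng, cds_len // 3 - 2)
                + "TAA" + _rand_seq(rng, total - head - cds_len))
        off_s, off_e = head, head + cds_len
    elif cds_mode == "UTR3":
        span = lens["E1"] + lens["E2"]
        cds_len = 3 * ((span - utr5 - 20) // 3)
        mrna = (_rand_seq(rng, utr5) + "ATG" + _nonstop_codons(rng, cds_len // 3 - 2)
                + "TAA" + _rand_seq(rng, total - utr5 - cds_len))
        off_s, off_e = utr5, utr5 + cds_len
    else:
        raise ValueError(cds_mode)

    seqs, pos = {}, 0
    for n in ann_names:
        seqs[n] = mrna[pos : pos + lens[n]]
        pos += lens[n]
    if "C" not in seqs:
        seqs["C"] = cassette_seq if cassette_seq is not None else _rand_seq(rng, lc)
    elif cassette_seq is not None:
        seqs["C"] = cassette_seq

    order = ["padL", "E1", "I1", "E2", "I2", "C", "I3", "E4", "I4", "E5", "padR"]
    ilens = dict(zip(["I1", "I2", "I3", "I4"], introns))
    piece_len = dict(padL=50, padR=50, **lens, **ilens)
    for n in order:
        if n not in seqs:
            seqs[n] = _rand_seq(rng, piece_len[n])
    iv, pos = {}, 0
    for n in order:
        iv[n] = (pos, pos + piece_len[n])
        pos += piece_len[n]
    chrom_seq = "".join(seqs[n] for n in order)

    ann_chain = tuple(iv[n] for n in ann_names)
    cds_start = spliced_to_genomic(ann_chain, "+", off_s)
    cds_end = spliced_to_genomic(ann_chain, "+", off_e - 1) + 1
    tx = Transcript("toy.t1", "toy", "chr_toy", "+", ann_chain, cds_start, cds_end)
    ev = SplicingEvent(
        event_id="ev_toy", event_type=EventType.CASSETTE, gene_id="toy",
        transcript_id="toy.t1", chrom="chr_toy", strand="+",
        alt_segment=iv["C"], upstream_exon=iv["E2"], downstream_exon=iv["E4"],
        inclusion_chain=(iv["E2"], iv["C"], iv["E4"]),
        exclusion_chain=(iv["E2"], iv["E4"]),
        annotated_isoform=annotated,
    )
    if mirror:
        tx, ev, chrom_seq = mirror_gene(tx, ev, chrom_seq)
    return tx, ev, {"chr_toy": chrom_seq}


@pytest.fixture
def toy_gene_factory():
    return toy_cassette_gene


@pytest.fixture(scope="session")
def small_study():
    """A 40-gene simulated study shared by read-only tests."""
    cfg = SimConfig(n_genes=40, seed=11)
    txome = make_transcriptome(cfg)
    truth = assign_truth(txome.events, cfg)
    counts = simulate_counts(txome.events, truth, cfg)
    return cfg, txome, truth, counts
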