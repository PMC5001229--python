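"""Flanked-peptide translation and protein-domain overlap.

Each frame-preserving, CDS-localized alternative segment is extended by up
to 30 nt into the upstream and downstream exons, the window is translated
in the annotated reading frame, and the resulting peptide interval is
intersected with a table of protein-domain coordinates. Overlaps are
reported separately for the alternative segment proper and for the flanks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .events import (
    Interval,
    SplicingEvent,
    Transcript,
    genomic_to_spliced,
    interval_len,
)

FLANK_NT = 30


@dataclass(frozen=True)
class DomainInterval:
    protein_id: str
    accession: str
    name: str
    start_aa: int  # 1-based inclusive
    end_aa: int
    description: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start_aa <= self.end_aa:
            raise ValueError(f"bad domain interval {self.start_aa}..{self.end_aa}")


@dataclass(frozen=True)
class FlankedPeptide:
    event_id: str
    protein_id: str
    window_nt: str              # spliced window (AS segment + <=30 nt flanks)
    peptide: str
    as_aa: tuple[int, int]      # 1-based inclusive protein coords of AS portion
    window_aa: tuple[int, int]  # same, for the whole translated window


def protein_id_for(tx: Transcript) -> str:
    return tx.transcript_id + "_prot"


def _segment_spliced(event: SplicingEvent, host: Transcript) -> tuple[int, int]:
    """Spliced [start, end) of the alternative segment on the host mRNA."""
    s, e = event.alt_segment
    g5 = s if host.strand == "+" else e - 1
    off = genomic_to_spliced(host.exons, host.strand, g5)
    return off, off + interval_len(event.alt_segment)


def as_protein_interval(
    event: SplicingEvent, host: Transcript
) -> tuple[int, int] | None:
    """1-based inclusive protein coordinates of the alternative segment.

    Returns None when the segment is not frame-preserving or not fully
    inside the CDS (excluding the stop codon). Raises if the annotated
    isoform does not contain the segment (the segment then has no
    coordinates on the annotated protein).
    """
    if event.annotated_isoform != "inclusion":
        raise ValueError(
            f"{event.event_id}: annotated isoform lacks the alternative segment"
        )
    if not host.has_cds:
        raise ValueError(f"{host.transcript_id} has no CDS annotation")
    if event.segment_length % 3 != 0:
        return None
    s0, s1 = _segment_spliced(event, host)
    cds_off = host.cds_offset()
    cds_len = host.stop_end_offset() - cds_off
    rel = s0 - cds_off
    if rel < 3 or rel + (s1 - s0) > cds_len - 3:  # inside CDS, past ATG, before stop
        return None
    # residues touched by the segment (codon boundaries need not align)
    return rel // 3 + 1, (rel + (s1 - s0) - 1) // 3 + 1


def build_flanked_peptide(
    event: SplicingEvent,
    host: Transcript,
    genome: dict[str, str],
    flank: int = FLANK_NT,
) -> FlankedPeptide:
    """Translate the AS segment with up to *flank* nt of each neighboring exon.

    The window start is advanced (and the end trimmed) to the nearest codon
    boundary of the annotated ORF, so translation is always in the
    annotated frame.
    """
    aa_iv = as_protein_interval(event, host)
    if aa_iv is None:
        raise ValueError(
            f"{event.event_id}: segment not frame-preserving CDS; no flanked peptide"
        )
    s0, s1 = _segment_spliced(event, host)
    up, down = event.upstream_exon, event.downstream_exon  # transcript-sense
    fu = min(flank, interval_len(up))
    fd = min(flank, interval_len(down))
    w0, w1 = s0 - fu, s1 + fd
    cds_off = host.cds_offset()
    stop_start = host.stop_end_offset() - 3
    w0 = max(w0, cds_off + 3)       # never include the start codon
    w1 = min(w1, stop_start)        # never run into the stop codon
    w0 += (3 - (w0 - cds_off) % 3) % 3
    w1 -= (w1 - cds_off) % 3
    mrna = host.mrna(genome)
    window = mrna[w0:w1]
    peptide = str(Seq(window).translate())
    window_aa = ((w0 - cds_off) // 3 + 1, (w1 - cds_off) // 3)
    return FlankedPeptide(
        event.event_id, protein_id_for(host), window, peptide, aa_iv, window_aa
    )


@dataclass(frozen=True)
class DomainOverlap:
    event_id: str
    protein_id: str
    accession: str
    name: str
    overlap_aa: int
    which_part: str  # AS_only | flank_only | both


def overlap_domains(
    peptide: FlankedPeptide,
    domain_table: Iterable[DomainInterval],
    min_overlap: int = 1,
) -> list[DomainOverlap]:
    """Intersect the flanked-peptide window with domain intervals.

    Domains on other proteins are ignored. ``which_part`` records whether
    the intersection covers the alternative segment's residues, flank
    residues only, or both.
    """
    out: list[DomainOverlap] = []
    (w0, w1), (a0, a1) = peptide.window_aa, peptide.as_aa
    for dom in domain_table:
        if dom.protein_id != peptide.protein_id:
            continue
        o0, o1 = max(dom.start_aa, w0), min(dom.end_aa, w1)
        if o1 - o0 + 1 < min_overlap:
            continue
        n_as = max(0, min(o1, a1) - max(o0, a0) + 1)
        n_flank = (o1 - o0 + 1) - n_as
        which = "both" if n_as and n_flank else ("AS_only" if n_as else "flank_only")
        out.append(
            DomainOverlap(peptide.event_id, peptide.protein_id, dom.accession,
                          dom.name, o1 - o0 + 1, which)
        )
    return out


def domains_from_frame(df: pd.DataFrame) -> list[DomainInterval]:
    return [
        DomainInterval(
            r.protein_id, r.accession, r.name, int(r.start_aa), int(r.end_aa),
            getattr(r, "description", ""),
        )
        for r in df.itertuples(index=False)
    ]
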