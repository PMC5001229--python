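"""Coding-consequence classification of differential splicing events.

Localizes the alternative segment within the host transcript (CDS vs
5'/3' UTR), decides frame preservation (segment length ≡ 0 mod 3), detects
premature termination codons by translating the minor isoform from the
annotated start codon, applies the 50-nt rule for NMD candidacy, and
tallies disorder categories and PTM-site overlaps from supplied
per-residue annotation tables (the predictors themselves are inputs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq

from .events import (
    SplicingEvent,
    Transcript,
    genomic_to_spliced,
    isoform_transcripts,
)

NMD_RULE_NT = 50
MIN_PEPTIDE_AA = 9


@dataclass(frozen=True)
class CodingAnnotation:
    event_id: str
    localization: str  # CDS | UTR5 | UTR3
    frame_preserving: bool | None = None   # defined only for CDS
    premature_stop: bool | None = None     # minor (variant) isoform
    nmd_candidate: bool | None = None
    novel_cterm: bool | None = None
    premature_stop_major: bool | None = None

    def __post_init__(self) -> None:
        if self.localization not in ("CDS", "UTR5", "UTR3"):
            raise ValueError(f"bad localization {self.localization!r}")
        if self.localization != "CDS" and self.frame_preserving is not None:
            raise ValueError("frame flags are defined only for CDS events")


@dataclass(frozen=True)
class DisorderCategory:
    event_id: str
    category: str  # totally_disordered | partially_disordered | structured
    fraction_disordered: float


def localize_event(event: SplicingEvent, host: Transcript) -> str:
    """CDS/UTR5/UTR3 by genomic overlap of the segment with the CDS span.

    Any overlap with the CDS (start through stop codon) classifies the
    event as CDS; a retained intron interrupting the CDS counts as CDS.
    """
    if not host.has_cds:
        raise ValueError(f"{host.transcript_id} lacks a CDS annotation")
    s, e = event.alt_segment
    if s < host.cds_end and e > host.cds_start:
        return "CDS"
    before = e <= host.cds_start  # genomically left of CDS
    if host.strand == "+":
        return "UTR5" if before else "UTR3"
    return "UTR3" if before else "UTR5"


def _translation_scan(
    tx: Transcript, host: Transcript, genome: dict[str, str], nmd_rule_nt: int
) -> tuple[bool, bool]:
    """(premature_stop, nmd_candidate) for one isoform.

    Translates from the host's annotated start codon on *tx*; a stop ending
    strictly upstream of the annotated stop's position on this isoform is
    premature; it is an NMD candidate when it also lies more than
    *nmd_rule_nt* nt upstream of the isoform's final exon–exon junction.
    """
    g_start = host.cds_start if host.strand == "+" else host.cds_end - 1
    off = genomic_to_spliced(tx.exons, tx.strand, g_start)
    mrna = tx.mrna(genome)
    coding = mrna[off : off + 3 * ((len(mrna) - off) // 3)]
    aa = str(Seq(coding).translate())
    k = aa.find("*")
    g_stop_last = host.cds_end - 1 if host.strand == "+" else host.cds_start
    try:
        ann_stop_end = genomic_to_spliced(tx.exons, tx.strand, g_stop_last) + 1
    except ValueError:  # annotated stop spliced out of this isoform
        ann_stop_end = len(mrna)
    if k < 0:
        return False, False
    stop_end = off + 3 * k + 3
    premature = stop_end < ann_stop_end
    junctions = tx.junction_offsets()
    nmd = bool(
        premature and junctions and (junctions[-1] - stop_end) > nmd_rule_nt
    )
    return premature, nmd


def classify_frame(
    event: SplicingEvent,
    host: Transcript,
    genome: dict[str, str],
    nmd_rule_nt: int = NMD_RULE_NT,
) -> CodingAnnotation:
    """Frame/PTC/NMD classification for a CDS-localized event.

    The minor isoform (the one differing from the annotated transcript) is
    the primary scan target; the annotated isoform's status is recorded in
    ``premature_stop_major``.
    """
    loc = localize_event(event, host)
    if loc != "CDS":
        return CodingAnnotation(event.event_id, loc)
    inc_tx, exc_tx = isoform_transcripts(event, host)
    minor = exc_tx if event.annotated_isoform == "inclusion" else inc_tx
    major = inc_tx if event.annotated_isoform == "inclusion" else exc_tx
    frame_ok = event.segment_length % 3 == 0
    ptc, nmd = _translation_scan(minor, host, genome, nmd_rule_nt)
    ptc_major, _ = _translation_scan(major, host, genome, nmd_rule_nt)
    nmd_flag = bool(nmd and (ptc or not frame_ok))
    return CodingAnnotation(
        event_id=event.event_id,
        localization="CDS",
        frame_preserving=frame_ok,
        premature_stop=ptc,
        nmd_candidate=nmd_flag,
        novel_cterm=bool((not frame_ok) and not nmd_flag),
        premature_stop_major=ptc_major,
    )


def disorder_category(
    event_id: str, calls: Sequence[int], min_len: int = MIN_PEPTIDE_AA
) -> DisorderCategory:
    """Categorize an AS peptide from per-residue disorder calls (1=disordered).

    Totally disordered / structured require fraction exactly 1 / 0; anything
    in between is partially disordered. Peptides shorter than *min_len*
    residues are rejected (unreliable prediction input).
    """
    calls = list(calls)
    if len(calls) < min_len:
        raise ValueError(
            f"{event_id}: peptide of {len(calls)} aa below the {min_len}-aa minimum"
        )
    if any(c not in (0, 1) for c in calls):
        raise ValueError("disorder calls must be 0/1")
    frac = sum(calls) / len(calls)
    if frac == 1.0:
        cat = "totally_disordered"
    elif frac == 0.0:
        cat = "structured"
    else:
        cat = "partially_disordered"
    return DisorderCategory(event_id, cat, frac)


def calls_for_interval(
    disorder: pd.DataFrame, protein_id: str, aa_interval: tuple[int, int]
) -> list[int]:
    """Per-residue 0/1 calls over a closed protein interval, in order.

    Missing residues are treated as structured (0).
    """
    a, b = aa_interval
    sub = disorder[disorder["protein_id"] == protein_id]
    lookup = dict(zip(sub["residue_index"], sub["call"]))
    return [int(lookup.get(i, 0)) for i in range(a, b + 1)]


def intersect_ptm(
    protein_id: str, aa_interval: tuple[int, int], ptm: pd.DataFrame
) -> pd.DataFrame:
    """PTM sites whose residue lies inside the closed AS protein interval."""
    a, b = aa_interval
    if ptm.empty:
        return ptm
    sub = ptm[(ptm["protein_id"] == protein_id)
              & (ptm["position"] >= a) & (ptm["position"] <= b)]
    return sub.reset_index(drop=True)


def ptm_matrix(
    regions: dict[str, tuple[str, tuple[int, int]]], ptm: pd.DataFrame
) -> pd.DataFrame:
    """Event × PTM-type count matrix over AS protein intervals.

    *regions* maps event_id → (protein_id, closed aa interval). Sites beyond
    a protein's annotated region table are simply never matched; rows for
    events with no sites are all-zero.
    """
    types = sorted(ptm["type"].unique()) if not ptm.empty else []
    rows = {}
    for event_id, (prot, iv) in sorted(regions.items()):
        hits = intersect_ptm(prot, iv, ptm)
        rows[event_id] = {t: int((hits["type"] == t).sum()) for t in types}
    return pd.DataFrame.from_dict(rows, orient="index", columns=types).fillna(0).astype(int)
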