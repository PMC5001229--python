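"""Core genomic data model: transcripts and alternative-splicing events.

Coordinates are 0-based, half-open genomic intervals everywhere inside the
package; conversion to 1-based inclusive happens only in the GFF3 writer.
An exon chain is a list of ``(start, end)`` intervals sorted by genomic
start; transcript (5'→3') order is the reverse of genomic order on the
minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

from Bio.Seq import Seq

Interval = tuple[int, int]


class EventType(str, Enum):
    """The four two-isoform event classes."""

    CASSETTE = "cassette"
    ALT5 = "alt5"
    ALT3 = "alt3"
    RETAINED_INTRON = "retained_intron"


def interval_len(iv: Interval) -> int:
    return iv[1] - iv[0]


def chain_len(chain: Sequence[Interval]) -> int:
    return sum(e - s for s, e in chain)


def _check_chain(chain: Sequence[Interval]) -> None:
    for s, e in chain:
        if e <= s:
            raise ValueError(f"empty or inverted interval {(s, e)}")
    for (s1, e1), (s2, e2) in zip(chain, chain[1:]):
        if s2 < e1:
            raise ValueError("exon chain intervals overlap or are unsorted")


def chain_seq(chain: Sequence[Interval], chrom_seq: str, strand: str) -> str:
    """Spliced (mRNA, 5'→3') sequence of an exon chain."""
    s = "".join(chrom_seq[a:b] for a, b in chain)
    if strand == "-":
        s = str(Seq(s).reverse_complement())
    return s


def genomic_to_spliced(chain: Sequence[Interval], strand: str, pos: int) -> int:
    """Map a genomic position (0-based, must be exonic) to spliced coords."""
    off = 0
    ordered = chain if strand == "+" else list(reversed(chain))
    for a, b in ordered:
        if a <= pos < b:
            return off + (pos - a if strand == "+" else b - 1 - pos)
        off += b - a
    raise ValueError(f"position {pos} is not exonic in chain {list(chain)}")


def spliced_to_genomic(chain: Sequence[Interval], strand: str, off: int) -> int:
    """Inverse of :func:`genomic_to_spliced` (off must be < spliced length)."""
    ordered = chain if strand == "+" else list(reversed(chain))
    acc = 0
    for a, b in ordered:
        if off < acc + (b - a):
            local = off - acc
            return a + local if strand == "+" else b - 1 - local
        acc += b - a
    raise ValueError(f"spliced offset {off} beyond transcript length {acc}")


def spliced_window_blocks(
    chain: Sequence[Interval], strand: str, start: int, length: int
) -> tuple[Interval, ...]:
    """Genomic blocks covered by a spliced-coordinate window.

    Returned blocks are sorted by genomic start regardless of strand, so a
    footprint is a canonical, orientation-free description of a read.
    """
    total = chain_len(chain)
    if start < 0 or start + length > total:
        raise ValueError("window outside transcript")
    ordered = chain if strand == "+" else list(reversed(chain))
    blocks: list[Interval] = []
    off = 0
    remaining = length
    for a, b in ordered:
        exon_len = b - a
        if off + exon_len <= start:
            off += exon_len
            continue
        local = max(0, start - off)  # offset into this exon (transcript sense)
        take = min(exon_len - local, remaining)
        if strand == "+":
            blocks.append((a + local, a + local + take))
        else:
            blocks.append((b - local - take, b - local))
        remaining -= take
        off += exon_len
        if remaining == 0:
            break
    blocks.sort()
    return tuple(blocks)


def window_in_chain(chain: Sequence[Interval], blocks: Sequence[Interval]) -> bool:
    """True if a genomic footprint is a contiguous spliced window of *chain*.

    Every block must be exonic, and consecutive blocks must be joined by the
    chain's own junctions (no intervening exonic sequence of the chain).
    """
    blocks = sorted(blocks)
    chain = sorted(chain)
    idx = None
    for bi, (s, e) in enumerate(blocks):
        found = None
        for ci, (a, b) in enumerate(chain):
            if a <= s and e <= b:
                found = ci
                break
        if found is None:
            return False
        if bi == 0:
            idx = found
        else:
            # must be the next exon of the chain and abut its boundaries
            if found != idx + 1:
                return False
            prev_s, prev_e = blocks[bi - 1]
            if prev_e != chain[idx][1] or s != chain[found][0]:
                return False
            idx = found
    return True


@dataclass(frozen=True)
class Transcript:
    """A transcript model with an optional CDS annotation.

    ``cds_start``/``cds_end`` delimit the CDS (start codon through stop
    codon, inclusive of the stop) as a genomic half-open interval.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        _check_chain(self.exons)
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    @property
    def spliced_length(self) -> int:
        return chain_len(self.exons)

    def mrna(self, genome: dict[str, str]) -> str:
        return chain_seq(self.exons, genome[self.chrom], self.strand)

    def cds_offset(self) -> int:
        """Spliced coordinate of the first base of the start codon."""
        if not self.has_cds:
            raise ValueError("transcript has no CDS")
        g = self.cds_start if self.strand == "+" else self.cds_end - 1
        return genomic_to_spliced(self.exons, self.strand, g)

    def stop_end_offset(self) -> int:
        """Spliced coordinate one past the last base of the stop codon."""
        if not self.has_cds:
            raise ValueError("transcript has no CDS")
        g = self.cds_end - 1 if self.strand == "+" else self.cds_start
        return genomic_to_spliced(self.exons, self.strand, g) + 1

    def junction_offsets(self) -> list[int]:
        """Spliced positions of exon–exon junctions (first base after each)."""
        offs, acc = [], 0
        ordered = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        for a, b in ordered[:-1]:
            acc += b - a
            offs.append(acc)
        return offs


@dataclass(frozen=True)
class SplicingEvent:
    """One two-isoform alternative-splicing event anchored to a transcript.

    ``alt_segment`` is the differential genomic interval (the cassette exon,
    the alt-5'/3' extension, or the retained intron). ``upstream_exon`` and
    ``downstream_exon`` are transcript-sense (5' and 3') flanking exons, so
    on the minus strand the upstream exon is genomic-right. The chains are
    exon chains over the event locus only (the flanking exons plus, for the
    inclusion form, the segment).
    ``annotated_isoform`` records which form carries the host transcript's
    CDS annotation.
    """

    event_id: str
    event_type: EventType
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    alt_segment: Interval
    upstream_exon: Interval
    downstream_exon: Interval
    inclusion_chain: tuple[Interval, ...]
    exclusion_chain: tuple[Interval, ...]
    annotated_isoform: str = "inclusion"

    def __post_init__(self) -> None:
        if interval_len(self.alt_segment) < 1:
            raise ValueError(f"{self.event_id}: empty alternative segment")
        _check_chain(self.inclusion_chain)
        _check_chain(self.exclusion_chain)
        if self.annotated_isoform not in ("inclusion", "exclusion"):
            raise ValueError("annotated_isoform must be 'inclusion' or 'exclusion'")
        # inclusion must contain every exonic base of the exclusion form
        inc = _as_base_set(self.inclusion_chain)
        exc = _as_base_set(self.exclusion_chain)
        if not exc <= inc:
            raise ValueError(f"{self.event_id}: exclusion chain not nested in inclusion")

    @property
    def segment_length(self) -> int:
        return interval_len(self.alt_segment)


def _as_base_set(chain: Sequence[Interval]) -> set[int]:
    return {p for a, b in chain for p in range(a, b)}


def isoform_transcripts(
    event: SplicingEvent, host: Transcript
) -> tuple[Transcript, Transcript]:
    """Full-length (inclusion, exclusion) transcripts for an event.

    *host* is the annotated transcript (``event.annotated_isoform`` says which
    form it is); the other isoform is derived by splicing the alternative
    segment in or out of the host's exon chain.
    """
    seg = event.alt_segment
    if event.annotated_isoform == "inclusion":
        inc = host
        exc = replace(
            host,
            transcript_id=host.transcript_id + ".exc",
            exons=_remove_segment(host.exons, seg),
        )
    else:
        exc = host
        inc = replace(
            host,
            transcript_id=host.transcript_id + ".inc",
            exons=_add_segment(host.exons, seg),
        )
    return inc, exc


def _remove_segment(exons: Sequence[Interval], seg: Interval) -> tuple[Interval, ...]:
    """Excise *seg* from an exon chain, splitting/trimming/dropping exons."""
    s, e = seg
    out: list[Interval] = []
    for a, b in exons:
        if b <= s or a >= e:
            out.append((a, b))
            continue
        if a < s:
            out.append((a, s))
        if b > e:
            out.append((e, b))
    return tuple(out)


def _add_segment(exons: Sequence[Interval], seg: Interval) -> tuple[Interval, ...]:
    """Insert *seg* into an exon chain, merging with abutting exons."""
    ivs = sorted(list(exons) + [seg])
    out: list[Interval] = [ivs[0]]
    for a, b in ivs[1:]:
        pa, pb = out[-1]
        if a <= pb:  # abut or overlap -> merge
            out[-1] = (pa, max(pb, b))
        else:
            out.append((a, b))
    return tuple(out)
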