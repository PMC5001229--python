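"""Readers and writers for the pipeline's on-disk formats.

Internal coordinates are 0-based half-open; GFF3 output is 1-based
inclusive. FASTA goes through Biopython, GFF3 parsing through gffutils,
tables through pandas TSV, and PWMs through minimal MEME motif text
(parsed back with Bio.motifs).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import gffutils
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .events import EventType, Interval, SplicingEvent, Transcript
from .motifs import PWM
from .quant import DiffSplicingCall


# ---------------------------------------------------------------------- FASTA

def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=c, description="") for c, s in sorted(genome.items())]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ----------------------------------------------------------------------- GFF3

def write_gff3(transcripts: Iterable[Transcript], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for tx in sorted(transcripts, key=lambda t: (t.chrom, t.exons[0][0])):
        g0 = tx.exons[0][0] + 1
        g1 = tx.exons[-1][1]
        lines.append(
            f"{tx.chrom}\tsplicedelta\tgene\t{g0}\t{g1}\t.\t{tx.strand}\t.\t"
            f"ID={tx.gene_id}"
        )
        lines.append(
            f"{tx.chrom}\tsplicedelta\tmRNA\t{g0}\t{g1}\t.\t{tx.strand}\t.\t"
            f"ID={tx.transcript_id};Parent={tx.gene_id}"
        )
        for i, (s, e) in enumerate(tx.exons, 1):
            lines.append(
                f"{tx.chrom}\tsplicedelta\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t"
                f"ID={tx.transcript_id}.exon{i};Parent={tx.transcript_id}"
            )
        if tx.has_cds:
            for s, e in tx.exons:
                cs, ce = max(s, tx.cds_start), min(e, tx.cds_end)
                if cs < ce:
                    lines.append(
                        f"{tx.chrom}\tsplicedelta\tCDS\t{cs + 1}\t{ce}\t.\t{tx.strand}\t0\t"
                        f"ID={tx.transcript_id}.cds;Parent={tx.transcript_id}"
                    )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> dict[str, Transcript]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out: dict[str, Transcript] = {}
    for mrna in db.features_of_type("mRNA"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
        cds_start = cds[0][0] if cds else None
        cds_end = cds[-1][1] if cds else None
        out[mrna.id] = Transcript(
            mrna.id, mrna.attributes["Parent"][0], mrna.seqid, mrna.strand,
            tuple(exons), cds_start, cds_end,
        )
    return out


# ------------------------------------------------------------------ event TSV

def _chain_str(chain: Sequence[Interval]) -> str:
    return ";".join(f"{s}-{e}" for s, e in chain)


def _parse_chain(text: str) -> tuple[Interval, ...]:
    return tuple(
        (int(a), int(b)) for a, b in (p.split("-") for p in text.split(";") if p)
    )


def write_events(events: Iterable[SplicingEvent], path: str | Path) -> None:
    rows = [
        dict(
            event_id=ev.event_id, event_type=ev.event_type.value, gene_id=ev.gene_id,
            transcript_id=ev.transcript_id, chrom=ev.chrom, strand=ev.strand,
            seg_start=ev.alt_segment[0], seg_end=ev.alt_segment[1],
            up_start=ev.upstream_exon[0], up_end=ev.upstream_exon[1],
            down_start=ev.downstream_exon[0], down_end=ev.downstream_exon[1],
            inclusion_chain=_chain_str(ev.inclusion_chain),
            exclusion_chain=_chain_str(ev.exclusion_chain),
            annotated_isoform=ev.annotated_isoform,
        )
        for ev in events
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> list[SplicingEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        SplicingEvent(
            event_id=r.event_id, event_type=EventType(r.event_type),
            gene_id=r.gene_id, transcript_id=r.transcript_id, chrom=r.chrom,
            strand=r.strand, alt_segment=(int(r.seg_start), int(r.seg_end)),
            upstream_exon=(int(r.up_start), int(r.up_end)),
            downstream_exon=(int(r.down_start), int(r.down_end)),
            inclusion_chain=_parse_chain(r.inclusion_chain),
            exclusion_chain=_parse_chain(r.exclusion_chain),
            annotated_isoform=r.annotated_isoform,
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------- calls / TSV

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def calls_to_frame(calls: Iterable[DiffSplicingCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                event_id=c.event_id,
                event_type=c.event_type.value if c.event_type else "",
                psi_control=round(c.psi_control, 6),
                ci_control_low=round(c.ci_control[0], 6),
                ci_control_high=round(c.ci_control[1], 6),
                psi_treated=round(c.psi_treated, 6),
                ci_treated_low=round(c.ci_treated[0], 6),
                ci_treated_high=round(c.ci_treated[1], 6),
                delta_psi=round(c.delta_psi, 6),
                bayes_factor=round(c.bayes_factor, 6) if np.isfinite(c.bayes_factor) else np.inf,
                log_bf=round(c.log_bf, 6),
                passes=c.passes,
            )
            for c in calls
        ]
    )


# ----------------------------------------------------------------------- MEME

def write_meme(pwms: Sequence[PWM], path: str | Path, alphabet: str = "ACGT") -> None:
    """Minimal MEME motif text (readable by Bio.motifs 'minimal' parser)."""
    buf = ["MEME version 4", "", f"ALPHABET= {alphabet}", "",
           "Background letter frequencies",
           " ".join(f"{c} 0.25" for c in alphabet), ""]
    for p in pwms:
        buf.append(f"MOTIF {p.motif_id} {p.rbp_name}")
        buf.append(
            # large nsites so probability -> count -> probability round trips
            f"letter-probability matrix: alength= 4 w= {p.width} nsites= 1000000 E= 0"
        )
        for row in p.matrix:
            buf.append(" " + " ".join(f"{x:.6f}" for x in row))
        buf.append("")
    Path(path).write_text("\n".join(buf))


def read_meme(path: str | Path) -> list[PWM]:
    text = Path(path).read_text()
    # the minimal parser drops the alternate (RBP) name; recover it here
    alt = {}
    for line in text.splitlines():
        if line.startswith("MOTIF"):
            parts = line.split()
            alt[parts[1]] = parts[2] if len(parts) > 2 else parts[1]
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
        out = []
        for m in records:
            mat = np.column_stack([m.pwm[c] for c in "ACGT"])
            out.append(PWM(m.name, alt.get(m.name, m.name), mat))
    return out
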