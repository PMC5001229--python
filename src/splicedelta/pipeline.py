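"""Pipeline orchestration: simulate → quantify → classify → domains → ppi → motifs.

Each stage reads the previous stage's files from the output directory and
writes its own TSVs plus a JSON summary, so stages can be re-run
individually. Identical configuration and seed reproduce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as classify_mod
from . import domains as domains_mod
from . import io as sio
from . import motifs as motifs_mod
from . import ppi as ppi_mod
from . import quant, synthdata
from .events import EventType


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class InputError(RuntimeError):
    """Missing or malformed stage input (CLI exit code 3)."""


STAGES = ("simulate", "quantify", "classify", "domains", "ppi", "motifs")


@dataclass
class PipelineConfig:
    outdir: str = "splicedelta_out"
    seed: int = 0
    sim: synthdata.SimConfig = field(default_factory=synthdata.SimConfig)
    bf_min: float = quant.DEFAULT_BF_MIN
    abs_dpsi_min: float = quant.DEFAULT_ABS_DPSI_MIN
    motif_p: float = motifs_mod.DEFAULT_P_CUT
    motif_fdr: float = motifs_mod.DEFAULT_FDR_CUT
    plant_motif_region: int = 3      # 0 disables motif planting
    plant_motif_direction: str = "up"
    expression_filter: bool = True
    stages: tuple = STAGES

    def __post_init__(self) -> None:
        if min(self.bf_min, self.abs_dpsi_min, self.motif_p, self.motif_fdr) <= 0:
            raise ConfigError("thresholds must be positive")
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad}")
        self.sim.seed = self.seed

    @property
    def out(self) -> Path:
        return Path(self.outdir)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _need(cfg: PipelineConfig, stage: str, *names: str) -> list[Path]:
    paths = [cfg.out / n for n in names]
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise InputError(
            f"stage '{stage}' requires outputs of an earlier stage; missing: {missing}"
        )
    return paths


def write_config(cfg: PipelineConfig) -> None:
    echo = dataclasses.asdict(cfg)
    echo["sim"]["event_type_mix"] = {
        k.value: v for k, v in cfg.sim.event_type_mix.items()
    }
    echo["stages"] = list(cfg.stages)
    (cfg.out / "config.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))


# --------------------------------------------------------------------- stages

def stage_simulate(cfg: PipelineConfig) -> dict:
    cfg.out.mkdir(parents=True, exist_ok=True)
    write_config(cfg)
    txome = synthdata.make_transcriptome(cfg.sim)
    truth = synthdata.assign_truth(txome.events, cfg.sim)
    fixtures = synthdata.make_annotation_fixtures(txome, cfg.sim)
    if cfg.plant_motif_region:
        txome = synthdata.plant_motif(
            txome, truth, fixtures.pwms[0], cfg.plant_motif_region,
            cfg.plant_motif_direction, cfg.sim,
        )
    counts = synthdata.simulate_counts(txome.events, truth, cfg.sim)

    sio.write_gff3(txome.transcripts.values(), cfg.out / "transcripts.gff3")
    sio.write_fasta(txome.genome, cfg.out / "genome.fa")
    sio.write_events(txome.events, cfg.out / "events.tsv")
    sio.write_table(counts, cfg.out / "counts.tsv")
    truth_df = pd.DataFrame(
        [dataclasses.asdict(t) for t in truth.values()]
    ).sort_values("event_id")
    sio.write_table(truth_df, cfg.out / "truth.tsv")
    sio.write_table(fixtures.domains, cfg.out / "domains_fixture.tsv")
    for i, edges in enumerate(fixtures.ppi_edges, 1):
        sio.write_table(edges, cfg.out / f"ppi_experimental_{i}.tsv")
    sio.write_table(fixtures.ddi, cfg.out / "ddi.tsv")
    sio.write_table(fixtures.gene_domains, cfg.out / "gene_domains.tsv")
    sio.write_table(fixtures.ptm, cfg.out / "ptm.tsv")
    sio.write_table(fixtures.disorder, cfg.out / "disorder.tsv")
    sio.write_meme(fixtures.pwms, cfg.out / "pwms.meme")
    (cfg.out / "expressed_genes.txt").write_text(
        "\n".join(sorted(fixtures.expressed_genes)) + "\n"
    )
    summary = {
        "n_genes": len(txome.transcripts),
        "n_events": len(txome.events),
        "by_type": {
            t.value: sum(1 for e in txome.events if e.event_type is t)
            for t in EventType
        },
        "n_differential_true": sum(t.is_differential for t in truth.values()),
    }
    _dump_json(summary, cfg.out / "simulate_summary.json")
    return summary


def _load_quant_inputs(cfg: PipelineConfig, stage: str):
    _need(cfg, stage, "events.tsv", "counts.tsv")
    events = sio.read_events(cfg.out / "events.tsv")
    counts = sio.read_table(cfg.out / "counts.tsv")
    sizes = {
        ev.event_id: quant.effective_sizes(ev, cfg.sim.read_length) for ev in events
    }
    return events, counts, sizes


def stage_quantify(cfg: PipelineConfig) -> dict:
    events, counts, sizes = _load_quant_inputs(cfg, "quantify")
    by_event = synthdata.counts_frame_to_event_counts(counts, sizes)
    ev_map = {e.event_id: e for e in events}
    calls, summary = quant.call_events(
        by_event, ev_map, bf_min=cfg.bf_min, abs_dpsi_min=cfg.abs_dpsi_min
    )
    sio.write_table(sio.calls_to_frame(calls), cfg.out / "calls.tsv")
    out = {
        "n_tested": summary.n_tested,
        "n_passing": summary.n_passing,
        "n_positive_dpsi": summary.n_positive,
        "n_negative_dpsi": summary.n_negative,
        "passing_by_type": dict(sorted(summary.by_type.items())),
        "n_untestable": len(events) - summary.n_tested,
    }
    _dump_json(out, cfg.out / "quantify_summary.json")
    return out


def _passing_calls(cfg: PipelineConfig, stage: str) -> pd.DataFrame:
    _need(cfg, stage, "calls.tsv")
    calls = sio.read_table(cfg.out / "calls.tsv")
    return calls[calls["passes"]]


def stage_classify(cfg: PipelineConfig) -> dict:
    _need(cfg, "classify", "events.tsv", "transcripts.gff3", "genome.fa")
    passing = _passing_calls(cfg, "classify")
    events = {e.event_id: e for e in sio.read_events(cfg.out / "events.tsv")}
    transcripts = sio.read_gff3(cfg.out / "transcripts.gff3")
    genome = sio.read_fasta(cfg.out / "genome.fa")
    disorder = sio.read_table(cfg.out / "disorder.tsv")
    ptm = sio.read_table(cfg.out / "ptm.tsv")

    rows, skipped = [], []
    ptm_regions: dict[str, tuple[str, tuple[int, int]]] = {}
    disorder_counts = {"totally_disordered": 0, "partially_disordered": 0, "structured": 0}
    for event_id in sorted(passing["event_id"]):
        ev = events[event_id]
        host = transcripts[ev.transcript_id]
        if not host.has_cds:
            skipped.append((event_id, "host transcript lacks CDS"))
            continue
        ann = classify_mod.classify_frame(ev, host, genome)
        rows.append(dataclasses.asdict(ann))
        # disorder + PTM need a protein-coordinate AS interval
        try:
            aa_iv = domains_mod.as_protein_interval(ev, host)
        except ValueError:
            aa_iv = None
        if aa_iv is not None:
            prot = domains_mod.protein_id_for(host)
            ptm_regions[event_id] = (prot, aa_iv)
            calls01 = classify_mod.calls_for_interval(disorder, prot, aa_iv)
            try:
                cat = classify_mod.disorder_category(event_id, calls01)
                disorder_counts[cat.category] += 1
            except ValueError as exc:
                skipped.append((event_id, str(exc)))
    ann_df = pd.DataFrame(
        rows, columns=["event_id", "localization", "frame_preserving",
                       "premature_stop", "nmd_candidate", "novel_cterm",
                       "premature_stop_major"],
    )
    sio.write_table(ann_df, cfg.out / "annotation.tsv")
    mat = classify_mod.ptm_matrix(ptm_regions, ptm)
    mat.to_csv(cfg.out / "ptm_matrix.tsv", sep="\t", index_label="event_id")
    n_cds = int((ann_df["localization"] == "CDS").sum()) if not ann_df.empty else 0
    frame = ann_df["frame_preserving"].map(lambda v: v is True) if not ann_df.empty else pd.Series(dtype=bool)
    ptc = ann_df["premature_stop"].map(lambda v: v is True) if not ann_df.empty else pd.Series(dtype=bool)
    cds_mask = (ann_df["localization"] == "CDS") if not ann_df.empty else pd.Series(dtype=bool)
    summary = {
        "n_annotated": len(ann_df),
        "localization": {
            k: int((ann_df["localization"] == k).sum()) if not ann_df.empty else 0
            for k in ("CDS", "UTR5", "UTR3")
        },
        "n_frame_preserving": int(frame.sum()),
        "n_ptc_or_frameshift": int((cds_mask & (ptc | ~frame)).sum()),
        "n_cds": n_cds,
        "disorder_categories": disorder_counts,
        "skipped": len(skipped),
    }
    _dump_json(summary, cfg.out / "classify_summary.json")
    return summary


def stage_domains(cfg: PipelineConfig) -> dict:
    _need(cfg, "domains", "events.tsv", "transcripts.gff3", "genome.fa",
          "domains_fixture.tsv", "annotation.tsv")
    passing = _passing_calls(cfg, "domains")
    events = {e.event_id: e for e in sio.read_events(cfg.out / "events.tsv")}
    transcripts = sio.read_gff3(cfg.out / "transcripts.gff3")
    genome = sio.read_fasta(cfg.out / "genome.fa")
    ann = sio.read_table(cfg.out / "annotation.tsv")
    dom_table = domains_mod.domains_from_frame(
        sio.read_table(cfg.out / "domains_fixture.tsv")
    )
    eligible = set(
        ann.loc[(ann["localization"] == "CDS") & (ann["frame_preserving"] == True),
                "event_id"]
    ) & set(passing["event_id"])
    rows = []
    for event_id in sorted(eligible):
        ev = events[event_id]
        host = transcripts[ev.transcript_id]
        try:
            pep = domains_mod.build_flanked_peptide(ev, host, genome)
        except ValueError:
            continue
        for ov in domains_mod.overlap_domains(pep, dom_table):
            rows.append(
                dict(event_id=ov.event_id, gene=ev.gene_id,
                     event_type=ev.event_type.value, protein_id=ov.protein_id,
                     accession=ov.accession, domain=ov.name,
                     overlap_aa=ov.overlap_aa, which_part=ov.which_part)
            )
    df = pd.DataFrame(
        rows, columns=["event_id", "gene", "event_type", "protein_id",
                       "accession", "domain", "overlap_aa", "which_part"],
    )
    sio.write_table(df, cfg.out / "domain_overlaps.tsv")
    summary = {
        "n_eligible_events": len(eligible),
        "n_overlaps": len(df),
        "n_as_overlap": int(df["which_part"].isin(["AS_only", "both"]).sum()) if not df.empty else 0,
        "n_flank_only": int((df["which_part"] == "flank_only").sum()) if not df.empty else 0,
    }
    _dump_json(summary, cfg.out / "domains_summary.json")
    return summary


def stage_ppi(cfg: PipelineConfig) -> dict:
    _need(cfg, "ppi", "domain_overlaps.tsv", "ddi.tsv", "gene_domains.tsv",
          "ppi_experimental_1.tsv", "ppi_experimental_2.tsv", "expressed_genes.txt")
    overlaps = sio.read_table(cfg.out / "domain_overlaps.tsv")
    disrupted = overlaps[overlaps["which_part"].isin(["AS_only", "both"])]
    as_gene_domains = sorted(
        {(r.gene, r.accession) for r in disrupted.itertuples(index=False)}
    )
    merged = ppi_mod.merge_ppi(
        [sio.read_table(cfg.out / f"ppi_experimental_{i}.tsv") for i in (1, 2)]
    )
    expressed = None
    if cfg.expression_filter:
        expressed = set(
            (cfg.out / "expressed_genes.txt").read_text().split()
        )
    interactions = ppi_mod.dual_evidence_join(
        as_gene_domains,
        sio.read_table(cfg.out / "ddi.tsv"),
        sio.read_table(cfg.out / "gene_domains.tsv"),
        merged,
        expressed_genes=expressed,
    )
    df = pd.DataFrame(
        [dataclasses.asdict(i) for i in interactions],
        columns=["as_gene", "as_domain", "partner_gene", "partner_domain",
                 "has_experimental", "has_structural"],
    )
    sio.write_table(df, cfg.out / "interactions.tsv")
    (cfg.out / "interactions.dot").write_text(ppi_mod.to_dot(interactions) + "\n")
    summary = {
        "n_as_genes_with_disrupted_domains": len({g for g, _ in as_gene_domains}),
        "n_merged_ppi_edges": len(merged),
        "n_dual_evidence_interactions": len(interactions),
    }
    _dump_json(summary, cfg.out / "ppi_summary.json")
    return summary


def stage_motifs(cfg: PipelineConfig) -> dict:
    _need(cfg, "motifs", "events.tsv", "genome.fa", "pwms.meme", "calls.tsv")
    calls_df = sio.read_table(cfg.out / "calls.tsv")
    events = {e.event_id: e for e in sio.read_events(cfg.out / "events.tsv")}
    genome = sio.read_fasta(cfg.out / "genome.fa")
    pwms = sio.read_meme(cfg.out / "pwms.meme")

    calls = [
        quant.DiffSplicingCall(
            r.event_id, r.psi_control, r.psi_treated, r.delta_psi,
            r.bayes_factor, r.log_bf, bool(r.passes),
        )
        for r in calls_df.itertuples(index=False)
        if events[r.event_id].event_type is EventType.CASSETTE
    ]
    region_sets = {
        c.event_id: motifs_mod.extract_regions(events[c.event_id], genome)
        for c in calls
        if c.passes
    }
    result = motifs_mod.motif_enrichment(
        calls, region_sets, pwms, p_cut=cfg.motif_p, fdr_cut=cfg.motif_fdr
    )
    sio.write_table(result.hits, cfg.out / "motif_hits.tsv")
    sio.write_table(result.table, cfg.out / "motif_table.tsv")
    summary = {
        "n_cassette_passing": len(region_sets),
        "n_motifs_up": int(
            result.hits.loc[result.hits["direction"] == "up", "motif_id"].nunique()
        ) if not result.hits.empty else 0,
        "n_motifs_down": int(
            result.hits.loc[result.hits["direction"] == "down", "motif_id"].nunique()
        ) if not result.hits.empty else 0,
        "up_only_motifs": sorted(result.up_only),
        "down_only_motifs": sorted(result.down_only),
    }
    _dump_json(summary, cfg.out / "motifs_summary.json")
    return summary


_STAGE_FN = {
    "simulate": stage_simulate,
    "quantify": stage_quantify,
    "classify": stage_classify,
    "domains": stage_domains,
    "ppi": stage_ppi,
    "motifs": stage_motifs,
}


def run(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order."""
    summary = {}
    for stage in STAGES:
        if stage in cfg.stages:
            summary[stage] = _STAGE_FN[stage](cfg)
    _dump_json(summary, cfg.out / "summary.json")
    return summary


def intersect_de(as_genes, de_genes) -> set:
    """Genes both alternatively spliced and differentially expressed."""
    if as_genes is None or de_genes is None:
        raise ValueError("both gene lists are required")
    return set(as_genes) & set(de_genes)
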