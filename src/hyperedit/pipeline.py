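"""End-to-end orchestration: simulate → align → detect → quantify → motif →
dsrna → annotate, with deterministic seeding and TSV/BED outputs."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate as ann
from . import dsrna as ds
from . import motif as mo
from .align import align_batch
from .detect import DetectConfig, collapse_sites, run_all_types
from .io import (
    Genome,
    Interval,
    Read,
    read_bed,
    read_fasta,
    read_fastq,
    write_bed,
    write_fasta,
    write_fastq,
    write_sites,
    write_summary,
)
from .quantify import build_signal_report, specificity
from .simulate import SimConfig, simulate_dataset, write_truth

log = logging.getLogger("hyperedit")


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Union of stage configs plus input/output paths.

    Either ``genome_fasta``+``reads_fastq`` are given, or a synthetic dataset
    is generated from ``sim``.
    """

    outdir: str = "hyperedit_out"
    seed: int = 0
    genome_fasta: str | None = None
    reads_fastq: str | None = None
    repeats_bed: str | None = None
    coding_bed: str | None = None
    stranded: bool = False
    initial_max_mm: int = 3
    sim: SimConfig = field(default_factory=SimConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    dsrna_flank: int = 2000
    dsrna_min_identity: float = 0.65
    dsrna_min_cov: float = 0.80
    n_potential_windows: int = 0  # 0 skips the genomic-potential scan
    label: str = "dataset"


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.genome_fasta:
        genome = read_fasta(cfg.genome_fasta)
        if not Path(cfg.genome_fasta).exists():
            raise PipelineConfigError(f"missing genome: {cfg.genome_fasta}")
        if not cfg.reads_fastq or not Path(cfg.reads_fastq).exists():
            raise PipelineConfigError(f"missing reads: {cfg.reads_fastq}")
        reads = list(read_fastq(cfg.reads_fastq))
        if cfg.repeats_bed:
            genome.repeats = read_bed(cfg.repeats_bed)
        if cfg.coding_bed:
            genome.coding = read_bed(cfg.coding_bed)
        return genome, reads, None
    sim_cfg = cfg.sim
    if sim_cfg.seed != cfg.seed:
        from dataclasses import replace

        sim_cfg = replace(sim_cfg, seed=cfg.seed)
    genome, reads, truth = simulate_dataset(sim_cfg)
    write_fasta(genome, outdir / "genome.fa")
    write_fastq(reads, outdir / "reads.fastq")
    write_bed(truth.repeats, outdir / "repeats.bed")
    write_bed(truth.coding, outdir / "coding.bed")
    write_truth(truth, outdir / "truth.tsv")
    return genome, reads, truth


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; idempotent given the seed."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        genome, reads, truth = _load_inputs(cfg, outdir)
    except (OSError, PipelineConfigError) as exc:
        raise PipelineConfigError(f"[input] {exc}") from exc

    log.info("source reads: %d", len(reads))
    batch = align_batch(reads, genome, max_mm=cfg.initial_max_mm, k=cfg.detect.k)
    pct_aligned = 100.0 * len(batch.mapped) / len(reads) if reads else 0.0
    log.info(
        "[align] mapped %d (%.1f%%), unmapped %d",
        len(batch.mapped), pct_aligned, len(batch.unmapped),
    )

    per_type, screen = run_all_types(batch.unmapped, genome, cfg.detect)
    signal_types = [("A", "G")] if cfg.stranded else [("A", "G"), ("T", "C")]
    detections = [d for t in signal_types for d in per_type[t]]
    log.info("[detect] rescued hyper-edited reads: %d", len(detections))
    sites = collapse_sites(detections, stranded=cfg.stranded)
    write_sites(sites, outdir / "sites.bed")
    screen_df = pd.DataFrame(
        [
            {
                "mismatch_type": f"{a}>{b}",
                "reads": screen.reads.get((a, b), 0),
                "events": screen.events.get((a, b), 0),
                "unique_sites": screen.unique_sites.get((a, b), 0),
            }
            for a in "ACGT"
            for b in "ACGT"
            if a != b
        ]
    )
    screen_df.to_csv(outdir / "type_screen.tsv", sep="\t", index=False)

    signal = build_signal_report(
        cfg.label, per_type, screen, batch.mapped_bases, stranded=cfg.stranded
    )
    spec_frac = specificity(screen, stranded=cfg.stranded)

    ag_sites = [s for s in sites if s.mismatch_type == ("A", "G")]
    spans = [d.cluster_span for d in detections]
    profile = mo.build_profile(ag_sites, genome, cluster_spans=spans)
    pd.DataFrame(profile.to_rows()).to_csv(outdir / "motif.tsv", sep="\t", index=False)

    # dsRNA partner search over merged cluster loci
    loci = ann._merge_spans(spans)
    hits: list[ds.DsRNAHit] = []
    n_control = 0
    for locus in loci:
        hit = ds.find_dsrna_partner(
            locus, genome, cfg.dsrna_flank, cfg.dsrna_min_identity, cfg.dsrna_min_cov
        )
        if hit:
            hits.append(hit)
        if ds.control_same_strand(
            locus, genome, cfg.dsrna_flank, cfg.dsrna_min_identity, cfg.dsrna_min_cov
        ):
            n_control += 1
    pd.DataFrame(
        [
            {
                "chrom": h.query.chrom,
                "query_start": h.query.start,
                "query_end": h.query.end,
                "partner_start": h.partner.start,
                "partner_end": h.partner.end,
                "identity": round(h.identity, 4),
                "coverage": round(h.coverage_of_query, 4),
                "score": h.score,
            }
            for h in hits
        ]
    ).to_csv(outdir / "dsrna_partners.tsv", sep="\t", index=False)
    enrichment = ds.dsrna_editing_enrichment(hits, ag_sites, genome)

    potential = None
    if cfg.n_potential_windows > 0:
        potential = ds.genomic_dsrna_potential(
            genome, cfg.n_potential_windows, seed=cfg.seed
        )

    frac_coding, _ = ann.overlap_fraction(ag_sites, genome.coding)
    frac_repeats, per_family = ann.overlap_fraction(ag_sites, genome.repeats)
    expr = ann.unedited_expression(detections, batch.mapped, ag_sites)

    summary = {
        "dataset": cfg.label,
        "source_reads": len(reads),
        "pct_aligned": round(pct_aligned, 2),
        "hyper_reads": len(detections),
        "editing_events": signal.editing_events,
        "unique_sites": len(ag_sites),
        "pct_a_to_g_of_all_types": (
            round(100.0 * spec_frac, 2) if spec_frac is not None else ""
        ),
        "pct_in_coding": round(100.0 * frac_coding, 2),
        "pct_in_repeats": round(100.0 * frac_repeats, 2),
    }
    write_summary([summary], outdir / "summary.tsv")
    pd.DataFrame(
        [
            {
                "label": cfg.label,
                "normalized_signal": signal.normalized,
                "false_positive_signal": signal.false_positive_signal,
                "mapped_bases": signal.mapped_bases,
            }
        ]
    ).to_csv(outdir / "signal.tsv", sep="\t", index=False)

    return {
        "summary": summary,
        "signal": signal,
        "screen": screen,
        "per_type": per_type,
        "sites": sites,
        "profile": profile,
        "dsrna_hits": hits,
        "dsrna_control_hits": n_control,
        "dsrna_loci": len(loci),
        "dsrna_enrichment": enrichment,
        "dsrna_potential": potential,
        "expression": expr,
        "per_repeat_family": per_family,
        "truth": truth,
        "batch": batch,
        "genome": genome,
    }
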