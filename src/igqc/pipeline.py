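"""End-to-end orchestration: inputs -> per-locus metrics -> reports -> plots.

The single metrics pass per locus is serialized once; every table and plot
derives from the same LocusResult, so outputs cannot disagree on shared
quantities.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, Thresholds
from .error_metrics import (
    CoverageBreak,
    LocusPileup,
    PositionFlagTrack,
    basepair_mismatch_rate,
    build_pileup,
    classify_breaks,
    detect_coverage_breaks,
    flag_poorly_supported,
)
from .gene_support import GeneSupportReport, gene_report, gene_report_frame
from .io_formats import (
    FormatError,
    GeneAnnotation,
    LocusInterval,
    ReferenceAssembly,
    load_assembly,
    load_genes,
    load_loci,
    stream_alignments,
    write_tsv,
)
from .read_stats import ReadSummary, collect_read_stats, read_stats_frame, summarize_reads
from .summary_report import LocusQualityCall, aggregate_species, call_locus
from .visualization import PlotSpec, plot_locus_diagnostics, plot_read_summaries


@dataclass
class LocusResult:
    """Everything computed for one locus interval in one metrics pass."""

    locus: LocusInterval
    read_stats: list
    n_skipped: int
    summary: ReadSummary
    pileup: LocusPileup
    flag_track: PositionFlagTrack
    breaks: list[CoverageBreak]
    gene_reports: list[GeneSupportReport] = field(default_factory=list)


def evaluate_locus(
    assembly: ReferenceAssembly,
    locus: LocusInterval,
    alignment_source,
    genes: list[GeneAnnotation] | None = None,
    thresholds: Thresholds | None = None,
) -> LocusResult:
    """Run the full metric stack over one locus.

    ``alignment_source`` is an indexed BAM path or an iterable of pysam
    records.
    """
    thr = thresholds or Thresholds()
    records = stream_alignments(alignment_source, locus)
    stats, skipped = collect_read_stats(records, assembly, thr)
    pileup = build_pileup(stats, locus, thr)
    flag_track = flag_poorly_supported(pileup, thr.min_bad_reads)
    breaks = detect_coverage_breaks(pileup, thr.break_threshold, thr.min_break_len)
    classify_breaks(breaks, assembly, thr.end_margin)
    reports = []
    for gene in genes or []:
        if (
            gene.contig == locus.contig
            and gene.start >= locus.start
            and gene.end <= locus.end
        ):
            reports.append(gene_report(gene, stats, pileup, thr))
    return LocusResult(
        locus, stats, skipped, summarize_reads(stats), pileup, flag_track,
        breaks, reports,
    )


def position_frame(result: LocusResult) -> pd.DataFrame:
    """Per-position metrics table (1-based inclusive positions)."""
    p = result.pileup
    support = p.support_fraction()
    return pd.DataFrame(
        {
            "contig": p.locus.contig,
            "pos": np.arange(p.locus.start, p.locus.end) + 1,
            "depth": p.depth,
            "delta": p.delta,
            "e_count": p.e_count,
            "support": np.round(support, 4),
            "mapq60": p.mapq60,
            "mapq_mid": p.mapq_mid,
            "mapq0": p.mapq0,
        }
    )


def breaks_frame(breaks: list[CoverageBreak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [b.contig for b in breaks],
            "start": [b.start + 1 for b in breaks],
            "end": [b.end for b in breaks],
            "length": [b.length for b in breaks],
            "min_depth": [b.min_depth for b in breaks],
            "spanning_reads": [b.spanning_reads for b in breaks],
            "category": [b.category for b in breaks],
        }
    )


def flags_frame(track: PositionFlagTrack) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": track.locus.contig,
            "start": [s + 1 for s, _ in track.intervals],
            "end": [e for _, e in track.intervals],
            "length": [e - s for s, e in track.intervals],
        }
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_locus_tables(
    result: LocusResult, outdir: Path, thresholds: Thresholds
) -> dict[str, Path]:
    """Write all per-locus TSVs; returns name -> path."""
    tag = f"{result.locus.locus_class}_{result.locus.contig}"
    header = ["# coordinates: 1-based inclusive"] + thresholds.header_lines()
    paths = {
        "positions": write_tsv(
            position_frame(result), outdir / f"{tag}.positions.tsv", header
        ),
        "flags": write_tsv(
            flags_frame(result.flag_track), outdir / f"{tag}.flags.tsv", header
        ),
        "breaks": write_tsv(
            breaks_frame(result.breaks), outdir / f"{tag}.breaks.tsv", header
        ),
        "reads": write_tsv(
            read_stats_frame(result.read_stats), outdir / f"{tag}.reads.tsv", header
        ),
    }
    if result.gene_reports:
        paths["genes"] = write_tsv(
            gene_report_frame(result.gene_reports), outdir / f"{tag}.genes.tsv", header
        )
    return paths


def run_evaluate(config: RunConfig) -> dict:
    """Evaluate every locus in the run config; write tables, plots, manifest."""
    thr = config.thresholds
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    assembly = load_assembly(config.assembly)
    loci = load_loci(
        config.loci, assembly, config.loci_dialect, config.haplotype_patterns
    )
    genes = load_genes(config.genes, loci) if config.genes else []

    results: list[LocusResult] = []
    outputs: dict[str, dict] = {}
    for locus in loci:
        result = evaluate_locus(assembly, locus, config.alignments, genes, thr)
        results.append(result)
        tag = f"{locus.locus_class}_{locus.contig}"
        outputs[tag] = {
            str(k): str(v) for k, v in write_locus_tables(result, outdir, thr).items()
        }
        if config.make_plots:
            img, sidecar = plot_locus_diagnostics(
                result.pileup,
                result.flag_track,
                result.breaks,
                PlotSpec(outdir / f"{tag}.diagnostics", format=config.plot_format,
                         support_min=thr.support_min),
            )
            outputs[tag]["plot"] = str(img)
            outputs[tag]["plot_overlays"] = str(sidecar)

    # one quality call per locus class, pooling haplotype intervals
    calls: list[LocusQualityCall] = []
    for locus_class in sorted({r.locus.locus_class for r in results}):
        group = [r for r in results if r.locus.locus_class == locus_class]
        calls.append(
            call_locus(
                [r.flag_track for r in group],
                [b for r in group for b in r.breaks],
                config.species,
                locus_class,
                config.haplotype_resolution,
                thr,
            )
        )
    calls_df = pd.DataFrame(
        {
            "species": [c.species for c in calls],
            "locus": [c.locus_class for c in calls],
            "resolution": [c.haplotype_resolution for c in calls],
            "mismatch_flag": [c.mismatch_flag for c in calls],
            "break_flag": [c.break_flag for c in calls],
            "category": [c.category for c in calls],
        }
    )
    calls_path = write_tsv(calls_df, outdir / "locus_calls.tsv", thr.header_lines())

    if config.make_plots and results:
        by_label = {
            (r.locus.haplotype_label or r.locus.contig): r.summary for r in results
        }
        plot_read_summaries(
            by_label, PlotSpec(outdir / "read_summaries", format=config.plot_format)
        )

    manifest = {
        "tool": "igqc",
        "version": __version__,
        "config_hash": config.config_hash(),
        "thresholds": thr.as_dict(),
        "seed": config.seed,
        "inputs": {
            name: _sha256(Path(p))
            for name, p in (
                ("assembly", config.assembly),
                ("alignments", config.alignments),
                ("loci", config.loci),
                ("genes", config.genes),
            )
            if p is not None and Path(p).exists()
        },
        "loci_evaluated": [r.locus.region_string() for r in results],
        "skipped_records": {r.locus.region_string(): r.n_skipped for r in results},
        "outputs": outputs,
        "calls": str(calls_path),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"results": results, "calls": calls, "manifest": manifest}


def run_summarize(
    calls_tsv: str | Path, out_path: str | Path | None = None,
    mode: str = "non-exclusive",
) -> pd.DataFrame:
    """Aggregate a per-species calls TSV into the summary table."""
    calls = pd.read_csv(calls_tsv, sep="\t", comment="#")
    for col in ("mismatch_flag", "break_flag"):
        if col in calls.columns and calls[col].dtype == object:
            calls[col] = calls[col].astype(str).str.lower().isin(("true", "1", "yes"))
    summary = aggregate_species(calls, mode=mode)
    if out_path is not None:
        write_tsv(summary, out_path, [f"# counting mode: {mode}"])
    return summary


def run_simulate(
    sim_config, outdir: str | Path, defect: tuple | None = None,
    reads_from: str = "truth",
) -> dict[str, Path]:
    """Generate a complete fixture directory (genome, assembly, reads,
    alignments, loci, genes, truth)."""
    from . import synthetic

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixture = synthetic.make_fixture(sim_config, defect, reads_from)
    paths: dict[str, Path] = {}
    paths["true_genome"] = synthetic.write_fasta(
        fixture.locus.haplotypes, outdir / "true_genome.fasta"
    )
    paths["assembly"] = synthetic.write_fasta(
        fixture.evaluated.contigs, outdir / "assembly.fasta"
    )
    paths["reads"] = synthetic.write_fastq(fixture.reads, outdir / "reads.fastq")
    paths["alignments"] = synthetic.write_sam(
        fixture.header, fixture.alignments, outdir / "alignments.sam"
    )
    loci_df = pd.DataFrame(
        {
            "contig": [l.contig for l in fixture.loci],
            "start": [l.start for l in fixture.loci],
            "end": [l.end for l in fixture.loci],
            "locus": [l.locus_class for l in fixture.loci],
            "haplotype": [l.haplotype_label for l in fixture.loci],
        }
    )
    paths["loci"] = outdir / "loci.bed"
    loci_df.to_csv(paths["loci"], sep="\t", index=False, header=False)
    genes_df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in fixture.genes],
            "segment_type": [g.segment_type for g in fixture.genes],
            "contig": [g.contig for g in fixture.genes],
            "start": [g.start for g in fixture.genes],
            "end": [g.end for g in fixture.genes],
            "strand": [g.strand for g in fixture.genes],
        }
    )
    paths["genes"] = outdir / "genes.tsv"
    with open(paths["genes"], "w") as fh:
        fh.write("# gene_id\tsegment_type\tcontig\tstart\tend\tstrand\n")
        genes_df.to_csv(fh, sep="\t", index=False, header=False)
    paths.update(synthetic.write_truth(fixture, outdir))
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(fixture.config.as_dict(), fh, indent=2, sort_keys=True)
    paths["config"] = outdir / "sim_config.json"
    return paths
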