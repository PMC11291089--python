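"""Per-gene quality calls.

Two views mirror the per-position metrics:

* read view — a gene is "affected" when more than ``gene_poor_read_max``
  (default 5, strict) poorly aligned reads overlap it by at least 1 bp.
  Genes are short relative to long reads, so any overlap attests.
* base view — a gene has "perfect support" only if every position in it is
  covered (depth > 0) and has support fraction strictly above
  ``support_min`` (default 0.8).  Uncovered positions are not perfect
  support.

A diagnostic "deletion observed" annotation is raised when more than half
of the covering reads carry a deletion at some gene position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Thresholds
from .error_metrics import LocusPileup
from .io_formats import FormatError, GeneAnnotation
from .read_stats import ReadAlignmentStats


@dataclass
class GeneSupportReport:
    gene_id: str
    segment_type: str
    contig: str
    start: int
    end: int
    strand: str
    overlapping_poor_reads: int = 0
    read_affected: bool = False
    min_support_fraction: float = 1.0
    weak_positions: list[tuple[int, float]] = field(default_factory=list)
    base_affected: bool = False
    deletion_observed: bool = False


def gene_read_support(
    gene: GeneAnnotation,
    reads: list[ReadAlignmentStats],
    gene_poor_read_max: int = 5,
) -> tuple[int, bool]:
    """Count poorly aligned reads overlapping the gene; affected iff > max."""
    count = sum(
        1
        for r in reads
        if r.poorly_aligned
        and r.contig == gene.contig
        and r.overlaps(gene.start, gene.end)
    )
    return count, count > gene_poor_read_max


def gene_base_support(
    gene: GeneAnnotation,
    pileup: LocusPileup,
    thresholds: Thresholds | None = None,
) -> GeneSupportReport:
    """Base-view support report over the gene interval.

    Weak positions (support <= support_min, or depth 0) are listed with the
    support percentage rounded to 0.1%.
    """
    thr = thresholds or Thresholds()
    locus = pileup.locus
    if (
        gene.contig != locus.contig
        or gene.start < locus.start
        or gene.end > locus.end
    ):
        raise FormatError(
            f"gene {gene.gene_id} ({gene.contig}:{gene.start}-{gene.end}) "
            f"outside analyzed locus {locus.region_string()}"
        )
    s = gene.start - locus.start
    e = gene.end - locus.start
    depth = pileup.depth[s:e]
    support = pileup.support_fraction()[s:e]

    report = GeneSupportReport(
        gene.gene_id, gene.segment_type, gene.contig, gene.start, gene.end,
        gene.strand,
    )
    weak: list[tuple[int, float]] = []
    min_support = 1.0
    for i in range(e - s):
        pos = gene.start + i
        if depth[i] == 0:
            weak.append((pos, 0.0))
            min_support = 0.0
        else:
            frac = float(support[i])
            min_support = min(min_support, frac)
            if not frac > thr.support_min:
                weak.append((pos, round(100.0 * frac, 1)))
    report.min_support_fraction = min_support
    report.weak_positions = weak
    report.base_affected = bool(weak)
    covered = depth > 0
    if covered.any():
        del_frac = pileup.deleted[s:e][covered] / depth[covered]
        report.deletion_observed = bool((del_frac > 0.5).any())
    return report


def gene_report(
    gene: GeneAnnotation,
    reads: list[ReadAlignmentStats],
    pileup: LocusPileup,
    thresholds: Thresholds | None = None,
) -> GeneSupportReport:
    """Full (read view + base view) report for one gene."""
    thr = thresholds or Thresholds()
    report = gene_base_support(gene, pileup, thr)
    count, affected = gene_read_support(gene, reads, thr.gene_poor_read_max)
    report.overlapping_poor_reads = count
    report.read_affected = affected
    return report


def gene_panel_summary(reports: list[GeneSupportReport]) -> dict:
    """Fractions of affected genes per view, overall and by segment type.

    Percentages are rounded to 0.1.  An empty gene set yields zeros.
    """
    def _group(sub: list[GeneSupportReport]) -> dict:
        n = len(sub)
        if n == 0:
            return {"n_genes": 0, "pct_read_affected": 0.0, "pct_base_affected": 0.0}
        return {
            "n_genes": n,
            "pct_read_affected": round(100.0 * sum(r.read_affected for r in sub) / n, 1),
            "pct_base_affected": round(100.0 * sum(r.base_affected for r in sub) / n, 1),
        }

    out = {"overall": _group(reports)}
    for seg in ("V", "D", "J"):
        out[seg] = _group([r for r in reports if r.segment_type == seg])
    return out


def gene_report_frame(reports: list[GeneSupportReport]) -> pd.DataFrame:
    """One row per gene for the report TSV (1-based inclusive coordinates)."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in reports],
            "type": [r.segment_type for r in reports],
            "contig": [r.contig for r in reports],
            "start": [r.start + 1 for r in reports],
            "end": [r.end for r in reports],
            "strand": [r.strand for r in reports],
            "poor_read_count": [r.overlapping_poor_reads for r in reports],
            "read_affected": [r.read_affected for r in reports],
            "min_support_pct": [round(100 * r.min_support_fraction, 1) for r in reports],
            "weak_positions": [
                ";".join(f"{p + 1}:{pct}" for p, pct in r.weak_positions)
                for r in reports
            ],
            "base_affected": [r.base_affected for r in reports],
            "deletion_observed": [r.deletion_observed for r in reports],
        }
    )
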