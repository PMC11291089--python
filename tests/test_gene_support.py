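"""Gene-level quality: read-view and base-view affected calls."""

import numpy as np
import pytest

from igqc.config import Thresholds
from igqc.error_metrics import build_pileup
from igqc.gene_support import (
    gene_base_support,
    gene_panel_summary,
    gene_read_support,
    gene_report,
    gene_report_frame,
)
from igqc.io_formats import FormatError, GeneAnnotation, LocusInterval
from igqc.read_stats import ReadAlignmentStats


def _read(start, end, poor=False, mismatches=(), deletions=()):
    return ReadAlignmentStats(
        read_id=f"r{start}{poor}", contig="c", start=start, end=end, mapq=60,
        aligned_length=end - start, substitutions=len(mismatches),
        soft_clip_bases=0, hard_clip_bases=0, indel_events=0,
        poorly_aligned=poor,
        mismatch_positions=np.asarray(mismatches, dtype=np.int64),
        deletion_spans=list(deletions),
    )


GENE = GeneAnnotation("IGHV3", "V", "c", 100, 160, "+")
LOCUS = LocusInterval("c", 0, 400, "IGH")


class TestReadView:
    @pytest.mark.parametrize("n_poor,expected", [(6, True), (5, False)],
                             ids=["six-affected", "five-boundary-not"])
    def test_strict_poor_read_rule(self, n_poor, expected):
        reads = [_read(90, 300, poor=i < n_poor) for i in range(12)]
        count, affected = gene_read_support(GENE, reads)
        assert count == n_poor and affected is expected

    def test_clean_reads_never_affect(self):
        reads = [_read(0, 400) for _ in range(30)]
        assert gene_read_support(GENE, reads) == (0, False)

    def test_one_bp_overlap_counts(self):
        touching = [_read(159, 300, poor=True) for _ in range(6)]
        outside = [_read(160, 300, poor=True) for _ in range(6)]
        assert gene_read_support(GENE, touching)[1] is True
        assert gene_read_support(GENE, outside)[0] == 0

    def test_counts_equal_bruteforce_overlap(self, small_deletion_fixture, thresholds):
        from igqc.read_stats import collect_read_stats

        fx = small_deletion_fixture
        records = [s for s in fx.alignments if s.reference_name == "hap1"]
        stats, _ = collect_read_stats(records, fx.assembly, thresholds)
        for gene in [g for g in fx.genes if g.contig == "hap1"]:
            count, _ = gene_read_support(gene, stats)
            brute = sum(
                1 for s in stats
                if s.poorly_aligned and s.start < gene.end and s.end > gene.start
            )
            assert count == brute


class TestBaseView:
    def test_worked_support_percentages(self):
        """10/13 -> 76.9% and 2/3 -> 66.7% weak positions."""
        reads = [_read(0, 400, mismatches=[120] if i < 3 else []) for i in range(13)]
        pile = build_pileup(reads, LOCUS)
        report = gene_base_support(GENE, pile)
        assert report.base_affected
        assert report.weak_positions == [(120, 76.9)]
        reads2 = [_read(0, 400, mismatches=[130] if i < 1 else []) for i in range(3)]
        report2 = gene_base_support(GENE, build_pileup(reads2, LOCUS))
        assert report2.weak_positions == [(130, 66.7)]

    def test_full_support_is_perfect(self):
        pile = build_pileup([_read(0, 400) for _ in range(10)], LOCUS)
        report = gene_base_support(GENE, pile)
        assert not report.base_affected and report.min_support_fraction == 1.0

    @pytest.mark.parametrize("depth,delta,affected",
                             [(5, 1, True), (1000, 199, False)],
                             ids=["exactly-80pct-not-perfect", "80.1pct-perfect"])
    def test_support_threshold_strict(self, depth, delta, affected):
        reads = [
            _read(0, 400, mismatches=[125] if i < delta else [])
            for i in range(depth)
        ]
        report = gene_base_support(GENE, build_pileup(reads, LOCUS))
        assert report.base_affected is affected

    def test_uncovered_position_affects(self):
        reads = [_read(0, 130) for _ in range(8)]  # gene tail uncovered
        report = gene_base_support(GENE, build_pileup(reads, LOCUS))
        assert report.base_affected and report.min_support_fraction == 0.0
        assert (135, 0.0) in report.weak_positions

    def test_gene_outside_locus_is_error(self):
        gene = GeneAnnotation("g", "V", "c", 390, 450, "+")
        pile = build_pileup([], LOCUS)
        with pytest.raises(FormatError, match="outside"):
            gene_base_support(gene, pile)

    def test_deletion_observation(self):
        reads = [_read(0, 400, deletions=[(110, 130)] if i < 6 else [])
                 for i in range(10)]
        report = gene_base_support(GENE, build_pileup(reads, LOCUS))
        assert report.deletion_observed


class TestPanelSummary:
    def test_fraction_rounding(self):
        reports = []
        for i in range(59):
            r = gene_report(
                GeneAnnotation(f"g{i}", "V", "c", 100, 160, "+"),
                [_read(0, 400, poor=True)] * (8 if i < 8 else 0),
                build_pileup([_read(0, 400)], LOCUS),
            )
            reports.append(r)
        summary = gene_panel_summary(reports)
        assert summary["overall"]["pct_read_affected"] == 13.6  # 8/59

    def test_empty_gene_set_zeroed(self):
        summary = gene_panel_summary([])
        assert summary["overall"] == {
            "n_genes": 0, "pct_read_affected": 0.0, "pct_base_affected": 0.0,
        }

    def test_report_frame_schema(self):
        pile = build_pileup([_read(0, 400)], LOCUS)
        df = gene_report_frame([gene_base_support(GENE, pile)])
        assert df.loc[0, "start"] == 101  # 1-based in reports
        assert not df.loc[0, "base_affected"]
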