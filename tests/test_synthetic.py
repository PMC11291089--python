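"""Synthetic diploid loci, read simulation, defect injection and truth."""

import numpy as np
import pytest

from igqc.io_formats import FormatError, find_n_runs
from igqc.synthetic import (
    SimConfig,
    generate_diploid_locus,
    inject_inversion_with_gap,
    inject_missing_segment,
    invert_with_gap,
    make_fixture,
    revcomp,
    simulate_reads,
    write_truth,
)

CFG = SimConfig(seed=21, locus_length=50_000, n_gene_cassettes=4, depth=20)


class TestDiploidLocus:
    def test_zero_divergence_identical_haplotypes(self):
        cfg = SimConfig(seed=1, locus_length=40_000, n_gene_cassettes=3, divergence=0.0)
        locus = generate_diploid_locus(cfg)
        assert locus.haplotypes["hap1"] == locus.haplotypes["hap2"]

    def test_seed_determinism(self):
        a = generate_diploid_locus(CFG)
        b = generate_diploid_locus(CFG)
        assert a.haplotypes == b.haplotypes
        assert [g.gene_id for g in a.genes] == [g.gene_id for g in b.genes]

    def test_measured_divergence_matches_configured(self):
        cfg = SimConfig(seed=2, locus_length=100_000, divergence=0.02)
        locus = generate_diploid_locus(cfg)
        h1 = np.frombuffer(locus.haplotypes["hap1"].encode(), dtype="S1")
        h2 = np.frombuffer(locus.haplotypes["hap2"].encode(), dtype="S1")
        measured = (h1 != h2).mean()
        assert measured == pytest.approx(0.02, rel=0.10)

    def test_infeasible_cassette_config_fatal(self):
        with pytest.raises(FormatError, match="fit"):
            generate_diploid_locus(
                SimConfig(locus_length=20_000, n_gene_cassettes=10, cassette_len=3_000)
            )

    def test_cassette_cnv_shortens_hap2(self):
        cfg = SimConfig(seed=3, locus_length=60_000, n_gene_cassettes=5,
                        cassette_cnv_delta=2)
        locus = generate_diploid_locus(cfg)
        assert len(locus.haplotypes["hap2"]) == 60_000 - 2 * cfg.cassette_len
        # coordinate map: positions after the CNV shift by its length
        ds, de = locus.cnv_deletion
        assert locus.hap2_to_hap1(ds - 1) == ds - 1
        assert locus.hap2_to_hap1(ds) == de


class TestReadSimulation:
    def test_error_free_reads_are_exact_substrings(self):
        cfg = SimConfig(seed=4, locus_length=30_000, n_gene_cassettes=3,
                        error_rate=0.0, depth=5)
        locus = generate_diploid_locus(cfg)
        reads = simulate_reads(locus.haplotypes, cfg)
        for r in reads[:50]:
            assert r.seq == locus.haplotypes[r.contig][r.start : r.end]
            assert r.n_errors == 0

    def test_realized_depth_within_15pct(self):
        cfg = SimConfig(seed=5, locus_length=100_000, depth=25)
        locus = generate_diploid_locus(cfg)
        reads = simulate_reads(locus.haplotypes, cfg)
        total = sum(r.end - r.start for r in reads if r.contig == "hap1")
        assert total / 100_000 == pytest.approx(25, rel=0.15)

    def test_realized_error_rate_within_20pct(self):
        cfg = SimConfig(seed=6, locus_length=100_000, error_rate=0.002)
        locus = generate_diploid_locus(cfg)
        reads = simulate_reads(locus.haplotypes, cfg)
        total_err = sum(r.n_errors for r in reads)
        total_bp = sum(r.end - r.start for r in reads)
        assert total_err / total_bp == pytest.approx(0.002, rel=0.20)

    def test_reverse_strand_reads_recorded(self):
        reads = simulate_reads(generate_diploid_locus(CFG).haplotypes, CFG)
        strands = {r.strand for r in reads}
        assert strands == {"+", "-"}
        rev = next(r for r in reads if r.strand == "-")
        assert rev.sequenced == revcomp(rev.seq)


class TestDefectInjection:
    def test_zero_length_deletion_is_noop(self):
        locus = generate_diploid_locus(CFG)
        ev = inject_missing_segment(locus, "hap2", 10_000, 10_000)
        assert ev.contigs == locus.haplotypes and not ev.defects

    def test_deletion_out_of_bounds_fatal(self):
        locus = generate_diploid_locus(CFG)
        with pytest.raises(FormatError, match="bounds"):
            inject_missing_segment(locus, "hap2", 10_000, 90_000)

    def test_deletion_geometry_and_truth(self):
        locus = generate_diploid_locus(CFG)
        ev = inject_missing_segment(locus, "hap2", 12_000, 18_000)
        assert len(ev.contigs["hap2"]) == 50_000 - 6_000
        (d,) = ev.defects
        assert (d.kind, d.start, d.end) == ("deleted_segment", 12_000, 18_000)
        assert (d.homolog_contig, d.homolog_start, d.homolog_end) == (
            "hap1", 12_000, 18_000,
        )
        # genes beyond the deletion shift left; genes inside are gone
        lost = [g for g in locus.genes
                if g.contig == "hap2" and g.start >= 12_000 and g.end <= 18_000]
        kept_ids = {g.gene_id for g in ev.genes}
        assert all(g.gene_id not in kept_ids for g in lost)

    def test_inversion_plants_detectable_gap(self):
        locus = generate_diploid_locus(CFG)
        ev = inject_inversion_with_gap(locus, "hap1", 20_000, 30_000, 8)
        runs = find_n_runs(ev.contigs["hap1"])
        assert (20_000, 20_008) in runs
        assert len(ev.contigs["hap1"]) == 50_008

    def test_inversion_is_involution_gap_aside(self):
        seq = "ACGTACGTACGTACGTACGT"
        once = invert_with_gap(seq, 4, 12, 3)
        # strip the gap, invert the same interval again
        stripped = once[:4] + once[7:]
        assert invert_with_gap(stripped, 4, 12, 0) == seq

    def test_truth_round_trips_through_serialization(self, tmp_path):
        import pandas as pd

        fx = make_fixture(CFG, defect=("deletion", "hap2", 12_000, 18_000))
        paths = write_truth(fx, tmp_path)
        defects = pd.read_csv(paths["truth_defects"], sep="\t")
        assert defects.loc[0, "kind"] == "deleted_segment"
        assert (defects.loc[0, "start"], defects.loc[0, "end"]) == (12_000, 18_000)
        reads = pd.read_csv(paths["truth_reads"], sep="\t")
        assert len(reads) == len(fx.reads)
        assert set(reads.columns) >= {"read", "contig", "start", "end", "strand"}


class TestOracleAlignment:
    def test_fixture_fully_deterministic(self):
        fa = make_fixture(CFG, defect=("inversion", "hap1", 20_000, 30_000, 50))
        fb = make_fixture(CFG, defect=("inversion", "hap1", 20_000, 30_000, 50))
        assert [r.seq for r in fa.reads] == [r.seq for r in fb.reads]
        sig = lambda fx: [
            (s.query_name, s.reference_start, s.cigarstring, s.get_tag("MD"))
            for s in fx.alignments
        ]
        assert sig(fa) == sig(fb)

    def test_alignments_sorted_and_tagged(self):
        fx = make_fixture(CFG)
        keys = [(s.reference_id, s.reference_start) for s in fx.alignments]
        assert keys == sorted(keys)
        for s in fx.alignments[:20]:
            assert s.has_tag("MD") and s.has_tag("NM")

    def test_md_consistent_with_reference(self, small_clean_fixture):
        """NM equals a direct recount of aligned mismatches."""
        fx = small_clean_fixture
        for seg in fx.alignments[:100]:
            ref = fx.evaluated.contigs[seg.reference_name]
            mism = sum(
                1
                for qpos, rpos in seg.get_aligned_pairs(matches_only=True)
                if seg.query_sequence[qpos] != ref[rpos]
            )
            assert seg.get_tag("NM") == mism

    def test_breakpoint_reads_softclipped(self):
        fx = make_fixture(CFG, defect=("inversion", "hap1", 20_000, 30_000, 50))
        clipped = [
            s for s in fx.alignments
            if s.reference_name == "hap1" and "S" in (s.cigarstring or "")
        ]
        assert clipped  # reads crossing a breakpoint exist and are clipped
        # no aligned base may sit inside the planted gap [20000, 20050)
        for s in fx.alignments:
            if s.reference_name == "hap1":
                assert s.reference_end <= 20_000 or s.reference_start >= 20_050
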