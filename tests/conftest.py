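"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's computation paths:
substitutions are recounted by a manual CIGAR walk against the reference
string, and pileup columns by per-position Python increments, so agreement
with the vectorized implementation is meaningful.
"""

from __future__ import annotations

import numpy as np
import pysam
import pytest
from hypothesis import settings

from igqc.config import Thresholds
from igqc.io_formats import LocusInterval
from igqc.synthetic import SimConfig, make_fixture, to_indexed_bam

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def toy_header(contigs: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": ln} for n, ln in sorted(contigs.items())],
        }
    )


def make_segment(
    header: pysam.AlignmentHeader,
    name: str,
    contig: str,
    start: int,
    cigar: list[tuple[int, int]],
    seq: str,
    mapq: int = 60,
    flag: int = 0,
    md: str | None = None,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.query_sequence = seq
    seg.flag = flag
    seg.reference_id = header.get_tid(contig)
    seg.reference_start = start
    seg.mapping_quality = mapq
    seg.cigartuples = cigar
    if md is not None:
        seg.set_tag("MD", md)
    return seg


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

_CONSUME_Q = {0, 1, 4, 7, 8}
_CONSUME_R = {0, 2, 3, 7, 8}


def walk_substitutions(record: pysam.AlignedSegment, reference: str):
    """Manual CIGAR walk; returns (aligned_len, [mismatch ref positions])."""
    qpos, rpos = 0, record.reference_start
    aligned = 0
    mismatches = []
    query = record.query_sequence
    for op, length in record.cigartuples:
        if op in (0, 7, 8):
            for i in range(length):
                aligned += 1
                rb = reference[rpos + i]
                if rb != "N" and query[qpos + i] != rb:
                    mismatches.append(rpos + i)
            qpos += length
            rpos += length
        else:
            if op in _CONSUME_Q:
                qpos += length
            if op in _CONSUME_R:
                rpos += length
    return aligned, mismatches


def naive_pileup_counts(
    records: list[pysam.AlignedSegment],
    reference: str,
    locus: LocusInterval,
    theta: float = 0.01,
) -> dict[str, list[int]]:
    """Per-position recount by plain Python increments."""
    L = locus.length
    counts = {
        k: [0] * L
        for k in ("depth", "delta", "e_count", "deleted", "mapq60", "mapq_mid", "mapq0")
    }
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        aligned, mismatches = walk_substitutions(rec, reference)
        e_r = len(mismatches) / aligned if aligned else 0.0
        poor = e_r > theta
        bin_key = (
            "mapq60"
            if rec.mapping_quality >= 60
            else ("mapq0" if rec.mapping_quality == 0 else "mapq_mid")
        )
        aligned_ref = set()
        rpos = rec.reference_start
        for op, length in rec.cigartuples:
            if op in (0, 7, 8):
                aligned_ref.update(range(rpos, rpos + length))
            if op in _CONSUME_R:
                rpos += length
        for pos in range(max(rec.reference_start, locus.start), min(rec.reference_end, locus.end)):
            i = pos - locus.start
            counts["depth"][i] += 1
            counts[bin_key][i] += 1
            if poor:
                counts["e_count"][i] += 1
            if pos not in aligned_ref:
                counts["deleted"][i] += 1
        for pos in mismatches:
            if locus.start <= pos < locus.end:
                counts["delta"][pos - locus.start] += 1
    return counts


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def thresholds() -> Thresholds:
    return Thresholds()


@pytest.fixture(scope="session")
def small_clean_fixture():
    """30 kb diploid locus, error-free control conditions, seeded."""
    cfg = SimConfig(seed=11, locus_length=30_000, n_gene_cassettes=3, depth=25)
    return make_fixture(cfg, reads_from="assembly")


@pytest.fixture(scope="session")
def small_deletion_fixture():
    """30 kb diploid locus with a 6 kb segment deleted from hap2."""
    cfg = SimConfig(seed=12, locus_length=30_000, n_gene_cassettes=3, depth=25)
    return make_fixture(cfg, defect=("deletion", "hap2", 12_000, 18_000))


@pytest.fixture()
def indexed_bam(tmp_path):
    """Factory: fixture -> coordinate-sorted, indexed BAM path."""

    def _make(fixture, name="aln.bam"):
        return to_indexed_bam(fixture.header, fixture.alignments, tmp_path / name)

    return _make
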