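"""Synthetic diploid IG-like loci with injected assembly defects.

Generates a two-haplotype locus built from tandem gene cassettes, simulates
HiFi-like reads from it, and injects the two defect archetypes the
detectors target:

* deleted_segment — a segment removed from one haplotype of the evaluated
  assembly while reads still come from the full genome.  Reads from the
  deleted region pile up on the retained homolog, producing the
  mismatch-error signature: clusters of poorly supported positions plus
  locally elevated coverage.
* inversion (+ N gap) — a segment reverse-complemented in the evaluated
  assembly with a run of Ns planted at the 5' breakpoint, producing a
  coverage break over the gap classified as n_gap.

Alignment of simulated reads uses an exact-placement oracle aligner: each
read is placed at coordinates derived from its recorded origin and the
known defect geometry, with mismatch (NM/MD) tags computed against the
evaluated assembly.  Reads crossing an inversion breakpoint are soft-
clipped at the breakpoint (the longer side is aligned); reads from a
deleted segment are remapped whole to the homologous coordinates.  This
keeps every fixture hermetic and byte-reproducible; a real aligner can be
substituted for integration runs.

Every operation is driven by a single seeded SimConfig; identical seeds
give identical sequences, reads, truth and alignments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .io_formats import (
    FormatError,
    GeneAnnotation,
    LocusInterval,
    ReferenceAssembly,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Study conditions for one synthetic fixture (desk scale).

    Defaults emulate a 100 kb IG-like locus per haplotype — eight 3 kb
    tandem gene cassettes plus a D/J tail — read at 30x per haplotype with
    3 kb +/- 0.6 kb reads carrying 0.2% substitution error (HiFi-like
    accuracy), and 2% inter-haplotype divergence.
    """

    seed: int = 0
    locus_length: int = 100_000
    n_gene_cassettes: int = 8
    cassette_len: int = 3_000
    cassette_divergence: float = 0.01
    divergence: float = 0.02
    cassette_cnv_delta: int = 0
    read_len_mean: int = 3_000
    read_len_sd: int = 600
    read_len_min: int = 500
    error_rate: float = 0.002
    depth: int = 30

    def __post_init__(self) -> None:
        for rate in (self.cassette_divergence, self.divergence, self.error_rate):
            if not 0 <= rate < 1:
                raise FormatError(f"rate {rate} outside [0, 1)")
        if self.depth < 1 or self.locus_length <= 0 or self.read_len_min <= 0:
            raise FormatError("depth, lengths must be positive")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Defect:
    kind: str  # deleted_segment | inversion
    contig: str
    start: int  # true-genome coordinates, half-open
    end: int
    gap_len: int = 0
    #: homologous interval on the other haplotype (deleted_segment only)
    homolog_contig: str = ""
    homolog_start: int = 0
    homolog_end: int = 0

    def as_row(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimRead:
    name: str
    contig: str
    start: int  # origin on the true genome, half-open
    end: int
    strand: str
    seq: str  # genome orientation, sequencing errors applied
    n_errors: int

    @property
    def sequenced(self) -> str:
        return self.seq if self.strand == "+" else revcomp(self.seq)


@dataclass
class DiploidLocus:
    config: SimConfig
    haplotypes: dict[str, str]
    genes: list[GeneAnnotation]
    #: interval deleted from hap2 relative to hap1 (cassette CNV), or None
    cnv_deletion: tuple[int, int] | None = None

    def hap2_to_hap1(self, pos: int) -> int:
        if self.cnv_deletion and pos >= self.cnv_deletion[0]:
            return pos + (self.cnv_deletion[1] - self.cnv_deletion[0])
        return pos

    def homolog_interval(self, contig: str, start: int, end: int) -> tuple[str, int, int]:
        """Map an interval to the homologous coordinates on the other haplotype."""
        if contig == "hap2":
            return "hap1", self.hap2_to_hap1(start), self.hap2_to_hap1(end)
        if self.cnv_deletion:
            ds, de = self.cnv_deletion
            shift = de - ds
            conv = lambda p: p - shift if p >= de else min(p, ds)
            return "hap2", conv(start), conv(end)
        return "hap2", start, end


@dataclass
class EvaluatedAssembly:
    """The assembly under evaluation: possibly defective haplotype contigs."""

    contigs: dict[str, str]
    genes: list[GeneAnnotation]
    defects: list[Defect] = field(default_factory=list)

    def reference(self) -> ReferenceAssembly:
        return ReferenceAssembly(contigs=dict(self.contigs))

    def loci(self, locus_class: str = "IGH") -> list[LocusInterval]:
        return [
            LocusInterval(name, 0, len(seq), locus_class, name)
            for name, seq in sorted(self.contigs.items())
        ]


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute bases i.i.d. at ``rate``, always to a different base."""
    out = seq.copy()
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return out
    pos = rng.choice(len(seq), size=k, replace=False)
    shift = rng.integers(1, 4, size=k)
    idx = (np.searchsorted(_BASES, out[pos]) + shift) % 4
    out[pos] = _BASES[idx]
    return out


def generate_diploid_locus(config: SimConfig) -> DiploidLocus:
    """Two haplotype sequences with cassette repeats, genes and truth.

    hap1 carries ``n_gene_cassettes`` tandem copies of a cassette (pairwise
    divergence ``cassette_divergence``), each holding one V gene, plus a
    D/J tail.  hap2 is hap1 mutated at ``divergence`` with optionally
    ``cassette_cnv_delta`` trailing cassette copies removed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L = cfg.locus_length
    c0 = L // 10
    tail = 10_000
    if c0 + cfg.n_gene_cassettes * cfg.cassette_len > L - tail:
        raise FormatError(
            f"{cfg.n_gene_cassettes} cassettes of {cfg.cassette_len} bp do not "
            f"fit a {L} bp locus"
        )
    if not 0 <= cfg.cassette_cnv_delta < cfg.n_gene_cassettes:
        raise FormatError("cassette_cnv_delta must be < n_gene_cassettes")

    hap1 = _random_seq(rng, L)
    proto = _random_seq(rng, cfg.cassette_len)
    genes: list[GeneAnnotation] = []
    v_off, v_len = cfg.cassette_len // 4, 300
    for i in range(cfg.n_gene_cassettes):
        start = c0 + i * cfg.cassette_len
        hap1[start : start + cfg.cassette_len] = _mutate(
            rng, proto, cfg.cassette_divergence
        )
        genes.append(
            GeneAnnotation(
                f"IGHV{i + 1}", "V", "hap1", start + v_off, start + v_off + v_len, "+"
            )
        )
    d0, j0 = L - 8_000, L - 6_000
    for i in range(3):
        genes.append(
            GeneAnnotation(f"IGHD{i + 1}", "D", "hap1", d0 + i * 200, d0 + i * 200 + 30, "+")
        )
    for i in range(4):
        genes.append(
            GeneAnnotation(f"IGHJ{i + 1}", "J", "hap1", j0 + i * 400, j0 + i * 400 + 60, "+")
        )

    hap2 = _mutate(rng, hap1, cfg.divergence)
    cnv: tuple[int, int] | None = None
    if cfg.cassette_cnv_delta:
        keep = cfg.n_gene_cassettes - cfg.cassette_cnv_delta
        cnv = (c0 + keep * cfg.cassette_len, c0 + cfg.n_gene_cassettes * cfg.cassette_len)
        hap2 = np.concatenate([hap2[: cnv[0]], hap2[cnv[1] :]])

    hap2_genes: list[GeneAnnotation] = []
    shift = (cnv[1] - cnv[0]) if cnv else 0
    for g in genes:
        if cnv and g.start >= cnv[0] and g.end <= cnv[1]:
            continue  # gene lost with the cassette
        s, e = g.start, g.end
        if cnv and s >= cnv[1]:
            s, e = s - shift, e - shift
        hap2_genes.append(
            GeneAnnotation(g.gene_id + "_h2", g.segment_type, "hap2", s, e, g.strand)
        )

    return DiploidLocus(
        config=cfg,
        haplotypes={
            "hap1": hap1.tobytes().decode(),
            "hap2": hap2.tobytes().decode(),
        },
        genes=genes + hap2_genes,
        cnv_deletion=cnv,
    )


def simulate_reads(
    sequences: dict[str, str],
    config: SimConfig,
    seed: int | None = None,
) -> list[SimRead]:
    """Uniformly placed reads at ``depth`` per contig, truncated-normal
    lengths, i.i.d. substitution errors at ``error_rate``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    reads: list[SimRead] = []
    for contig in sorted(sequences):
        seq = np.frombuffer(sequences[contig].encode(), dtype="S1")
        L = len(seq)
        n = max(1, round(cfg.depth * L / cfg.read_len_mean))
        lengths = np.clip(
            np.rint(rng.normal(cfg.read_len_mean, cfg.read_len_sd, n)).astype(int),
            cfg.read_len_min,
            L,
        )
        for i, rlen in enumerate(lengths):
            start = int(rng.integers(0, L - rlen + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            sub = seq[start : start + rlen]
            with_err = _mutate(rng, sub, cfg.error_rate)
            n_err = int((sub != with_err).sum())
            reads.append(
                SimRead(
                    name=f"{contig}_read{i:05d}",
                    contig=contig,
                    start=start,
                    end=start + int(rlen),
                    strand=strand,
                    seq=with_err.tobytes().decode(),
                    n_errors=n_err,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# defect injection
# ---------------------------------------------------------------------------


def clean_assembly(locus: DiploidLocus) -> EvaluatedAssembly:
    """The evaluated assembly equals the true genome (no defect)."""
    return EvaluatedAssembly(contigs=dict(locus.haplotypes), genes=list(locus.genes))


def inject_missing_segment(
    locus: DiploidLocus, contig: str, start: int, end: int
) -> EvaluatedAssembly:
    """Delete [start, end) of ``contig`` from the evaluated assembly.

    Reads keep coming from the full genome; the truth records both the
    deleted interval and its retained homolog, where the mismatch signature
    is expected to appear.
    """
    seq = locus.haplotypes.get(contig)
    if seq is None:
        raise FormatError(f"unknown contig {contig!r}")
    if not 0 <= start <= end <= len(seq):
        raise FormatError(f"deletion {start}-{end} out of bounds for {contig}")
    if start == end:
        return clean_assembly(locus)
    contigs = dict(locus.haplotypes)
    contigs[contig] = seq[:start] + seq[end:]
    hc, hs, he = locus.homolog_interval(contig, start, end)
    defect = Defect(
        "deleted_segment", contig, start, end,
        homolog_contig=hc, homolog_start=hs, homolog_end=he,
    )
    genes: list[GeneAnnotation] = []
    for g in locus.genes:
        if g.contig != contig:
            genes.append(g)
        elif g.end <= start:
            genes.append(g)
        elif g.start >= end:
            genes.append(
                GeneAnnotation(
                    g.gene_id, g.segment_type, g.contig,
                    g.start - (end - start), g.end - (end - start), g.strand,
                )
            )
        # genes inside or straddling the deletion are gone from the assembly
    return EvaluatedAssembly(contigs=contigs, genes=genes, defects=[defect])


def invert_with_gap(seq: str, start: int, end: int, gap_len: int) -> str:
    """Reverse-complement [start, end) and plant gap_len Ns at the 5' breakpoint."""
    return seq[:start] + "N" * gap_len + revcomp(seq[start:end]) + seq[end:]


def inject_inversion_with_gap(
    locus: DiploidLocus, contig: str, start: int, end: int, gap_len: int
) -> EvaluatedAssembly:
    """Reverse-complement [start, end) of ``contig`` with an N-gap planted
    at the 5' breakpoint of the evaluated assembly."""
    seq = locus.haplotypes.get(contig)
    if seq is None:
        raise FormatError(f"unknown contig {contig!r}")
    if not (0 <= start < end <= len(seq)) or gap_len < 1:
        raise FormatError(
            f"inversion {start}-{end} (gap {gap_len}) invalid for {contig}"
        )
    contigs = dict(locus.haplotypes)
    contigs[contig] = invert_with_gap(seq, start, end, gap_len)
    defect = Defect("inversion", contig, start, end, gap_len=gap_len)
    g_shift = gap_len
    genes: list[GeneAnnotation] = []
    for g in locus.genes:
        if g.contig != contig or g.end <= start:
            genes.append(g)
        elif g.start >= end:
            genes.append(
                GeneAnnotation(
                    g.gene_id, g.segment_type, g.contig,
                    g.start + g_shift, g.end + g_shift, g.strand,
                )
            )
        elif g.start >= start and g.end <= end:
            flipped = "-" if g.strand == "+" else "+"
            genes.append(
                GeneAnnotation(
                    g.gene_id, g.segment_type, g.contig,
                    start + gap_len + (end - g.end),
                    start + gap_len + (end - g.start),
                    flipped,
                )
            )
        # genes straddling a breakpoint are disrupted and dropped
    return EvaluatedAssembly(contigs=contigs, genes=genes, defects=[defect])


# ---------------------------------------------------------------------------
# oracle aligner
# ---------------------------------------------------------------------------


@dataclass
class _Placement:
    contig: str
    pos: int
    reverse: bool  # aligned orientation opposite the genome orientation
    #: (soft_left, matched, soft_right) over the assembly-forward sequence
    clip: tuple[int, int, int]


def _place_read(
    read: SimRead, defects: dict[str, Defect], locus: DiploidLocus
) -> _Placement:
    d = defects.get(read.contig)
    rlen = read.end - read.start
    if d is None:
        return _Placement(read.contig, read.start, False, (0, rlen, 0))
    if d.kind == "deleted_segment":
        if read.end <= d.start:
            return _Placement(read.contig, read.start, False, (0, rlen, 0))
        if read.start >= d.end:
            return _Placement(
                read.contig, read.start - (d.end - d.start), False, (0, rlen, 0)
            )
        # origin overlaps the deletion: best match is the retained homolog
        hc, hs, _he = locus.homolog_interval(read.contig, read.start, read.end)
        return _Placement(hc, hs, False, (0, rlen, 0))
    if d.kind == "inversion":
        s, e, g = d.start, d.end, d.gap_len
        if read.end <= s:
            return _Placement(read.contig, read.start, False, (0, rlen, 0))
        if read.start >= e:
            return _Placement(read.contig, read.start + g, False, (0, rlen, 0))
        if read.start >= s and read.end <= e:
            return _Placement(
                read.contig, s + g + (e - read.end), True, (0, rlen, 0)
            )
        if read.start < s <= read.end <= e:  # crosses 5' breakpoint
            left, right = s - read.start, read.end - s
            if left >= right:
                return _Placement(read.contig, read.start, False, (0, left, right))
            return _Placement(
                read.contig, s + g + (e - read.end), True, (0, right, left)
            )
        if s <= read.start < e < read.end:  # crosses 3' breakpoint
            left, right = e - read.start, read.end - e
            if right >= left:
                return _Placement(read.contig, e + g, False, (left, right, 0))
            return _Placement(read.contig, s + g, True, (right, left, 0))
        raise FormatError(
            f"read {read.name} spans the whole inverted interval; use a "
            "longer inversion or shorter reads"
        )
    raise FormatError(f"unknown defect kind {d.kind!r}")


def _md_and_nm(read_seq: str, ref_seq: str) -> tuple[str, int]:
    """MD string and NM count for an all-match (M) alignment block."""
    parts: list[str] = []
    run = 0
    nm = 0
    for rb, qb in zip(ref_seq, read_seq):
        if qb == rb:
            run += 1
        else:
            parts.append(str(run))
            parts.append(rb)
            run = 0
            nm += 1
    parts.append(str(run))
    return "".join(parts), nm


def oracle_align(
    reads: list[SimRead],
    evaluated: EvaluatedAssembly,
    locus: DiploidLocus,
    mapq: int = 60,
) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    """Place every simulated read on the evaluated assembly.

    Returns a coordinate-sorted list of AlignedSegment with CIGAR, NM and
    MD computed against the evaluated contigs.
    """
    defects = {d.contig: d for d in evaluated.defects}
    names = sorted(evaluated.contigs)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": len(evaluated.contigs[n])} for n in names],
        }
    )
    tid = {n: i for i, n in enumerate(names)}
    segments: list[pysam.AlignedSegment] = []
    for read in reads:
        p = _place_read(read, defects, locus)
        fwd = read.seq if not p.reverse else revcomp(read.seq)
        sl, m, sr = p.clip
        # clip any part running off the contig end (homolog length mismatch)
        contig_seq = evaluated.contigs[p.contig]
        pos = p.pos
        if pos < 0:
            cut = -pos
            sl, m, pos = sl + cut, m - cut, 0
        over = pos + m - len(contig_seq)
        if over > 0:
            sr, m = sr + over, m - over
        if m <= 0:
            continue  # nowhere to align; read dropped (unmapped)
        aligned = fwd[sl : sl + m]
        md, nm = _md_and_nm(aligned, contig_seq[pos : pos + m])
        seg = pysam.AlignedSegment(header)
        seg.query_name = read.name
        seg.query_sequence = fwd
        seg.flag = 16 if (p.reverse != (read.strand == "-")) else 0
        seg.reference_id = tid[p.contig]
        seg.reference_start = pos
        seg.mapping_quality = mapq
        cigar = []
        if sl:
            cigar.append((4, sl))
        cigar.append((0, m))
        if sr:
            cigar.append((4, sr))
        seg.cigartuples = cigar
        seg.query_qualities = pysam.qualitystring_to_array("I" * len(fwd))
        seg.set_tag("NM", nm)
        seg.set_tag("MD", md)
        segments.append(seg)
    segments.sort(key=lambda s: (s.reference_id, s.reference_start, s.query_name))
    return header, segments


# ---------------------------------------------------------------------------
# fixture assembly + serialization
# ---------------------------------------------------------------------------


@dataclass
class Fixture:
    """A complete hermetic test fixture with machine-readable truth."""

    config: SimConfig
    locus: DiploidLocus
    evaluated: EvaluatedAssembly
    reads: list[SimRead]
    header: pysam.AlignmentHeader
    alignments: list[pysam.AlignedSegment]

    @property
    def assembly(self) -> ReferenceAssembly:
        return self.evaluated.reference()

    @property
    def loci(self) -> list[LocusInterval]:
        return self.evaluated.loci()

    @property
    def genes(self) -> list[GeneAnnotation]:
        return self.evaluated.genes


def make_fixture(
    config: SimConfig,
    defect: tuple | None = None,
    reads_from: str = "truth",
) -> Fixture:
    """Generate locus, inject an optional defect, simulate and align reads.

    ``defect`` is None, ("deletion", contig, start, end) or
    ("inversion", contig, start, end, gap_len).  ``reads_from="truth"``
    simulates reads from the true genome (defect fixtures);
    ``"assembly"`` simulates from the evaluated assembly itself (the
    error-free control).
    """
    locus = generate_diploid_locus(config)
    if defect is None:
        evaluated = clean_assembly(locus)
    elif defect[0] == "deletion":
        evaluated = inject_missing_segment(locus, *defect[1:4])
    elif defect[0] == "inversion":
        evaluated = inject_inversion_with_gap(locus, *defect[1:5])
    else:
        raise FormatError(f"unknown defect spec {defect!r}")

    if reads_from == "assembly":
        source = evaluated.contigs
        source_locus = DiploidLocus(
            config=config, haplotypes=dict(evaluated.contigs), genes=[]
        )
        reads = simulate_reads(source, config, seed=config.seed + 1)
        header, segments = oracle_align(
            reads, EvaluatedAssembly(contigs=dict(source), genes=[]), source_locus
        )
    else:
        reads = simulate_reads(locus.haplotypes, config, seed=config.seed + 1)
        header, segments = oracle_align(reads, evaluated, locus)
    return Fixture(config, locus, evaluated, reads, header, segments)


def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 80) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sorted(contigs):
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def write_fastq(reads: list[SimRead], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for r in reads:
            seq = r.sequenced
            fh.write(f"@{r.name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


def write_sam(
    header: pysam.AlignmentHeader,
    segments: list[pysam.AlignedSegment],
    path: str | Path,
) -> Path:
    path = Path(path)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for seg in segments:
            out.write(seg)
    return path


def to_indexed_bam(
    header: pysam.AlignmentHeader,
    segments: list[pysam.AlignedSegment],
    bam_path: str | Path,
) -> Path:
    """Write a coordinate-sorted, indexed BAM (segments must be pre-sorted)."""
    bam_path = Path(bam_path)
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as out:
        for seg in segments:
            out.write(seg)
    pysam.index(str(bam_path))
    return bam_path


def write_truth(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Serialize the truth set: defects BED, gene truth TSV, per-read origins."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    defects = pd.DataFrame([d.as_row() for d in fixture.evaluated.defects])
    if defects.empty:
        defects = pd.DataFrame(
            columns=[
                "kind", "contig", "start", "end", "gap_len",
                "homolog_contig", "homolog_start", "homolog_end",
            ]
        )
    paths["truth_defects"] = outdir / "truth_defects.tsv"
    defects.to_csv(paths["truth_defects"], sep="\t", index=False)
    genes = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id, "segment_type": g.segment_type,
                "contig": g.contig, "start": g.start, "end": g.end,
                "strand": g.strand,
            }
            for g in fixture.locus.genes
        ]
    )
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    origins = pd.DataFrame(
        [
            {
                "read": r.name, "contig": r.contig, "start": r.start,
                "end": r.end, "strand": r.strand, "n_errors": r.n_errors,
            }
            for r in fixture.reads
        ]
    )
    paths["truth_reads"] = outdir / "truth_reads.tsv"
    origins.to_csv(paths["truth_reads"], sep="\t", index=False)
    return paths
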