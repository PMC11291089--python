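"""Input/output layer: FASTA, BAM/SAM, BED/locus tables, mpileup, TSV reports.

Internal coordinates are 0-based half-open everywhere.  BED is consumed
natively; human-facing report tables and region strings use 1-based
inclusive coordinates, with the dialect noted in a header comment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

LOCUS_CLASSES = ("IGH", "IGK", "IGL")
_VALID = set("ACGTN")


class FormatError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ReferenceAssembly:
    """Assembly contigs with an index of N-runs (assembly gaps).

    ``n_runs[contig]`` is a sorted list of maximal 0-based half-open
    intervals whose bases are all ``N``.
    """

    contigs: dict[str, str]
    n_runs: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.n_runs:
            self.n_runs = {
                name: find_n_runs(seq) for name, seq in self.contigs.items()
            }

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def sequence(self, contig: str, start: int = 0, end: int | None = None) -> str:
        return self.contigs[contig][start:end]

    def n_runs_in(self, contig: str, start: int, end: int) -> list[tuple[int, int]]:
        """N-runs overlapping [start, end), clipped to it."""
        return [
            (max(s, start), min(e, end))
            for s, e in self.n_runs.get(contig, [])
            if s < end and e > start
        ]


@dataclass(frozen=True)
class LocusInterval:
    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    locus_class: str
    haplotype_label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.locus_class not in LOCUS_CLASSES:
            raise FormatError(
                f"unknown locus class {self.locus_class!r}; expected one of "
                f"{LOCUS_CLASSES}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def region_string(self) -> str:
        """1-based inclusive region string (samtools convention)."""
        return f"{self.contig}:{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    segment_type: str  # V, D or J
    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.segment_type not in ("V", "D", "J"):
            raise FormatError(
                f"gene {self.gene_id}: segment type must be V, D or J, "
                f"got {self.segment_type!r}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(f"gene {self.gene_id}: bad interval")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def find_n_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal 0-based half-open runs of N in ``seq`` (case-insensitive)."""
    return [(m.start(), m.end()) for m in re.finditer(r"[Nn]+", seq)]


def load_assembly(fasta_path: str | Path, ambiguous: str = "to_n") -> ReferenceAssembly:
    """Load a FASTA assembly, uppercasing and indexing N-runs.

    ``ambiguous`` controls non-ACGTN letters (IUPAC codes): ``"to_n"`` maps
    them to N, ``"reject"`` raises.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise FormatError(f"assembly FASTA not found: {path}")
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise FormatError(f"duplicate contig id {record.id!r} in {path}")
        seq = str(record.seq).upper()
        bad = set(seq) - _VALID
        if bad:
            if ambiguous == "reject":
                raise FormatError(
                    f"contig {record.id!r}: non-ACGTN characters {sorted(bad)}"
                )
            seq = re.sub(f"[{''.join(re.escape(c) for c in bad)}]", "N", seq)
        contigs[record.id] = seq
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return ReferenceAssembly(contigs=contigs)


# ---------------------------------------------------------------------------
# loci and genes
# ---------------------------------------------------------------------------


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse a 1-based inclusive region string into 0-based half-open coords."""
    m = re.fullmatch(r"(.+):([\d,]+)-([\d,]+)", region)
    if not m:
        raise FormatError(f"cannot parse region string {region!r}")
    contig = m.group(1)
    start1 = int(m.group(2).replace(",", ""))
    end1 = int(m.group(3).replace(",", ""))
    return contig, start1 - 1, end1


def _assign_haplotype(contig: str, patterns: dict[str, str]) -> str:
    for label, pat in patterns.items():
        if re.search(pat, contig):
            return label
    return ""


def load_loci(
    path: str | Path,
    assembly: ReferenceAssembly | None = None,
    dialect: str = "bed",
    haplotype_patterns: dict[str, str] | None = None,
) -> list[LocusInterval]:
    """Load locus intervals from BED4 or a contig/start/end/locus table.

    ``dialect="bed"`` reads 0-based half-open coordinates; ``"one-based"``
    reads 1-based inclusive and shifts internally.  A 5th column, when
    present, is the haplotype label; otherwise labels come from
    ``haplotype_patterns`` (label -> contig-name regex).
    """
    loci: list[LocusInterval] = []
    patterns = haplotype_patterns or {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 columns")
            contig, start, end, label = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if dialect == "one-based":
                start -= 1
            elif dialect != "bed":
                raise FormatError(f"unknown coordinate dialect {dialect!r}")
            hap = fields[4] if len(fields) > 4 else _assign_haplotype(contig, patterns)
            locus = LocusInterval(contig, start, end, label.upper(), hap)
            if assembly is not None:
                if contig not in assembly.contigs:
                    raise FormatError(
                        f"{path}:{lineno}: contig {contig!r} not in assembly"
                    )
                if end > len(assembly.contigs[contig]):
                    raise FormatError(
                        f"{path}:{lineno}: interval end {end} exceeds contig "
                        f"length {len(assembly.contigs[contig])}"
                    )
            loci.append(locus)
    return loci


def load_genes(
    path: str | Path,
    loci: list[LocusInterval] | None = None,
) -> list[GeneAnnotation]:
    """Load gene annotations from a TSV:
    gene_id, segment_type, contig, start, end, strand (BED-style coords)."""
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            gene = GeneAnnotation(f[0], f[1], f[2], int(f[3]), int(f[4]), f[5])
            if loci is not None and not any(
                g.contig == gene.contig and g.start <= gene.start and gene.end <= g.end
                for g in loci
            ):
                raise FormatError(
                    f"{path}:{lineno}: gene {gene.gene_id} outside every locus"
                )
            genes.append(gene)
    return genes


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def stream_alignments(
    source: str | Path | Iterable[pysam.AlignedSegment],
    locus: LocusInterval,
    include_supplementary: bool = False,
) -> Iterator[pysam.AlignedSegment]:
    """Yield mapped primary alignments overlapping ``locus``.

    ``source`` is a coordinate-sorted, indexed BAM path, or any iterable of
    pysam records (pre-fetched or in-memory).  Secondary alignments are
    always excluded; supplementary alignments are excluded from the pileup
    path by default (they contribute to clip statistics elsewhere).
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise FormatError(f"alignment file not found: {path}")
        af = pysam.AlignmentFile(str(path))
        if not af.has_index():
            raise FormatError(
                f"{path} has no index; sort and index it "
                "(samtools sort / samtools index) before evaluation"
            )
        records: Iterable[pysam.AlignedSegment] = af.fetch(
            locus.contig, locus.start, locus.end
        )
    else:
        records = (
            r
            for r in source
            if not r.is_unmapped
            and r.reference_name == locus.contig
            and r.reference_start < locus.end
            and r.reference_end is not None
            and r.reference_end > locus.start
        )
    for rec in records:
        if rec.is_unmapped or rec.is_secondary:
            continue
        if rec.is_supplementary and not include_supplementary:
            continue
        yield rec


# ---------------------------------------------------------------------------
# mpileup ingestion (basepair-oriented path only)
# ---------------------------------------------------------------------------

_INDEL_RE = re.compile(r"[+-](\d+)")


def parse_mpileup_bases(bases: str) -> tuple[int, int, int]:
    """Count (matches, mismatches, deletions) in one mpileup base column.

    Handles ``^X`` read starts, ``$`` ends, ``+N.../−N...`` indel insertions
    and ``*`` deletion placeholders per the samtools text format.
    """
    match = mismatch = deleted = 0
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret + mapq char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            m = _INDEL_RE.match(bases, i)
            if not m:
                raise FormatError(f"bad indel encoding in mpileup column: {bases!r}")
            i = m.end() + int(m.group(1))
            continue
        if c in ".,":
            match += 1
        elif c in "ACGTNacgtn":
            mismatch += 1
        elif c in "*#":
            deleted += 1
        elif c in "<>":
            pass  # reference skip
        else:
            raise FormatError(f"unexpected mpileup base character {c!r}")
        i += 1
    return match, mismatch, deleted


def load_mpileup(path: str | Path) -> pd.DataFrame:
    """Parse a samtools mpileup text stream into per-position counts.

    Returns a DataFrame with columns contig, pos (0-based), depth, delta
    (mismatching reads) and deleted.  Only the basepair-oriented metrics can
    be derived from mpileup — it carries no per-read identity, so the
    read-oriented counts require the alignment records themselves.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                continue
            contig, pos1, _ref, depth, bases = f[0], int(f[1]), f[2], int(f[3]), f[4]
            match, mism, deleted = parse_mpileup_bases(bases)
            if match + mism + deleted != depth:
                raise FormatError(
                    f"{path}: depth {depth} at {contig}:{pos1} disagrees with "
                    f"base column ({match}+{mism}+{deleted})"
                )
            rows.append((contig, pos1 - 1, depth, mism, deleted))
    return pd.DataFrame(
        rows, columns=["contig", "pos", "depth", "delta", "deleted"]
    )


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    header_comments: Iterable[str] = (),
) -> Path:
    """Write a TSV with '#'-prefixed header comments. Deterministic output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(line if line.startswith("#") else f"# {line}")
            fh.write("\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
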