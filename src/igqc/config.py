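"""Run-level configuration: the thresholds that define every quality call.

All defaults follow the read-support model the package implements:

* ``theta`` — per-read mismatch-rate threshold above which a read is
  "poorly aligned" (strict ``>``).  Default 0.01, i.e. 1%: HiFi reads have
  <0.5% sequencing error, so a read mismatching at >1% is evidence that the
  assembly, not the sequencer, is wrong.
* ``min_bad_reads`` — a position is "poorly supported" when the count of
  covering poorly-aligned reads exceeds this (strict ``>``).  Default 5.
* ``break_threshold`` — a position belongs to a coverage break when its
  depth is at or below this.  Default 2 reads.
* ``support_min`` — per-position base-support fraction a gene must exceed
  (strict ``>``) at every covered position to count as perfectly supported.
  Default 0.8.
* ``gene_poor_read_max`` — a gene is read-affected when more than this many
  poorly aligned reads overlap it (strict ``>``).  Default 5.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class Thresholds:
    theta: float = 0.01
    min_bad_reads: int = 5
    break_threshold: int = 2
    support_min: float = 0.8
    gene_poor_read_max: int = 5
    indel_min_len: int = 2
    end_margin: int = 5_000
    min_break_len: int = 1
    #: minimum break length (bp) that raises the locus-level break flag
    call_min_break_len: int = 10
    #: locus mismatch call: >=1 merged flagged interval at least this long ...
    call_min_flag_interval: int = 100
    #: ... or flagged fraction of the locus at least this
    call_min_flag_fraction: float = 0.005
    mapq_min: int = 0
    #: columns with depth > factor * median locus depth are annotated "elevated"
    coverage_high_factor: float = 2.0
    #: denominator for e_r: "aligned" (M/=/X bases) or "full" (whole read)
    mismatch_denominator: str = "aligned"

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def header_lines(self) -> list[str]:
        """'#'-comment lines echoing every threshold, for output tables."""
        return [f"# {k}={v}" for k, v in sorted(self.as_dict().items())]


@dataclass
class RunConfig:
    """Paths + thresholds + reproducibility knobs for one evaluation run."""

    assembly: Path
    alignments: Path
    loci: Path
    genes: Path | None = None
    outdir: Path = Path("igqc_out")
    species: str = "sample"
    haplotype_resolution: str = "resolved"
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    make_plots: bool = True
    plot_format: str = "png"
    #: map of haplotype label -> regex matched against contig names
    haplotype_patterns: dict[str, str] = field(default_factory=dict)
    #: coordinate dialect of the loci table: "bed" (0-based half-open)
    #: or "one-based" (1-based inclusive)
    loci_dialect: str = "bed"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        for key in ("assembly", "alignments", "loci", "genes", "outdir"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(thresholds=thr, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {**{k: str(v) for k, v in dataclasses.asdict(self).items()}},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
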