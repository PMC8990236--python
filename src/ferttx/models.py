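"""Core coordinate-frame types shared by every pipeline stage.

Genomic coordinates are 1-based inclusive throughout the package; the only
exception is BED12 serialization (0-based half-open), which is handled in
:mod:`ferttx.io` so no other module performs coordinate arithmetic across
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Tuple

Strand = Literal["+", "-"]

#: Region labels assigned to SNP positions relative to a gene model.
REGION_LABELS = ("five_prime_utr", "cds", "three_prime_utr", "intron", "intergenic")

#: Zygosity labels for called loci.
ZYGOSITY_LABELS = ("het", "hom_ref", "hom_alt", "uncallable")


def _check_exons(exons: Tuple[Tuple[int, int], ...]) -> None:
    if not exons:
        raise ValueError("at least one exon is required")
    prev_stop = None
    for start, stop in exons:
        if start > stop:
            raise ValueError(f"exon start {start} > stop {stop}")
        if start < 1:
            raise ValueError(f"exon start {start} < 1 (coordinates are 1-based)")
        if prev_stop is not None and start <= prev_stop + 1:
            raise ValueError("exons must be sorted and non-overlapping with gaps >= 1 bp")
        prev_stop = stop


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware exon chain with CDS boundaries.

    ``cds_start``/``cds_end`` are genomic coordinates of the coding span
    (``cds_start <= cds_end`` regardless of strand). The 5'-most coding base
    in transcription direction is ``five_prime_pos``.
    """

    gene_id: str
    chrom: str
    strand: Strand
    exons: Tuple[Tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))
        _check_exons(self.exons)
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.cds_start > self.cds_end:
            raise ValueError("cds_start must be <= cds_end")
        span_start, span_end = self.span
        if self.cds_start < span_start or self.cds_end > span_end:
            raise ValueError("CDS span must lie within the exon span")

    @property
    def span(self) -> Tuple[int, int]:
        """Genomic span from first exon start to last exon end."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def five_prime_pos(self) -> int:
        """Genomic position of the 5'-most coding base (strand-aware)."""
        return self.cds_start if self.strand == "+" else self.cds_end

    @property
    def transcript_start(self) -> int:
        """5' transcript boundary in transcription direction."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def transcript_end(self) -> int:
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]

    @property
    def cds_len(self) -> int:
        """Number of exonic bases inside the CDS span."""
        total = 0
        for start, stop in self.exons:
            lo = max(start, self.cds_start)
            hi = min(stop, self.cds_end)
            if lo <= hi:
                total += hi - lo + 1
        return total

    def contains(self, pos: int) -> bool:
        span_start, span_end = self.span
        return span_start <= pos <= span_end

    def is_exonic(self, pos: int) -> bool:
        return any(start <= pos <= stop for start, stop in self.exons)


@dataclass(frozen=True)
class AlleleCountRecord:
    """Biallelic read counts at one locus from one source.

    ``source`` identifies the animal; ``tissue`` is None for WGS records.
    ``allele_a`` is the reference allele by convention.
    """

    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    count_a: int
    count_b: int
    source: str
    tissue: Optional[str] = None

    def __post_init__(self) -> None:
        if self.count_a < 0 or self.count_b < 0:
            raise ValueError(
                f"negative allele counts at {self.chrom}:{self.pos}: "
                f"({self.count_a}, {self.count_b})"
            )

    @property
    def total(self) -> int:
        return self.count_a + self.count_b


@dataclass(frozen=True)
class SnpLocus:
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    zygosity: str = "uncallable"
    region: Optional[str] = None

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITY_LABELS:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.region is not None and self.region not in REGION_LABELS:
            raise ValueError(f"unknown region {self.region!r}")


@dataclass(frozen=True)
class CagePeak:
    """Strand-aware CAGE tag cluster.

    ``start`` is the cluster boundary nearer the gene 5' position measured in
    the upstream direction; ``stop`` is the farther boundary. Either may be
    numerically below the other on either strand.
    """

    chrom: str
    strand: Strand
    start: int
    stop: int
    mode_pos: int
    tag_count: int

    def __post_init__(self) -> None:
        if self.tag_count <= 0:
            raise ValueError("tag_count must be positive")
        lo, hi = min(self.start, self.stop), max(self.start, self.stop)
        if not lo <= self.mode_pos <= hi:
            raise ValueError("mode_pos must lie between the cluster boundaries")


@dataclass(frozen=True)
class IsoformChain:
    """Exon chain of one isoform; junctions (introns) are derived."""

    isoform_id: str
    gene_id: str
    chrom: str
    strand: Strand
    exons: Tuple[Tuple[int, int], ...]
    source: str = "long_read"
    tissues: Tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))
        object.__setattr__(self, "tissues", tuple(self.tissues))
        _check_exons(self.exons)

    @property
    def junctions(self) -> Tuple[Tuple[int, int], ...]:
        """Introns as 1-based inclusive intervals; empty for single-exon chains."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]
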