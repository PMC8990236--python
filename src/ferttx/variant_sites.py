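"""Heterozygous-site calling, SNP region classification, and the
haplotype-level divergence/homology statistic.

A locus is called heterozygous when both alleles are observed in at least
``min_reads_per_allele`` reads (default 2). Divergence is computed from
genome-wide counts of homozygous-alternative (Ho) and heterozygous (He) loci
as ``D = (Ho + He/2) / genome_size`` with homology ``100 * (1 - D)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple, Union

import pandas as pd

from .models import AlleleCountRecord, CagePeak, GeneModel, SnpLocus

DEFAULT_GENOME_SIZE = 2_700_000_000
DEFAULT_MIN_READS_PER_ALLELE = 2


@dataclass(frozen=True)
class DivergenceResult:
    ho_count: int
    he_count: int
    genome_size: int
    divergence: float

    @property
    def homology_pct(self) -> float:
        return 100.0 * (1.0 - self.divergence)

    @property
    def homology_pct_rounded(self) -> float:
        """Homology as reported: three decimal places."""
        return round(self.homology_pct, 3)


def call_zygosity(
    record: AlleleCountRecord,
    min_reads_per_allele: int = DEFAULT_MIN_READS_PER_ALLELE,
) -> str:
    """Zygosity label for one allele-count record.

    het iff both allele counts reach ``min_reads_per_allele``; otherwise the
    majority allele determines a homozygous call (allele A is the reference).
    Zero-total loci — and exact nonzero ties below the het threshold, which
    carry no majority signal — are uncallable.
    """
    a, b = record.count_a, record.count_b
    if a < 0 or b < 0:
        raise ValueError("allele counts must be non-negative")
    if a >= min_reads_per_allele and b >= min_reads_per_allele:
        return "het"
    if a + b == 0 or a == b:
        return "uncallable"
    return "hom_ref" if a > b else "hom_alt"


def call_snp_locus(
    record: AlleleCountRecord,
    min_reads_per_allele: int = DEFAULT_MIN_READS_PER_ALLELE,
) -> SnpLocus:
    return SnpLocus(
        chrom=record.chrom, pos=record.pos,
        allele_a=record.allele_a, allele_b=record.allele_b,
        zygosity=call_zygosity(record, min_reads_per_allele),
    )


def classify_snp_region(
    snp: Union[SnpLocus, int],
    gene: GeneModel,
    tss: Optional[Union[CagePeak, int]] = None,
) -> str:
    """Region label of a SNP relative to one gene model (strand-aware).

    Without a CAGE peak the 5' transcript boundary is the annotated first
    exon edge; with a peak the peak-derived TSS bounds the 5'UTR, so
    positions between the peak TSS and the annotated transcript start are
    5'UTR rather than intergenic.
    """
    if isinstance(snp, SnpLocus):
        if snp.chrom != gene.chrom:
            raise ValueError(
                f"SNP chrom {snp.chrom!r} does not match gene chrom {gene.chrom!r}"
            )
        pos = snp.pos
    else:
        pos = int(snp)

    tss_pos: Optional[int] = None
    if tss is not None:
        tss_pos = tss.stop if isinstance(tss, CagePeak) else int(tss)

    span_start, span_end = gene.span
    exonic = gene.is_exonic(pos)

    if gene.strand == "+":
        in_upstream_ext = (
            tss_pos is not None and tss_pos < span_start and tss_pos <= pos < span_start
        )
        if exonic or in_upstream_ext:
            if pos < gene.cds_start:
                return "five_prime_utr"
            if pos <= gene.cds_end:
                return "cds"
            return "three_prime_utr"
        if span_start <= pos <= span_end:
            return "intron"
        return "intergenic"

    in_upstream_ext = (
        tss_pos is not None and tss_pos > span_end and span_end < pos <= tss_pos
    )
    if exonic or in_upstream_ext:
        if pos > gene.cds_end:
            return "five_prime_utr"
        if pos >= gene.cds_start:
            return "cds"
        return "three_prime_utr"
    if span_start <= pos <= span_end:
        return "intron"
    return "intergenic"


def divergence(
    ho_count: int,
    he_count: int,
    genome_size: int = DEFAULT_GENOME_SIZE,
) -> DivergenceResult:
    """Haplotype-level divergence ``D = (Ho + He/2) / genome_size``."""
    if ho_count < 0 or he_count < 0:
        raise ValueError("Ho and He counts must be non-negative")
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    d = (ho_count + he_count / 2.0) / genome_size
    return DivergenceResult(
        ho_count=ho_count, he_count=he_count, genome_size=genome_size, divergence=d,
    )


def tally_zygosity(loci: Iterable[SnpLocus]) -> Tuple[int, int]:
    """Count (Ho, He) over called loci; uncallable/hom_ref loci are ignored."""
    ho = he = 0
    for locus in loci:
        if locus.zygosity == "hom_alt":
            ho += 1
        elif locus.zygosity == "het":
            he += 1
    return ho, he


def snp_table(
    records: Iterable[AlleleCountRecord],
    genes: Iterable[GeneModel],
    min_reads_per_allele: int = DEFAULT_MIN_READS_PER_ALLELE,
) -> pd.DataFrame:
    """Call zygosity for every record and attach a region label.

    The region is taken from the gene whose span covers the locus (the first
    covering gene in input order); loci outside every gene are intergenic.
    """
    gene_list: List[GeneModel] = list(genes)
    rows = []
    for record in records:
        locus = call_snp_locus(record, min_reads_per_allele)
        region = "intergenic"
        for gene in gene_list:
            if gene.chrom == record.chrom and gene.contains(record.pos):
                region = classify_snp_region(locus, gene)
                break
        rows.append(
            {
                "chrom": record.chrom, "pos": record.pos,
                "allele_a": record.allele_a, "allele_b": record.allele_b,
                "count_a": record.count_a, "count_b": record.count_b,
                "source": record.source, "zygosity": locus.zygosity, "region": region,
            }
        )
    return pd.DataFrame(rows)


def divergence_report(
    snp_frame: pd.DataFrame,
    genome_size: int = DEFAULT_GENOME_SIZE,
) -> pd.DataFrame:
    """Per-source Ho/He tallies with divergence and 3-decimal homology."""
    rows = []
    for source, group in snp_frame.groupby("source", sort=True):
        ho = int((group["zygosity"] == "hom_alt").sum())
        he = int((group["zygosity"] == "het").sum())
        result = divergence(ho, he, genome_size)
        rows.append(
            {
                "source": source, "ho_count": ho, "he_count": he,
                "divergence": result.divergence,
                "homology_pct": result.homology_pct_rounded,
            }
        )
    return pd.DataFrame(rows)
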