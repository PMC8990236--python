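"""Seeded synthetic-data generator with a machine-readable truth record.

Emits an annotation, WGS/RNA allele-count tables, CAGE tag coverage, and
long-read isoform chains with planted variants, so that every downstream
stage can be scored without external data. All randomness flows from the
config seed through per-stage ``numpy`` generators; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from . import io as ftio
from .errors import ConfigError, PlacementError
from .models import AlleleCountRecord, GeneModel, IsoformChain

TECHNOLOGIES = ("rna_seq", "cage_seq", "iso_seq")
DEFAULT_LIBRARY_SIZES = {"rna_seq": 1_000_000, "cage_seq": 200_000, "iso_seq": 20_000}

# per-stage RNG stream ids, combined with the config seed
_STAGE_ANNOTATION = 0
_STAGE_WGS = 1
_STAGE_RNA = 2
_STAGE_CAGE = 3
_STAGE_ISO = 4

_BASES = ("A", "C", "G", "T")


class PlantedIsoform(BaseModel):
    """One planted long-read isoform for a gene."""

    gene: str
    category: str  # known | novel_junction | intron_retention | novel_terminal
    retained_introns: Tuple[int, ...] = ()  # 1-based, for intron_retention
    junction_index: int = 1  # 1-based intron index, for novel_junction
    junction_shift: int = 12  # bp moved at the donor side
    terminal_end: str = "5p"  # "5p" | "3p" in transcription direction
    terminal_delta: int = 600  # bp the terminal boundary moves outward
    supported: bool = True  # short-read junction corroboration
    isoform_id: Optional[str] = None
    tissues: Tuple[str, ...] = ()

    @field_validator("category")
    @classmethod
    def _check_category(cls, v: str) -> str:
        allowed = {"known", "novel_junction", "intron_retention", "novel_terminal"}
        if v not in allowed:
            raise ValueError(f"category must be one of {sorted(allowed)}")
        return v


class NestedExonSpec(BaseModel):
    """Request a guest gene with one exon nested inside a host gene span."""

    host_gene: str
    guest_gene: str = "guest"
    exon_offset: int = 50  # nested exon start, relative to host span start
    exon_length: int = 80
    opposite_strand: bool = True


class SyntheticConfig(BaseModel):
    n_genes: int = 5
    chrom: str = "chr1"
    chrom_length: int = 1_000_000
    strand_mix: float = 0.5  # fraction of minus-strand genes
    exons_per_gene: Tuple[int, int] = (2, 5)
    exon_length: Tuple[int, int] = (150, 400)
    intron_length: Tuple[int, int] = (80, 300)
    intergenic_gap: Tuple[int, int] = (500, 2000)
    snp_density: float = 1.0  # SNPs per kbp of gene span
    het_fraction: float = 0.6  # het share among planted SNPs
    wgs_depth_mean: float = 40.0
    rna_depth_mean: float = 60.0
    reference_bias: float = 0.5  # expected reference-allele share in WGS
    error_rate: float = 0.0  # per-read error alleles at hom loci (off)
    animal: str = "cow"
    tissues: Tuple[str, ...] = ("liver", "lung")
    ase_effects: Dict[int, Dict[str, float]] = Field(default_factory=dict)
    tss_offsets: Dict[str, int] = Field(default_factory=dict)
    tss_offset_default: int = 100
    cage_peak_width: int = 5  # kernel half-width; 0 = spike
    cage_tags_per_gene: int = 200
    cage_noise: float = 0.0  # Poisson background mean per promoter bp
    unexpressed_genes: Tuple[str, ...] = ()
    dominant_genes: Dict[str, str] = Field(default_factory=dict)  # tissue -> gene
    planted_isoforms: Tuple[PlantedIsoform, ...] = ()
    nested_exon_spec: Optional[NestedExonSpec] = None
    library_sizes: Dict[str, Dict[str, int]] = Field(default_factory=dict)
    junction_read_depth: int = 20
    seed: int

    @field_validator("strand_mix", "reference_bias", "het_fraction", "error_rate")
    @classmethod
    def _check_fraction(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
        return v

    @field_validator("chrom_length", "wgs_depth_mean", "rna_depth_mean",
                     "cage_tags_per_gene", "n_genes")
    @classmethod
    def _check_positive(cls, v):
        if v <= 0:
            raise ValueError("depths, lengths and counts must be positive")
        return v

    @model_validator(mode="after")
    def _check_effects(self) -> "SyntheticConfig":
        for idx, per_tissue in self.ase_effects.items():
            if idx < 0:
                raise ValueError("ase_effects locus indices must be non-negative")
            for tissue, f in per_tissue.items():
                if tissue not in self.tissues:
                    raise ValueError(f"ase_effects references unknown tissue {tissue!r}")
                if not 0.0 <= f <= 1.0:
                    raise ValueError("planted allele fractions must lie in [0, 1]")
        return self

    def library_size(self, tissue: str, technology: str) -> int:
        return int(
            self.library_sizes.get(tissue, {}).get(
                technology, DEFAULT_LIBRARY_SIZES[technology]
            )
        )


@dataclass
class SyntheticTruth:
    """Planted truth; sufficient to score every downstream stage."""

    snp_loci: List[dict] = field(default_factory=list)  # all planted SNPs
    het_loci: List[dict] = field(default_factory=list)  # het subset, index order
    ase_effects: Dict[int, Dict[str, float]] = field(default_factory=dict)
    true_tss: Dict[str, int] = field(default_factory=dict)
    true_utr_lengths: Dict[str, int] = field(default_factory=dict)
    expression_weights: Dict[str, Dict[str, float]] = field(default_factory=dict)
    isoform_categories: Dict[str, str] = field(default_factory=dict)
    retained_introns: Dict[str, List[int]] = field(default_factory=dict)
    nested_hits: List[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "snp_loci": self.snp_loci,
            "het_loci": self.het_loci,
            "ase_effects": {
                str(k): dict(v) for k, v in self.ase_effects.items()
            },
            "true_tss": self.true_tss,
            "true_utr_lengths": self.true_utr_lengths,
            "expression_weights": self.expression_weights,
            "isoform_categories": self.isoform_categories,
            "retained_introns": self.retained_introns,
            "nested_hits": self.nested_hits,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticTruth":
        return cls(
            snp_loci=data["snp_loci"],
            het_loci=data["het_loci"],
            ase_effects={int(k): v for k, v in data["ase_effects"].items()},
            true_tss=data["true_tss"],
            true_utr_lengths=data["true_utr_lengths"],
            expression_weights=data["expression_weights"],
            isoform_categories=data["isoform_categories"],
            retained_introns=data["retained_introns"],
            nested_hits=data["nested_hits"],
        )


def _rng(config: SyntheticConfig, stage: int, seed: Optional[int] = None) -> np.random.Generator:
    return np.random.default_rng([seed if seed is not None else config.seed, stage])


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SyntheticConfig) -> Tuple[List[GeneModel], SyntheticTruth]:
    """Place non-overlapping genes (plus the requested nested pair) and
    plant SNP and TSS truth."""
    rng = _rng(config, _STAGE_ANNOTATION)
    truth = SyntheticTruth(ase_effects={k: dict(v) for k, v in config.ase_effects.items()})
    genes: List[GeneModel] = []

    gene_ids = [f"g{i}" for i in range(1, config.n_genes + 1)]
    known_ids = set(gene_ids)
    if config.nested_exon_spec is not None:
        known_ids.add(config.nested_exon_spec.guest_gene)
    for gid in config.tss_offsets:
        if gid not in known_ids:
            raise ConfigError(f"tss_offsets references unknown gene {gid!r}")

    cursor = 1 + int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
    for gid in gene_ids:
        strand = "-" if rng.random() < config.strand_mix else "+"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        utr = int(config.tss_offsets.get(gid, config.tss_offset_default))
        exon_lens = rng.integers(
            config.exon_length[0], config.exon_length[1] + 1, size=n_ex
        ).tolist()
        intron_lens = rng.integers(
            config.intron_length[0], config.intron_length[1] + 1, size=max(n_ex - 1, 0)
        ).tolist()
        # the 5'-terminal exon must hold the planted UTR plus a CDS margin
        if strand == "+":
            exon_lens[0] = max(exon_lens[0], utr + 40)
        else:
            exon_lens[-1] = max(exon_lens[-1], utr + 40)

        exons = []
        pos = cursor
        for i, length in enumerate(exon_lens):
            exons.append((pos, pos + int(length) - 1))
            pos = exons[-1][1] + 1
            if i < len(intron_lens):
                pos += int(intron_lens[i])
        span_end = exons[-1][1]
        if span_end + config.intergenic_gap[0] > config.chrom_length:
            raise PlacementError(
                f"cannot place gene {gid}: span end {span_end} exceeds "
                f"chrom_length {config.chrom_length}"
            )
        if strand == "+":
            cds_start = exons[0][0] + utr
            cds_end = exons[-1][1] - min(20, exon_lens[-1] - 1)
        else:
            cds_end = exons[-1][1] - utr
            cds_start = exons[0][0] + min(20, exon_lens[0] - 1)
        if cds_start > cds_end:
            raise PlacementError(f"gene {gid}: planted UTR {utr} leaves no CDS room")
        gene = GeneModel(
            gene_id=gid, chrom=config.chrom, strand=strand,
            exons=tuple(exons), cds_start=cds_start, cds_end=cds_end,
        )
        genes.append(gene)
        truth.true_tss[gid] = gene.five_prime_pos - utr if strand == "+" else gene.five_prime_pos + utr
        truth.true_utr_lengths[gid] = utr
        cursor = span_end + 1 + int(
            rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1)
        )

    if config.nested_exon_spec is not None:
        genes.append(_place_guest(config, genes, truth))

    _plant_snps(config, genes, truth, rng)
    return genes, truth


def _place_guest(
    config: SyntheticConfig, genes: List[GeneModel], truth: SyntheticTruth
) -> GeneModel:
    spec = config.nested_exon_spec
    hosts = [g for g in genes if g.gene_id == spec.host_gene]
    if not hosts:
        raise ConfigError(f"nested_exon_spec host gene {spec.host_gene!r} does not exist")
    host = hosts[0]
    host_start, host_end = host.span
    nested_exon = (
        host_start + spec.exon_offset,
        host_start + spec.exon_offset + spec.exon_length - 1,
    )
    if nested_exon[1] > host_end:
        raise ConfigError("nested exon does not fit inside the host gene span")
    outer_exon = (host_start - 300, host_start - 181)
    if outer_exon[0] < 1:
        raise ConfigError("no room upstream of the host gene for the guest gene")
    for other in genes:
        if other.gene_id != host.gene_id and not (
            other.span[1] < outer_exon[0] or other.span[0] > nested_exon[1]
        ):
            raise ConfigError(
                f"guest gene would overlap {other.gene_id}; increase intergenic gaps"
            )
    strand = ("-" if host.strand == "+" else "+") if spec.opposite_strand else host.strand
    utr = int(config.tss_offsets.get(spec.guest_gene, config.tss_offset_default))
    guest = GeneModel(
        gene_id=spec.guest_gene, chrom=config.chrom, strand=strand,
        exons=(outer_exon, nested_exon),
        cds_start=outer_exon[0] + 10, cds_end=nested_exon[1] - 10,
    )
    truth.true_tss[spec.guest_gene] = (
        guest.five_prime_pos - utr if strand == "+" else guest.five_prime_pos + utr
    )
    truth.true_utr_lengths[spec.guest_gene] = utr
    truth.nested_hits.append(
        {
            "guest_gene": spec.guest_gene, "host_gene": spec.host_gene,
            "exon": list(nested_exon),
            "strand_relation": "opposite" if strand != host.strand else "same",
        }
    )
    return guest


def _plant_snps(
    config: SyntheticConfig,
    genes: List[GeneModel],
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> None:
    for gene in genes:
        span_start, span_end = gene.span
        span_len = span_end - span_start + 1
        n_snps = int(round(span_len / 1000.0 * config.snp_density))
        if n_snps <= 0:
            continue
        positions = np.sort(
            rng.choice(np.arange(span_start, span_end + 1), size=n_snps, replace=False)
        )
        for pos in positions:
            a_idx = int(rng.integers(0, 4))
            b_idx = (a_idx + int(rng.integers(1, 4))) % 4
            zyg = "het" if rng.random() < config.het_fraction else "hom_alt"
            record = {
                "chrom": config.chrom, "pos": int(pos),
                "allele_a": _BASES[a_idx], "allele_b": _BASES[b_idx],
                "zygosity": zyg, "gene": gene.gene_id,
            }
            truth.snp_loci.append(record)
            if zyg == "het":
                truth.het_loci.append(record)


# ---------------------------------------------------------------------------
# WGS allele counts
# ---------------------------------------------------------------------------

def generate_wgs_counts(
    truth: SyntheticTruth, config: SyntheticConfig, seed: Optional[int] = None
) -> List[AlleleCountRecord]:
    """Binomial allele counts at every planted SNP.

    Het loci draw the reference allele with probability ``reference_bias``;
    homozygous loci are monoallelic unless the error model is on.
    """
    rng = _rng(config, _STAGE_WGS, seed)
    records = []
    for locus in truth.snp_loci:
        depth = int(rng.poisson(config.wgs_depth_mean))
        if locus["zygosity"] == "het":
            count_a = int(rng.binomial(depth, config.reference_bias)) if depth else 0
            count_b = depth - count_a
        else:  # hom_alt
            count_a = int(rng.binomial(depth, config.error_rate)) if config.error_rate > 0 and depth else 0
            count_b = depth - count_a
        records.append(
            AlleleCountRecord(
                chrom=locus["chrom"], pos=locus["pos"],
                allele_a=locus["allele_a"], allele_b=locus["allele_b"],
                count_a=count_a, count_b=count_b, source=config.animal,
            )
        )
    return records


# ---------------------------------------------------------------------------
# RNA allele counts and per-gene totals
# ---------------------------------------------------------------------------

def generate_rnaseq_counts(
    annotation: List[GeneModel],
    truth: SyntheticTruth,
    config: SyntheticConfig,
    seed: Optional[int] = None,
) -> Tuple[List[AlleleCountRecord], pd.DataFrame]:
    """Per-tissue RNA allele counts plus the gene_totals table.

    Het loci with a planted effect in a tissue draw allele A with the
    planted fraction; all other het loci follow the WGS bias fraction.
    Per-gene totals are multinomial over planted expression weights, so
    they sum exactly to the configured library size.
    """
    rng = _rng(config, _STAGE_RNA, seed)
    n_het = len(truth.het_loci)
    for idx, per_tissue in truth.ase_effects.items():
        if idx >= n_het:
            raise ConfigError(
                f"ase_effects locus index {idx} is not a planted het locus "
                f"(only {n_het} het loci exist)"
            )
        for tissue in per_tissue:
            if tissue not in config.tissues:
                raise ConfigError(f"ase_effects references unknown tissue {tissue!r}")

    records = []
    for tissue in config.tissues:
        for idx, locus in enumerate(truth.het_loci):
            f = truth.ase_effects.get(idx, {}).get(tissue, config.reference_bias)
            depth = int(rng.poisson(config.rna_depth_mean))
            count_a = int(rng.binomial(depth, f)) if depth else 0
            records.append(
                AlleleCountRecord(
                    chrom=locus["chrom"], pos=locus["pos"],
                    allele_a=locus["allele_a"], allele_b=locus["allele_b"],
                    count_a=count_a, count_b=depth - count_a,
                    source=config.animal, tissue=tissue,
                )
            )

    gene_ids = [g.gene_id for g in annotation]
    rows = []
    for tissue in config.tissues:
        weights = rng.dirichlet(np.ones(len(gene_ids)))
        weights = np.asarray(weights, dtype=float)
        for i, gid in enumerate(gene_ids):
            if gid in config.unexpressed_genes:
                weights[i] = 0.0
        dominant = config.dominant_genes.get(tissue)
        if dominant is not None:
            if dominant not in gene_ids:
                raise ConfigError(f"dominant gene {dominant!r} is not in the annotation")
            weights = weights / weights.sum() * 0.4
            weights[gene_ids.index(dominant)] = 0.6
        weights = weights / weights.sum()
        truth.expression_weights[tissue] = {
            gid: float(w) for gid, w in zip(gene_ids, weights)
        }
        for technology in TECHNOLOGIES:
            total = config.library_size(tissue, technology)
            counts = rng.multinomial(total, weights)
            for gid, count in zip(gene_ids, counts):
                rows.append(
                    {
                        "gene_id": gid, "tissue": tissue, "technology": technology,
                        "mapped_reads": int(count), "library_total": total,
                    }
                )
    gene_totals = pd.DataFrame(rows, columns=ftio.GENE_TOTAL_COLUMNS)
    return records, gene_totals


# ---------------------------------------------------------------------------
# CAGE coverage
# ---------------------------------------------------------------------------

def generate_cage_coverage(
    annotation: List[GeneModel],
    truth: SyntheticTruth,
    config: SyntheticConfig,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Unimodal tag clusters (discretized triangular kernel) at planted TSSs.

    Width 0 collapses to a single-position spike. Unexpressed genes get no
    tags. Optional Poisson background over each promoter window.
    """
    rng = _rng(config, _STAGE_CAGE, seed)
    width = config.cage_peak_width
    coverage: Dict[Tuple[str, str, int], int] = {}

    def add(strand: str, pos: int, tags: int) -> None:
        if tags <= 0 or pos < 1 or pos > config.chrom_length:
            return
        key = (config.chrom, strand, pos)
        coverage[key] = coverage.get(key, 0) + tags

    for gene in annotation:
        if gene.gene_id in config.unexpressed_genes:
            continue
        center = truth.true_tss[gene.gene_id]
        if width == 0:
            add(gene.strand, center, config.cage_tags_per_gene)
        else:
            unit = max(1, config.cage_tags_per_gene // (width + 1) ** 2)
            for d in range(-width, width + 1):
                add(gene.strand, center + d, (width + 1 - abs(d)) * unit)
        if config.cage_noise > 0:
            lo = center - (5 * width + 50)
            hi = center + (5 * width + 50)
            noise = rng.poisson(config.cage_noise, size=hi - lo + 1)
            for offset, tags in enumerate(noise):
                add(gene.strand, lo + offset, int(tags))

    rows = [
        {"chrom": chrom, "pos": pos, "strand": strand, "tag_count": tags}
        for (chrom, strand, pos), tags in sorted(coverage.items())
    ]
    return pd.DataFrame(rows, columns=ftio.CAGE_COLUMNS)


# ---------------------------------------------------------------------------
# Isoform chains
# ---------------------------------------------------------------------------

def _build_planted_chain(
    planted: PlantedIsoform, gene: GeneModel, config: SyntheticConfig, isoform_id: str
) -> IsoformChain:
    exons = list(gene.exons)
    n_introns = len(exons) - 1

    if planted.category == "known":
        pass
    elif planted.category == "novel_junction":
        j = planted.junction_index
        if not 1 <= j <= n_introns:
            raise ConfigError(
                f"{isoform_id}: junction_index {j} out of range (gene has {n_introns} introns)"
            )
        start, stop = exons[j - 1]
        new_stop = stop + planted.junction_shift
        if new_stop < start or new_stop >= exons[j][0] - 1:
            raise ConfigError(f"{isoform_id}: junction_shift {planted.junction_shift} is infeasible")
        exons[j - 1] = (start, new_stop)
    elif planted.category == "intron_retention":
        retained = sorted(set(planted.retained_introns))
        if not retained:
            raise ConfigError(f"{isoform_id}: intron_retention needs retained_introns")
        if retained[0] < 1 or retained[-1] > n_introns:
            raise ConfigError(f"{isoform_id}: retained intron index out of range")
        fused: List[Tuple[int, int]] = [exons[0]]
        for i in range(1, len(exons)):
            if i in retained:  # intron i (1-based) precedes exon i (0-based index i)
                fused[-1] = (fused[-1][0], exons[i][1])
            else:
                fused.append(exons[i])
        exons = fused
    elif planted.category == "novel_terminal":
        extend_left = (planted.terminal_end == "5p") == (gene.strand == "+")
        if extend_left:
            new_start = exons[0][0] - planted.terminal_delta
            if new_start < 1:
                raise ConfigError(f"{isoform_id}: terminal_delta extends past the chromosome start")
            exons[0] = (new_start, exons[0][1])
        else:
            new_stop = exons[-1][1] + planted.terminal_delta
            if new_stop > config.chrom_length:
                raise ConfigError(f"{isoform_id}: terminal_delta extends past the chromosome end")
            exons[-1] = (exons[-1][0], new_stop)
    else:  # pragma: no cover - pydantic already validated
        raise ConfigError(f"unknown category {planted.category!r}")

    tissues = planted.tissues or (config.tissues[0],)
    return IsoformChain(
        isoform_id=isoform_id, gene_id=gene.gene_id, chrom=gene.chrom,
        strand=gene.strand, exons=tuple(exons), source="long_read", tissues=tissues,
    )


def generate_isoform_reads(
    annotation: List[GeneModel],
    truth: SyntheticTruth,
    config: SyntheticConfig,
    seed: Optional[int] = None,
) -> Tuple[List[IsoformChain], List[IsoformChain], Dict[Tuple[str, int, int, str], int]]:
    """Reference chains, planted candidate chains, and junction counts.

    Supported chains (and every reference) contribute
    ``junction_read_depth`` spanning reads per junction; unsupported
    planted chains contribute none.
    """
    gene_index = {g.gene_id: g for g in annotation}
    references = [
        IsoformChain(
            isoform_id=f"{g.gene_id}.ref", gene_id=g.gene_id, chrom=g.chrom,
            strand=g.strand, exons=g.exons, source="reference",
        )
        for g in annotation
    ]

    candidates: List[IsoformChain] = []
    counters: Dict[str, int] = {}
    unsupported: set = set()
    for planted in config.planted_isoforms:
        gene = gene_index.get(planted.gene)
        if gene is None:
            raise ConfigError(f"planted isoform references unknown gene {planted.gene!r}")
        counters[planted.gene] = counters.get(planted.gene, 0) + 1
        isoform_id = planted.isoform_id or f"{planted.gene}.iso{counters[planted.gene]}"
        chain = _build_planted_chain(planted, gene, config, isoform_id)
        candidates.append(chain)
        if not planted.supported:
            unsupported.add(isoform_id)
        truth.isoform_categories[isoform_id] = planted.category
        if planted.category == "intron_retention":
            truth.retained_introns[isoform_id] = sorted(set(planted.retained_introns))

    if config.nested_exon_spec is not None:
        guest_id = config.nested_exon_spec.guest_gene
        guest = gene_index.get(guest_id)
        if guest is not None:
            iso_id = f"{guest_id}.iso1"
            if iso_id not in truth.isoform_categories:
                candidates.append(
                    IsoformChain(
                        isoform_id=iso_id, gene_id=guest_id, chrom=guest.chrom,
                        strand=guest.strand, exons=guest.exons,
                        source="long_read", tissues=(config.tissues[0],),
                    )
                )
                truth.isoform_categories[iso_id] = "known"

    counts: Dict[Tuple[str, int, int, str], int] = {}
    for chain in references + [c for c in candidates if c.isoform_id not in unsupported]:
        for js, je in chain.junctions:
            key = (chain.chrom, js, je, chain.strand)
            counts[key] = max(counts.get(key, 0), config.junction_read_depth)
    return references, candidates, counts


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    genes: List[GeneModel]
    truth: SyntheticTruth
    wgs_counts: List[AlleleCountRecord]
    rna_counts: List[AlleleCountRecord]
    gene_totals: pd.DataFrame
    cage_coverage: pd.DataFrame
    reference_chains: List[IsoformChain]
    candidate_chains: List[IsoformChain]
    junction_counts: Dict[Tuple[str, int, int, str], int]


def simulate(config: SyntheticConfig) -> SimulationResult:
    """Run every generator stage from one config."""
    genes, truth = generate_annotation(config)
    wgs = generate_wgs_counts(truth, config)
    rna, totals = generate_rnaseq_counts(genes, truth, config)
    cage = generate_cage_coverage(genes, truth, config)
    refs, cands, junctions = generate_isoform_reads(genes, truth, config)
    return SimulationResult(
        genes=genes, truth=truth, wgs_counts=wgs, rna_counts=rna,
        gene_totals=totals, cage_coverage=cage,
        reference_chains=refs, candidate_chains=cands, junction_counts=junctions,
    )


def write_simulation(result: SimulationResult, out_dir) -> Dict[str, Path]:
    """Write every artifact as plain text; returns a name -> path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": out / "annotation.gff3",
        "wgs_counts": out / "wgs_counts.tsv",
        "rna_counts": out / "rna_counts.tsv",
        "gene_totals": out / "gene_totals.tsv",
        "cage_coverage": out / "cage_coverage.tsv",
        "isoforms": out / "isoforms.bed12",
        "junction_counts": out / "junction_counts.tsv",
        "truth": out / "truth.json",
    }
    ftio.write_gff3(result.genes, paths["annotation"])
    ftio.write_allele_counts(result.wgs_counts, paths["wgs_counts"])
    ftio.write_allele_counts(result.rna_counts, paths["rna_counts"])
    ftio.write_table(result.gene_totals, paths["gene_totals"])
    ftio.write_table(result.cage_coverage, paths["cage_coverage"])
    ftio.write_bed12(result.candidate_chains, paths["isoforms"])
    ftio.write_junction_counts(result.junction_counts, paths["junction_counts"])
    ftio.write_truth(result.truth.to_dict(), paths["truth"])
    return paths


def default_isoform_fixture(seed: int = 7) -> SyntheticConfig:
    """Noise-free fixture with >=20 planted isoforms across all four
    categories plus one partially nested antisense exon."""
    planted = []
    for gid in ("g1", "g2", "g3", "g4", "g5"):
        planted.extend(
            [
                PlantedIsoform(gene=gid, category="known"),
                PlantedIsoform(gene=gid, category="novel_junction",
                               junction_index=1, junction_shift=15),
                PlantedIsoform(gene=gid, category="intron_retention",
                               retained_introns=(2,)),
                PlantedIsoform(gene=gid, category="intron_retention",
                               retained_introns=(2, 3)),
                PlantedIsoform(gene=gid, category="novel_terminal",
                               terminal_end="5p", terminal_delta=600),
            ]
        )
    return SyntheticConfig(
        n_genes=5,
        chrom_length=2_000_000,
        exons_per_gene=(5, 6),
        planted_isoforms=tuple(planted),
        nested_exon_spec=NestedExonSpec(host_gene="g3", guest_gene="gx"),
        seed=seed,
    )
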