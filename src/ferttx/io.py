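"""Readers and writers for the on-disk formats used by the pipeline.

All coordinate conversions between the internal 1-based inclusive frame and
BED's 0-based half-open frame happen here and nowhere else.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import pandas as pd

from .models import AlleleCountRecord, GeneModel, IsoformChain

PathLike = Union[str, Path]

ALLELE_COUNT_COLUMNS = [
    "chrom", "pos", "allele_a", "allele_b", "count_a", "count_b", "source", "tissue",
]
CAGE_COLUMNS = ["chrom", "pos", "strand", "tag_count"]
GENE_TOTAL_COLUMNS = ["gene_id", "tissue", "technology", "mapped_reads", "library_total"]
JUNCTION_COLUMNS = ["chrom", "intron_start", "intron_stop", "strand", "reads"]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def format_gff3(genes: Sequence[GeneModel]) -> str:
    """Serialize gene models to GFF3 (gene / mRNA / exon / CDS features)."""
    lines = ["##gff-version 3"]
    for gene in genes:
        span_start, span_end = gene.span
        tid = f"{gene.gene_id}.t1"
        lines.append(
            "\t".join(
                [gene.chrom, "ferttx", "gene", str(span_start), str(span_end),
                 ".", gene.strand, ".", f"ID={gene.gene_id}"]
            )
        )
        lines.append(
            "\t".join(
                [gene.chrom, "ferttx", "mRNA", str(span_start), str(span_end),
                 ".", gene.strand, ".", f"ID={tid};Parent={gene.gene_id}"]
            )
        )
        for i, (start, stop) in enumerate(gene.exons, start=1):
            lines.append(
                "\t".join(
                    [gene.chrom, "ferttx", "exon", str(start), str(stop),
                     ".", gene.strand, ".", f"ID={tid}.exon{i};Parent={tid}"]
                )
            )
        for i, (start, stop) in enumerate(gene.exons, start=1):
            lo = max(start, gene.cds_start)
            hi = min(stop, gene.cds_end)
            if lo <= hi:
                lines.append(
                    "\t".join(
                        [gene.chrom, "ferttx", "CDS", str(lo), str(hi),
                         ".", gene.strand, "0", f"ID={tid}.cds{i};Parent={tid}"]
                    )
                )
    return "\n".join(lines) + "\n"


def write_gff3(genes: Sequence[GeneModel], path: PathLike) -> None:
    Path(path).write_text(format_gff3(genes))


def read_gff3(path_or_text: PathLike, *, from_string: bool = False) -> List[GeneModel]:
    """Load gene models from GFF3 using an in-memory gffutils database."""
    import gffutils

    data = str(path_or_text)
    db = gffutils.create_db(
        data, dbfn=":memory:", from_string=from_string, force=True,
        keep_order=True, merge_strategy="create_unique",
    )
    genes: List[GeneModel] = []
    for feat in db.features_of_type("gene", order_by="start"):
        exons = sorted(
            (child.start, child.end)
            for child in db.children(feat, featuretype="exon")
        )
        cds = [(child.start, child.end) for child in db.children(feat, featuretype="CDS")]
        if not cds:
            raise ValueError(f"gene {feat.id} has no CDS features")
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                strand=feat.strand,
                exons=tuple(exons),
                cds_start=min(s for s, _ in cds),
                cds_end=max(e for _, e in cds),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

def chain_to_bed12(chain: IsoformChain) -> str:
    """One BED12 line; the name column packs isoform, gene and tissues."""
    span_start, span_end = chain.span
    sizes = ",".join(str(stop - start + 1) for start, stop in chain.exons)
    rel_starts = ",".join(str(start - span_start) for start, _ in chain.exons)
    name = "|".join([chain.isoform_id, chain.gene_id, ",".join(chain.tissues)])
    fields = [
        chain.chrom, str(span_start - 1), str(span_end), name, "0", chain.strand,
        str(span_start - 1), str(span_end), "0", str(len(chain.exons)),
        sizes, rel_starts,
    ]
    return "\t".join(fields)


def bed12_to_chain(line: str, source: str = "long_read") -> IsoformChain:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ValueError(f"expected 12 BED columns, got {len(fields)}")
    chrom = fields[0]
    chrom_start = int(fields[1])
    name_parts = fields[3].split("|")
    isoform_id = name_parts[0]
    gene_id = name_parts[1] if len(name_parts) > 1 else isoform_id
    tissues = tuple(t for t in (name_parts[2].split(",") if len(name_parts) > 2 else []) if t)
    strand = fields[5]
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    rel_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    exons = tuple(
        (chrom_start + rel + 1, chrom_start + rel + size)
        for rel, size in zip(rel_starts, sizes)
    )
    return IsoformChain(
        isoform_id=isoform_id, gene_id=gene_id, chrom=chrom, strand=strand,
        exons=exons, source=source, tissues=tissues,
    )


def write_bed12(chains: Sequence[IsoformChain], path: PathLike) -> None:
    Path(path).write_text("".join(chain_to_bed12(c) + "\n" for c in chains))


def read_bed12(path: PathLike, source: str = "long_read") -> List[IsoformChain]:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln and not ln.startswith("#")]
    return [bed12_to_chain(ln, source=source) for ln in lines]


# ---------------------------------------------------------------------------
# Allele-count tables
# ---------------------------------------------------------------------------

def allele_counts_to_frame(records: Iterable[AlleleCountRecord]) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.chrom, "pos": r.pos, "allele_a": r.allele_a,
            "allele_b": r.allele_b, "count_a": r.count_a, "count_b": r.count_b,
            "source": r.source, "tissue": r.tissue if r.tissue is not None else "",
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=ALLELE_COUNT_COLUMNS)


def frame_to_allele_counts(frame: pd.DataFrame) -> List[AlleleCountRecord]:
    records = []
    for row in frame.itertuples(index=False):
        tissue = getattr(row, "tissue", "")
        tissue = None if (pd.isna(tissue) or tissue == "") else str(tissue)
        records.append(
            AlleleCountRecord(
                chrom=str(row.chrom), pos=int(row.pos),
                allele_a=str(row.allele_a), allele_b=str(row.allele_b),
                count_a=int(row.count_a), count_b=int(row.count_b),
                source=str(row.source), tissue=tissue,
            )
        )
    return records


def write_allele_counts(records: Iterable[AlleleCountRecord], path: PathLike) -> None:
    allele_counts_to_frame(records).to_csv(path, sep="\t", index=False)


def read_allele_counts(path: PathLike) -> List[AlleleCountRecord]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    return frame_to_allele_counts(frame)


def read_vcf_allele_counts(path: PathLike) -> List[AlleleCountRecord]:
    """Minimal VCF reader: biallelic SNPs with per-sample AD fields."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: List[AlleleCountRecord] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        depths = variant.format("AD")
        if depths is None:
            continue
        for sample, ad in zip(samples, depths):
            records.append(
                AlleleCountRecord(
                    chrom=variant.CHROM, pos=variant.POS,
                    allele_a=variant.REF, allele_b=variant.ALT[0],
                    count_a=max(int(ad[0]), 0), count_b=max(int(ad[1]), 0),
                    source=sample,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Simple TSV tables
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_cage_coverage(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})


def read_gene_totals(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "tissue": str, "technology": str})


def read_junction_counts(path: PathLike) -> Dict[Tuple[str, int, int, str], int]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    return {
        (row.chrom, int(row.intron_start), int(row.intron_stop), row.strand): int(row.reads)
        for row in frame.itertuples(index=False)
    }


def write_junction_counts(counts: Dict[Tuple[str, int, int, str], int], path: PathLike) -> None:
    rows = [
        {"chrom": c, "intron_start": s, "intron_stop": e, "strand": st, "reads": n}
        for (c, s, e, st), n in sorted(counts.items())
    ]
    pd.DataFrame(rows, columns=JUNCTION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Truth record
# ---------------------------------------------------------------------------

def write_truth(truth_dict: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(truth_dict, indent=2, sort_keys=True) + "\n")


def read_truth(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
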