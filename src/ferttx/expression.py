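"""Per-gene, per-tissue, per-technology relative expression (RPM/RPKM)."""

from __future__ import annotations

from typing import Iterable, Optional, Tuple

import pandas as pd

from .models import GeneModel

MILLION = 1_000_000

#: Read unit per technology, recorded in outputs (RNA-seq counts read pairs).
TECHNOLOGY_UNITS = {
    "rna_seq": "read_pairs",
    "cage_seq": "reads",
    "iso_seq": "reads",
}


def rpm(mapped_reads: float, library_total: float) -> float:
    """Reads per million: T / A * 1,000,000."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if mapped_reads < 0:
        raise ValueError("mapped_reads must be non-negative")
    if mapped_reads > library_total:
        raise ValueError(
            f"mapped_reads ({mapped_reads}) exceeds library_total ({library_total})"
        )
    return mapped_reads / library_total * MILLION


def rpkm_correct(rpm_value: float, cds_length: int) -> float:
    """Length-corrected expression: RPM divided by CDS length in kbp."""
    if cds_length <= 0:
        raise ValueError("cds_length must be positive")
    return rpm_value / (cds_length / 1000.0)


def expression_matrix(
    gene_totals: pd.DataFrame,
    annotation: Optional[Iterable[GeneModel]] = None,
    min_rpm: float = 0.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Expression records plus per-(tissue, technology) rankings.

    ``gene_totals`` columns: gene_id, tissue, technology, mapped_reads,
    library_total. Genes present in the annotation but absent from a
    (tissue, technology) table get rpm=0 / detected=False rows. ``detected``
    is mapped_reads > 0 and rpm >= min_rpm.
    """
    required = {"gene_id", "tissue", "technology", "mapped_reads", "library_total"}
    missing = required - set(gene_totals.columns)
    if missing:
        raise ValueError(f"gene_totals is missing columns: {sorted(missing)}")

    bad = gene_totals[gene_totals["library_total"] <= 0]
    if not bad.empty:
        pairs = sorted(set(zip(bad["tissue"], bad["technology"])))
        raise ValueError(f"missing or zero library totals for: {pairs}")

    cds_lengths = {}
    all_genes = []
    if annotation is not None:
        for gene in annotation:
            # longest coding span wins when a gene id repeats (isoforms)
            cds_lengths[gene.gene_id] = max(cds_lengths.get(gene.gene_id, 0), gene.cds_len)
            if gene.gene_id not in all_genes:
                all_genes.append(gene.gene_id)

    library_totals = {
        (row.tissue, row.technology): int(row.library_total)
        for row in gene_totals.itertuples(index=False)
    }
    observed = {
        (row.gene_id, row.tissue, row.technology): int(row.mapped_reads)
        for row in gene_totals.itertuples(index=False)
    }

    gene_order = all_genes or sorted({g for g, _, _ in observed})
    rows = []
    for (tissue, technology), total in sorted(library_totals.items()):
        for gene_id in gene_order:
            mapped = observed.get((gene_id, tissue, technology), 0)
            value = rpm(mapped, total)
            cds_len = cds_lengths.get(gene_id)
            rows.append(
                {
                    "gene_id": gene_id, "tissue": tissue, "technology": technology,
                    "unit": TECHNOLOGY_UNITS.get(technology, "reads"),
                    "mapped_reads": mapped, "library_total": total,
                    "rpm": value,
                    "rpkm": rpkm_correct(value, cds_len) if cds_len else float("nan"),
                    "detected": mapped > 0 and value >= min_rpm,
                }
            )
    matrix = pd.DataFrame(rows)

    rank_rows = []
    for (tissue, technology), group in matrix.groupby(["tissue", "technology"], sort=True):
        ordered = group.sort_values(["rpm", "gene_id"], ascending=[False, True])
        for rank, row in enumerate(ordered.itertuples(index=False), start=1):
            rank_rows.append(
                {
                    "tissue": tissue, "technology": technology, "rank": rank,
                    "gene_id": row.gene_id, "rpm": row.rpm,
                }
            )
    rankings = pd.DataFrame(rank_rows)
    return matrix, rankings
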