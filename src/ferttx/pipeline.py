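"""End-to-end orchestration: simulate -> variants -> ase -> expression ->
tss -> isoforms, from one config, with a consolidated report.

Every number in the report is read back from a stage output table; the
report performs no computation of its own beyond truth scoring on
synthetic runs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
from pydantic import BaseModel, model_validator

from . import io as ftio
from .ase import ase_screen
from .errors import ConfigError
from .expression import expression_matrix
from .isoform_class import (
    classify_isoform,
    detect_nested_exons,
    retention_dependency,
)
from .models import AlleleCountRecord, GeneModel, IsoformChain
from .synthetic_data import SimulationResult, SyntheticConfig, simulate, write_simulation
from .tss import gene_peak, summarize_tss
from .variant_sites import DEFAULT_GENOME_SIZE, divergence_report, snp_table

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Exactly one of ``synthetic`` (a generator config) or ``inputs``
    (paths to real files) drives a run."""

    synthetic: Optional[SyntheticConfig] = None
    inputs: Optional[Dict[str, str]] = None
    genome_size: int = DEFAULT_GENOME_SIZE
    min_reads_per_allele: int = 2
    alpha_primary: float = 1e-4
    alpha_confirm: float = 1e-2
    min_depth: int = 10
    min_rpm: float = 0.0
    promoter_window: int = 5_000
    min_tags: int = 1
    utr_rule: str = "stop"
    terminal_fuzz: int = 50
    min_junction_reads: int = 2

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "PipelineConfig":
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("provide exactly one of 'synthetic' or 'inputs'")
        return self


def _load_inputs(inputs: Dict[str, str]):
    required = {"annotation", "wgs_counts", "rna_counts", "gene_totals",
                "cage_coverage", "isoforms", "junction_counts"}
    missing = required - set(inputs)
    if missing:
        raise ConfigError(f"pipeline inputs missing paths: {sorted(missing)}")
    genes = ftio.read_gff3(inputs["annotation"])
    wgs = ftio.read_allele_counts(inputs["wgs_counts"])
    rna = ftio.read_allele_counts(inputs["rna_counts"])
    totals = ftio.read_gene_totals(inputs["gene_totals"])
    cage = ftio.read_cage_coverage(inputs["cage_coverage"])
    candidates = ftio.read_bed12(inputs["isoforms"])
    junctions = ftio.read_junction_counts(inputs["junction_counts"])
    references = [
        IsoformChain(
            isoform_id=f"{g.gene_id}.ref", gene_id=g.gene_id, chrom=g.chrom,
            strand=g.strand, exons=g.exons, source="reference",
        )
        for g in genes
    ]
    return genes, wgs, rna, totals, cage, references, candidates, junctions


def classify_chains(
    candidates: List[IsoformChain],
    references: List[IsoformChain],
    junction_counts: Dict[Tuple[str, int, int, str], int],
    terminal_fuzz: int,
    min_junction_reads: int,
) -> pd.DataFrame:
    """Classify every candidate against its gene's references."""
    refs_by_gene: Dict[str, List[IsoformChain]] = {}
    for ref in references:
        refs_by_gene.setdefault(ref.gene_id, []).append(ref)

    rows = []
    for chain in candidates:
        local_counts = {
            (s, e): n
            for (chrom, s, e, strand), n in junction_counts.items()
            if chrom == chain.chrom and strand == chain.strand
        }
        result = classify_isoform(
            chain, refs_by_gene.get(chain.gene_id, []), local_counts,
            terminal_fuzz=terminal_fuzz, min_junction_reads=min_junction_reads,
        )
        rows.append(
            {
                "isoform_id": result.isoform_id, "gene_id": chain.gene_id,
                "category": result.category,
                "matched_reference": result.matched_reference or "",
                "retained_introns": ",".join(map(str, result.retained_introns)),
                "multi_evidence": result.multi_evidence,
                "tissues": ",".join(chain.tissues),
                "_classification": result,
            }
        )
    return pd.DataFrame(rows)


def _score_truth(
    result: SimulationResult,
    config: PipelineConfig,
    snp_frame: pd.DataFrame,
    ase_frame: pd.DataFrame,
    tss_frame: pd.DataFrame,
    class_frame: pd.DataFrame,
    nested_frame: pd.DataFrame,
) -> pd.DataFrame:
    """Precision/recall and accuracy of each stage against planted truth."""
    truth = result.truth
    rows = []

    # zygosity accuracy (error model off => should be perfect at high depth)
    truth_zyg = {(s["chrom"], s["pos"]): s["zygosity"] for s in truth.snp_loci}
    called = snp_frame[snp_frame["zygosity"] != "uncallable"]
    correct = sum(
        truth_zyg.get((row.chrom, row.pos)) == row.zygosity
        for row in called.itertuples(index=False)
    )
    rows.append(("zygosity_accuracy", correct / len(called) if len(called) else float("nan")))

    # ASE precision/recall on final calls
    pos_of_het = {i: (h["chrom"], h["pos"]) for i, h in enumerate(truth.het_loci)}
    true_pos = {
        (*pos_of_het[idx], tissue)
        for idx, per_tissue in truth.ase_effects.items()
        for tissue, f in per_tissue.items()
        if f != config.synthetic.reference_bias
    }
    if not ase_frame.empty:
        calls = {
            (row.chrom, row.pos, row.tissue)
            for row in ase_frame[ase_frame["final_call"]].itertuples(index=False)
        }
    else:
        calls = set()
    tp = len(calls & true_pos)
    rows.append(("ase_precision", tp / len(calls) if calls else float("nan")))
    rows.append(("ase_recall", tp / len(true_pos) if true_pos else float("nan")))

    # TSS/UTR recovery: exact for spike peaks, within kernel half-width else
    tolerance = config.synthetic.cage_peak_width if config.synthetic else 0
    with_peak = tss_frame.dropna(subset=["utr_length"])
    recovered = sum(
        abs(truth.true_utr_lengths.get(row.gene_id, -10**9) - row.utr_length) <= tolerance
        for row in with_peak.itertuples(index=False)
    )
    rows.append(
        ("utr_recovered_fraction", recovered / len(with_peak) if len(with_peak) else float("nan"))
    )

    # isoform classification accuracy
    if not class_frame.empty:
        right = sum(
            truth.isoform_categories.get(row.isoform_id) == row.category
            for row in class_frame.itertuples(index=False)
        )
        rows.append(("isoform_accuracy", right / len(class_frame)))
    else:
        rows.append(("isoform_accuracy", float("nan")))

    # nested exon recovery
    expected_nested = {
        (h["guest_gene"], h["host_gene"], tuple(h["exon"])) for h in truth.nested_hits
    }
    found = {
        (row.guest_gene, row.host_gene, (row.exon_start, row.exon_stop))
        for row in nested_frame.itertuples(index=False)
    } if not nested_frame.empty else set()
    rows.append(("nested_exons_recovered", len(expected_nested & found)))
    rows.append(("nested_exons_expected", len(expected_nested)))

    return pd.DataFrame(rows, columns=["metric", "value"])


def run_pipeline(config: PipelineConfig, out_dir) -> Dict[str, object]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim_result: Optional[SimulationResult] = None
    if config.synthetic is not None:
        logger.info("stage simulate: generating synthetic data")
        sim_result = simulate(config.synthetic)
        write_simulation(sim_result, out / "sim")
        genes = sim_result.genes
        wgs, rna = sim_result.wgs_counts, sim_result.rna_counts
        totals, cage = sim_result.gene_totals, sim_result.cage_coverage
        references, candidates = sim_result.reference_chains, sim_result.candidate_chains
        junctions = sim_result.junction_counts
    else:
        logger.info("stage load: reading real inputs")
        (genes, wgs, rna, totals, cage, references, candidates,
         junctions) = _load_inputs(config.inputs)

    logger.info("stage variants: %d WGS records, %d genes", len(wgs), len(genes))
    snp_frame = snp_table(wgs, genes, config.min_reads_per_allele)
    ftio.write_table(snp_frame, out / "snp_table.tsv")
    div_frame = divergence_report(snp_frame, config.genome_size)
    ftio.write_table(div_frame, out / "divergence.tsv")

    logger.info("stage ase: %d RNA records", len(rna))
    report = ase_screen(
        rna, wgs,
        alpha_primary=config.alpha_primary, alpha_confirm=config.alpha_confirm,
        min_depth=config.min_depth, min_reads_per_allele=config.min_reads_per_allele,
    )
    ase_frame = report.to_frame()
    ftio.write_table(ase_frame, out / "ase_results.tsv")
    skipped_frame = pd.DataFrame(
        list(report.skipped), columns=["chrom", "pos", "tissue", "reason"]
    )
    ftio.write_table(skipped_frame, out / "ase_skipped.tsv")

    logger.info("stage expression: %d gene-total rows", len(totals))
    matrix, rankings = expression_matrix(totals, genes, min_rpm=config.min_rpm)
    ftio.write_table(matrix, out / "expression_matrix.tsv")
    ftio.write_table(rankings, out / "expression_rankings.tsv")

    logger.info("stage tss: %d coverage rows", len(cage))
    peaks = {
        g.gene_id: gene_peak(cage, g, config.promoter_window, config.min_tags)
        for g in genes
    }
    tss_frame, tss_stats = summarize_tss(genes, peaks, rule=config.utr_rule)
    ftio.write_table(tss_frame, out / "tss_report.tsv")

    logger.info("stage isoforms: %d candidates vs %d references",
                len(candidates), len(references))
    class_frame = classify_chains(
        candidates, references, junctions,
        config.terminal_fuzz, config.min_junction_reads,
    )
    classifications = list(class_frame["_classification"]) if not class_frame.empty else []
    out_class = class_frame.drop(columns=["_classification"]) if not class_frame.empty else class_frame
    ftio.write_table(out_class, out / "isoform_classifications.tsv")

    dep_rows = []
    by_gene: Dict[str, list] = {}
    for chain, cls in zip(candidates, classifications):
        by_gene.setdefault(chain.gene_id, []).append(cls)
    for gene_id, gene_classes in sorted(by_gene.items()):
        for (a, b), implied in sorted(retention_dependency(gene_classes).items()):
            dep_rows.append(
                {"gene_id": gene_id, "intron_a": a, "intron_b": b, "implies": implied}
            )
    dep_frame = pd.DataFrame(dep_rows, columns=["gene_id", "intron_a", "intron_b", "implies"])
    ftio.write_table(dep_frame, out / "retention_dependencies.tsv")

    chains_by_gene: Dict[str, List[IsoformChain]] = {}
    for chain in candidates:
        chains_by_gene.setdefault(chain.gene_id, []).append(chain)
    nested_rows = []
    for guest in genes:
        for host in genes:
            if guest.gene_id == host.gene_id or guest.chrom != host.chrom:
                continue
            for hit in detect_nested_exons(guest, host, chains_by_gene.get(guest.gene_id, ())):
                nested_rows.append(
                    {
                        "guest_gene": hit.guest_gene, "host_gene": hit.host_gene,
                        "exon_start": hit.exon[0], "exon_stop": hit.exon[1],
                        "strand_relation": hit.strand_relation,
                        "tissues": ",".join(hit.tissues),
                    }
                )
    nested_frame = pd.DataFrame(
        nested_rows,
        columns=["guest_gene", "host_gene", "exon_start", "exon_stop",
                 "strand_relation", "tissues"],
    )
    ftio.write_table(nested_frame, out / "nested_exons.tsv")

    summary: Dict[str, object] = {
        "n_genes": len(genes),
        "n_wgs_records": len(wgs),
        "n_rna_records": len(rna),
        "n_ase_tested": len(report.results),
        "n_ase_final_calls": sum(r.final_call for r in report.results),
        "n_candidates": len(candidates),
        "tss_stats": tss_stats,
    }

    if sim_result is not None:
        score_frame = _score_truth(
            sim_result, config, snp_frame, ase_frame, tss_frame, out_class, nested_frame
        )
        ftio.write_table(score_frame, out / "truth_scores.tsv")
        summary["truth_scores"] = dict(zip(score_frame["metric"], score_frame["value"]))

    report_rows = [{"key": k, "value": str(v)} for k, v in summary.items()]
    ftio.write_table(pd.DataFrame(report_rows), out / "report.tsv")
    return summary
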