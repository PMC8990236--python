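"""Pearson chi-squared allele-specific-expression testing.

Two null models for the expected allele split at a heterozygous locus:

* ``equal`` — both alleles expected at R/2, where R is the RNA depth;
* ``wgs_ratio`` — expected split follows the allele ratio observed in the
  same animal's whole-genome sequencing, ``E_i = R * G_i / sum(G)``, which
  absorbs reference/sequencing bias.

The two-stage screen tests every eligible locus under the equal null at a
strict primary cutoff, then re-tests the hits under the WGS-ratio null at a
confirmation cutoff; the final call requires significance under both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .errors import UntestableLocusError
from .models import AlleleCountRecord
from .variant_sites import DEFAULT_MIN_READS_PER_ALLELE, call_zygosity

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_PRIMARY = 1e-4
DEFAULT_ALPHA_CONFIRM = 1e-2
DEFAULT_MIN_DEPTH = 10


def expected_equal(total_depth: float) -> Tuple[float, float]:
    """Expected counts under the 1:1 null: (R/2, R/2)."""
    if total_depth < 0:
        raise ValueError("total depth must be non-negative")
    half = total_depth / 2.0
    return half, half


def expected_wgs(total_depth: float, wgs_counts: Tuple[int, int]) -> Tuple[float, float]:
    """Expected counts under the WGS-ratio null: E_i = R * G_i / sum(G)."""
    g_a, g_b = wgs_counts
    g_total = g_a + g_b
    if g_total <= 0:
        raise UntestableLocusError("WGS depth is zero; locus untestable under wgs_ratio null")
    return total_depth * g_a / g_total, total_depth * g_b / g_total


def chi_squared(
    observed: Tuple[float, float], expected: Tuple[float, float]
) -> Tuple[float, float]:
    """Pearson chi-squared statistic (df=1, no continuity correction) and
    its upper-tail p-value."""
    if any(e <= 0 for e in expected):
        raise UntestableLocusError(f"expected counts must be positive, got {expected}")
    if any(o < 0 for o in observed):
        raise ValueError("observed counts must be non-negative")
    stat = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return float(stat), float(_chi2_dist.sf(stat, df=1))


@dataclass(frozen=True)
class AseTestResult:
    chrom: str
    pos: int
    tissue: str
    null_model: str  # "equal" | "wgs_ratio"
    observed: Tuple[int, int]
    expected: Tuple[float, float]
    total_depth: int
    wgs_counts: Optional[Tuple[int, int]]
    chi2: float
    p_value: float

    @property
    def significant_1e4(self) -> bool:
        return self.p_value < 1e-4

    @property
    def significant_1e2(self) -> bool:
        return self.p_value < 1e-2


@dataclass(frozen=True)
class LocusScreenResult:
    """Both stages of the screen for one locus x tissue."""

    chrom: str
    pos: int
    tissue: str
    stage1: AseTestResult
    stage2: Optional[AseTestResult]
    final_call: bool


@dataclass(frozen=True)
class AseScreenReport:
    results: Tuple[LocusScreenResult, ...]
    skipped: Tuple[Tuple[str, int, str, str], ...]  # (chrom, pos, tissue, reason)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per locus x tissue x null model."""
        rows = []
        for res in self.results:
            for test in (res.stage1, res.stage2):
                if test is None:
                    continue
                rows.append(
                    {
                        "chrom": test.chrom, "pos": test.pos, "tissue": test.tissue,
                        "null_model": test.null_model,
                        "count_a": test.observed[0], "count_b": test.observed[1],
                        "expected_a": test.expected[0], "expected_b": test.expected[1],
                        "total_depth": test.total_depth,
                        "chi2": test.chi2, "p_value": test.p_value,
                        "significant_1e4": test.significant_1e4,
                        "significant_1e2": test.significant_1e2,
                        "final_call": res.final_call,
                    }
                )
        return pd.DataFrame(rows)


def single_locus_test(
    rna: AlleleCountRecord,
    null_model: str = "equal",
    wgs_counts: Optional[Tuple[int, int]] = None,
) -> AseTestResult:
    """Run one chi-squared ASE test under the requested null model."""
    observed = (rna.count_a, rna.count_b)
    depth = rna.total
    if null_model == "equal":
        expected = expected_equal(depth)
    elif null_model == "wgs_ratio":
        if wgs_counts is None:
            raise ValueError("wgs_counts required for the wgs_ratio null")
        expected = expected_wgs(depth, wgs_counts)
    else:
        raise ValueError(f"unknown null model {null_model!r}")
    stat, p = chi_squared(observed, expected)
    return AseTestResult(
        chrom=rna.chrom, pos=rna.pos, tissue=rna.tissue or "",
        null_model=null_model, observed=observed, expected=expected,
        total_depth=depth, wgs_counts=wgs_counts, chi2=stat, p_value=p,
    )


def ase_screen(
    rna_counts: Iterable[AlleleCountRecord],
    wgs_counts: Iterable[AlleleCountRecord],
    alpha_primary: float = DEFAULT_ALPHA_PRIMARY,
    alpha_confirm: float = DEFAULT_ALPHA_CONFIRM,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_reads_per_allele: int = DEFAULT_MIN_READS_PER_ALLELE,
) -> AseScreenReport:
    """Two-stage ASE screen over an RNA allele-count table.

    Only loci that are heterozygous in the matching animal's WGS counts are
    tested. Stage 1 applies the equal null at ``alpha_primary``; stage 2
    re-tests stage-1 hits under the WGS-ratio null at ``alpha_confirm``.
    """
    wgs_index: Dict[Tuple[str, str, int], AlleleCountRecord] = {}
    for record in wgs_counts:
        wgs_index[(record.source, record.chrom, record.pos)] = record

    results: List[LocusScreenResult] = []
    skipped: List[Tuple[str, int, str, str]] = []

    for rna in rna_counts:
        tissue = rna.tissue or ""
        key = (rna.source, rna.chrom, rna.pos)
        wgs = wgs_index.get(key)
        if wgs is None:
            reason = "locus absent from WGS table"
            logger.info("skipping %s:%d (%s): %s", rna.chrom, rna.pos, tissue, reason)
            skipped.append((rna.chrom, rna.pos, tissue, reason))
            continue
        if call_zygosity(wgs, min_reads_per_allele) != "het":
            reason = "not heterozygous in WGS"
            skipped.append((rna.chrom, rna.pos, tissue, reason))
            continue
        if rna.total < min_depth:
            reason = f"RNA depth {rna.total} below min_depth {min_depth}"
            skipped.append((rna.chrom, rna.pos, tissue, reason))
            continue

        stage1 = single_locus_test(rna, null_model="equal")
        stage2: Optional[AseTestResult] = None
        final = False
        if stage1.p_value < alpha_primary:
            stage2 = single_locus_test(
                rna, null_model="wgs_ratio", wgs_counts=(wgs.count_a, wgs.count_b)
            )
            final = stage2.p_value < alpha_confirm
        results.append(
            LocusScreenResult(
                chrom=rna.chrom, pos=rna.pos, tissue=tissue,
                stage1=stage1, stage2=stage2, final_call=final,
            )
        )

    return AseScreenReport(results=tuple(results), skipped=tuple(skipped))
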