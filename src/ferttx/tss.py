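"""CAGE tag-cluster peak calling and 5'UTR length derivation.

Peak boundaries are oriented along the upstream direction of the gene:
``start`` is the boundary less far upstream of the gene 5' position and
``stop`` the farther one, so either may be numerically below the other on
either strand. The 5'UTR length is ``|stop - five_prime_pos|`` — the rule
that reproduces the reference coordinate table exactly; the center-of-peak
rule is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .models import CagePeak, GeneModel

DEFAULT_PROMOTER_WINDOW = 5_000
DEFAULT_MIN_TAGS = 1


def _upstream_distance(pos: int, five_prime_pos: int, strand: str) -> int:
    """Signed distance of ``pos`` from the gene 5' position, positive when
    ``pos`` is upstream in transcription direction."""
    return five_prime_pos - pos if strand == "+" else pos - five_prime_pos


def call_peaks(
    coverage: pd.DataFrame,
    gene: GeneModel,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    min_tags: int = DEFAULT_MIN_TAGS,
) -> List[CagePeak]:
    """Tag clusters near the gene 5' end on the gene's strand.

    A cluster is a run of contiguous positions with tag_count >= min_tags
    within +/- promoter_window of the gene 5' position. Clusters are
    returned sorted by total tag count (descending), ties broken by
    proximity of the cluster mode to the gene 5' end.
    """
    five = gene.five_prime_pos
    sel = coverage[
        (coverage["chrom"] == gene.chrom)
        & (coverage["strand"] == gene.strand)
        & (coverage["tag_count"] >= min_tags)
        & (coverage["pos"] >= five - promoter_window)
        & (coverage["pos"] <= five + promoter_window)
    ]
    if sel.empty:
        return []
    counts: Dict[int, int] = {}
    for row in sel.itertuples(index=False):
        counts[int(row.pos)] = counts.get(int(row.pos), 0) + int(row.tag_count)
    positions = sorted(counts)

    clusters: List[List[int]] = []
    run: List[int] = [positions[0]]
    for pos in positions[1:]:
        if pos == run[-1] + 1:
            run.append(pos)
        else:
            clusters.append(run)
            run = [pos]
    clusters.append(run)

    peaks = []
    for run in clusters:
        total = sum(counts[p] for p in run)
        mode = max(run, key=lambda p: (counts[p], -p))  # tie -> lowest coordinate
        lo, hi = run[0], run[-1]
        # stop = boundary farther upstream of the gene 5' position
        if _upstream_distance(lo, five, gene.strand) >= _upstream_distance(hi, five, gene.strand):
            start, stop = hi, lo
        else:
            start, stop = lo, hi
        peaks.append(
            CagePeak(
                chrom=gene.chrom, strand=gene.strand,
                start=start, stop=stop, mode_pos=mode, tag_count=total,
            )
        )
    peaks.sort(
        key=lambda p: (-p.tag_count, abs(_upstream_distance(p.mode_pos, five, gene.strand)))
    )
    return peaks


def gene_peak(
    coverage: pd.DataFrame,
    gene: GeneModel,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    min_tags: int = DEFAULT_MIN_TAGS,
) -> Optional[CagePeak]:
    """The gene's TSS peak: the maximal-sum cluster, or None if no tags."""
    peaks = call_peaks(coverage, gene, promoter_window, min_tags)
    return peaks[0] if peaks else None


def utr_length(five_prime_pos: int, peak: CagePeak, rule: str = "stop") -> int:
    """5'UTR length in bp from the gene 5' position and its TSS peak.

    ``rule="stop"`` (default) measures to the peak's far-upstream boundary;
    ``rule="center"`` measures to the midpoint of the two boundaries.
    """
    if rule == "stop":
        return abs(peak.stop - five_prime_pos)
    if rule == "center":
        center = (peak.start + peak.stop) / 2.0
        return int(round(abs(center - five_prime_pos)))
    raise ValueError(f"unknown UTR rule {rule!r}")


@dataclass(frozen=True)
class UtrResult:
    gene_id: str
    five_prime_pos: int
    peak: Optional[CagePeak]

    @property
    def utr_length(self) -> Optional[int]:
        if self.peak is None:
            return None
        return utr_length(self.five_prime_pos, self.peak)


def summarize_tss(
    genes: Iterable[GeneModel],
    peaks: Dict[str, Optional[CagePeak]],
    rule: str = "stop",
) -> Tuple[pd.DataFrame, dict]:
    """Per-gene TSS/UTR report plus min/max/mean UTR summary stats.

    Genes without a peak are listed with empty peak columns and excluded
    from the summary statistics.
    """
    rows = []
    lengths = {}
    for gene in genes:
        peak = peaks.get(gene.gene_id)
        if peak is None:
            rows.append(
                {
                    "gene_id": gene.gene_id, "five_prime_pos": gene.five_prime_pos,
                    "peak_start": pd.NA, "peak_stop": pd.NA, "peak_mode": pd.NA,
                    "tag_count": pd.NA, "utr_length": pd.NA,
                }
            )
            continue
        length = utr_length(gene.five_prime_pos, peak, rule=rule)
        lengths[gene.gene_id] = length
        rows.append(
            {
                "gene_id": gene.gene_id, "five_prime_pos": gene.five_prime_pos,
                "peak_start": peak.start, "peak_stop": peak.stop,
                "peak_mode": peak.mode_pos, "tag_count": peak.tag_count,
                "utr_length": length,
            }
        )
    report = pd.DataFrame(rows)
    if lengths:
        values = list(lengths.values())
        stats = {
            "n_with_peak": len(values),
            "n_without_peak": len(report) - len(values),
            "min_utr": min(values),
            "max_utr": max(values),
            "mean_utr": sum(values) / len(values),
            "min_gene": min(lengths, key=lambda g: (lengths[g], g)),
            "max_gene": max(lengths, key=lambda g: (lengths[g], g)),
        }
    else:
        stats = {
            "n_with_peak": 0, "n_without_peak": len(report),
            "min_utr": None, "max_utr": None, "mean_utr": None,
            "min_gene": None, "max_gene": None,
        }
    return report, stats
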