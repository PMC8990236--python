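"""Exon-chain isoform classification against a reference annotation.

Categories:

* ``known`` — identical junction chain to a reference and both terminal
  ends within the fuzz window (the boundary case, difference == fuzz, is
  known);
* ``intron_retention`` — the candidate's junction chain equals a reference
  chain minus one or more introns, each retained intron being exonic in the
  candidate;
* ``novel_terminal`` — identical junction chain but a terminal end beyond
  the fuzz window, requiring corroborating short-read junction support
  (without support the call is ``ambiguous_degradation``);
* ``novel_junction`` — anything else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .models import GeneModel, IsoformChain

logger = logging.getLogger(__name__)

DEFAULT_TERMINAL_FUZZ = 50
DEFAULT_MIN_JUNCTION_READS = 2

CATEGORIES = (
    "known", "novel_junction", "intron_retention", "novel_terminal",
    "ambiguous_degradation",
)

JunctionCounts = Mapping[Tuple[int, int], int]


def intron_chain(exons: Sequence[Tuple[int, int]]) -> Tuple[Tuple[int, int], ...]:
    """Introns of an exon chain as 1-based inclusive intervals."""
    chain = IsoformChain(
        isoform_id="_", gene_id="_", chrom="_", strand="+", exons=tuple(exons)
    )
    return chain.junctions


def junction_support(
    junctions: Sequence[Tuple[int, int]],
    counts: Optional[JunctionCounts],
    min_reads: int = DEFAULT_MIN_JUNCTION_READS,
) -> List[bool]:
    """Per-junction support flags: count >= min_reads (missing count = 0)."""
    if counts is None:
        counts = {}
    return [counts.get(tuple(j), 0) >= min_reads for j in junctions]


@dataclass(frozen=True)
class IsoformClassification:
    isoform_id: str
    category: str
    matched_reference: Optional[str]
    retained_introns: Tuple[int, ...]  # 1-based reference intron indices
    junction_supported: Tuple[bool, ...]
    multi_evidence: bool


@dataclass(frozen=True)
class NestedExonHit:
    guest_gene: str
    host_gene: str
    exon: Tuple[int, int]
    strand_relation: str  # "same" | "opposite"
    tissues: Tuple[str, ...]


def _retention_match(
    cand_junctions: Tuple[Tuple[int, int], ...],
    cand_exons: Tuple[Tuple[int, int], ...],
    ref_junctions: Tuple[Tuple[int, int], ...],
) -> Optional[Tuple[int, ...]]:
    """Reference intron indices retained by the candidate, or None.

    Requires every candidate junction to appear in the reference chain
    (flanking junctions match) and every missing reference intron to be
    covered by a candidate exon (retained region is exonic).
    """
    ref_set = set(ref_junctions)
    if not set(cand_junctions) <= ref_set:
        return None
    if len(cand_junctions) >= len(ref_junctions):
        return None
    retained = []
    cand_set = set(cand_junctions)
    for idx, intron in enumerate(ref_junctions, start=1):
        if intron in cand_set:
            continue
        if not any(start <= intron[0] and intron[1] <= stop for start, stop in cand_exons):
            return None
        retained.append(idx)
    return tuple(retained)


def classify_isoform(
    candidate: IsoformChain,
    references: Iterable[IsoformChain],
    junction_counts: Optional[JunctionCounts] = None,
    terminal_fuzz: int = DEFAULT_TERMINAL_FUZZ,
    min_junction_reads: int = DEFAULT_MIN_JUNCTION_READS,
) -> IsoformClassification:
    """Classify one candidate chain against a reference set.

    The result is deterministic and independent of reference input order
    (references are processed sorted by isoform id).
    """
    refs = sorted(references, key=lambda r: r.isoform_id)
    if not refs:
        logger.warning(
            "empty reference set: %s classified novel_junction by default",
            candidate.isoform_id,
        )
    cand_j = candidate.junctions
    supported = junction_support(cand_j, junction_counts, min_junction_reads)
    multi_evidence = all(supported)

    # exact junction chain matches: known, else terminal variant
    equal_chain = [r for r in refs if r.junctions == cand_j]
    if equal_chain:
        def terminal_diff(ref: IsoformChain) -> int:
            return max(
                abs(candidate.exons[0][0] - ref.exons[0][0]),
                abs(candidate.exons[-1][1] - ref.exons[-1][1]),
            )

        best = min(equal_chain, key=lambda r: (terminal_diff(r), r.isoform_id))
        if terminal_diff(best) <= terminal_fuzz:
            return IsoformClassification(
                isoform_id=candidate.isoform_id, category="known",
                matched_reference=best.isoform_id, retained_introns=(),
                junction_supported=tuple(supported), multi_evidence=multi_evidence,
            )
        category = "novel_terminal" if multi_evidence else "ambiguous_degradation"
        return IsoformClassification(
            isoform_id=candidate.isoform_id, category=category,
            matched_reference=best.isoform_id, retained_introns=(),
            junction_supported=tuple(supported), multi_evidence=multi_evidence,
        )

    # intron retention: junction chain is a reference chain minus >=1 introns
    retention_hits = []
    for ref in refs:
        retained = _retention_match(cand_j, candidate.exons, ref.junctions)
        if retained is not None:
            retention_hits.append((len(retained), ref.isoform_id, ref, retained))
    if retention_hits:
        _, _, ref, retained = min(retention_hits, key=lambda t: (t[0], t[1]))
        return IsoformClassification(
            isoform_id=candidate.isoform_id, category="intron_retention",
            matched_reference=ref.isoform_id, retained_introns=retained,
            junction_supported=tuple(supported), multi_evidence=multi_evidence,
        )

    return IsoformClassification(
        isoform_id=candidate.isoform_id, category="novel_junction",
        matched_reference=None, retained_introns=(),
        junction_supported=tuple(supported), multi_evidence=multi_evidence,
    )


def retention_dependency(
    classifications: Iterable[IsoformClassification],
) -> Dict[Tuple[int, int], bool]:
    """Implication table over retained introns of one gene.

    ``result[(a, b)]`` is True when every observed retention chain that
    retains intron a also retains intron b. Empty when no chain retains
    anything.
    """
    retained_sets = [
        set(c.retained_introns)
        for c in classifications
        if c.category == "intron_retention" and c.retained_introns
    ]
    introns = sorted(set().union(*retained_sets)) if retained_sets else []
    table: Dict[Tuple[int, int], bool] = {}
    for a in introns:
        with_a = [s for s in retained_sets if a in s]
        for b in introns:
            table[(a, b)] = all(b in s for s in with_a)
    return table


def detect_nested_exons(
    guest: GeneModel,
    host: GeneModel,
    chains: Iterable[IsoformChain] = (),
) -> List[NestedExonHit]:
    """Guest exons fully contained in the host gene span (inclusive).

    Exons come from the provided guest chains when given, otherwise from
    the guest gene model. Partial overlaps are not hits.
    """
    if guest.gene_id == host.gene_id or guest.chrom != host.chrom:
        return []
    host_start, host_end = host.span
    relation = "same" if guest.strand == host.strand else "opposite"

    sources: List[Tuple[Tuple[int, int], Tuple[str, ...]]] = []
    chain_list = list(chains)
    if chain_list:
        for chain in chain_list:
            for exon in chain.exons:
                sources.append((exon, chain.tissues))
    else:
        for exon in guest.exons:
            sources.append((exon, ()))

    hits = []
    seen = set()
    for exon, tissues in sources:
        if host_start <= exon[0] and exon[1] <= host_end:
            key = (exon, tissues)
            if key in seen:
                continue
            seen.add(key)
            hits.append(
                NestedExonHit(
                    guest_gene=guest.gene_id, host_gene=host.gene_id,
                    exon=exon, strand_relation=relation, tissues=tissues,
                )
            )
    return hits
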