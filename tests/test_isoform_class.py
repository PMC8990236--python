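import pytest

from ferttx.isoform_class import (
    classify_isoform,
    detect_nested_exons,
    intron_chain,
    junction_support,
    retention_dependency,
)
from ferttx.models import GeneModel, IsoformChain


def _chain(exons, isoform_id="cand", gene_id="g", strand="+", tissues=()):
    return IsoformChain(isoform_id=isoform_id, gene_id=gene_id, chrom="chr1",
                        strand=strand, exons=tuple(exons), tissues=tuple(tissues))


REF_EXONS = ((1, 100), (201, 300), (401, 500), (601, 700))
REF = _chain(REF_EXONS, isoform_id="ref1")
FULL_SUPPORT = {j: 10 for j in REF.junctions}


class TestIntronChain:
    @pytest.mark.parametrize(
        "exons,expected",
        [
            ([(1, 100), (201, 300)], ((101, 200),)),
            ([(1, 100)], ()),
            ([(1, 100), (201, 300), (401, 500)], ((101, 200), (301, 400))),
        ],
    )
    def test_examples(self, exons, expected):
        assert intron_chain(exons) == expected

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            intron_chain([(201, 300), (1, 100)])


class TestJunctionSupport:
    def test_both_supported(self):
        flags = junction_support([(1, 5), (10, 20)], {(1, 5): 5, (10, 20): 7}, min_reads=2)
        assert flags == [True, True]

    def test_missing_count_unsupported(self):
        flags = junction_support([(1, 5), (10, 20)], {(1, 5): 5}, min_reads=2)
        assert flags == [True, False]

    def test_zero_threshold_vacuous(self):
        assert junction_support([(1, 5)], {}, min_reads=0) == [True]


class TestClassifyIsoform:
    def test_identical_chain_is_known(self):
        result = classify_isoform(_chain(REF_EXONS), [REF], FULL_SUPPORT)
        assert result.category == "known"
        assert result.matched_reference == "ref1"

    def test_terminal_difference_within_fuzz_is_known(self):
        cand = _chain(((1, 100), (201, 300), (401, 500), (601, 750)))
        result = classify_isoform(cand, [REF], FULL_SUPPORT, terminal_fuzz=50)
        assert result.category == "known"

    def test_boundary_difference_exactly_fuzz_is_known(self):
        cand = _chain((REF_EXONS[0], REF_EXONS[1], REF_EXONS[2], (601, 750)))
        assert classify_isoform(cand, [REF], FULL_SUPPORT, terminal_fuzz=50).category == "known"
        assert (
            classify_isoform(cand, [REF], FULL_SUPPORT, terminal_fuzz=49).category
            == "novel_terminal"
        )

    def test_retention_of_middle_intron(self):
        # reference introns {1,2,3}; candidate splices {1,3} only
        cand = _chain(((1, 100), (201, 500), (601, 700)))
        result = classify_isoform(cand, [REF], FULL_SUPPORT)
        assert result.category == "intron_retention"
        assert result.retained_introns == (2,)
        assert result.matched_reference == "ref1"

    def test_fully_unspliced_retains_everything(self):
        cand = _chain(((1, 700),))
        result = classify_isoform(cand, [REF], FULL_SUPPORT)
        assert result.category == "intron_retention"
        assert result.retained_introns == (1, 2, 3)

    def test_novel_terminal_long_first_exon_with_support(self):
        cand = _chain((( 1, 100), (201, 300), (401, 500), (601, 1300)))
        result = classify_isoform(cand, [REF], FULL_SUPPORT, terminal_fuzz=50)
        assert result.category == "novel_terminal"
        assert result.multi_evidence

    def test_novel_terminal_without_support_is_ambiguous(self):
        cand = _chain(((1, 100), (201, 300), (401, 500), (601, 1300)))
        result = classify_isoform(cand, [REF], junction_counts={}, terminal_fuzz=50)
        assert result.category == "ambiguous_degradation"
        assert not result.multi_evidence

    def test_moved_splice_site_is_novel_junction(self):
        cand = _chain(((1, 120), (201, 300), (401, 500), (601, 700)))
        result = classify_isoform(cand, [REF], FULL_SUPPORT)
        assert result.category == "novel_junction"
        assert result.matched_reference is None

    def test_empty_reference_set_defaults_to_novel_junction(self):
        result = classify_isoform(_chain(REF_EXONS), [], FULL_SUPPORT)
        assert result.category == "novel_junction"

    def test_reference_order_invariance(self):
        other = _chain(((1, 100), (201, 700)), isoform_id="ref2")
        cand = _chain(((1, 100), (201, 500), (601, 700)))
        forward = classify_isoform(cand, [REF, other], FULL_SUPPORT)
        backward = classify_isoform(cand, [other, REF], FULL_SUPPORT)
        assert forward == backward

    def test_translation_invariance(self):
        shift = 10_000
        cand_exons = ((1, 100), (201, 500), (601, 700))
        base = classify_isoform(_chain(cand_exons), [REF], FULL_SUPPORT)
        moved_ref = _chain(
            tuple((s + shift, e + shift) for s, e in REF_EXONS), isoform_id="ref1"
        )
        moved_counts = {(s + shift, e + shift): 10 for s, e in REF.junctions}
        moved = classify_isoform(
            _chain(tuple((s + shift, e + shift) for s, e in cand_exons)),
            [moved_ref], moved_counts,
        )
        assert moved.category == base.category
        assert moved.retained_introns == base.retained_introns


class TestRetentionDependency:
    def _retained(self, *sets):
        return [
            classify_isoform(
                _chain(self._fuse(retained), isoform_id=f"c{i}"), [REF], FULL_SUPPORT
            )
            for i, retained in enumerate(sets)
        ]

    @staticmethod
    def _fuse(retained):
        exons = [list(REF_EXONS[0])]
        for i in range(1, len(REF_EXONS)):
            if i in retained:
                exons[-1][1] = REF_EXONS[i][1]
            else:
                exons.append(list(REF_EXONS[i]))
        return tuple(tuple(e) for e in exons)

    def test_asymmetric_implication(self):
        # chains retaining {2} and {2,3}: 3=>2 true, 2=>3 false
        table = retention_dependency(self._retained({2}, {2, 3}))
        assert table[(3, 2)] is True
        assert table[(2, 3)] is False

    def test_single_chain_diagonal_only(self):
        table = retention_dependency(self._retained({1}))
        assert table == {(1, 1): True}

    def test_no_retention_gives_empty_table(self):
        known = classify_isoform(_chain(REF_EXONS), [REF], FULL_SUPPORT)
        assert retention_dependency([known]) == {}


class TestNestedExons:
    HOST = GeneModel(gene_id="host", chrom="chr1", strand="-",
                     exons=((50, 240), (260, 500)), cds_start=60, cds_end=490)

    def _guest(self, exons, strand="+"):
        return GeneModel(gene_id="guest", chrom="chr1", strand=strand,
                         exons=exons, cds_start=exons[0][0], cds_end=exons[-1][1])

    def test_contained_exon_opposite_strand(self):
        guest = self._guest(((100, 200),))
        hits = detect_nested_exons(guest, self.HOST)
        assert len(hits) == 1
        assert hits[0].strand_relation == "opposite"
        assert hits[0].exon == (100, 200)

    def test_partial_overlap_is_not_a_hit(self):
        guest = self._guest(((400, 600),))
        assert detect_nested_exons(guest, self.HOST) == []

    def test_exon_equal_to_host_span_is_a_hit(self):
        guest = self._guest(((50, 500),))
        assert len(detect_nested_exons(guest, self.HOST)) == 1

    def test_span_mode_ignores_host_introns(self):
        # exon inside the host's intron (241-259) still nests in the span
        guest = self._guest(((245, 255),))
        assert len(detect_nested_exons(guest, self.HOST)) == 1

    def test_chains_supply_exons_and_tissues(self):
        guest = self._guest(((100, 200),))
        chain = _chain(((20, 40), (100, 200)), gene_id="guest", tissues=("blood",))
        hits = detect_nested_exons(guest, self.HOST, [chain])
        assert len(hits) == 1
        assert hits[0].exon == (100, 200)
        assert hits[0].tissues == ("blood",)

    def test_same_gene_is_never_nested_in_itself(self):
        assert detect_nested_exons(self.HOST, self.HOST) == []
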