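import math

import numpy as np
import pytest

from ferttx.errors import ConfigError, PlacementError
from ferttx.synthetic_data import (
    NestedExonSpec,
    PlantedIsoform,
    SyntheticConfig,
    default_isoform_fixture,
    generate_annotation,
    generate_cage_coverage,
    generate_isoform_reads,
    generate_rnaseq_counts,
    generate_wgs_counts,
    simulate,
    write_simulation,
)


class TestConfigValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SyntheticConfig(seed=1, reference_bias=1.5)

    def test_effect_fraction_bounds(self):
        with pytest.raises(ValueError):
            SyntheticConfig(seed=1, ase_effects={0: {"liver": 1.2}})

    def test_effect_unknown_tissue(self):
        with pytest.raises(ValueError, match="unknown tissue"):
            SyntheticConfig(seed=1, tissues=("liver",), ase_effects={0: {"brain": 0.8}})


class TestAnnotation:
    def test_zero_utr_single_exon_cds_starts_at_transcript_start(self):
        config = SyntheticConfig(
            seed=2, n_genes=1, exons_per_gene=(1, 1), strand_mix=0.0,
            tss_offsets={"g1": 0},
        )
        genes, truth = generate_annotation(config)
        gene = genes[0]
        assert gene.cds_start == gene.transcript_start
        assert truth.true_utr_lengths["g1"] == 0
        assert truth.true_tss["g1"] == gene.cds_start

    def test_planted_utr_is_realizable(self):
        config = SyntheticConfig(seed=2, n_genes=2, tss_offsets={"g1": 350, "g2": 7})
        genes, truth = generate_annotation(config)
        for gene in genes[:2]:
            utr = truth.true_utr_lengths[gene.gene_id]
            tss = truth.true_tss[gene.gene_id]
            assert abs(tss - gene.five_prime_pos) == utr

    def test_genes_do_not_overlap(self, small_config):
        genes, _ = generate_annotation(small_config)
        spans = sorted(g.span for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2

    def test_nested_pair_overlaps_as_requested(self, nested_config):
        genes, truth = generate_annotation(nested_config)
        by_id = {g.gene_id: g for g in genes}
        host, guest = by_id["g2"], by_id["gx"]
        nested = truth.nested_hits[0]
        exon = tuple(nested["exon"])
        assert host.span[0] <= exon[0] and exon[1] <= host.span[1]
        assert exon in guest.exons
        assert guest.strand != host.strand
        assert nested["strand_relation"] == "opposite"

    def test_unknown_tss_offset_gene_rejected(self):
        with pytest.raises(ConfigError):
            generate_annotation(SyntheticConfig(seed=1, n_genes=1, tss_offsets={"g9": 5}))

    def test_infeasible_placement_raises(self):
        with pytest.raises(PlacementError):
            generate_annotation(SyntheticConfig(seed=1, n_genes=50, chrom_length=10_000))

    def test_deterministic_gff3_output(self, tmp_path, small_config):
        from ferttx.io import format_gff3

        first, _ = generate_annotation(small_config)
        second, _ = generate_annotation(small_config.model_copy(deep=True))
        assert format_gff3(first) == format_gff3(second)


class TestWgsCounts:
    def test_unbiased_het_fraction_within_three_se(self):
        config = SyntheticConfig(seed=4, n_genes=1, wgs_depth_mean=10_000.0,
                                 snp_density=2.0, het_fraction=1.0)
        _, truth = generate_annotation(config)
        records = generate_wgs_counts(truth, config)
        assert records
        for record in records:
            frac = record.count_a / record.total
            se = math.sqrt(0.25 / record.total)
            assert abs(frac - 0.5) <= 3 * se

    def test_homozygous_locus_monoallelic_without_error_model(self, small_config):
        config = small_config.model_copy(update={"het_fraction": 0.0, "snp_density": 2.0})
        _, truth = generate_annotation(config)
        for record in generate_wgs_counts(truth, config):
            assert record.count_a == 0

    def test_degenerate_bias_silences_allele_b(self):
        config = SyntheticConfig(seed=4, n_genes=2, reference_bias=1.0,
                                 het_fraction=1.0, snp_density=2.0)
        _, truth = generate_annotation(config)
        for record in generate_wgs_counts(truth, config):
            assert record.count_b == 0

    def test_error_model_adds_reference_reads_at_hom_loci(self):
        config = SyntheticConfig(seed=4, n_genes=2, het_fraction=0.0,
                                 snp_density=3.0, error_rate=0.2,
                                 wgs_depth_mean=200.0)
        _, truth = generate_annotation(config)
        records = generate_wgs_counts(truth, config)
        assert sum(r.count_a for r in records) > 0


class TestRnaCounts:
    def test_planted_fraction_within_three_se(self):
        config = SyntheticConfig(seed=6, n_genes=1, snp_density=1.0,
                                 het_fraction=1.0, rna_depth_mean=400.0,
                                 tissues=("liver",), ase_effects={0: {"liver": 0.8}})
        genes, truth = generate_annotation(config)
        records, _ = generate_rnaseq_counts(genes, truth, config)
        target = next(
            r for r in records
            if r.pos == truth.het_loci[0]["pos"] and r.tissue == "liver"
        )
        frac = target.count_a / target.total
        se = math.sqrt(0.8 * 0.2 / target.total)
        assert abs(frac - 0.8) <= 3 * se

    def test_monoallelic_effect(self):
        config = SyntheticConfig(seed=6, n_genes=1, snp_density=1.0,
                                 het_fraction=1.0, rna_depth_mean=50.0,
                                 tissues=("liver",), ase_effects={0: {"liver": 1.0}})
        genes, truth = generate_annotation(config)
        records, _ = generate_rnaseq_counts(genes, truth, config)
        target = next(
            r for r in records
            if r.pos == truth.het_loci[0]["pos"] and r.tissue == "liver"
        )
        assert target.count_b == 0

    def test_effect_at_missing_het_locus_rejected(self, small_config):
        config = small_config.model_copy(update={"ase_effects": {999: {"liver": 0.8}}})
        genes, truth = generate_annotation(config)
        with pytest.raises(ConfigError, match="not a planted het locus"):
            generate_rnaseq_counts(genes, truth, config)

    def test_totals_conserve_library_size(self, small_config):
        genes, truth = generate_annotation(small_config)
        _, totals = generate_rnaseq_counts(genes, truth, small_config)
        sums = totals.groupby(["tissue", "technology"]).agg(
            total=("mapped_reads", "sum"), lib=("library_total", "first")
        )
        assert (sums["total"] == sums["lib"]).all()


class TestCageCoverage:
    def test_width_zero_is_a_spike(self, small_config):
        config = small_config.model_copy(update={"cage_peak_width": 0})
        genes, truth = generate_annotation(config)
        coverage = generate_cage_coverage(genes, truth, config)
        for gene in genes:
            rows = coverage[coverage["strand"] == gene.strand]
            gene_rows = rows[rows["pos"] == truth.true_tss[gene.gene_id]]
            assert len(gene_rows) == 1
            assert int(gene_rows.iloc[0]["tag_count"]) == config.cage_tags_per_gene

    def test_planted_utr_81_mode_is_81_bp_upstream_of_cds_start(self):
        config = SyntheticConfig(seed=8, n_genes=1, strand_mix=0.0,
                                 tss_offsets={"g1": 81})
        genes, truth = generate_annotation(config)
        coverage = generate_cage_coverage(genes, truth, config)
        gene = genes[0]
        mode_row = coverage.loc[coverage["tag_count"].idxmax()]
        assert int(mode_row["pos"]) == gene.five_prime_pos - 81

    def test_unexpressed_gene_has_no_tags(self, small_config):
        config = small_config.model_copy(update={"unexpressed_genes": ("g2",)})
        genes, truth = generate_annotation(config)
        coverage = generate_cage_coverage(genes, truth, config)
        tss = truth.true_tss["g2"]
        window = coverage[(coverage["pos"] > tss - 200) & (coverage["pos"] < tss + 200)]
        gene = next(g for g in genes if g.gene_id == "g2")
        assert window[window["strand"] == gene.strand].empty


class TestIsoformGeneration:
    def test_known_chain_equals_reference(self):
        config = SyntheticConfig(
            seed=9, n_genes=1, exons_per_gene=(4, 4),
            planted_isoforms=(PlantedIsoform(gene="g1", category="known"),),
        )
        genes, truth = generate_annotation(config)
        refs, cands, _ = generate_isoform_reads(genes, truth, config)
        assert cands[0].junctions == refs[0].junctions
        assert cands[0].exons == genes[0].exons

    def test_retention_fuses_exons_and_shortens_junctions(self):
        config = SyntheticConfig(
            seed=9, n_genes=1, exons_per_gene=(4, 4),
            planted_isoforms=(
                PlantedIsoform(gene="g1", category="intron_retention",
                               retained_introns=(2,)),
            ),
        )
        genes, truth = generate_annotation(config)
        refs, cands, _ = generate_isoform_reads(genes, truth, config)
        ref, cand = refs[0], cands[0]
        assert len(cand.junctions) == len(ref.junctions) - 1
        # exon2-exon3 fused
        assert cand.exons[1] == (ref.exons[1][0], ref.exons[2][1])

    def test_novel_terminal_moves_5p_boundary_only(self):
        config = SyntheticConfig(
            seed=9, n_genes=1, exons_per_gene=(3, 3), strand_mix=0.0,
            planted_isoforms=(
                PlantedIsoform(gene="g1", category="novel_terminal",
                               terminal_end="5p", terminal_delta=600),
            ),
        )
        genes, truth = generate_annotation(config)
        refs, cands, _ = generate_isoform_reads(genes, truth, config)
        ref, cand = refs[0], cands[0]
        assert cand.junctions == ref.junctions
        assert cand.exons[0][0] == ref.exons[0][0] - 600

    def test_unsupported_chain_junctions_absent_from_counts(self):
        config = SyntheticConfig(
            seed=9, n_genes=2, exons_per_gene=(3, 3),
            planted_isoforms=(
                PlantedIsoform(gene="g1", category="novel_junction",
                               junction_index=1, junction_shift=15,
                               supported=False),
            ),
        )
        genes, truth = generate_annotation(config)
        refs, cands, counts = generate_isoform_reads(genes, truth, config)
        moved = cands[0].junctions[0]
        assert (cands[0].chrom, moved[0], moved[1], cands[0].strand) not in counts
        # reference junctions are still supported
        ref_j = refs[0].junctions[0]
        assert (refs[0].chrom, ref_j[0], ref_j[1], refs[0].strand) in counts

    def test_out_of_range_retention_index_rejected(self):
        config = SyntheticConfig(
            seed=9, n_genes=1, exons_per_gene=(2, 2),
            planted_isoforms=(
                PlantedIsoform(gene="g1", category="intron_retention",
                               retained_introns=(5,)),
            ),
        )
        genes, truth = generate_annotation(config)
        with pytest.raises(ConfigError, match="out of range"):
            generate_isoform_reads(genes, truth, config)

    def test_unknown_gene_rejected(self):
        config = SyntheticConfig(
            seed=9, n_genes=1,
            planted_isoforms=(PlantedIsoform(gene="g77", category="known"),),
        )
        genes, truth = generate_annotation(config)
        with pytest.raises(ConfigError, match="unknown gene"):
            generate_isoform_reads(genes, truth, config)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path, nested_config):
        config = nested_config.model_copy(
            update={"planted_isoforms": (PlantedIsoform(gene="g1", category="known"),)}
        )
        paths1 = write_simulation(simulate(config), tmp_path / "a")
        paths2 = write_simulation(simulate(config.model_copy(deep=True)), tmp_path / "b")
        for name, p1 in paths1.items():
            assert p1.read_bytes() == paths2[name].read_bytes(), name

    def test_different_seed_changes_counts(self, small_config):
        res1 = simulate(small_config)
        res2 = simulate(small_config.model_copy(update={"seed": 999}))
        counts1 = [(r.count_a, r.count_b) for r in res1.wgs_counts]
        counts2 = [(r.count_a, r.count_b) for r in res2.wgs_counts]
        assert counts1 != counts2


class TestTruthSufficiency:
    def test_truth_round_trips_through_json(self, tmp_path, nested_config):
        from ferttx.io import read_truth, write_truth
        from ferttx.synthetic_data import SyntheticTruth

        config = nested_config.model_copy(update={"ase_effects": {0: {"liver": 0.9}}})
        result = simulate(config)
        path = tmp_path / "truth.json"
        write_truth(result.truth.to_dict(), path)
        back = SyntheticTruth.from_dict(read_truth(path))
        assert back.to_dict() == result.truth.to_dict()
        assert back.ase_effects == {0: {"liver": 0.9}}

    def test_default_fixture_has_twenty_plus_isoforms_all_categories(self):
        config = default_isoform_fixture()
        result = simulate(config)
        categories = list(result.truth.isoform_categories.values())
        assert len(categories) >= 20
        assert {"known", "novel_junction", "intron_retention", "novel_terminal"} <= set(categories)
        assert result.truth.nested_hits
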