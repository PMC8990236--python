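# ferttx

Characterization of fertility-gene transcription from three expression
assays, as a tested Python pipeline:

- **variant_sites** — heterozygous-site calling from biallelic allele
  counts (both alleles in ≥ 2 reads), SNP region classification
  (5′UTR / CDS / 3′UTR / intron / intergenic, strand-aware, optionally
  bounded by a CAGE-derived TSS), and the haplotype divergence statistic
  `D = (Ho + He/2) / 2,700,000,000` with homology `100·(1 − D)`.
- **ase** — Pearson chi-squared allele-specific-expression testing (df = 1,
  no continuity correction) under an equal-allele null and a WGS-allele-ratio
  null (`E_i = R·G_i/ΣG`), combined into a two-stage screen
  (p < 1e-4 under the equal null, confirmed at p < 1e-2 under the WGS ratio).
- **expression** — reads-per-million (`RPM = T/A × 1,000,000`) per gene ×
  tissue × technology, CDS-length-corrected RPKM, detection flags, and
  per-(tissue, technology) rankings.
- **tss** — CAGE tag-cluster peak calling in gene promoter windows and
  5′UTR length derivation (`|peak stop − gene 5′ position|`, where *stop* is
  the cluster boundary farther upstream of the gene; a center-of-peak rule
  is available for comparison).
- **isoform_class** — long-read exon-chain classification against a
  reference annotation (known / novel_junction / intron_retention /
  novel_terminal, with an ambiguous_degradation fallback when short-read
  junction support is missing), intron-retention dependency tables, and
  detection of exons nested inside another gene's span.
- **synthetic_data** — a fully seeded generator (annotation, WGS/RNA allele
  counts, CAGE coverage, isoform chains) with planted truth, so every stage
  is scored without external data.
- **pipeline / cli** — end-to-end orchestration with a consolidated report
  and truth scoring on synthetic runs.

## CLI

Every stage runs standalone on plain-text tables (TSV, GFF3, BED12):

```sh
# generate synthetic data + truth record
ferttx simulate --config cfg.yaml --out sim/

# individual stages
ferttx variants   --wgs sim/wgs_counts.tsv --annotation sim/annotation.gff3 --out var/
ferttx ase        --rna sim/rna_counts.tsv --wgs sim/wgs_counts.tsv --out ase/
ferttx expression --gene-totals sim/gene_totals.tsv --annotation sim/annotation.gff3 --out expr/
ferttx tss        --coverage sim/cage_coverage.tsv --annotation sim/annotation.gff3 --out tss/ --window 5000
ferttx isoforms   --candidates sim/isoforms.bed12 --annotation sim/annotation.gff3 \
                  --junction-counts sim/junction_counts.tsv --out iso/ --terminal-fuzz 50

# full pipeline from one YAML config (synthetic or real inputs)
ferttx run --config pipeline.yaml --out out/
```

A synthetic `cfg.yaml` is any `SyntheticConfig` mapping, e.g.

```yaml
seed: 1
n_genes: 5
tissues: [liver, lung]
ase_effects: {0: {liver: 0.9}}
nested_exon_spec: {host_gene: g2, guest_gene: gx}
```

and a pipeline config wraps it under a `synthetic:` key (or provides an
`inputs:` map of file paths instead — exactly one of the two).

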