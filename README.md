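# paleoroh

Analysis machinery for evaluating imputed low-coverage diploid genomes and
studying runs of homozygosity (ROH):

- **synthetic** — simulate a mosaic haplotype panel, plant autozygous tracts
  with known coordinates in diploid individuals, and emit imputation-like
  corrupted callsets (class-dependent genotype errors that worsen at low MAF,
  a monotone INFO score, Poisson depth, allelic depths). Reads/writes VCF.
- **filters** — validation-callset depth/allele-balance filtering, panel
  missingness filtering, MAF/INFO post-imputation cleanup, transversion-only
  restriction.
- **concordance** — truth-vs-imputed genotype confusion, per-class error
  rates, non-reference discordance (NRD), and r² by MAF bin under INFO-score
  sweeps.
- **roh_caller** — sliding-window ROH caller (50-SNP windows, ≤1 het,
  ≤5 missing, 5% hit-fraction threshold, 500-kb minimum span/gap, density
  cap), with a transversion-only mode.
- **roh_accuracy** — base-pair and segment confusion of predicted vs truth
  ROH; F1, MCC, normalised MCC, sensitivity, specificity, FDR.
- **inbreeding** — F_ROH with a short/long split at 1.6 Mb; exact (ties-aware)
  Mann–Whitney rank-sum cohort comparisons.
- **landscape** — 500-kb windowed ROH prevalence per cohort, depth-outlier
  window exclusion (mean ± 2 sd), ROH-desert detection (<5% in every cohort),
  and hypergeometric gene-category enrichment with gene-length-corrected
  permutation FWER.
- **pca** — PC space from a reference genotype matrix (p(1−p) scaling),
  least-squares projection of sparse samples, eigenvalue-weighted PC
  distances.
- **pipeline** — end-to-end benchmark (coverage sweep) and analysis
  (cohorts → F_ROH → deserts → enrichment) modes with seeded, manifest-checked
  outputs.

## CLI

```sh
paleoroh simulate  --seed 1 --outdir sim --n-samples 2 --target-froh 0.1
paleoroh benchmark --seed 1 --outdir bench [--config cfg.yaml]
paleoroh roh       --vcf sim/sample0.imputed.vcf --out roh.tsv [--transversions-only]
paleoroh froh      --bed a.roh.bed --bed b.roh.bed --chrom-sizes chrom.sizes \
                   --metadata meta.tsv --out froh.tsv
paleoroh landscape --bed a.roh.bed --bed b.roh.bed --chrom-sizes chrom.sizes \
                   --metadata meta.tsv --outdir ls
paleoroh enrich    --deserts ls/deserts.bed --genes genes.bed \
                   --categories gene2cat.tsv --background retained.bed --out enr.tsv
paleoroh pca       --reference panel.vcf --project sample.vcf --outdir pca
```

YAML config keys mirror `pipeline.RunConfig` (e.g. `coverage_levels`,
`roh_params`, `base_model`); see `paleoroh/pipeline.py`.

## File formats

VCF v4.2 (FORMAT `GT:DP:AD:PR`, INFO `AF`/`INFO`), BED-like ROH TSVs,
two-column chrom-sizes TSVs, sample-metadata TSV (`sample`, `cohort`,
optional `age_bp`, `region`), gene BED with gene names, and a two-column
gene→category TSV.
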