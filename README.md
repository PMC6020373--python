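# bloodtx

Comparative analysis of whole-blood transcriptomes across two inflammatory
disease cohorts — for example juvenile idiopathic arthritis (JIA, with
oligoarticular / polyarticular / systemic sub-types) versus inflammatory
bowel disease (IBD, Crohn's disease / ulcerative colitis) — from gene-level
RNA-seq counts and genotype dosages.  The package is aimed at statistical
geneticists who want to ask: *are the genetic effects on blood gene
expression the same in two diseases, and do the disease-associated alleles
leave a measurable transcriptome-level risk signature?*

## What it computes

- **Preparation** — FPKM-based expression filtering (genes with > 10
  individuals at > 6 reads and FPKM > 0.1), log2-CPM normalization,
  surrogate-variable-style removal of latent factors while *protecting*
  the disease design, and PLINK-style genotype QC (biallelic, Hardy-
  Weinberg exact/χ² p ≥ 10⁻³, MAF ≥ 1%, missingness ≤ 5%).
- **Signatures** — immune-axis and blood-transcript-module scores as the
  first principal component of each gene set (genes standardized, sign
  oriented to positive mean loading), Ward clustering of samples,
  principal variance component analysis (PVCA), two-group differential
  expression with Benjamini-Hochberg control, and one-way ANOVA of scores
  across sub-types.
- **cis-eQTL mapping** — all SNP-gene pairs within ±250 kb of the gene
  body, additive OLS per pair (β in expression SD per ALT-allele copy),
  one peak eSNP per gene, empirical FDR by expression permutation, and a
  MAF/outlier diagnostic that refits each call after removing the most
  extreme minor-homozygote value.
- **Genotype-by-disease interaction** — candidates pooled as the union of
  peaks significant in either cohort, then refit jointly as
  `expr ~ g + d + g·d`; the Wald p of the product term tests whether the
  regulatory effect differs between diseases.  Cross-cohort effect-size
  correlation and discovery-stratified |β| ratios quantify sharing and
  winner's-curse asymmetry.
- **Colocalization** — Wakefield approximate Bayes factors per SNP and the
  standard five-hypothesis posterior (H0 none, H1/H2 one trait only, H3
  distinct causal variants, H4 one shared causal variant) with priors
  p1 = p2 = 10⁻⁴, p12 = 10⁻⁵.
- **Transcriptional risk score (TRS)** — for genes validated by coloc H4,
  each sample's score is Σ polarity × z(expression), where polarity is +1
  when the GWAS risk allele increases expression and −1 when it decreases
  it (alleles harmonized across datasets, strand flips resolved); group
  contrasts are reported in pooled-SD units (∆s.d.) with ANOVA.
- **Synthetic cohorts** — `bloodtx.simulate` generates genotypes in HWE
  with first-order LD blocks, co-expression modules on latent immune-like
  axes, planted shared or disease-specific cis-eQTL, per-group mean
  shifts, latent confounders, and GWAS summary statistics with known risk
  alleles, so every stage is testable against ground truth.

## Worked example

Run the whole pipeline on a synthetic 202-sample cohort (six disease
groups, 60 genes, 15 planted eQTL that are strong in cohort A (β = 0.8)
and weak in cohort B (β = 0.2), every locus also a GWAS risk locus, and an
inflammatory-group mean shift on the first co-expression module):

```python
from bloodtx.pipeline import run_pipeline

manifest = run_pipeline({
    "out_dir": "demo", "seed": 7,
    "sim": {"n_genes": 60, "n_snps": 240, "n_eqtl": 15, "beta": 0.8,
            "beta_b": 0.2, "shared": False, "gwas_frac": 1.0,
            "group_shift_plan": {0: {"sJIA": 1.0, "CD": 1.2, "UC": 1.2}}},
    "eqtl": {"n_perms": 20},
})
print(manifest["counts"])
```

prints (stage → key counts):

```
simulate:     {n_samples: 202, n_snps: 240, n_genes: 60}
preprocess:   {genes_kept: 60, snps_kept: 239}
signatures:   {n_modules: 3, anova_min_p: 9.2e-78}
eqtl:         {A: 11, B: 0}
interaction:  {n_candidates: 11, n_called_fdr: 9, n_nominal: 6}
coloc:        {n_loci: 15, n_h4_gt_0.5: 14}
trs:          {n_definition_genes: 14, anova_p: 0.00026}
```

Reading this: the strong cohort-A effects yield 11 significant peak eSNPs
in A and none in B (β = 0.2 is underpowered at n = 75), the joint model
calls 9 of the 11 pooled candidates as genotype-by-disease interactions at
FDR 10%, 14 of 15 planted loci colocalize with their GWAS signal at
PP(H4) > 0.5, and the resulting 14-gene TRS separates the disease groups
(ANOVA p ≈ 3 × 10⁻⁴).  `demo/interactions.tsv` mirrors the per-locus
table — per-disease marginal betas and the interaction p/q — e.g.

```
gene_id  snp_id   beta_disease0  beta_disease1  p_interaction  called
G0006    rs00026  0.718          0.093          0.0056         True
G0007    rs00030  0.830          0.219          0.0104         True
```

and `demo/trs_contrast.json` reports each group's ∆s.d. against healthy
controls (here CD: ∆s.d. = 1.00, p = 0.0023).  Every output directory
also contains `manifest.json` with parameters, seeds, row counts, and
SHA-256 hashes of all files; rerunning with the same seed reproduces the
hashes exactly.

The same stages are available from the shell:

```bash
bloodtx simulate --out fixtures --seed 7 --n-eqtl 15
bloodtx preprocess --counts fixtures/counts.tsv --bed fixtures/genes.bed \
    --vcf fixtures/genotypes.vcf --meta fixtures/metadata.tsv --out-dir prep
bloodtx eqtl --expr prep/expression_adjusted.tsv --bed fixtures/genes.bed \
    --vcf fixtures/genotypes.vcf --perms 100 --out peaks.tsv
bloodtx pipeline run --config pipeline.yaml
```

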