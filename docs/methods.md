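# Methods

This note documents the statistical models implemented in `bloodtx`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that matter for reproducibility.

## Data model

Expression is a genes × samples matrix with a unit tag that moves only
forward through the declared chain raw-count → FPKM → log-normalized →
z-score; gene annotation carries 1-based inclusive coordinates and a
length in bp.  Genotypes are SNPs × samples additive ALT-allele dosages in
{0, 1, 2} with `NaN` for missing calls and 1-based positions.  After QC,
missing dosages are mean-imputed for all regression stages; this is
benign because QC caps missingness at 5%.

## Preparation

**Filtering.**  A gene is retained iff strictly more than 10 individuals
have strictly more than 6 reads *and* its FPKM criterion exceeds 0.1.
The FPKM criterion is the across-sample mean by default (`fpkm_mode=
"any"` switches to the most permissive single-sample reading); the
detection thresholds are deliberately strict inequalities.  The filter is
idempotent: removing genes only shrinks library sizes, which can only
raise the FPKM of survivors.

**Normalization** is log2(CPM + 1).  A trimmed-mean-of-M-values scale
factor was considered and rejected: every downstream model here is a
linear model on log scale, and for those the simple library-size scaling
suffices while keeping proportional samples exactly identical.  The unit
tag records the decision.

**Latent-factor adjustment.**  Technical structure is removed with a
surrogate-variable-style two-step that protects the design: (1) each
gene is residualized on the protected design (disease sub-type, plus any
medication / disease-duration columns supplied the same way); (2) the top
`n_factors` (default 15) principal components of the residual matrix are
taken as latent factors; (3) genes are refit jointly on
[protected design, factors] and only the factor component is subtracted.
The two-step residualization is an explicit approximation to iterative
surrogate-variable estimation; its guarantee — protected group means are
preserved up to numerical tolerance while orthogonal confounders are
removed — is what the tests verify.  Requesting `n_factors` at or above
the residual rank is an error rather than a silent truncation.

**Genotype QC** drops non-biallelic variants, HWE violations at p < 10⁻³,
MAF < 1%, and missingness > 5%.  The HWE test is the conditional exact
test on heterozygote counts when any expected genotype class is below 5,
and the 1-df χ² otherwise; the exact branch is validated in the tests
against a Monte-Carlo allele-pairing oracle.

## Signature analyses

Axis and module scores are the first principal component over the set's
genes after per-gene standardization, which makes the score invariant to
per-gene affine rescaling.  The PC sign is a convention; we orient the
mean gene loading positive, so a module of positively co-regulated genes
scores high when its genes are high.  The proportion of set variance
explained by PC1 is reported alongside (well-defined immune axes
typically explain upward of 70%).

PVCA decomposes each of the top `n_pc` (default 5) expression PCs by a
sequential (type-I) ANOVA over the caller-ordered categorical factors and
weights each factor's η² by the PC's share of total variance; the
returned vector includes a residual term closing the budget to exactly 1.
A random-effects/REML variant was rejected for transparency — with the
factor order fixed by the caller, sequential sums of squares are exact
and easily audited.  Nested designs (sub-type within disease) are
expressed by passing the combined factor.  Aliased factors raise an error
naming the offending column.

Sample clustering is Ward linkage on Euclidean distances of z-scores, cut
at k = 6 by default, with a per-sub-type cluster membership table whose
rows sum to 1.  Differential expression is a normal-theory two-group
contrast on log scale with BH adjustment — a deliberate simplification of
count-based negative-binomial engines, adequate here because the DE step
only feeds direction-split gene lists; constant genes get p = 1 and a
flag rather than an exception.

## cis-eQTL mapping

Pairing takes every SNP with position in [start − 250 kb, stop + 250 kb],
inclusive at both bounds.  Each pair is fit by OLS,
`expr ~ 1 + dosage (+ covariates)`, with β in expression SD per ALT
copy and a two-sided t-test p floored at 10⁻³⁰⁰.  A kinship-based mixed
model was considered and rejected: at cohort sizes near 50–110 the
kinship estimate is noisy, and the interaction stage is defined on the
plain joint linear model anyway; genotype-PC covariates are supported
instead.  One peak (minimum-p) eSNP is retained per gene; conditional
secondary-signal analysis is out of scope.

The empirical FDR at the calling threshold (default p < 10⁻⁴) is
mean(permutation peak hits)/observed peak hits over `n_perms` (default
100) sample-label permutations of the expression matrix, one shared
shuffle per round.  The MAF diagnostic reports the correlation between
MAF and −log10 p across calls and refits every call after deleting the
single most extreme expression value among minor-allele homozygotes;
calls that then lose significance are flagged — the classic signature of
a spurious low-MAF eQTL driven by one outlier.

## Genotype-by-disease interaction

Candidates are the union of peak pairs significant in either cohort,
with provenance (A-only / B-only / both).  The joint model is
`expr ~ g + d + g·d (+ covariates)` on the pooled samples with disease as
a 0/1 indicator; the interaction p is the Wald t-test of the product
term (equivalent to the LRT for OLS).  Because the model is saturated in
disease, the per-disease marginal slopes follow exactly from the joint
coefficients (β_ref = β_g, β_other = β_g + β_gxd), and swapping the
disease coding negates β_gxd without changing its p.  BH at FDR 10%
controls the candidate list; the nominal-p count at 0.02 is reported for
comparability.

For effect-size comparison we report the cross-cohort Pearson r of betas
and, per discovery stratum, the mean |β| ratio of discovery over the
other cohort.  Under fully shared effects with estimation noise the
observed r attenuates to var(β)/√((var(β)+mse_A)(var(β)+mse_B)) — the
two-cohort form of the usual var/(var+mean se²) — and the discovery ratio
still exceeds 1 purely through winner's curse; both facts are used as
oracles in the tests and the output carries the caveat.

## Colocalization

Per-SNP evidence is the Wakefield log approximate Bayes factor
0.5[log(V/(V+W)) + z²·W/(V+W)] with prior effect SD 0.15 for
quantitative traits and 0.2 (log-odds) for case-control.  For
quantitative traits V = se²; for case-control traits V is the
effective-sample-size proxy 1/(n·φ(1−φ)), so the posterior depends on the
summaries only through z and n and is invariant to joint rescaling of
betas and SEs — the natural convention when case-control summary scales
vary across sources.  Locus posteriors over H0–H4 come from summing
single-causal-variant configurations in log space with priors
p1 = p2 = 10⁻⁴ and p12 = 10⁻⁵ (exposed as flags; the per-SNP H4
credible contributions are returned for locus plots).  Only SNPs present
in both series are analyzed.

## Transcriptional risk score

Genes enter the TRS definition when their locus colocalizes with the
GWAS signal at PP(H4) ≥ 0.5 (the cutoff is a flag; the H4-validated
principle is fixed).  GWAS effect alleles are harmonized to the eQTL ALT
allele, trying a direct match, an allele swap, and a strand complement in
that order; unresolvable records are dropped with a warning rather than
guessed.  Polarity is +1 iff the risk allele increases expression.  A
sample's TRS is Σ polarity × z over the definition genes present
(missing genes are reported, never silently skipped); z-scores are
computed across all samples by default, on the latent-factor-adjusted
matrix, with a flag to standardize to a reference group or to use the
unadjusted matrix instead.  ∆s.d. between groups is pooled-SD Cohen's d
with a two-sided t-test, plus an overall ANOVA.

## Synthetic cohorts

The generator emulates the structure such a two-disease pediatric study
needs for method validation, with the default cohort of 202 samples in
six groups (12 controls; 43/46/26 oligoarticular/polyarticular/systemic
arthritis; 60/15 Crohn's/colitis), and all randomness drawn from one
PCG64 stream per component seeded by `SimConfig.seed` (fixed seed ⇒
bit-identical output).

- **Genotypes**: per-SNP ALT frequency uniform on `maf_range`; within an
  LD block each haplotype copies the previous SNP's allele with
  probability `ld_rho` (else redraws), and the genotype is the sum of two
  independent haplotypes — HWE by construction, adjacent-SNP correlation
  equal to `ld_rho` when frequencies match.  Genes are spaced 1 Mb apart
  so cis windows are disjoint; SNPs are placed in contiguous per-gene
  chunks, and blocks never span genes.
- **Expression** is simulated directly on log scale: module loading ×
  latent factor + per-group shift + planted eQTL β(disease) × dosage +
  confounder loadings × confounder + N(0, noise_sd).  A raw-count view is
  produced by exponentiating against uniform gene baselines and sampling
  reads multinomially at a Poisson library depth, for exercising the
  count-level filters.  Planted effect magnitudes default to |β| = 0.8
  with random signs — sign variation is what makes recovery correlations
  well defined.
- **GWAS summaries**: each flagged risk locus gets a causal log-odds
  effect drawn from U(0.10, 0.20) at 10,000 cases / 10,000 controls,
  positive on the designated risk allele, and the other cis SNPs receive
  z ≈ r·z_causal + N(0, 1) through the realized LD, with SEs from the
  standard case-control approximation.
- The TRS scenario plants a per-gene case shift of d/√G residual SDs so
  the summed polarized score has Cohen's d ≈ d (default d = 1.1 over 39
  genes at 75 cases vs 12 controls).

What it does **not** emulate: sequence-level reads, population structure
or admixture, realistic long-range LD (first-order copying is enough for
shared- vs distinct-causal coloc scenarios but has geometric r² decay),
cell-type composition effects, or negative-binomial count dispersion.
Passing the recovery tests therefore demonstrates correctness of the
estimators under their assumed models, not robustness to those real-data
complications.

## Benchmark problem sizes

The benchmark scenarios (`bloodtx.benchmarks`, driven by both the
acceptance tests and `scripts/acceptance.py`) use: 500 genes × 109
samples with 50 planted eQTL for recovery; 5000 null and 1000 mixture
simulations at n = 109 + 54 for interaction calibration; 500 replicates
for interaction power (β 0.94 vs 0.21); 2000 shared effects for the
winner's-curse geometry; 80–100-SNP loci for coloc; 40 replicates of the
75-vs-12 TRS contrast; and 100 random matrices for the filter-vs-oracle
checks.  These sizes give the assertions comfortable Monte-Carlo margins
while the full suite runs in well under a minute.

## Numerical conventions

p-values are floored at 10⁻³⁰⁰; PC sign is mean-loading-positive;
z-scoring uses ddof = 1 and maps constant genes to 0; BH is
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`; Ward
clustering uses `scipy.cluster.hierarchy` on Euclidean distances; the
coloc H3 term is computed with a log-space complement, clipped so a
single-SNP locus yields H3 ≈ 0 rather than −∞.  Degenerate inputs
(monomorphic dosage, constant gene, groups below the size floor) yield
flagged records with p = 1, not exceptions, so genome-scale scans never
abort mid-run.
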