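"""Expression filtering/normalization, latent-factor adjustment, genotype QC.

The preparation chain mirrors a standard whole-blood RNA-seq + array
workflow: FPKM for an expression-level filter, log2-CPM normalization
(pseudocount 1), removal of latent technical factors while protecting the
design variables of interest, and PLINK-style genotype QC (biallelic, HWE,
MAF, missingness).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BloodtxError, ExpressionMatrix, GenotypeMatrix


@dataclass
class QcThresholds:
    """PLINK-style variant QC cutoffs (defaults as commonly applied)."""

    hwe_p_min: float = 1e-3
    maf_min: float = 0.01
    missing_max: float = 0.05
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "maf_min", "missing_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise BloodtxError(f"{name}={v} outside [0, 1]")


def compute_fpkm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Fragments per kilobase per million mapped reads.

    FPKM = count / (gene length in kb x library size in millions).
    """
    if counts.unit != "raw-count":
        raise BloodtxError(f"compute_fpkm expects raw counts, got {counts.unit}")
    lengths = counts.genes["length"].reindex(counts.gene_ids)
    if lengths.isna().any():
        bad = list(lengths.index[lengths.isna()][:10])
        raise BloodtxError(f"missing gene length for {bad}")
    lib = counts.values.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise BloodtxError(f"zero library size for samples {bad}")
    fpkm = counts.values.div(lengths / 1e3, axis=0).div(lib / 1e6, axis=1)
    return replace(counts, values=fpkm, unit="fpkm")


def filter_expressed_genes(counts: ExpressionMatrix, min_individuals: int = 10,
                           min_count: int = 6, min_fpkm: float = 0.1,
                           fpkm_mode: str = "mean"):
    """Keep genes detectably expressed across the cohort.

    A gene is kept iff (#samples with count > ``min_count``) >
    ``min_individuals`` AND its FPKM passes ``min_fpkm`` under
    ``fpkm_mode`` ("mean" of samples, or "any" sample).  Both
    inequalities are strict.  Returns (filtered matrix, report frame with
    per-gene keep flag and failure reasons).
    """
    if counts.unit != "raw-count":
        raise BloodtxError("filter_expressed_genes expects raw counts")
    if fpkm_mode not in ("mean", "any"):
        raise BloodtxError(f"unknown fpkm_mode {fpkm_mode!r}")
    if counts.n_genes == 0:
        return counts, pd.DataFrame(
            columns=["kept", "n_samples_detected", "fpkm_criterion",
                     "failed_detection", "failed_fpkm"])
    fpkm = compute_fpkm(counts)
    n_detect = (counts.values > min_count).sum(axis=1)
    pass_count = n_detect > min_individuals
    fp = fpkm.values.mean(axis=1) if fpkm_mode == "mean" else fpkm.values.max(axis=1)
    pass_fpkm = fp > min_fpkm
    keep = pass_count & pass_fpkm
    report = pd.DataFrame({
        "kept": keep,
        "n_samples_detected": n_detect,
        "fpkm_criterion": fp,
        "failed_detection": ~pass_count,
        "failed_fpkm": ~pass_fpkm,
    })
    kept = replace(counts, values=counts.values.loc[keep],
                   genes=counts.genes.loc[keep])
    return kept, report


def normalize_expression(counts: ExpressionMatrix,
                         pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(CPM + pseudocount) per sample.

    Library-size scaling makes proportional samples identical; the
    pseudocount keeps zeros finite.
    """
    if counts.unit != "raw-count":
        raise BloodtxError("normalize_expression expects raw counts")
    if counts.values.empty:
        raise BloodtxError("empty count matrix")
    lib = counts.values.sum(axis=0)
    if (lib <= 0).any():
        raise BloodtxError("zero library size")
    cpm = counts.values.div(lib / 1e6, axis=1)
    return replace(counts, values=np.log2(cpm + pseudocount),
                   unit="log-normalized")


def _design_matrix(protected: pd.DataFrame) -> np.ndarray:
    """Intercept + dummy-coded protected design; errors on collinearity."""
    parts = [np.ones((len(protected), 1))]
    names = ["intercept"]
    for col in protected.columns:
        s = protected[col]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(d.to_numpy())
            names.extend(d.columns)
        else:
            parts.append(s.to_numpy(dtype=float)[:, None])
            names.append(col)
    X = np.hstack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise BloodtxError(
            f"collinear protected design (columns: {list(protected.columns)})")
    return X


def adjust_latent_factors(expr: ExpressionMatrix, protected: pd.DataFrame,
                          n_factors: int = 15) -> ExpressionMatrix:
    """Remove latent expression factors while protecting design variables.

    Surrogate-variable-style two-step: (1) residualize every gene on the
    protected design; (2) the top ``n_factors`` principal components of the
    residuals are the latent factors; (3) refit each gene jointly on
    [protected design, latent factors] and subtract only the latent-factor
    component.  Group structure on the protected variables is preserved up
    to numerical tolerance.
    """
    if expr.unit not in ("log-normalized", "z-score"):
        raise BloodtxError("adjust_latent_factors expects log-scale expression")
    protected = protected.reindex(expr.sample_ids)
    X = _design_matrix(protected)
    n = expr.n_samples
    if n_factors < 0:
        raise BloodtxError("n_factors must be >= 0")
    max_rank = min(n - np.linalg.matrix_rank(X), expr.n_genes)
    if n_factors >= max_rank and n_factors > 0:
        raise BloodtxError(
            f"n_factors={n_factors} >= available residual rank {max_rank}")
    if n_factors == 0:
        return replace(expr, values=expr.values.copy())

    Y = expr.values.to_numpy(dtype=float).T          # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    # latent factors: top PCs of the protected-residual matrix
    U, s, _ = np.linalg.svd(R - R.mean(axis=0), full_matrices=False)
    F = U[:, :n_factors] * s[:n_factors]             # samples x k
    F = (F - F.mean(axis=0)) / F.std(axis=0, ddof=1)
    XF = np.hstack([X, F])
    beta2, *_ = np.linalg.lstsq(XF, Y, rcond=None)
    cleaned = Y - F @ beta2[X.shape[1]:]
    return replace(expr, values=pd.DataFrame(cleaned.T, index=expr.gene_ids,
                                             columns=expr.sample_ids))


# ---------------------------------------------------------------------------
# Hardy-Weinberg testing


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact HWE test (two-sided, sum of probabilities <= observed).

    Conditional distribution of heterozygote count given allele counts,
    per the standard exact formulation used by PLINK.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # possible heterozygote counts share parity with n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logprob = np.zeros(len(hets))
    from scipy.special import gammaln
    n_common = 2 * n - n_rare
    for i, h in enumerate(hets):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        logprob[i] = (h * np.log(2) + gammaln(n + 1)
                      - gammaln(h + 1) - gammaln(rare_hom + 1)
                      - gammaln(common_hom + 1)
                      + gammaln(n_rare + 1) + gammaln(n_common + 1)
                      - gammaln(2 * n + 1))
    prob = np.exp(logprob - logprob.max())
    prob /= prob.sum()
    obs = np.searchsorted(hets, n_het)
    return float(min(1.0, prob[prob <= prob[obs] * (1 + 1e-12)].sum()))


def hwe_chi2_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    p = (2 * n_hom1 + n_het) / (2 * n)
    q = 1 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom1, n_het, n_hom2], dtype=float)
    if (exp == 0).any():
        return 1.0
    chi2 = ((obs - exp) ** 2 / exp).sum()
    return float(stats.chi2.sf(chi2, df=1))


def hwe_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact test when any expected genotype count < 5, else chi-square."""
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    p = (2 * n_hom1 + n_het) / (2 * n)
    q = 1 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    if (exp < 5).any():
        return hwe_exact_pvalue(n_het, n_hom1, n_hom2)
    return hwe_chi2_pvalue(n_het, n_hom1, n_hom2)


def qc_genotypes(geno: GenotypeMatrix,
                 thresholds: QcThresholds | None = None):
    """Drop variants failing biallelic / HWE / MAF / missingness rules.

    Returns (filtered GenotypeMatrix, report dict with per-filter drop
    counts; a variant can fail several filters).  Emits a warning and an
    empty matrix if nothing survives.
    """
    thresholds = thresholds or QcThresholds()
    d = geno.dosages
    bases = {"A", "C", "G", "T"}
    if thresholds.biallelic_only:
        ok_allele = geno.snps.apply(
            lambda r: str(r["ref"]).upper() in bases
            and str(r["alt"]).upper() in bases, axis=1)
    else:
        ok_allele = pd.Series(True, index=geno.snp_ids)

    miss = geno.missing_rate()
    maf = geno.maf()
    hwe = pd.Series(1.0, index=geno.snp_ids)
    arr = d.to_numpy()
    for i, sid in enumerate(geno.snp_ids):
        row = arr[i]
        row = row[~np.isnan(row)]
        hwe.loc[sid] = hwe_pvalue(int((row == 1).sum()), int((row == 2).sum()),
                                  int((row == 0).sum()))
    fail_hwe = hwe < thresholds.hwe_p_min
    fail_maf = maf < thresholds.maf_min
    fail_miss = miss > thresholds.missing_max
    fail_allele = ~ok_allele
    keep = ~(fail_hwe | fail_maf | fail_miss | fail_allele)
    report = {
        "n_input": int(len(keep)),
        "n_kept": int(keep.sum()),
        "dropped_non_biallelic": int(fail_allele.sum()),
        "dropped_hwe": int(fail_hwe.sum()),
        "dropped_maf": int(fail_maf.sum()),
        "dropped_missing": int(fail_miss.sum()),
    }
    if keep.sum() == 0:
        warnings.warn("qc_genotypes: all SNPs dropped", stacklevel=2)
    return GenotypeMatrix(d.loc[keep], geno.snps.loc[keep]), report
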