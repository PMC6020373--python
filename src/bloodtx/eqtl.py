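"""Per-cohort cis-eQTL mapping.

Cis pairing takes every SNP within a window (default 250 kb) of a gene's
start/stop, inclusive at both bounds.  Each pair is fit with an additive
OLS model (expression ~ intercept + dosage [+ covariates]); one peak eSNP
is retained per gene and the call threshold is accompanied by an empirical
FDR from expression-permutation.  A leverage diagnostic re-fits each call
after removing the most extreme minor-homozygote expression value, the
classic guard against single-outlier eQTL at low MAF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BloodtxError, ExpressionMatrix, GenotypeMatrix

P_FLOOR = 1e-300


@dataclass
class AssociationRecord:
    """One SNP-gene additive association."""

    snp_id: str
    gene_id: str
    beta: float
    se: float
    p: float
    n: int
    maf: float
    cohort: str = ""
    flag: str = ""


@dataclass
class EqtlCallSet:
    """Peak (per-gene best) associations plus the empirical FDR estimate."""

    peaks: pd.DataFrame
    p_threshold: float
    empirical_fdr: float
    n_perms: int
    all_records: pd.DataFrame | None = None
    flags: list = field(default_factory=list)


def build_cis_pairs(genes: pd.DataFrame, snps: pd.DataFrame,
                    window: int = 250_000) -> pd.DataFrame:
    """All (snp, gene) pairs with SNP in [start - window, stop + window].

    Bounds are inclusive.  ``distance`` is signed: 0 inside the gene body,
    negative upstream of start, positive downstream of stop.
    """
    if window < 0:
        raise BloodtxError("window must be >= 0")
    gchroms, schroms = set(genes["chrom"]), set(snps["chrom"])
    if not gchroms & schroms:
        raise BloodtxError(
            f"no shared chromosome names: genes {sorted(gchroms)[:5]} vs "
            f"snps {sorted(schroms)[:5]}")
    rows = []
    for chrom in sorted(gchroms & schroms, key=str):
        gs = genes[genes["chrom"] == chrom]
        ss = snps[snps["chrom"] == chrom].sort_values("pos")
        pos = ss["pos"].to_numpy()
        sid = ss.index.to_numpy()
        for gid, g in gs.iterrows():
            lo = np.searchsorted(pos, g.start - window, side="left")
            hi = np.searchsorted(pos, g.stop + window, side="right")
            for j in range(lo, hi):
                d = 0
                if pos[j] < g.start:
                    d = int(pos[j] - g.start)
                elif pos[j] > g.stop:
                    d = int(pos[j] - g.stop)
                rows.append((sid[j], gid, d))
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "distance"])


def _residualize(v: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    if C is None:
        return v - v.mean(axis=-1, keepdims=True)
    beta, *_ = np.linalg.lstsq(C, v.T, rcond=None)
    return (v.T - C @ beta).T


def _covariate_design(covariates, n) -> tuple[np.ndarray | None, int]:
    if covariates is None:
        return None, 0
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    C = np.hstack([np.ones((n, 1)), C])
    return C, np.linalg.matrix_rank(C) - 1


def fit_eqtl(dosage, expression, covariates=None, snp_id: str = "",
             gene_id: str = "", cohort: str = "", min_n: int = 10,
             maf: float | None = None) -> AssociationRecord:
    """Additive OLS association of one dosage/expression pair.

    Missing dosages are dropped pairwise.  Zero dosage variance yields a
    flagged p = 1 record; fewer than ``min_n`` complete observations yields
    a skip flag.
    """
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(expression, dtype=float)
    ok = ~(np.isnan(g) | np.isnan(y))
    g, y = g[ok], y[ok]
    n = len(g)
    p_alt = g.mean() / 2 if n else 0.0
    maf = min(p_alt, 1 - p_alt) if maf is None else maf
    base = dict(snp_id=snp_id, gene_id=gene_id, n=n, maf=maf, cohort=cohort)
    if n < min_n:
        return AssociationRecord(beta=np.nan, se=np.nan, p=1.0,
                                 flag="skipped_low_n", **base)
    if np.var(g) == 0:
        return AssociationRecord(beta=0.0, se=np.nan, p=1.0,
                                 flag="monomorphic", **base)
    C, q = _covariate_design(
        None if covariates is None else np.asarray(covariates)[ok], n)
    gr = _residualize(g[None, :], C)[0]
    yr = _residualize(y[None, :], C)[0]
    sxx = (gr ** 2).sum()
    sxy = (gr * yr).sum()
    syy = (yr ** 2).sum()
    beta = sxy / sxx
    df = n - 2 - q
    sigma2 = max(syy - beta * sxy, 0.0) / df
    if sigma2 == 0:
        return AssociationRecord(beta=float(beta), se=0.0, p=P_FLOOR,
                                 flag="perfect_fit", **base)
    se = float(np.sqrt(sigma2 / sxx))
    t = beta / se
    p = max(2 * stats.t.sf(abs(t), df), P_FLOOR)
    return AssociationRecord(beta=float(beta), se=se, p=float(p), **base)


def _gene_scan(D: np.ndarray, y: np.ndarray, df: int):
    """Vectorized simple-regression scan: D (snps x n, centered), y centered."""
    sxx = (D ** 2).sum(axis=1)
    syy = (y ** 2).sum()
    sxy = D @ y
    sxx = np.where(sxx == 0, np.inf, sxx)
    beta = sxy / sxx
    r2 = np.clip(sxy ** 2 / (sxx * syy) if syy > 0 else np.zeros_like(sxy),
                 0, 1 - 1e-15)
    t2 = r2 * df / (1 - r2)
    p = np.maximum(2 * stats.t.sf(np.sqrt(t2), df), P_FLOOR)
    sigma2 = (syy * (1 - r2)) / df
    se = np.sqrt(sigma2 / sxx)
    return beta, se, p


def call_eqtls(pairs: pd.DataFrame, genotypes: GenotypeMatrix,
               expression: ExpressionMatrix, p_threshold: float = 1e-4,
               n_perms: int = 100, cohort: str = "", seed: int = 0,
               keep_all: bool = True) -> EqtlCallSet:
    """Fit all cis pairs, keep the per-gene peak, estimate empirical FDR.

    The empirical FDR is mean(#peak hits at the threshold over
    permutations of sample labels) / #observed peak hits; permutation uses
    one sample-order shuffle per round applied to all genes.
    """
    if n_perms < 10:
        warnings.warn("n_perms < 10: FDR estimate is low-confidence",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    dosages = genotypes.mean_imputed().dosages
    maf = genotypes.maf()
    n = expression.n_samples
    dosages = dosages[expression.sample_ids]
    by_gene = pairs.groupby("gene_id", sort=True)

    gene_blocks = []   # (gene_id, snp ids, centered dosage block, y centered)
    for gid, sub in by_gene:
        sids = [s for s in sub["snp_id"] if s in dosages.index]
        if not sids or gid not in expression.gene_ids:
            continue
        D = dosages.loc[sids].to_numpy(dtype=float)
        D = D - D.mean(axis=1, keepdims=True)
        y = expression.values.loc[gid].to_numpy(dtype=float)
        gene_blocks.append((gid, sids, D, y - y.mean()))
    if not gene_blocks:
        raise BloodtxError("no testable cis pairs")

    df = n - 2
    peak_rows, all_rows = [], []
    for gid, sids, D, y in gene_blocks:
        beta, se, p = _gene_scan(D, y, df)
        i = int(np.argmin(p))
        peak_rows.append((sids[i], gid, float(beta[i]), float(se[i]),
                          float(p[i]), n, float(maf.loc[sids[i]])))
        if keep_all:
            for j, sid in enumerate(sids):
                all_rows.append((sid, gid, float(beta[j]), float(se[j]),
                                 float(p[j]), n, float(maf.loc[sid])))
    cols = ["snp_id", "gene_id", "beta", "se", "p", "n", "maf"]
    peaks = pd.DataFrame(peak_rows, columns=cols)
    peaks["cohort"] = cohort
    peaks = peaks.set_index("gene_id")
    observed_hits = int((peaks["p"] < p_threshold).sum())

    perm_hits = np.zeros(n_perms)
    for b in range(n_perms):
        order = rng.permutation(n)
        hits = 0
        for gid, sids, D, y in gene_blocks:
            _, _, p = _gene_scan(D, y[order], df)
            hits += p.min() < p_threshold
        perm_hits[b] = hits
    fdr = float(perm_hits.mean() / max(observed_hits, 1))

    all_records = None
    if keep_all:
        all_records = pd.DataFrame(all_rows, columns=cols)
        all_records["cohort"] = cohort
    return EqtlCallSet(peaks=peaks, p_threshold=p_threshold,
                       empirical_fdr=fdr, n_perms=n_perms,
                       all_records=all_records)


def significant_peaks(callset: EqtlCallSet) -> pd.DataFrame:
    return callset.peaks[callset.peaks["p"] < callset.p_threshold]


def maf_significance_check(callset: EqtlCallSet, genotypes: GenotypeMatrix,
                           expression: ExpressionMatrix,
                           p_degrade_threshold: float | None = None):
    """MAF-vs-significance diagnostic plus single-outlier leverage audit.

    Reports the correlation of MAF with -log10 p across called eQTL, and
    refits each call after removing the single most extreme expression
    value among minor-allele homozygotes; calls whose p then rises above
    the threshold (default: the callset threshold) are flagged — the
    signature of a spurious low-MAF eQTL driven by one outlier.
    """
    sig = significant_peaks(callset)
    if sig.empty:
        raise BloodtxError("callset has no significant peaks")
    thr = callset.p_threshold if p_degrade_threshold is None else p_degrade_threshold
    mlp = -np.log10(sig["p"].to_numpy())
    maf = sig["maf"].to_numpy()
    if len(sig) >= 3 and np.std(maf) > 0 and np.std(mlp) > 0:
        r, r_p = stats.pearsonr(maf, mlp)
    else:
        r, r_p = np.nan, np.nan
    dosages = genotypes.mean_imputed().dosages[expression.sample_ids]
    flags = []
    rows = []
    for gid, rec in sig.iterrows():
        g = dosages.loc[rec["snp_id"]].to_numpy(dtype=float)
        y = expression.values.loc[gid].to_numpy(dtype=float)
        p_alt = g.mean() / 2
        minor_dosage = 2.0 if p_alt <= 0.5 else 0.0
        hom = np.where(np.round(g) == minor_dosage)[0]
        p_refit = rec["p"]
        if len(hom) > 0:
            extreme = hom[np.argmax(np.abs(y[hom] - y.mean()))]
            keep = np.ones(len(g), dtype=bool)
            keep[extreme] = False
            refit = fit_eqtl(g[keep], y[keep], snp_id=rec["snp_id"], gene_id=gid)
            p_refit = refit.p
        flagged = p_refit >= thr
        if flagged:
            flags.append(gid)
        rows.append((gid, rec["snp_id"], rec["maf"], rec["p"], p_refit,
                     len(hom), flagged))
    diag = pd.DataFrame(rows, columns=["gene_id", "snp_id", "maf", "p",
                                       "p_outlier_removed", "n_minor_hom",
                                       "flagged"]).set_index("gene_id")
    return {"maf_logp_correlation": float(r) if np.isfinite(r) else np.nan,
            "correlation_p": float(r_p) if np.isfinite(r_p) else np.nan,
            "diagnostics": diag, "flagged": flags}
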