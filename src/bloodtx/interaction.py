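"""Genotype-by-disease interaction testing across two cohorts.

Candidate loci are the union of peak eQTL significant in either cohort.
Each is refit jointly on the pooled samples with
``expr ~ genotype + disease + genotype x disease`` (OLS, Wald p on the
product term); per-disease marginal slopes follow algebraically from the
joint coefficients.  BH control at the stated FDR, plus the
effect-size-comparison geometry (cross-cohort correlation and the
winner's-curse discovery asymmetry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import BloodtxError

P_FLOOR = 1e-300


@dataclass
class InteractionRecord:
    """Joint-model coefficients for one SNP-gene pair across two cohorts."""

    snp_id: str
    gene_id: str
    beta_genotype: float
    se_genotype: float
    p_genotype: float
    beta_disease: float
    se_disease: float
    p_disease: float
    beta_interaction: float
    se_interaction: float
    p_interaction: float
    beta_disease0: float     # marginal slope in the reference disease
    beta_disease1: float     # = beta_genotype + beta_interaction
    n: int
    flag: str = ""


def pool_cohorts(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Union of peak (snp, gene) pairs significant in either cohort.

    Inputs are peak frames indexed by gene with a ``snp_id`` column (as
    produced by :func:`bloodtx.eqtl.significant_peaks`).  Provenance is
    recorded as A-only / B-only / both.
    """
    a = set(zip(calls_a["snp_id"], calls_a.index))
    b = set(zip(calls_b["snp_id"], calls_b.index))
    union = a | b
    if not union:
        raise BloodtxError("empty candidate union")
    rows = []
    for snp, gene in sorted(union):
        prov = "both" if (snp, gene) in a and (snp, gene) in b else (
            "A-only" if (snp, gene) in a else "B-only")
        rows.append((snp, gene, prov))
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "provenance"])


def interaction_test(dosage, expression, disease, covariates=None,
                     snp_id: str = "", gene_id: str = "",
                     min_per_group: int = 10) -> InteractionRecord:
    """OLS fit of expr ~ g + d + g*d (+ covariates); Wald p per term.

    ``disease`` is a 0/1 indicator (reference disease coded 0).  A record
    is flagged untestable when either group has fewer than
    ``min_per_group`` samples or zero within-group dosage variance.
    """
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(expression, dtype=float)
    d = np.asarray(disease, dtype=float)
    ok = ~(np.isnan(g) | np.isnan(y) | np.isnan(d))
    g, y, d = g[ok], y[ok], d[ok]
    n = len(g)
    base = dict(snp_id=snp_id, gene_id=gene_id, n=n)
    nan_rec = dict(beta_genotype=np.nan, se_genotype=np.nan, p_genotype=1.0,
                   beta_disease=np.nan, se_disease=np.nan, p_disease=1.0,
                   beta_interaction=np.nan, se_interaction=np.nan,
                   p_interaction=1.0, beta_disease0=np.nan,
                   beta_disease1=np.nan)
    n0, n1 = int((d == 0).sum()), int((d == 1).sum())
    if n0 < min_per_group or n1 < min_per_group:
        return InteractionRecord(flag="too_few_per_group", **nan_rec, **base)
    if np.var(g[d == 0]) == 0 or np.var(g[d == 1]) == 0:
        return InteractionRecord(flag="monomorphic_within_group",
                                 **nan_rec, **base)
    X = np.column_stack([np.ones(n), g, d, g * d])
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.hstack([X, C[ok]])
    k = X.shape[1]
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = n - k
    sigma2 = (resid @ resid) / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = np.maximum(2 * stats.t.sf(np.abs(t), df), P_FLOOR)
    return InteractionRecord(
        beta_genotype=float(beta[1]), se_genotype=float(se[1]),
        p_genotype=float(p[1]),
        beta_disease=float(beta[2]), se_disease=float(se[2]),
        p_disease=float(p[2]),
        beta_interaction=float(beta[3]), se_interaction=float(se[3]),
        p_interaction=float(p[3]),
        beta_disease0=float(beta[1]),
        beta_disease1=float(beta[1] + beta[3]),
        **base)


def records_frame(records: list[InteractionRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def call_interactions(records: pd.DataFrame, fdr: float = 0.10,
                      nominal_p: float = 0.02) -> dict:
    """BH at the stated FDR on interaction p; nominal-p count reported too."""
    testable = records[records["flag"] == ""] if "flag" in records else records
    p = testable["p_interaction"].to_numpy()
    out = records.copy()
    out["q_interaction"] = np.nan
    out["called"] = False
    if len(p):
        rej, q, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
        out.loc[testable.index, "q_interaction"] = q
        out.loc[testable.index, "called"] = rej
    return {
        "records": out,
        "n_called_fdr": int(out["called"].sum()),
        "n_nominal": int((out.loc[testable.index, "p_interaction"]
                          < nominal_p).sum()),
        "fdr": fdr,
        "nominal_p": nominal_p,
    }


def expected_attenuation(var_beta: float, mean_se2_a: float,
                         mean_se2_b: float) -> float:
    """Predicted cross-cohort correlation of estimated effects.

    For fully shared true effects with variance ``var_beta`` observed with
    independent estimation noise, corr(beta_hat_A, beta_hat_B) =
    var_beta / sqrt((var_beta + mse_A)(var_beta + mse_B)); this reduces to
    var/(var + mean se^2) when the two cohorts have matched SEs.
    """
    return var_beta / np.sqrt((var_beta + mean_se2_a) * (var_beta + mean_se2_b))


def effect_size_comparison(records: pd.DataFrame,
                           discovery_col: str = "provenance") -> dict:
    """Cross-cohort effect-size geometry with winner's-curse annotation.

    ``records`` needs per-disease betas (``beta_a``, ``beta_b``) and a
    discovery tag.  Reports the overall Pearson correlation and, per
    discovery stratum, mean |beta| in the discovery vs the other cohort —
    under winner's curse the discovery-cohort ratio exceeds 1 even for
    fully shared effects.
    """
    if len(records) < 3:
        raise BloodtxError("need >= 3 records for effect-size comparison")
    ba = records["beta_a"].to_numpy(dtype=float)
    bb = records["beta_b"].to_numpy(dtype=float)
    r, r_p = stats.pearsonr(ba, bb)
    strata = {}
    for tag, sub in records.groupby(discovery_col):
        sa = np.abs(sub["beta_a"]).mean()
        sb = np.abs(sub["beta_b"]).mean()
        if tag == "A-only":
            ratio = sa / sb
        elif tag == "B-only":
            ratio = sb / sa
        else:
            ratio = np.nan
        strata[tag] = {"mean_abs_beta_a": float(sa),
                       "mean_abs_beta_b": float(sb),
                       "discovery_abs_ratio": float(ratio)}
    return {
        "correlation": float(r),
        "correlation_p": float(r_p),
        "strata": strata,
        "caveat": ("discovery-stratified |beta| ratios are inflated by "
                   "winner's curse; shared effects still show ratio > 1"),
    }
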