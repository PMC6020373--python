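"""Transcriptional risk score (TRS).

A TRS definition is a list of genes validated as both eQTL and GWAS loci
(shared causal variant, coloc H4), each carrying a polarity: +1 when the
GWAS risk allele increases the gene's expression, -1 when it decreases
it.  A sample's TRS is the sum over definition genes of polarity x
expression z-score, so a positive TRS represents transcriptome-level
elevated risk.  Group contrasts report the difference in pooled-SD units
(Cohen's d) against a reference group plus an overall ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BloodtxError, ExpressionMatrix

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class TrsDefinition:
    """Per-gene polarities with provenance (source SNP, risk allele, H4)."""

    table: pd.DataFrame   # gene_id, polarity, snp_id, risk_allele, h4

    def __post_init__(self) -> None:
        if self.table["gene_id"].duplicated().any():
            raise BloodtxError("TRS definition has duplicate genes")
        if not set(self.table["polarity"]).issubset({-1, 1}):
            raise BloodtxError("polarity must be +1 or -1")

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.table["gene_id"])


@dataclass
class TrsScores:
    scores: pd.Series                 # per-sample TRS
    groups: pd.Series | None
    genes_used: list
    genes_missing: list


def _harmonize(eff_allele: str, oth_allele: str, ref: str, alt: str):
    """Return +1/-1 multiplier mapping a GWAS effect onto the ALT allele.

    Tries direct match, allele swap, then strand complement; returns None
    when unresolvable.
    """
    e, o = eff_allele.upper(), oth_allele.upper()
    for flip in (False, True):
        if flip:
            e, o = e.translate(_COMPLEMENT), o.translate(_COMPLEMENT)
        if (e, o) == (alt, ref):
            return 1
        if (e, o) == (ref, alt):
            return -1
    return None


def build_trs_definition(gwas: pd.DataFrame, eqtl_peaks: pd.DataFrame,
                         coloc_results: dict, h4_min: float = 0.5) -> TrsDefinition:
    """Select H4-validated genes and assign expression polarities.

    ``gwas`` columns: snp_id, effect_allele, other_allele, beta (risk on
    the positive side of effect_allele).  ``eqtl_peaks`` is indexed by
    gene with snp_id, beta and the eQTL coded alleles ``ref``/``alt``
    (dosage counts ALT).  ``coloc_results`` maps gene_id -> ColocResult or
    PP4 float.  Polarity is +1 iff the harmonized risk allele increases
    expression.
    """
    gw = gwas.drop_duplicates("snp_id").set_index("snp_id")
    rows = []
    for gene_id, rec in eqtl_peaks.iterrows():
        res = coloc_results.get(gene_id)
        if res is None:
            continue
        pp4 = res if isinstance(res, (int, float)) else res.pp4
        if pp4 < h4_min:
            continue
        snp = rec["snp_id"]
        if snp not in gw.index:
            warnings.warn(f"gene {gene_id}: peak SNP {snp} absent from GWAS",
                          stacklevel=2)
            continue
        grec = gw.loc[snp]
        mult = _harmonize(str(grec["effect_allele"]), str(grec["other_allele"]),
                          str(rec["ref"]).upper(), str(rec["alt"]).upper())
        if mult is None:
            warnings.warn(f"gene {gene_id}: alleles unresolvable at {snp}; dropped",
                          stacklevel=2)
            continue
        beta_gwas_alt = mult * float(grec["beta"])   # risk direction on ALT
        risk_is_alt = beta_gwas_alt > 0
        risk_allele = rec["alt"] if risk_is_alt else rec["ref"]
        beta_eqtl = float(rec["beta"])               # expression per ALT copy
        polarity = int(np.sign(beta_eqtl) * (1 if risk_is_alt else -1))
        if polarity == 0:
            continue
        rows.append((gene_id, polarity, snp, risk_allele, float(pp4)))
    if not rows:
        raise BloodtxError("no genes passed the H4 filter")
    return TrsDefinition(pd.DataFrame(
        rows, columns=["gene_id", "polarity", "snp_id", "risk_allele", "h4"]))


def compute_trs(expr: ExpressionMatrix, definition: TrsDefinition,
                groups: pd.Series | None = None,
                reference_group: str | None = None) -> TrsScores:
    """Sum of polarized per-gene z-scores per sample.

    z-scores are computed across all samples by default; with
    ``reference_group`` the standardization uses that group's mean/SD.
    Definition genes missing from the matrix are reported, never silently
    skipped.
    """
    present = [g for g in definition.genes if g in expr.gene_ids]
    missing = [g for g in definition.genes if g not in expr.gene_ids]
    if not present:
        raise BloodtxError("no TRS definition genes present in expression matrix")
    v = expr.values.loc[present].to_numpy(dtype=float)
    if expr.unit == "z-score" and reference_group is None:
        z = v
    else:
        if reference_group is not None:
            if groups is None:
                raise BloodtxError("reference_group requires group labels")
            mask = (groups.reindex(expr.sample_ids) == reference_group).to_numpy()
            if mask.sum() < 2:
                raise BloodtxError(f"reference group {reference_group!r} too small")
            mu = v[:, mask].mean(axis=1, keepdims=True)
            sd = v[:, mask].std(axis=1, ddof=1, keepdims=True)
        else:
            mu = v.mean(axis=1, keepdims=True)
            sd = v.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (v - mu) / sd
    pol = definition.table.set_index("gene_id").loc[present, "polarity"]
    trs = pol.to_numpy()[:, None] * z
    scores = pd.Series(trs.sum(axis=0), index=expr.sample_ids, name="TRS")
    if groups is not None:
        groups = groups.reindex(expr.sample_ids)
    return TrsScores(scores=scores, groups=groups, genes_used=present,
                     genes_missing=missing)


def trs_group_contrast(scores: TrsScores, reference: str,
                       groups: pd.Series | None = None) -> dict:
    """Per-group Cohen's d (pooled SD) vs the reference, plus overall ANOVA."""
    groups = groups if groups is not None else scores.groups
    if groups is None:
        raise BloodtxError("group labels required")
    groups = groups.reindex(scores.scores.index)
    ref = scores.scores[groups == reference].to_numpy()
    if len(ref) < 3:
        raise BloodtxError(f"reference group {reference!r} needs >= 3 samples")
    out = {}
    for g in groups.dropna().unique():
        if g == reference:
            continue
        x = scores.scores[groups == g].to_numpy()
        nx, nr = len(x), len(ref)
        pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (nr - 1) * ref.var(ddof=1))
                         / (nx + nr - 2))
        if pooled == 0:
            raise BloodtxError("zero pooled SD in contrast")
        d = (x.mean() - ref.mean()) / pooled
        t, p = stats.ttest_ind(x, ref, equal_var=True)
        out[g] = {"delta_sd": float(d), "p": float(p), "n": nx,
                  "n_reference": nr}
    levels = groups.dropna().unique()
    if len(levels) > 1:
        samples = [scores.scores[groups == g].to_numpy() for g in levels]
        F, p = stats.f_oneway(*samples)
        anova = {"F": float(F), "p": float(p)}
    else:
        anova = {"F": np.nan, "p": np.nan}
    return {"contrasts": out, "anova": anova, "reference": reference}
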