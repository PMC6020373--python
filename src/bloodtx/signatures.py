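"""Transcriptome-level descriptive analyses.

Immune-axis and blood-transcript-module scores are first principal
components over the member genes (genes standardized first, sign oriented
so the mean gene loading is positive); sample clustering is Ward linkage
on z-scores; PVCA partitions the variance of the top expression PCs among
design factors; differential expression is a normal-theory two-group
contrast on log-scale values with Benjamini-Hochberg control.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .containers import BloodtxError, ExpressionMatrix, ScoreTable


def default_axis_collection() -> dict:
    """Bundled placeholder gene sets for the seven blood immune axes.

    Synthetic stand-in ids (``BIT_T_01``...): the real published axis and
    module memberships are user-supplied via GMT.
    """
    from importlib.resources import files

    from .io import read_gmt
    return read_gmt(files("bloodtx.data") / "axes_synthetic.gmt")


def _pc1(values: np.ndarray):
    """PC1 of a genes x samples block after per-gene standardization.

    Returns (sample scores, variance explained, gene loadings).  Scores
    carry the singular-value scale; orientation makes the mean loading
    positive.
    """
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    ok = sd[:, 0] > 0
    z = (values[ok] - mu[ok]) / sd[ok]
    if z.shape[0] < 2:
        raise BloodtxError("fewer than 2 non-constant genes in set")
    U, s, Vt = np.linalg.svd(z, full_matrices=False)
    sign = 1.0 if U[:, 0].mean() >= 0 else -1.0
    scores = sign * s[0] * Vt[0]
    ve = float(s[0] ** 2 / (s ** 2).sum())
    loadings = np.full(values.shape[0], np.nan)
    loadings[ok] = sign * U[:, 0]
    return scores, ve, loadings


def axis_score(expr: ExpressionMatrix, gene_set, name: str = "axis") -> ScoreTable:
    """Per-sample PC1 score over a gene set (an immune-axis signature).

    Genes are standardized before the SVD so the score is invariant to
    per-gene affine rescaling; the proportion of set variance explained by
    PC1 is reported (blood-informative axes typically exceed 70%).
    """
    if expr.unit not in ("log-normalized", "z-score"):
        raise BloodtxError("axis_score expects log-normalized or z-scored input")
    present = expr.gene_ids.intersection(pd.Index(gene_set))
    if len(present) < 2:
        raise BloodtxError(
            f"gene set {name!r}: only {len(present)} genes resolvable (need >= 2)")
    scores, ve, _ = _pc1(expr.values.loc[present].to_numpy(dtype=float))
    return ScoreTable(pd.DataFrame({name: scores}, index=expr.sample_ids),
                      variance_explained={name: ve})


def btm_scores(expr: ExpressionMatrix, collection: dict,
               groups: pd.Series | None = None) -> ScoreTable:
    """Axis scoring applied per module of a gene-set collection.

    Modules with < 2 resolvable genes are skipped with a warning.  When
    group labels are supplied the returned table supports
    ``group_means()`` for the module x sub-type heat-map export.
    """
    cols = {}
    ve = {}
    for name, genes in collection.items():
        try:
            st = axis_score(expr, genes, name=name)
        except BloodtxError:
            warnings.warn(f"module {name!r} skipped: <2 resolvable genes",
                          stacklevel=2)
            continue
        cols[name] = st.scores[name]
        ve[name] = st.variance_explained[name]
    if not cols:
        raise BloodtxError("no module had >= 2 resolvable genes")
    return ScoreTable(pd.DataFrame(cols), variance_explained=ve, groups=groups)


def cluster_samples(expr_z: ExpressionMatrix, k: int = 6,
                    groups: pd.Series | None = None):
    """Ward hierarchical clustering of samples, cut at ``k`` clusters.

    Returns (assignments Series, membership frame or None).  The
    membership table gives, per sub-type, the proportion of its samples in
    each cluster (rows sum to 1).
    """
    if expr_z.unit != "z-score":
        raise BloodtxError("cluster_samples expects z-scored expression")
    if k > expr_z.n_samples:
        raise BloodtxError(f"k={k} exceeds {expr_z.n_samples} samples")
    X = expr_z.values.to_numpy(dtype=float).T
    Z = linkage(X, method="ward")
    assign = pd.Series(fcluster(Z, t=k, criterion="maxclust"),
                       index=expr_z.sample_ids, name="cluster")
    membership = None
    if groups is not None:
        groups = groups.reindex(expr_z.sample_ids)
        tab = pd.crosstab(groups, assign)
        membership = tab.div(tab.sum(axis=1), axis=0)
    return assign, membership


def _sequential_ss(y: np.ndarray, factors: pd.DataFrame):
    """Sequential (type-I) sums of squares of a factor-effects model."""
    n = len(y)
    X = np.ones((n, 1))
    sstot = ((y - y.mean()) ** 2).sum()
    parts = {}
    prev_rank = 1
    prev_ssr = 0.0
    for col in factors.columns:
        d = pd.get_dummies(factors[col], prefix=col, dtype=float).to_numpy()
        X = np.hstack([X, d])
        rank = np.linalg.matrix_rank(X)
        if rank <= prev_rank:
            raise BloodtxError(
                f"factor {col!r} aliased with preceding factors")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        ssr = ((fitted - y.mean()) ** 2).sum()
        parts[col] = ssr - prev_ssr
        prev_ssr, prev_rank = ssr, rank
    resid = sstot - prev_ssr
    return parts, resid, sstot


def pvca(expr: ExpressionMatrix, factors: pd.DataFrame,
         n_pc: int = 5) -> pd.Series:
    """Principal variance component analysis.

    Each of the top ``n_pc`` expression PCs is decomposed by a sequential
    ANOVA over the (categorical) design factors; per-PC eta-squared shares
    are weighted by the PC's fraction of total expression variance.  The
    returned proportions include a ``residual`` entry closing the budget to
    exactly 1.
    """
    factors = factors.reindex(expr.sample_ids)
    if n_pc > expr.n_samples - 1:
        raise BloodtxError("n_pc must be <= samples - 1")
    Y = expr.values.to_numpy(dtype=float)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    eigfrac = s ** 2 / (s ** 2).sum()
    out = {col: 0.0 for col in factors.columns}
    resid_w = 0.0
    for j in range(n_pc):
        pc = Vt[j] * s[j]
        parts, resid, sstot = _sequential_ss(pc, factors)
        for col, ss in parts.items():
            out[col] += eigfrac[j] * ss / sstot
        resid_w += eigfrac[j] * resid / sstot
    out["residual"] = resid_w + (1.0 - eigfrac[:n_pc].sum())
    return pd.Series(out, name="variance_proportion")


def differential_expression(expr: ExpressionMatrix, groups: pd.Series,
                            group_a: str, group_b: str,
                            fdr: float = 0.05) -> pd.DataFrame:
    """Two-group linear-model contrast per gene with BH correction.

    Effect is mean(A) - mean(B) on the log scale (a log fold change when
    the input is log-normalized).  Constant genes get p = 1 and a flag.
    Returns a frame with effect, t, p, q, significance and direction.
    """
    if expr.unit not in ("log-normalized", "z-score"):
        raise BloodtxError("differential_expression expects log-scale input")
    groups = groups.reindex(expr.sample_ids)
    in_a = (groups == group_a).to_numpy()
    in_b = (groups == group_b).to_numpy()
    na, nb = int(in_a.sum()), int(in_b.sum())
    if na < 3 or nb < 3:
        raise BloodtxError("each group needs >= 3 samples")
    A = expr.values.to_numpy(dtype=float)[:, in_a]
    B = expr.values.to_numpy(dtype=float)[:, in_b]
    effect = A.mean(axis=1) - B.mean(axis=1)
    ssa = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((B - B.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = na + nb - 2
    pooled = (ssa + ssb) / df
    degenerate = pooled <= 0
    se = np.sqrt(np.where(degenerate, np.nan, pooled) * (1 / na + 1 / nb))
    t = np.where(degenerate, 0.0, effect / np.where(degenerate, 1.0, se))
    p = np.where(degenerate, 1.0, 2 * stats.t.sf(np.abs(t), df))
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({
        "effect": effect, "t": t, "p": p, "q": q,
        "significant": q < fdr,
        "direction": np.where(effect > 0, f"up_in_{group_a}", f"up_in_{group_b}"),
        "degenerate": degenerate,
    }, index=expr.gene_ids)
    return out


def group_anova(scores: ScoreTable, groups: pd.Series | None = None) -> pd.DataFrame:
    """One-way ANOVA across group labels for each score column."""
    groups = groups if groups is not None else scores.groups
    if groups is None:
        raise BloodtxError("group labels required")
    groups = groups.reindex(scores.scores.index)
    levels = groups.dropna().unique()
    if len(levels) < 2:
        raise BloodtxError("ANOVA needs >= 2 groups")
    rows = {}
    for col in scores.scores.columns:
        samples = [scores.scores.loc[groups == g, col].to_numpy()
                   for g in levels]
        if any(len(s) < 2 for s in samples):
            raise BloodtxError("each group needs >= 2 samples")
        F, p = stats.f_oneway(*samples)
        rows[col] = {"F": float(F), "p": float(p)}
    return pd.DataFrame(rows).T
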