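"""Ground-truth benchmark scenarios for the full method stack.

Each function simulates a study condition with planted truth, runs the
corresponding pipeline stage(s), and returns the measured recovery /
calibration quantities.  The scenarios fix the cohort geometry of the
motivating design (109 + 54 genotyped subjects across two disease
classes, 75 vs 12 for the TRS case/control contrast) and are used both
by the acceptance test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import comb

from .containers import ExpressionMatrix, GenotypeMatrix
from .coloc import SummarySeries, colocalize
from .eqtl import build_cis_pairs, call_eqtls, significant_peaks
from .interaction import (call_interactions, effect_size_comparison,
                          expected_attenuation, interaction_test,
                          records_frame)
from .preprocess import compute_fpkm, filter_expressed_genes, qc_genotypes
from .signatures import axis_score, cluster_samples, pvca
from .simulate import (SimConfig, default_eqtl_plan, sample_labels,
                       generate_expression, generate_genotypes,
                       simulate_trs_cohort)
from .trs import TrsDefinition, build_trs_definition, compute_trs


# ---------------------------------------------------------------------------
# eQTL recovery


def eqtl_recovery(seed: int = 0, n_genes: int = 500, n_samples: int = 109,
                  n_planted: int = 50, beta: float = 0.8,
                  n_perms: int = 20) -> dict:
    """Planted-eQTL recovery in a single 109-sample cohort.

    50 cis-eQTL of magnitude 0.8 SD (random sign, MAF >= 0.2) among 500
    genes; reports the correlation of estimated peak betas with truth and
    the fraction called at p < 1e-4.
    """
    cfg = SimConfig(n_samples_per_group={"JIA": n_samples}, n_genes=n_genes,
                    n_snps=n_genes * 3, maf_range=(0.2, 0.5), n_modules=1,
                    module_size=2, n_latent_confounders=0, seed=seed)
    cfg.eqtl_plan = default_eqtl_plan(cfg, n_eqtl=n_planted, beta=beta,
                                      seed=seed + 1)
    geno = generate_genotypes(cfg)
    labels = sample_labels(cfg)
    sim = generate_expression(cfg, geno, labels)
    pairs = build_cis_pairs(sim.log_expr.genes, geno.snps)
    cs = call_eqtls(pairs, geno, sim.log_expr, p_threshold=1e-4,
                    n_perms=n_perms, seed=seed)
    truth = {pe.gene_id: pe.beta_per_disease["JIA"] for pe in cfg.eqtl_plan}
    est = cs.peaks.loc[list(truth), "beta"].to_numpy()
    true = np.array(list(truth.values()))
    called = (cs.peaks.loc[list(truth), "p"] < 1e-4).mean()
    return {"beta_correlation": float(np.corrcoef(est, true)[0, 1]),
            "power": float(called), "empirical_fdr": cs.empirical_fdr,
            "n_planted": n_planted}


# ---------------------------------------------------------------------------
# interaction calibration / power / winner's curse


def _interaction_sim(rng, b0, b1, n0=109, n1=54, maf=0.3):
    g = rng.binomial(2, maf, n0 + n1).astype(float)
    d = np.concatenate([np.zeros(n0), np.ones(n1)])
    y = np.where(d == 0, b0, b1) * g + rng.standard_normal(n0 + n1)
    return g, y, d


def interaction_calibration(seed: int = 0, n_null: int = 5000,
                            n_mixture: int = 1000,
                            true_frac: float = 0.2) -> dict:
    """Null rejection rate at p < 0.02 and BH FDR on a 20%-true mixture."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_null):
        g, y, d = _interaction_sim(rng, 0.5, 0.5)
        rej += interaction_test(g, y, d).p_interaction < 0.02
    n_true = int(n_mixture * true_frac)
    recs, is_true = [], []
    for i in range(n_mixture):
        true = i < n_true
        g, y, d = _interaction_sim(rng, 1.5 if true else 0.3, 0.3)
        recs.append(interaction_test(g, y, d, gene_id=f"g{i}"))
        is_true.append(true)
    res = call_interactions(records_frame(recs), fdr=0.10)
    called = res["records"]["called"].to_numpy()
    fp = int((called & ~np.array(is_true)).sum())
    return {"null_rejection_rate": rej / n_null,
            "mixture_empirical_fdr": fp / max(res["n_called_fdr"], 1),
            "n_null": n_null, "n_mixture": n_mixture}


def interaction_power(seed: int = 0, n_reps: int = 500, beta_a: float = 0.94,
                      beta_b: float = 0.21) -> dict:
    """Power to detect a disease-specific eQTL (0.94 vs 0.21, 109+54)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        g, y, d = _interaction_sim(rng, beta_a, beta_b)
        hits += interaction_test(g, y, d).p_interaction < 0.02
    return {"power": hits / n_reps, "n_reps": n_reps}


def winners_curse_geometry(seed: int = 0, n_effects: int = 2000,
                           sd_beta: float = 0.3, se: float = 0.15) -> dict:
    """Fully shared effects: attenuation of r and discovery-ratio asymmetry."""
    rng = np.random.default_rng(seed)
    beta = rng.normal(0, sd_beta, n_effects)
    a = beta + rng.normal(0, se, n_effects)
    b = beta + rng.normal(0, se, n_effects)
    disc_a = np.abs(a / se) > 3.5
    disc_b = (np.abs(b / se) > 3.5) & ~disc_a
    prov = np.where(disc_a, "A-only", np.where(disc_b, "B-only", "none"))
    df = pd.DataFrame({"beta_a": a, "beta_b": b, "provenance": prov})
    res = effect_size_comparison(df[df["provenance"] != "none"])
    r_all = float(np.corrcoef(a, b)[0, 1])
    pred = expected_attenuation(sd_beta ** 2, se ** 2, se ** 2)
    return {"correlation": r_all,
            "predicted_correlation": float(pred),
            "attenuation_gap": abs(r_all - pred),
            "discovery_ratio_a": res["strata"]["A-only"]["discovery_abs_ratio"],
            "n_effects": n_effects}


# ---------------------------------------------------------------------------
# colocalization scenarios


def _locus(rng, n=200, m=80, causal=0, z=8.0):
    G = rng.binomial(2, 0.3, (m, n)).astype(float)
    Gc = G - G.mean(axis=1, keepdims=True)
    norms = np.sqrt((Gc ** 2).sum(axis=1))
    r = (Gc @ Gc[causal]) / (norms * norms[causal])
    zs = r * z + rng.standard_normal(m)
    se = np.full(m, 0.05)
    return SummarySeries(pd.DataFrame({
        "snp_id": [f"v{i}" for i in range(m)], "position": np.arange(m),
        "beta": zs * se, "se": se, "n": n}))


def coloc_scenarios(seed: int = 0) -> dict:
    """Flat-null, shared-causal, and distinct-causal locus posteriors."""
    rng = np.random.default_rng(seed)
    null_1 = SummarySeries(pd.DataFrame({
        "snp_id": [f"v{i}" for i in range(100)], "position": np.arange(100),
        "beta": rng.normal(0, 0.05, 100), "se": np.full(100, 0.05), "n": 200}))
    null_2 = SummarySeries(null_1.table.assign(
        beta=rng.normal(0, 0.05, 100)))
    pp_null = colocalize(null_1, null_2)
    shared = colocalize(_locus(rng, causal=10), _locus(rng, causal=10))
    distinct = colocalize(_locus(rng, causal=5), _locus(rng, causal=60))
    sums = [float(r.pp.sum()) for r in (pp_null, shared, distinct)]
    return {"pp0_null": float(pp_null.pp[0]), "pp4_shared": shared.pp4,
            "pp3_distinct": distinct.pp3,
            "max_sum_error": max(abs(s - 1.0) for s in sums)}


# ---------------------------------------------------------------------------
# TRS


def trs_polarity_recovery(seed: int = 0, n_eqtl: int = 12) -> dict:
    """Genotypes -> eQTL -> harmonization -> definition vs planted truth."""
    cfg = SimConfig(n_genes=40, n_snps=200, seed=seed, maf_range=(0.2, 0.5),
                    n_latent_confounders=0)
    cfg.eqtl_plan = default_eqtl_plan(cfg, n_eqtl=n_eqtl, beta=1.0,
                                      gwas_frac=1.0, seed=seed + 1)
    geno = generate_genotypes(cfg)
    labels = sample_labels(cfg)
    sim = generate_expression(cfg, geno, labels)
    from .simulate import generate_gwas_summary
    gwas = generate_gwas_summary(cfg, sim.truth, geno)
    pairs = build_cis_pairs(sim.log_expr.genes, geno.snps)
    cs = call_eqtls(pairs, geno, sim.log_expr, n_perms=10, seed=seed)
    peaks = significant_peaks(cs).join(geno.snps[["ref", "alt"]], on="snp_id")
    coloc_res = {}
    all_rec = cs.all_records
    for gene_id, sub in all_rec.groupby("gene_id"):
        gsub = gwas[gwas["locus_gene"] == gene_id]
        if gsub.empty or gene_id not in peaks.index:
            continue
        s_eqtl = SummarySeries(pd.DataFrame({
            "snp_id": sub["snp_id"].to_numpy(),
            "position": np.arange(len(sub)),
            "beta": sub["beta"].to_numpy(), "se": sub["se"].to_numpy(),
            "n": sub["n"].to_numpy()}))
        s_gwas = SummarySeries(
            gsub[["snp_id", "position", "beta", "se", "n"]], trait_type="cc")
        coloc_res[gene_id] = colocalize(s_eqtl, s_gwas)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        definition = build_trs_definition(gwas, peaks, coloc_res, h4_min=0.5)
    truth = sim.truth.risk_polarity
    hits = [int(row.polarity) == truth[row.gene_id]
            for row in definition.table.itertuples() if row.gene_id in truth]
    return {"polarity_agreement": float(np.mean(hits)) if hits else np.nan,
            "n_definition_genes": len(definition.table),
            "n_planted": n_eqtl}


def trs_effect_recovery(seed: int = 0, n_reps: int = 40, d: float = 1.1,
                        n_case: int = 75, n_control: int = 12) -> dict:
    """Planted summed-z effect of d=1.1 at 75 vs 12, mean over replicates."""
    from .trs import trs_group_contrast
    ds = []
    for rep in range(n_reps):
        expr, labels, defn = simulate_trs_cohort(
            n_case=n_case, n_control=n_control, d=d,
            seed=seed * n_reps + rep)
        scores = compute_trs(expr, TrsDefinition(defn), groups=labels)
        res = trs_group_contrast(scores, "control")
        ds.append(res["contrasts"]["case"]["delta_sd"])
    return {"mean_delta_sd": float(np.mean(ds)), "sd_delta_sd":
            float(np.std(ds, ddof=1)), "n_reps": n_reps,
            "anova_p_last": res["anova"]["p"]}


# ---------------------------------------------------------------------------
# signatures


def _expr_from(values, unit="log-normalized"):
    values = np.asarray(values, dtype=float)
    ids = pd.Index([f"g{i}" for i in range(values.shape[0])], name="gene_id")
    genes = pd.DataFrame({"chrom": "1", "start": 1, "stop": 1000,
                          "length": 1000}, index=ids)
    cols = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=ids, columns=cols),
                            genes, unit=unit)


def adjusted_rand_index(a, b) -> float:
    """ARI from the pair-counting contingency formula."""
    a, b = pd.Categorical(a).codes, pd.Categorical(b).codes
    tab = pd.crosstab(a, b).to_numpy()
    n = tab.sum()
    sum_comb = comb(tab, 2).sum()
    sum_a = comb(tab.sum(axis=1), 2).sum()
    sum_b = comb(tab.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    return float((sum_comb - expected) / (max_index - expected))


def signatures_recovery(seed: int = 0) -> dict:
    """Axis-score, PVCA, and clustering recovery of planted structure."""
    rng = np.random.default_rng(seed)
    # one-factor module carrying 75% of per-gene variance, 40 genes
    share, n, g = 0.75, 500, 40
    f = rng.standard_normal(n)
    values = f[None, :] + rng.normal(0, np.sqrt((1 - share) / share), (g, n))
    st = axis_score(_expr_from(values), [f"g{i}" for i in range(g)])
    axis_cor = float(np.corrcoef(st.scores["axis"], f)[0, 1])
    axis_ve = st.variance_explained["axis"]

    # disease factor explaining 30% of expression variance
    n2, g2, share2 = 200, 50, 0.3
    d = rng.permutation(np.repeat([0.0, 1.0], n2 // 2))
    load = rng.standard_normal(g2)
    load /= np.linalg.norm(load)
    dc = (d - d.mean()) / d.std()
    noise = rng.normal(0, 1, (g2, n2))
    signal = load[:, None] * dc[None, :]
    alpha = np.sqrt(share2 / (1 - share2) * noise.var() * g2
                    / (signal ** 2).sum() * n2)
    values2 = alpha * signal + noise
    expr2 = _expr_from(values2)
    factors = pd.DataFrame({"disease": np.where(d == 1, "x", "y")},
                           index=expr2.sample_ids)
    pv = pvca(expr2, factors, n_pc=10)
    planted_share = float((alpha * signal).var() / values2.var())

    # six separated clusters
    k, per, g3 = 6, 25, 40
    centers = rng.normal(0, 4, (k, g3))
    blobs = np.vstack([centers[i] + rng.normal(0, 1, (per, g3))
                       for i in range(k)]).T
    truth = np.repeat(np.arange(k), per)
    expr3 = _expr_from(blobs).zscore()
    assign, _ = cluster_samples(expr3, k=k)
    ari = adjusted_rand_index(truth, assign.to_numpy())
    return {"axis_correlation": axis_cor, "axis_variance_explained": axis_ve,
            "planted_axis_share": share, "pvca_disease_share": float(pv["disease"]),
            "planted_pvca_share": planted_share, "cluster_ari": ari}


# ---------------------------------------------------------------------------
# filters vs brute force


def filter_oracle_agreement(seed: int = 0, n_matrices: int = 100) -> dict:
    """Exact agreement of both filters with independent per-rule scans."""
    from .preprocess import hwe_pvalue
    rng = np.random.default_rng(seed)
    expr_ok = geno_ok = 0
    for it in range(n_matrices):
        # expression filter
        n_g, n_s = 60, 25
        lam = rng.uniform(0.2, 20, n_g)
        ids = pd.Index([f"g{i}" for i in range(n_g)], name="gene_id")
        genes = pd.DataFrame({"chrom": "1", "start": 1, "stop": 1000,
                              "length": rng.integers(500, 5000, n_g)},
                             index=ids)
        counts = ExpressionMatrix(
            pd.DataFrame(rng.poisson(lam[:, None], (n_g, n_s)), index=ids,
                         columns=[f"s{j}" for j in range(n_s)]),
            genes, unit="raw-count")
        if counts.values.sum(axis=0).min() == 0:
            continue
        kept, _ = filter_expressed_genes(counts)
        fpkm = compute_fpkm(counts).values
        expected = [g for g in ids
                    if int((counts.values.loc[g] > 6).sum()) > 10
                    and fpkm.loc[g].mean() > 0.1]
        kept2, _ = filter_expressed_genes(kept)
        expr_ok += (list(kept.gene_ids) == expected
                    and kept2.values.equals(kept.values))

        # genotype QC
        n_v, n_i = 25, 120
        sids = pd.Index([f"v{i}" for i in range(n_v)], name="snp_id")
        snps = pd.DataFrame({"chrom": "1", "pos": np.arange(n_v) * 100 + 1,
                             "ref": "A",
                             "alt": rng.choice(["G", "G", "G,T"], n_v)},
                            index=sids)
        dos = rng.binomial(2, rng.uniform(0.0, 0.5, n_v)[:, None],
                           (n_v, n_i)).astype(float)
        miss = rng.random((n_v, n_i)) < rng.uniform(0, 0.1, n_v)[:, None]
        dos[miss] = np.nan
        geno = GenotypeMatrix(
            pd.DataFrame(dos, index=sids,
                         columns=[f"s{j}" for j in range(n_i)]), snps)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kept_g, _ = qc_genotypes(geno)
            again, _ = qc_genotypes(kept_g)
        exp_g = []
        for i, sid in enumerate(sids):
            row = pd.Series(dos[i]).dropna()
            p = row.mean() / 2
            hwe = hwe_pvalue(int((row == 1).sum()), int((row == 2).sum()),
                             int((row == 0).sum()))
            if (min(p, 1 - p) >= 0.01 and hwe >= 1e-3
                    and np.isnan(dos[i]).mean() <= 0.05
                    and snps.loc[sid, "alt"] in "ACGT"):
                exp_g.append(sid)
        geno_ok += (list(kept_g.snp_ids) == exp_g
                    and again.dosages.equals(kept_g.dosages))
    return {"expression_filter_agreement": expr_ok / n_matrices,
            "genotype_qc_agreement": geno_ok / n_matrices,
            "n_matrices": n_matrices}


# ---------------------------------------------------------------------------
# determinism


def pipeline_determinism(seed: int = 0, out_root=None) -> dict:
    """Two full synthetic runs with one seed: manifest hashes must match."""
    import tempfile
    from .pipeline import run_pipeline
    root = tempfile.mkdtemp(dir=out_root)
    mk = lambda tag: {"out_dir": f"{root}/{tag}", "seed": seed,
                      "sim": {"n_genes": 30, "n_snps": 120, "n_eqtl": 8,
                              "beta": 0.9, "gwas_frac": 1.0},
                      "eqtl": {"n_perms": 12}}
    m1 = run_pipeline(mk("r1"))
    m2 = run_pipeline(mk("r2"))
    identical = m1["outputs"] == m2["outputs"]
    return {"identical_hashes": bool(identical),
            "n_output_files": len(m1["outputs"])}
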