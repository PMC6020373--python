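"""End-to-end pipeline runner with config validation and provenance.

A single flat YAML config (sections per stage, unknown keys rejected)
drives: simulate -> preprocess -> signatures | eqtl (per cohort) ->
interaction -> coloc -> trs.  Every enabled stage writes plain-text
outputs under ``out_dir`` and the manifest records parameters, seeds,
per-stage row counts and SHA-256 hashes of every file, so a rerun with
the same seed is verifiable as bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as btio
from .containers import BloodtxError
from .coloc import SummarySeries, colocalize
from .eqtl import build_cis_pairs, call_eqtls, significant_peaks
from .interaction import (call_interactions, interaction_test, pool_cohorts,
                          records_frame)
from .preprocess import (adjust_latent_factors, filter_expressed_genes,
                         normalize_expression, qc_genotypes)
from .signatures import btm_scores, cluster_samples, group_anova, pvca
from .simulate import SimConfig, default_eqtl_plan, simulate_cohort
from .trs import build_trs_definition, compute_trs, trs_group_contrast

log = logging.getLogger("bloodtx.pipeline")

ALL_STAGES = ("simulate", "preprocess", "signatures", "eqtl", "interaction",
              "coloc", "trs")

_SCHEMA = {
    "out_dir": None,
    "seed": None,
    "stages": None,
    "sim": {"n_genes", "n_snps", "n_samples_per_group", "maf_range",
            "ld_block_size", "ld_rho", "n_modules", "module_size",
            "loading_sd", "n_latent_confounders", "noise_sd", "missing_rate",
            "n_eqtl", "beta", "beta_b", "shared", "gwas_frac",
            "group_shift_plan"},
    "cohort_a": None,
    "cohort_b": None,
    "preprocess": {"min_individuals", "min_count", "min_fpkm", "n_factors"},
    "signatures": {"k", "n_pc"},
    "eqtl": {"window", "p_threshold", "n_perms"},
    "interaction": {"fdr", "nominal_p"},
    "coloc": {"p1", "p2", "p12"},
    "trs": {"h4_min", "reference_group"},
}


def validate_config(cfg: dict) -> dict:
    unknown = set(cfg) - set(_SCHEMA)
    if unknown:
        raise BloodtxError(f"unknown config keys: {sorted(unknown)}")
    for key, allowed in _SCHEMA.items():
        if allowed is None or key not in cfg:
            continue
        bad = set(cfg[key]) - allowed
        if bad:
            raise BloodtxError(f"unknown keys in [{key}]: {sorted(bad)}")
    if "out_dir" not in cfg:
        raise BloodtxError("config requires out_dir")
    stages = cfg.get("stages", list(ALL_STAGES))
    bad = set(stages) - set(ALL_STAGES)
    if bad:
        raise BloodtxError(f"unknown stages: {sorted(bad)}")
    order = [s for s in ALL_STAGES if s in stages]
    deps = {"preprocess": "simulate", "signatures": "preprocess",
            "interaction": "eqtl", "coloc": "eqtl", "trs": "coloc"}
    for stage, need in deps.items():
        if stage in order and need not in order:
            raise BloodtxError(f"stage {stage!r} requires {need!r}")
    cfg = dict(cfg)
    cfg["stages"] = order
    cfg.setdefault("seed", 0)
    cfg.setdefault("cohort_a", ["oligoJIA", "polyJIA", "sJIA"])
    cfg.setdefault("cohort_b", ["CD", "UC"])
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_sim_config(cfg: dict) -> tuple[SimConfig, dict]:
    sim_cfg = dict(cfg.get("sim", {}))
    n_eqtl = sim_cfg.pop("n_eqtl", 10)
    beta = sim_cfg.pop("beta", 0.8)
    beta_b = sim_cfg.pop("beta_b", None)
    shared = sim_cfg.pop("shared", True)
    gwas_frac = sim_cfg.pop("gwas_frac", 1.0)
    if "maf_range" in sim_cfg:
        sim_cfg["maf_range"] = tuple(sim_cfg["maf_range"])
    if "group_shift_plan" in sim_cfg:
        sim_cfg["group_shift_plan"] = {
            int(k): dict(v) for k, v in sim_cfg["group_shift_plan"].items()}
    config = SimConfig(seed=int(cfg["seed"]), **sim_cfg)
    config.eqtl_plan = default_eqtl_plan(
        config, n_eqtl=n_eqtl, beta=beta, beta_b=beta_b, shared=shared,
        groups_a=tuple(cfg["cohort_a"]), groups_b=tuple(cfg["cohort_b"]),
        gwas_frac=gwas_frac)
    return config, {"n_eqtl": n_eqtl, "beta": beta, "beta_b": beta_b,
                    "shared": shared, "gwas_frac": gwas_frac}


def run_pipeline(cfg: dict) -> dict:
    """Execute enabled stages in dependency order; returns the manifest."""
    cfg = validate_config(cfg)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {"seed": seed, "stages": cfg["stages"], "outputs": {},
                "counts": {}, "timings_s": {}, "params": {}}

    def emit(name: str, writer, *args):
        path = out / name
        writer(*args, path) if args else None
        manifest["outputs"][name] = _sha256(path)

    def timed(stage):
        t0 = time.time()
        return lambda: manifest["timings_s"].__setitem__(
            stage, round(time.time() - t0, 3))

    state: dict = {}
    try:
        if "simulate" in cfg["stages"]:
            done = timed("simulate")
            config, plan_params = _build_sim_config(cfg)
            manifest["params"]["sim"] = plan_params
            geno, sim, labels, gwas = simulate_cohort(config)
            state.update(geno=geno, sim=sim, labels=labels, gwas=gwas,
                         sim_config=config)
            emit("genotypes.vcf", btio.write_vcf, geno)
            emit("dosages.tsv", btio.write_dosage_tsv, geno)
            emit("counts.tsv", btio.write_counts_tsv, sim.counts)
            emit("genes.bed", btio.write_bed, sim.log_expr.genes)
            emit("metadata.tsv", btio.write_metadata_tsv, labels)
            gmt = {f"module_{k}": v for k, v in sim.truth.module_genes.items()}
            emit("modules.gmt", btio.write_gmt, gmt)
            if gwas is not None:
                emit("gwas_summary.tsv", btio.write_gwas_tsv, gwas)
            (out / "ground_truth.json").write_text(sim.truth.to_json())
            manifest["outputs"]["ground_truth.json"] = _sha256(
                out / "ground_truth.json")
            manifest["counts"]["simulate"] = {
                "n_samples": int(len(labels)), "n_snps": geno.n_snps,
                "n_genes": sim.log_expr.n_genes}
            done()

        if "preprocess" in cfg["stages"]:
            done = timed("preprocess")
            pp = cfg.get("preprocess", {})
            geno_qc, qc_report = qc_genotypes(state["geno"])
            kept, _ = filter_expressed_genes(
                state["sim"].counts,
                min_individuals=pp.get("min_individuals", 10),
                min_count=pp.get("min_count", 6),
                min_fpkm=pp.get("min_fpkm", 0.1))
            normed = normalize_expression(kept)
            protected = state["labels"].to_frame()
            n_factors = pp.get("n_factors", 5)
            adjusted = adjust_latent_factors(normed, protected,
                                             n_factors=n_factors)
            state.update(geno_qc=geno_qc, expr=adjusted)
            emit("expression_adjusted.tsv", btio.write_counts_tsv, adjusted)
            btio.write_json(qc_report, out / "qc_report.json")
            manifest["outputs"]["qc_report.json"] = _sha256(out / "qc_report.json")
            manifest["counts"]["preprocess"] = {
                "genes_kept": adjusted.n_genes, "snps_kept": geno_qc.n_snps}
            done()

        if "signatures" in cfg["stages"]:
            done = timed("signatures")
            sg = cfg.get("signatures", {})
            expr = state["expr"]
            collection = {f"module_{k}": v
                          for k, v in state["sim"].truth.module_genes.items()}
            scores = btm_scores(expr, collection, groups=state["labels"])
            anova = group_anova(scores)
            assign, membership = cluster_samples(
                expr.zscore(), k=min(sg.get("k", 6), expr.n_samples),
                groups=state["labels"])
            pv = pvca(expr, state["labels"].to_frame(),
                      n_pc=sg.get("n_pc", 5))
            scores.scores.to_csv(out / "module_scores.tsv", sep="\t",
                                 index_label="sample")
            membership.to_csv(out / "cluster_membership.tsv", sep="\t")
            pv.to_csv(out / "pvca.tsv", sep="\t", header=["proportion"])
            for f in ("module_scores.tsv", "cluster_membership.tsv", "pvca.tsv"):
                manifest["outputs"][f] = _sha256(out / f)
            manifest["counts"]["signatures"] = {
                "n_modules": scores.scores.shape[1],
                "anova_min_p": float(anova["p"].min())}
            done()

        if "eqtl" in cfg["stages"]:
            done = timed("eqtl")
            eq = cfg.get("eqtl", {})
            expr = state.get("expr", state["sim"].log_expr)
            geno = state.get("geno_qc", state["geno"])
            pairs = build_cis_pairs(expr.genes, geno.snps,
                                    window=eq.get("window", 250_000))
            callsets = {}
            for tag, groups in (("A", cfg["cohort_a"]), ("B", cfg["cohort_b"])):
                samples = state["labels"][state["labels"].isin(groups)].index
                sub_expr = type(expr)(expr.values[samples], expr.genes,
                                      unit=expr.unit)
                cs = call_eqtls(pairs, geno.subset_samples(samples), sub_expr,
                                p_threshold=eq.get("p_threshold", 1e-4),
                                n_perms=eq.get("n_perms", 20), cohort=tag,
                                seed=seed)
                callsets[tag] = cs
                cs.peaks.to_csv(out / f"eqtl_peaks_{tag}.tsv", sep="\t")
                manifest["outputs"][f"eqtl_peaks_{tag}.tsv"] = _sha256(
                    out / f"eqtl_peaks_{tag}.tsv")
            state["callsets"] = callsets
            state["pairs"] = pairs
            manifest["counts"]["eqtl"] = {
                tag: int((cs.peaks["p"] < cs.p_threshold).sum())
                for tag, cs in callsets.items()}
            manifest["params"]["eqtl_fdr"] = {
                tag: cs.empirical_fdr for tag, cs in callsets.items()}
            done()

        if "interaction" in cfg["stages"]:
            done = timed("interaction")
            it = cfg.get("interaction", {})
            expr = state.get("expr", state["sim"].log_expr)
            geno = state.get("geno_qc", state["geno"]).mean_imputed()
            cand = pool_cohorts(significant_peaks(state["callsets"]["A"]),
                                significant_peaks(state["callsets"]["B"]))
            labels = state["labels"]
            in_a = labels.isin(cfg["cohort_a"])
            in_b = labels.isin(cfg["cohort_b"])
            use = labels.index[in_a | in_b]
            disease = in_b.astype(float)[use]
            recs = []
            for _, row in cand.iterrows():
                if row.snp_id not in geno.snp_ids or row.gene_id not in expr.gene_ids:
                    continue
                recs.append(interaction_test(
                    geno.dosages.loc[row.snp_id, use],
                    expr.values.loc[row.gene_id, use], disease,
                    snp_id=row.snp_id, gene_id=row.gene_id))
            res = call_interactions(records_frame(recs),
                                    fdr=it.get("fdr", 0.10),
                                    nominal_p=it.get("nominal_p", 0.02))
            res["records"].to_csv(out / "interactions.tsv", sep="\t",
                                  index=False)
            manifest["outputs"]["interactions.tsv"] = _sha256(
                out / "interactions.tsv")
            manifest["counts"]["interaction"] = {
                "n_candidates": len(cand),
                "n_called_fdr": res["n_called_fdr"],
                "n_nominal": res["n_nominal"]}
            state["interactions"] = res
            done()

        if "coloc" in cfg["stages"]:
            done = timed("coloc")
            cl = cfg.get("coloc", {})
            gwas = state.get("gwas")
            if gwas is None:
                raise BloodtxError("coloc stage requires simulated GWAS loci "
                                   "(sim.gwas_frac > 0)")
            results = {}
            all_rec = state["callsets"]["A"].all_records
            for gene_id, sub in all_rec.groupby("gene_id"):
                gsub = gwas[gwas["locus_gene"] == gene_id]
                if gsub.empty:
                    continue
                pos = state["geno"].snps.loc[sub["snp_id"], "pos"].to_numpy()
                s_eqtl = SummarySeries(pd.DataFrame({
                    "snp_id": sub["snp_id"].to_numpy(), "position": pos,
                    "beta": sub["beta"].to_numpy(), "se": sub["se"].to_numpy(),
                    "n": sub["n"].to_numpy()}), trait_type="quant")
                s_gwas = SummarySeries(gsub.rename(columns={
                    "position": "position"})[["snp_id", "position", "beta",
                                              "se", "n"]],
                                       trait_type="cc")
                results[gene_id] = colocalize(
                    s_eqtl, s_gwas, p1=cl.get("p1", 1e-4),
                    p2=cl.get("p2", 1e-4), p12=cl.get("p12", 1e-5))
            if not results:
                raise BloodtxError("no loci shared between eQTL and GWAS")
            btio.write_json({g: r.as_dict() for g, r in results.items()},
                            out / "coloc.json")
            manifest["outputs"]["coloc.json"] = _sha256(out / "coloc.json")
            manifest["counts"]["coloc"] = {
                "n_loci": len(results),
                "n_h4_gt_0.5": int(sum(r.pp4 > 0.5 for r in results.values()))}
            state["coloc"] = results
            done()

        if "trs" in cfg["stages"]:
            done = timed("trs")
            tr = cfg.get("trs", {})
            expr = state.get("expr", state["sim"].log_expr)
            peaks = state["callsets"]["A"].peaks.join(
                state["geno"].snps[["ref", "alt"]], on="snp_id")
            definition = build_trs_definition(
                state["gwas"], peaks, state["coloc"],
                h4_min=tr.get("h4_min", 0.5))
            scores = compute_trs(expr, definition, groups=state["labels"])
            reference = tr.get("reference_group", "control")
            contrast = trs_group_contrast(scores, reference)
            definition.table.to_csv(out / "trs_definition.tsv", sep="\t",
                                    index=False)
            scores.scores.to_frame().join(state["labels"]).to_csv(
                out / "trs_scores.tsv", sep="\t", index_label="sample")
            btio.write_json(contrast, out / "trs_contrast.json")
            for f in ("trs_definition.tsv", "trs_scores.tsv",
                      "trs_contrast.json"):
                manifest["outputs"][f] = _sha256(out / f)
            manifest["counts"]["trs"] = {
                "n_definition_genes": len(definition.table),
                "anova_p": contrast["anova"]["p"]}
            state["trs"] = (definition, scores, contrast)
            done()
    except Exception as exc:
        manifest["failure"] = {"stage": "unknown", "error": str(exc)}
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str))
        raise

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return manifest
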