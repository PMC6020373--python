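"""Synthetic cohort generator with known ground truth.

Emulates the structure of a pediatric autoimmune whole-blood study: six
disease groups (healthy controls, oligoarticular/polyarticular/systemic
juvenile arthritis, Crohn's disease, ulcerative colitis), HWE genotypes
with first-order LD blocks, co-expression modules driven by latent immune
axes, planted cis-eQTL that may be shared or disease-specific, per-group
mean shifts along modules, latent technical confounders, and GWAS summary
statistics with known risk-allele directions.

All randomness flows from ``SimConfig.seed`` through
``numpy.random.default_rng`` (PCG64); a fixed seed gives bit-identical
output across runs and platforms.  Expression is simulated on the log
scale with Gaussian noise; a raw-count view (multinomial read sampling) is
emitted alongside for testing count-level filters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import BloodtxError, ExpressionMatrix, GenotypeMatrix

#: Cohort layout of the motivating study: 202 subjects across six groups.
DEFAULT_GROUPS = {
    "control": 12,
    "oligoJIA": 43,
    "polyJIA": 46,
    "sJIA": 26,
    "CD": 60,
    "UC": 15,
}

GENE_SPACING = 1_000_000     # bp between gene starts; keeps cis windows disjoint
GENE_LENGTH = 20_000         # bp
CIS_MARGIN = 240_000         # SNPs placed within +/-240 kb of the gene body


class SimConfigError(BloodtxError):
    pass


@dataclass
class PlantedEqtl:
    """A planted cis regulatory effect, possibly disease-specific.

    ``beta_per_disease`` maps group label -> additive effect per ALT-allele
    copy in units of the residual expression SD.  ``gwas_locus=True`` marks
    the SNP as a GWAS risk locus so that a summary series is emitted for it;
    ``risk_allele_is_alt`` fixes the ground-truth risk allele.
    """

    snp_id: str
    gene_id: str
    beta_per_disease: dict[str, float]
    gwas_locus: bool = False
    risk_allele_is_alt: bool = True

    @property
    def shared(self) -> bool:
        betas = list(self.beta_per_disease.values())
        return len(set(betas)) == 1


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults mirror the motivating cohort: 202 samples in six groups,
    modest LD (first-order copying, rho=0.9, blocks of 5), three immune-like
    co-expression modules of 10 genes, one latent technical confounder, and
    unit residual noise on the log-expression scale.
    """

    n_samples_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS))
    n_genes: int = 200
    n_snps: int = 600
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_size: int = 5
    ld_rho: float = 0.9
    n_modules: int = 3
    module_size: int = 10
    loading_sd: float = 0.25          # gene loadings ~ N(1, loading_sd)
    n_latent_confounders: int = 1
    confounder_loading_sd: float = 0.5
    eqtl_plan: list[PlantedEqtl] = field(default_factory=list)
    group_shift_plan: dict[int, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    count_depth: int = 2_000_000      # mean library size for the count view
    gwas_n_cases: int = 10_000
    gwas_n_controls: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        counts = [self.n_genes, self.n_snps, self.ld_block_size,
                  self.n_modules, self.module_size, self.count_depth,
                  *self.n_samples_per_group.values()]
        if not self.n_samples_per_group:
            raise SimConfigError("n_samples_per_group is empty")
        if any(c <= 0 for c in counts):
            raise SimConfigError("all counts must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SimConfigError(f"maf_range {self.maf_range} not within (0, 0.5]")
        if not 0 <= self.ld_rho <= 1:
            raise SimConfigError("ld_rho must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise SimConfigError("missing_rate must be in [0, 1)")
        if self.n_modules * self.module_size > self.n_genes:
            raise SimConfigError("modules do not fit into n_genes")

    @property
    def n_samples(self) -> int:
        return sum(self.n_samples_per_group.values())


@dataclass
class GroundTruth:
    """Everything planted: recovery tests read this, never re-derive it."""

    labels: pd.Series                       # sample -> group
    module_genes: dict[int, list[str]]
    factors: pd.DataFrame                   # module x sample latent factors
    loadings: pd.DataFrame                  # gene x module loading (0 off-module)
    confounders: pd.DataFrame               # confounder x sample
    confounder_loadings: pd.DataFrame       # gene x confounder
    group_shift_plan: dict[int, dict[str, float]]
    eqtl_plan: list[PlantedEqtl]
    risk_polarity: dict[str, int]           # gene -> +1/-1 (risk allele raises/lowers expr)

    def to_json(self) -> str:
        payload = {
            "labels": self.labels.to_dict(),
            "module_genes": {str(k): v for k, v in self.module_genes.items()},
            "group_shift_plan": {str(k): v for k, v in self.group_shift_plan.items()},
            "eqtl_plan": [asdict(e) for e in self.eqtl_plan],
            "risk_polarity": self.risk_polarity,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def sample_labels(config: SimConfig) -> pd.Series:
    """Deterministic sample ids S0001.. with group labels in config order."""
    ids, groups = [], []
    i = 1
    for g, n in config.n_samples_per_group.items():
        for _ in range(n):
            ids.append(f"S{i:04d}")
            groups.append(g)
            i += 1
    return pd.Series(groups, index=pd.Index(ids, name="sample"), name="group")


def gene_table(config: SimConfig) -> pd.DataFrame:
    """Gene annotation: evenly spaced genes on chr1, cis windows disjoint."""
    starts = GENE_SPACING * (1 + np.arange(config.n_genes))
    return pd.DataFrame(
        {
            "chrom": "1",
            "start": starts,
            "stop": starts + GENE_LENGTH - 1,
            "length": GENE_LENGTH,
        },
        index=pd.Index([f"G{i:04d}" for i in range(config.n_genes)], name="gene_id"),
    )


def snp_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """SNPs assigned to genes in contiguous chunks, placed in the cis window."""
    genes = gene_table(config)
    per_gene = np.full(config.n_genes, config.n_snps // config.n_genes)
    per_gene[: config.n_snps % config.n_genes] += 1
    rows = []
    snp_idx = 0
    bases = np.array(list("ACGT"))
    for (gid, g), k in zip(genes.iterrows(), per_gene):
        if k == 0:
            continue
        lo, hi = g.start - CIS_MARGIN, g.stop + CIS_MARGIN
        pos = np.sort(rng.choice(np.arange(lo, hi), size=k, replace=False))
        for p in pos:
            ref, alt = rng.choice(bases, size=2, replace=False)
            rows.append((f"rs{snp_idx:05d}", "1", int(p), ref, alt, gid))
            snp_idx += 1
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt",
                                     "cis_gene"]).set_index("snp_id")
    return df


def generate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """HWE genotypes with first-order LD copying within blocks.

    Each sample carries two independent haplotypes.  Within an LD block
    (blocks never span genes), each haplotype copies the previous SNP's
    allele with probability ``ld_rho`` and otherwise redraws a fresh
    Bernoulli(p) allele; the genotype is the haplotype sum, so HWE holds by
    construction.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    snps = snp_table(config, rng)
    labels = sample_labels(config)
    n = len(labels)
    m = len(snps)
    p = rng.uniform(*config.maf_range, size=m)

    hap = np.empty((m, 2 * n), dtype=np.int8)
    cis_gene = snps["cis_gene"].to_numpy()
    within = np.zeros(m, dtype=int)
    for j in range(1, m):
        within[j] = within[j - 1] + 1 if cis_gene[j] == cis_gene[j - 1] else 0
    new_block = (within % config.ld_block_size == 0)
    for j in range(m):
        fresh = rng.random(2 * n) < p[j]
        if new_block[j]:
            hap[j] = fresh
        else:
            copy = rng.random(2 * n) < config.ld_rho
            hap[j] = np.where(copy, hap[j - 1], fresh)

    dosage = (hap[:, :n] + hap[:, n:]).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan
    dosages = pd.DataFrame(dosage, index=snps.index, columns=labels.index)
    return GenotypeMatrix(dosages, snps.drop(columns="cis_gene"))


@dataclass
class ExpressionSim:
    log_expr: ExpressionMatrix      # log-scale values (unit log-normalized)
    counts: ExpressionMatrix        # multinomial raw-count view
    truth: GroundTruth


def generate_expression(config: SimConfig, genotypes: GenotypeMatrix,
                        labels: pd.Series) -> ExpressionSim:
    """Latent-factor + group-shift + planted-eQTL + confounder expression.

    Per-gene value = loading x module factor + group shift + sum of planted
    eQTL beta(disease) x dosage + confounder loading x confounder + N(0,
    noise_sd).  The count view exponentiates gene baselines plus the log
    values and samples reads multinomially per sample.
    """
    config.validate()
    if not labels.index.equals(genotypes.sample_ids):
        missing = genotypes.sample_ids.difference(labels.index)
        if len(missing):
            raise BloodtxError(f"labels missing for samples {list(missing[:5])}")
        labels = labels.reindex(genotypes.sample_ids)
    rng = np.random.default_rng([config.seed, 2])
    genes = gene_table(config)
    n = len(labels)
    gids = genes.index

    module_genes = {
        k: list(gids[k * config.module_size:(k + 1) * config.module_size])
        for k in range(config.n_modules)
    }
    factors = pd.DataFrame(rng.standard_normal((config.n_modules, n)),
                           index=range(config.n_modules), columns=labels.index)
    loadings = pd.DataFrame(0.0, index=gids, columns=range(config.n_modules))
    for k, mg in module_genes.items():
        loadings.loc[mg, k] = rng.normal(1.0, config.loading_sd, size=len(mg))

    values = loadings.to_numpy() @ factors.to_numpy()

    # per-module per-group mean shifts
    for k, shifts in config.group_shift_plan.items():
        if k not in module_genes:
            raise BloodtxError(f"group_shift_plan references unknown module {k}")
        shift = labels.map(lambda g: shifts.get(g, 0.0)).to_numpy()
        rows = gids.get_indexer(module_genes[k])
        values[rows] += shift

    # planted cis-eQTL
    dos = genotypes.mean_imputed().dosages
    for pe in config.eqtl_plan:
        if pe.gene_id not in gids:
            raise BloodtxError(f"eqtl_plan references unknown gene {pe.gene_id}")
        if pe.snp_id not in dos.index:
            raise BloodtxError(f"eqtl_plan references unknown snp {pe.snp_id}")
        beta = labels.map(lambda g: pe.beta_per_disease.get(g, 0.0)).to_numpy()
        values[gids.get_loc(pe.gene_id)] += beta * dos.loc[pe.snp_id].to_numpy()

    confounders = pd.DataFrame(
        rng.standard_normal((config.n_latent_confounders, n)),
        index=[f"C{j}" for j in range(config.n_latent_confounders)],
        columns=labels.index)
    conf_load = pd.DataFrame(
        rng.normal(0.0, config.confounder_loading_sd,
                   size=(config.n_genes, config.n_latent_confounders)),
        index=gids, columns=confounders.index)
    if config.n_latent_confounders:
        values = values + conf_load.to_numpy() @ confounders.to_numpy()

    values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    log_expr = ExpressionMatrix(
        pd.DataFrame(values, index=gids, columns=labels.index),
        genes.copy(), unit="log-normalized")

    # count view: gene baselines spread over ~5 log2 units, multinomial reads
    baseline = rng.uniform(0.0, 5.0, size=config.n_genes)
    intensity = np.power(2.0, values + baseline[:, None])
    probs = intensity / intensity.sum(axis=0, keepdims=True)
    depths = rng.poisson(config.count_depth, size=n)
    counts = np.empty_like(values, dtype=np.int64)
    for j in range(n):
        counts[:, j] = rng.multinomial(depths[j], probs[:, j])
    count_mat = ExpressionMatrix(
        pd.DataFrame(counts, index=gids, columns=labels.index),
        genes.copy(), unit="raw-count")

    risk_polarity = {}
    for pe in config.eqtl_plan:
        if not pe.gwas_locus:
            continue
        beta = np.mean(list(pe.beta_per_disease.values()))
        sign = 1 if beta > 0 else -1
        risk_polarity[pe.gene_id] = sign if pe.risk_allele_is_alt else -sign

    truth = GroundTruth(labels=labels, module_genes=module_genes,
                        factors=factors, loadings=loadings,
                        confounders=confounders, confounder_loadings=conf_load,
                        group_shift_plan=config.group_shift_plan,
                        eqtl_plan=config.eqtl_plan,
                        risk_polarity=risk_polarity)
    return ExpressionSim(log_expr=log_expr, counts=count_mat, truth=truth)


def generate_gwas_summary(config: SimConfig, truth: GroundTruth,
                          genotypes: GenotypeMatrix) -> pd.DataFrame:
    """GWAS summary statistics for every planted risk locus.

    For each planted eQTL flagged ``gwas_locus``, the causal SNP receives a
    case-control log-odds effect whose risk allele matches the planted
    ground truth; the remaining SNPs in the same cis window receive
    z-scores propagated through observed LD (z ~ r x z_causal + N(0,1)).
    SEs follow the standard case-control approximation
    se = 1/sqrt(2 p (1-p) N phi (1-phi)).

    Returns a frame with columns snp_id, position, effect_allele (ALT),
    other_allele (REF), risk_allele, beta, se, p, n — beta is signed for
    the ALT allele, and beta > 0 on the risk allele by construction.
    """
    rng = np.random.default_rng([config.seed, 3])
    risk_loci = [pe for pe in truth.eqtl_plan if pe.gwas_locus]
    if not risk_loci:
        raise BloodtxError("ground truth contains no planted GWAS risk loci")
    n_eff = config.gwas_n_cases + config.gwas_n_controls
    phi = config.gwas_n_cases / n_eff
    dos = genotypes.mean_imputed().dosages
    genes = gene_table(config)
    rows = []
    for pe in risk_loci:
        g = genes.loc[pe.gene_id]
        in_cis = genotypes.snps[
            (genotypes.snps["pos"] >= g.start - CIS_MARGIN - 10_000)
            & (genotypes.snps["pos"] <= g.stop + CIS_MARGIN + 10_000)].index
        sub = dos.loc[in_cis].to_numpy()
        causal = dos.loc[pe.snp_id].to_numpy()
        cc = causal - causal.mean()
        denom = np.sqrt((sub - sub.mean(axis=1, keepdims=True)).var(axis=1)
                        * cc.var())
        denom[denom == 0] = np.inf
        r = ((sub - sub.mean(axis=1, keepdims=True)) @ cc / len(cc)) / denom

        p_alt = np.clip(dos.loc[in_cis].mean(axis=1).to_numpy() / 2, 1e-3, 1 - 1e-3)
        se = 1.0 / np.sqrt(2 * p_alt * (1 - p_alt) * n_eff * phi * (1 - phi))
        # causal log-odds effect, risk allele positive by definition
        beta_risk = rng.uniform(0.10, 0.20)
        z_causal = beta_risk / se[in_cis.get_loc(pe.snp_id)]
        z = r * z_causal + rng.standard_normal(len(in_cis))
        # sign convention: beta reported for the ALT allele
        alt_sign = 1.0 if pe.risk_allele_is_alt else -1.0
        beta_alt = alt_sign * z * se
        from scipy import stats
        pvals = 2 * stats.norm.sf(np.abs(z))
        for i, sid in enumerate(in_cis):
            ref, alt = genotypes.snps.loc[sid, ["ref", "alt"]]
            risk = alt if beta_alt[i] > 0 else ref
            rows.append((sid, int(genotypes.snps.loc[sid, "pos"]), alt, ref,
                         risk, float(beta_alt[i]), float(se[i]),
                         float(max(pvals[i], 1e-300)), n_eff, pe.gene_id,
                         sid == pe.snp_id))
    return pd.DataFrame(rows, columns=["snp_id", "position", "effect_allele",
                                       "other_allele", "risk_allele", "beta",
                                       "se", "p", "n", "locus_gene",
                                       "is_causal"])


def simulate_cohort(config: SimConfig):
    """One-call convenience: genotypes, expression sim, labels, GWAS (if any)."""
    labels = sample_labels(config)
    geno = generate_genotypes(config)
    sim = generate_expression(config, geno, labels)
    gwas = None
    if any(pe.gwas_locus for pe in config.eqtl_plan):
        gwas = generate_gwas_summary(config, sim.truth, geno)
    return geno, sim, labels, gwas


def default_eqtl_plan(config: SimConfig, n_eqtl: int, beta: float = 0.8,
                      groups_a=("oligoJIA", "polyJIA", "sJIA"),
                      groups_b=("CD", "UC"), shared: bool = True,
                      beta_b: float | None = None, gwas_frac: float = 0.0,
                      random_sign: bool = True, seed: int | None = None,
                      ) -> list[PlantedEqtl]:
    """Plant one eQTL per gene for the first ``n_eqtl`` genes.

    Uses the middle SNP of each gene's cis chunk as the causal variant.
    With ``shared`` the effect is identical in all groups; otherwise the
    ``groups_b`` cohort gets ``beta_b``.  Signs are randomized per gene so
    recovery correlations are well defined.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    snps = snp_table(config, np.random.default_rng([config.seed, 1]))
    plan = []
    all_groups = list(config.n_samples_per_group)
    for k, gid in enumerate(gene_table(config).index[:n_eqtl]):
        cis = snps.index[snps["cis_gene"] == gid]
        if not len(cis):
            continue
        snp = cis[len(cis) // 2]
        sign = rng.choice([-1.0, 1.0]) if random_sign else 1.0
        b_a, b_b = beta, (beta if beta_b is None else beta_b)
        betas = {}
        for g in all_groups:
            if g in groups_b and not shared:
                betas[g] = sign * b_b
            else:
                betas[g] = sign * b_a
        plan.append(PlantedEqtl(snp_id=snp, gene_id=gid,
                                beta_per_disease=betas,
                                gwas_locus=rng.random() < gwas_frac,
                                risk_allele_is_alt=bool(rng.random() < 0.5)))
    return plan


def simulate_trs_cohort(n_case: int = 75, n_control: int = 12,
                        n_risk_genes: int = 39, d: float = 1.1,
                        n_background_genes: int = 61, seed: int = 0):
    """Case/control expression with a planted summed-z-score effect size.

    Each risk gene is shifted in cases by ``polarity x d/sqrt(G)`` residual
    SDs, so the polarized sum over the G risk genes has Cohen's d close to
    ``d``.  Returns (ExpressionMatrix [log-normalized], labels,
    TrsDefinition-ready frame with the planted polarities).
    """
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    total_genes = n_risk_genes + n_background_genes
    ids = pd.Index([f"G{i:04d}" for i in range(total_genes)], name="gene_id")
    samples = pd.Index([f"S{i:04d}" for i in range(1, n + 1)], name="sample")
    labels = pd.Series(["case"] * n_case + ["control"] * n_control,
                       index=samples, name="group")
    values = rng.standard_normal((total_genes, n))
    polarity = rng.choice([-1, 1], size=n_risk_genes)
    per_gene_shift = d / np.sqrt(n_risk_genes)
    case_mask = (labels == "case").to_numpy()
    values[:n_risk_genes, case_mask] += polarity[:, None] * per_gene_shift
    genes = pd.DataFrame({"chrom": "1",
                          "start": 1 + np.arange(total_genes) * 10_000,
                          "stop": 5_000 + np.arange(total_genes) * 10_000,
                          "length": 5_000}, index=ids)
    expr = ExpressionMatrix(pd.DataFrame(values, index=ids, columns=samples),
                            genes, unit="log-normalized")
    definition = pd.DataFrame({
        "gene_id": ids[:n_risk_genes],
        "polarity": polarity,
        "snp_id": [f"rs{i:05d}" for i in range(n_risk_genes)],
        "risk_allele": "A",
        "h4": 1.0,
    })
    return expr, labels, definition
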