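import numpy as np
import pandas as pd
import pytest

from bloodtx.containers import ExpressionMatrix, GenotypeMatrix
from bloodtx.simulate import SimConfig, default_eqtl_plan, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 202-sample cohort with planted eQTL, GWAS loci and shifts."""
    cfg = SimConfig(n_genes=40, n_snps=160, seed=11,
                    group_shift_plan={0: {"sJIA": 1.0, "CD": 1.2, "UC": 1.2}})
    cfg.eqtl_plan = default_eqtl_plan(cfg, n_eqtl=10, beta=0.9, gwas_frac=1.0)
    geno, sim, labels, gwas = simulate_cohort(cfg)
    return dict(config=cfg, geno=geno, sim=sim, labels=labels, gwas=gwas)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_counts(rng, n_genes=6, n_samples=4, lam=50):
    ids = pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
    samples = [f"s{j}" for j in range(n_samples)]
    genes = pd.DataFrame({"chrom": "1",
                          "start": 1 + 10_000 * np.arange(n_genes),
                          "stop": 2_000 + 10_000 * np.arange(n_genes),
                          "length": 2_000}, index=ids)
    values = pd.DataFrame(rng.poisson(lam, (n_genes, n_samples)),
                          index=ids, columns=samples)
    return ExpressionMatrix(values, genes, unit="raw-count")


def toy_genotypes(rng, n_snps=20, n_samples=100, maf=0.3):
    ids = pd.Index([f"v{i}" for i in range(n_snps)], name="snp_id")
    snps = pd.DataFrame({"chrom": "1",
                         "pos": 100 + 50 * np.arange(n_snps),
                         "ref": "A", "alt": "G"}, index=ids)
    d = rng.binomial(2, maf, (n_snps, n_samples)).astype(float)
    dosages = pd.DataFrame(d, index=ids,
                           columns=[f"s{j}" for j in range(n_samples)])
    return GenotypeMatrix(dosages, snps)
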