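"""FPKM, expression filters, normalization, latent-factor adjustment, QC."""

import numpy as np
import pandas as pd
import pytest

from bloodtx.containers import BloodtxError, ExpressionMatrix, GenotypeMatrix
from bloodtx.preprocess import (QcThresholds, adjust_latent_factors,
                                compute_fpkm, filter_expressed_genes,
                                hwe_chi2_pvalue, hwe_exact_pvalue, hwe_pvalue,
                                normalize_expression, qc_genotypes)

from conftest import toy_counts, toy_genotypes


def _expr(counts, lengths, unit="raw-count"):
    ids = pd.Index([f"g{i}" for i in range(len(counts))], name="gene_id")
    genes = pd.DataFrame({"chrom": "1", "start": 1, "stop": lengths,
                          "length": lengths}, index=ids)
    values = pd.DataFrame(np.atleast_2d(counts), index=ids,
                          columns=[f"s{j}" for j in
                                   range(np.atleast_2d(counts).shape[1])])
    return ExpressionMatrix(values, genes, unit=unit)


class TestFpkm:
    def test_definition_and_hand_computed_table(self):
        # count 100 / (1 kb x 1 M reads) -> 100; zero gene -> 0
        counts = np.array([[100, 200], [0, 0], [900, 1800]])
        e = _expr(counts, [1000, 500, 2000])
        lib = counts.sum(axis=0)  # (1000, 2000)... actually (1000, 2000)
        fp = compute_fpkm(e)
        expected = counts / (np.array([1.0, 0.5, 2.0])[:, None] * lib / 1e6)
        assert np.allclose(fp.values.to_numpy(), expected)
        assert fp.unit == "fpkm"

    def test_simple_case_is_exact(self):
        e = _expr(np.array([[100], [1_000_000 - 100]]), [1000, 1000])
        fp = compute_fpkm(e)
        assert fp.values.iloc[0, 0] == pytest.approx(100.0)

    def test_errors(self):
        e = _expr(np.array([[0], [0]]), [1000, 1000])
        with pytest.raises(BloodtxError, match="zero library"):
            compute_fpkm(e)
        e2 = _expr(np.array([[5], [5]]), [1000, 1000])
        e2.genes.loc["g1", "length"] = np.nan
        with pytest.raises(BloodtxError, match="g1"):
            compute_fpkm(e2)


class TestFilter:
    def test_threshold_boundaries(self):
        # 11 samples with count 7 (>6 in >10 individuals), high FPKM -> kept
        counts = np.tile([7], (1, 11))
        filler = np.tile([7], (1, 11))
        e = _expr(np.vstack([counts, filler]), [1000, 1000])
        kept, report = filter_expressed_genes(e)
        assert report.loc["g0", "kept"]
        # exactly 10 individuals is not enough (strict >)
        counts10 = np.array([[7] * 10 + [0]])
        e2 = _expr(np.vstack([counts10, filler]), [1000, 1000])
        _, report2 = filter_expressed_genes(e2)
        assert not report2.loc["g0", "kept"]

    def test_all_zero_gene_dropped(self, rng):
        e = toy_counts(rng, n_genes=5)
        e.values.iloc[2] = 0
        kept, report = filter_expressed_genes(e)
        assert "g2" not in kept.gene_ids
        assert report.loc["g2", "failed_detection"]

    def test_matches_bruteforce_oracle_and_idempotent(self, rng):
        for _ in range(10):
            lam = rng.uniform(0.5, 15, size=200)
            e = toy_counts(rng, n_genes=200, n_samples=30, lam=1)
            e.values.iloc[:, :] = rng.poisson(lam[:, None], (200, 30))
            kept, _ = filter_expressed_genes(e)
            fpkm = compute_fpkm(e).values
            expected = []
            for g in e.gene_ids:
                row = e.values.loc[g]
                ok = (int((row > 6).sum()) > 10) and (fpkm.loc[g].mean() > 0.1)
                if ok:
                    expected.append(g)
            assert list(kept.gene_ids) == expected
            again, _ = filter_expressed_genes(kept)
            pd.testing.assert_frame_equal(again.values, kept.values)


class TestNormalize:
    def test_scale_invariance(self, rng):
        e = toy_counts(rng, n_genes=50, n_samples=2, lam=200)
        e.values["s1"] = 2 * e.values["s0"]
        n = normalize_expression(e)
        assert np.allclose(n.values["s0"], n.values["s1"])

    def test_matches_hand_computed_logcpm(self):
        counts = np.array([[10, 0], [90, 100]])
        e = _expr(counts, [1000, 1000])
        n = normalize_expression(e)
        lib = counts.sum(axis=0)
        expected = np.log2(counts / lib * 1e6 + 1)
        assert np.allclose(n.values.to_numpy(), expected)
        assert n.unit == "log-normalized"

    def test_empty_errors(self):
        e = ExpressionMatrix(pd.DataFrame(index=pd.Index([], name="gene_id")),
                             pd.DataFrame(), unit="raw-count")
        with pytest.raises(BloodtxError):
            normalize_expression(e)


class TestAdjustLatentFactors:
    @staticmethod
    def _planted(n=120, n_genes=80, seed=0):
        rng = np.random.default_rng(seed)
        disease = np.repeat([0, 1], n // 2)
        batch = rng.standard_normal(n)
        batch -= batch.mean()
        # orthogonalize batch against disease
        d = disease - disease.mean()
        batch -= d * (batch @ d) / (d @ d)
        shift = rng.normal(0, 1, n_genes)
        bload = rng.normal(0, 2, n_genes)
        values = (shift[:, None] * disease[None, :]
                  + bload[:, None] * batch[None, :]
                  + rng.normal(0, 0.5, (n_genes, n)))
        ids = pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
        genes = pd.DataFrame({"chrom": "1", "start": 1, "stop": 1000,
                              "length": 1000}, index=ids)
        cols = [f"s{j}" for j in range(n)]
        expr = ExpressionMatrix(pd.DataFrame(values, index=ids, columns=cols),
                                genes, unit="log-normalized")
        protected = pd.DataFrame(
            {"disease": np.where(disease == 1, "case", "ctrl")}, index=cols)
        return expr, protected, batch, shift, disease

    def test_zero_factors_is_identity(self):
        expr, protected, *_ = self._planted()
        out = adjust_latent_factors(expr, protected, n_factors=0)
        pd.testing.assert_frame_equal(out.values, expr.values)

    def test_removes_batch_keeps_disease(self):
        expr, protected, batch, shift, disease = self._planted()
        out = adjust_latent_factors(expr, protected, n_factors=1)
        v = out.values.to_numpy()
        # oracle: compare against directly regressing out the true batch
        bc = (batch - batch.mean()) / batch.std()
        cors = np.array([np.corrcoef(v[i], bc)[0, 1]
                         for i in range(v.shape[0])])
        assert np.abs(cors).max() < 0.05
        est_shift = (v[:, disease == 1].mean(axis=1)
                     - v[:, disease == 0].mean(axis=1))
        big = np.abs(shift) > 0.5
        rel = np.abs(est_shift[big] - shift[big]) / np.abs(shift[big])
        assert np.median(rel) < 0.1

    def test_sample_and_gene_sets_unchanged(self):
        expr, protected, *_ = self._planted()
        out = adjust_latent_factors(expr, protected, n_factors=3)
        assert out.gene_ids.equals(expr.gene_ids)
        assert out.sample_ids.equals(expr.sample_ids)

    def test_errors(self):
        expr, protected, *_ = self._planted(n=20)
        with pytest.raises(BloodtxError, match="n_factors"):
            adjust_latent_factors(expr, protected, n_factors=19)
        bad = protected.copy()
        bad["dup"] = bad["disease"]
        with pytest.raises(BloodtxError, match="collinear"):
            adjust_latent_factors(expr, bad, n_factors=1)


class TestHwe:
    def test_exact_matches_montecarlo_oracle(self, rng):
        # oracle: random pairings of a fixed allele pool
        n, n_het, n_hom_alt = 100, 21, 18
        n_alt = 2 * n_hom_alt + n_het
        draws = 40_000
        alleles = np.array([1] * n_alt + [0] * (2 * n - n_alt))
        obs_prob = None
        het_counts = np.empty(draws, dtype=int)
        for b in range(draws):
            perm = rng.permutation(alleles)
            het_counts[b] = int((perm[::2] != perm[1::2]).sum())
        # empirical two-sided exact p: mass of het counts at most as probable
        vals, freq = np.unique(het_counts, return_counts=True)
        prob = dict(zip(vals, freq / draws))
        p_obs = prob.get(n_het, 0.0)
        p_mc = sum(q for q in prob.values() if q <= p_obs + 1e-12)
        p_exact = hwe_exact_pvalue(n_het, n_hom_alt, n - n_het - n_hom_alt)
        assert p_exact == pytest.approx(p_mc, abs=0.02)

    def test_chi2_branch_agrees_with_exact_at_large_n(self):
        p_chi = hwe_chi2_pvalue(480, 270, 250)
        p_ex = hwe_exact_pvalue(480, 270, 250)
        assert p_chi == pytest.approx(p_ex, abs=0.05)
        assert hwe_pvalue(480, 270, 250) == p_chi

    def test_equilibrium_is_not_rejected(self):
        assert hwe_pvalue(50, 25, 25) > 0.5


class TestQcGenotypes:
    def test_default_thresholds(self):
        t = QcThresholds()
        assert (t.hwe_p_min, t.maf_min, t.missing_max, t.biallelic_only) == \
            (1e-3, 0.01, 0.05, True)

    def test_monomorphic_dropped(self, rng):
        g = toy_genotypes(rng, n_snps=5)
        g.dosages.iloc[0] = 0.0
        kept, report = qc_genotypes(g)
        assert "v0" not in kept.snp_ids
        assert report["dropped_maf"] >= 1

    def test_matches_independent_per_rule_oracle(self, rng):
        g = toy_genotypes(rng, n_snps=20, n_samples=200)
        # plant: an HWE violation (all hets), a multiallelic, heavy missingness
        g.dosages.iloc[1] = 1.0
        g.snps.iloc[2, g.snps.columns.get_loc("alt")] = "G,T"
        g.dosages.iloc[3, :30] = np.nan
        kept, _ = qc_genotypes(g)
        expected = []
        for i, sid in enumerate(g.snp_ids):
            row = g.dosages.iloc[i].dropna()
            p = row.mean() / 2
            maf = min(p, 1 - p)
            hwe = hwe_pvalue(int((row == 1).sum()), int((row == 2).sum()),
                             int((row == 0).sum()))
            miss = g.dosages.iloc[i].isna().mean()
            alt = g.snps.iloc[i]["alt"]
            if (maf >= 0.01 and hwe >= 1e-3 and miss <= 0.05
                    and alt in "ACGT" and len(alt) == 1):
                expected.append(sid)
        assert list(kept.snp_ids) == expected
        assert "v1" not in kept.snp_ids and "v2" not in kept.snp_ids
        assert "v3" not in kept.snp_ids

    def test_idempotent(self, rng):
        g = toy_genotypes(rng, n_snps=30, n_samples=150)
        once, _ = qc_genotypes(g)
        twice, _ = qc_genotypes(once)
        pd.testing.assert_frame_equal(once.dosages, twice.dosages)

    def test_all_dropped_warns(self, rng):
        g = toy_genotypes(rng, n_snps=3)
        g.dosages.iloc[:] = 0.0
        with pytest.warns(UserWarning, match="all SNPs dropped"):
            kept, _ = qc_genotypes(g)
        assert kept.n_snps == 0

    def test_mean_imputation(self, rng):
        g = toy_genotypes(rng, n_snps=3, n_samples=10)
        g.dosages.iloc[0, 0] = np.nan
        imp = g.mean_imputed()
        assert imp.dosages.iloc[0, 0] == pytest.approx(
            g.dosages.iloc[0, 1:].mean())
        assert not imp.dosages.isna().any().any()
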