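"""Axis/module scores, clustering, PVCA, differential expression, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bloodtx.containers import BloodtxError, ExpressionMatrix, ScoreTable
from bloodtx.signatures import (axis_score, btm_scores, cluster_samples,
                                default_axis_collection,
                                differential_expression, group_anova, pvca)


def _expr(values, unit="log-normalized", prefix="g"):
    values = np.asarray(values, dtype=float)
    ids = pd.Index([f"{prefix}{i}" for i in range(values.shape[0])],
                   name="gene_id")
    genes = pd.DataFrame({"chrom": "1", "start": 1, "stop": 1000,
                          "length": 1000}, index=ids)
    cols = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=ids, columns=cols),
                            genes, unit=unit)


def _planted_module(n=200, n_genes=10, share=0.75, seed=0):
    """One-factor module whose factor carries `share` of per-gene variance."""
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n)
    noise = np.sqrt((1 - share) / share)
    values = f[None, :] + rng.normal(0, noise, (n_genes, n))
    return _expr(values), f


class TestAxisScore:
    def test_identical_rows_give_full_variance_explained(self):
        rng = np.random.default_rng(0)
        profile = rng.standard_normal(30)
        values = np.vstack([2 * profile + 1, -0.5 * profile + 3,
                            profile])  # affine copies of one profile
        st = axis_score(_expr(values), ["g0", "g1", "g2"])
        assert st.variance_explained["axis"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        got = st.scores["axis"].to_numpy()
        assert abs(abs(np.corrcoef(got, z)[0, 1]) - 1) < 1e-12

    def test_recovers_planted_factor_with_positive_orientation(self):
        expr, f = _planted_module(share=0.95)
        st = axis_score(expr, list(expr.gene_ids))
        r = np.corrcoef(st.scores["axis"], f)[0, 1]
        assert abs(r) > 0.99 and r > 0  # loadings all positive -> oriented up

    def test_variance_explained_tracks_planted_share(self):
        expr, _ = _planted_module(share=0.75, n=400)
        st = axis_score(expr, list(expr.gene_ids))
        assert st.variance_explained["axis"] == pytest.approx(0.75, abs=0.05)

    def test_affine_invariance_and_negation(self):
        expr, _ = _planted_module(seed=3)
        st = axis_score(expr, list(expr.gene_ids))
        scaled = _expr(expr.values.to_numpy() * 7.0 + 4.0)
        st2 = axis_score(scaled, list(expr.gene_ids))
        assert np.allclose(st.scores, st2.scores)
        neg = _expr(-expr.values.to_numpy())
        st3 = axis_score(neg, list(expr.gene_ids))
        assert np.allclose(st3.scores, -st.scores)

    def test_too_few_genes_errors(self):
        expr, _ = _planted_module()
        with pytest.raises(BloodtxError, match="resolvable"):
            axis_score(expr, ["g0", "nope"])

    def test_bundled_axis_collection_shape(self):
        coll = default_axis_collection()
        assert set(coll) == {f"axis_{a}" for a in "TBNRIGC"}
        assert all(len(v) == 10 for v in coll.values())


class TestBtmScores:
    def test_single_module_reduces_to_axis_score(self):
        expr, _ = _planted_module()
        st = btm_scores(expr, {"m1": list(expr.gene_ids)})
        ax = axis_score(expr, list(expr.gene_ids), name="m1")
        assert np.allclose(st.scores["m1"], ax.scores["m1"])

    def test_disjoint_modules_uncorrelated(self):
        e1, _ = _planted_module(seed=1)
        e2, _ = _planted_module(seed=2)
        values = np.vstack([e1.values.to_numpy(), e2.values.to_numpy()])
        expr = _expr(values)
        coll = {"a": [f"g{i}" for i in range(10)],
                "b": [f"g{i}" for i in range(10, 20)]}
        st = btm_scores(expr, coll)
        r = np.corrcoef(st.scores["a"], st.scores["b"])[0, 1]
        assert abs(r) < 0.15

    def test_group_mean_matrix_consistent(self):
        expr, _ = _planted_module()
        groups = pd.Series(["x"] * 100 + ["y"] * 100,
                           index=expr.sample_ids)
        st = btm_scores(expr, {"m": list(expr.gene_ids)}, groups=groups)
        gm = st.group_means()
        assert gm.loc["m", "x"] == pytest.approx(
            st.scores.loc[groups == "x", "m"].mean())

    def test_small_modules_skipped_with_warning(self):
        expr, _ = _planted_module()
        with pytest.warns(UserWarning, match="skipped"):
            st = btm_scores(expr, {"ok": list(expr.gene_ids), "tiny": ["g0"]})
        assert list(st.scores.columns) == ["ok"]


class TestClustering:
    def test_two_blobs_recovered_exactly(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, (30, 25))
        b = rng.normal(8, 1, (30, 25))
        expr = _expr(np.hstack([a, b])).zscore()
        assign, _ = cluster_samples(expr, k=2)
        first, second = assign.iloc[:25], assign.iloc[25:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_membership_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        expr = _expr(rng.standard_normal((20, 40))).zscore()
        groups = pd.Series(rng.choice(["u", "v", "w"], 40),
                           index=expr.sample_ids)
        _, membership = cluster_samples(expr, k=4, groups=groups)
        assert np.allclose(membership.sum(axis=1), 1.0, atol=1e-12)

    def test_k_larger_than_samples_errors(self):
        rng = np.random.default_rng(6)
        expr = _expr(rng.standard_normal((5, 4))).zscore()
        with pytest.raises(BloodtxError):
            cluster_samples(expr, k=10)


class TestPvca:
    def test_independent_factor_has_near_zero_share(self):
        rng = np.random.default_rng(7)
        expr = _expr(rng.standard_normal((60, 200)))
        factors = pd.DataFrame({"junk": rng.choice(["a", "b"], 200)},
                               index=expr.sample_ids)
        out = pvca(expr, factors, n_pc=5)
        assert out["junk"] < 0.02

    def test_factor_owning_pc1_gets_its_eigenfraction(self):
        # one factor fully determines a direction carrying ~50% of variance
        rng = np.random.default_rng(8)
        n, g = 200, 40
        d = np.repeat([0.0, 1.0], n // 2)
        load = rng.standard_normal(g)
        load /= np.linalg.norm(load)
        noise = rng.normal(0, 1, (g, n))
        signal = load[:, None] * (d - d.mean())[None, :]
        # scale signal so it carries half the total variance
        alpha = np.sqrt(noise.var() * g / (signal ** 2).mean() / g)
        values = alpha * signal + noise
        expr = _expr(values)
        factors = pd.DataFrame({"d": np.where(d == 1, "x", "y")},
                               index=expr.sample_ids)
        out = pvca(expr, factors, n_pc=10)
        frac = (alpha * signal).var() / values.var()
        assert out["d"] == pytest.approx(frac, abs=0.06)

    def test_proportions_close_budget(self):
        rng = np.random.default_rng(9)
        expr = _expr(rng.standard_normal((30, 100)))
        factors = pd.DataFrame({"f1": rng.choice(["a", "b"], 100),
                                "f2": rng.choice(["c", "d", "e"], 100)},
                               index=expr.sample_ids)
        out = pvca(expr, factors, n_pc=5)
        assert (out >= -1e-12).all()
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_permuting_a_factor_kills_its_share(self):
        rng = np.random.default_rng(10)
        n = 200
        d = rng.choice(["x", "y"], n)
        shift = (d == "x").astype(float)
        values = np.outer(np.ones(30), shift) * 2 + rng.normal(0, 1, (30, n))
        expr = _expr(values)
        factors = pd.DataFrame({"d": d}, index=expr.sample_ids)
        real = pvca(expr, factors, n_pc=5)["d"]
        perm = pd.DataFrame({"d": rng.permutation(d)}, index=expr.sample_ids)
        permuted = pvca(expr, perm, n_pc=5)["d"]
        assert real > 0.2 and permuted < 0.03

    def test_aliased_factors_error(self):
        rng = np.random.default_rng(11)
        expr = _expr(rng.standard_normal((10, 40)))
        d = rng.choice(["a", "b"], 40)
        factors = pd.DataFrame({"f1": d, "f2": d}, index=expr.sample_ids)
        with pytest.raises(BloodtxError, match="aliased"):
            pvca(expr, factors, n_pc=3)


class TestDifferentialExpression:
    @staticmethod
    def _groups(na, nb):
        return pd.Series(["A"] * na + ["B"] * nb,
                         index=[f"s{j}" for j in range(na + nb)])

    def test_bh_step_hand_example(self):
        from statsmodels.stats.multitest import multipletests
        rej, q, *_ = multipletests([0.01, 0.02, 0.03, 0.5], alpha=0.05,
                                   method="fdr_bh")
        assert list(rej) == [True, True, True, False]

    def test_null_simulation_controls_fdr(self):
        rng = np.random.default_rng(12)
        hits = []
        for _ in range(20):
            expr = _expr(rng.standard_normal((1000, 60)))
            res = differential_expression(expr, self._groups(30, 30), "A", "B")
            hits.append(int(res["significant"].sum()))
        assert np.mean(np.array(hits) <= 2) >= 0.9

    def test_planted_shifts_recovered(self):
        rng = np.random.default_rng(13)
        values = rng.standard_normal((1000, 60))
        values[:50, :30] += 2.0
        expr = _expr(values)
        res = differential_expression(expr, self._groups(30, 30), "A", "B")
        called = set(res.index[res["significant"]])
        true = {f"g{i}" for i in range(50)}
        recall = len(called & true) / 50
        fdr = len(called - true) / max(len(called), 1)
        assert recall > 0.9 and fdr <= 0.07
        # direction labels agree with raw group-mean differences
        sig = res[res["significant"]]
        assert (sig["direction"] == np.where(sig["effect"] > 0, "up_in_A",
                                             "up_in_B")).all()

    def test_degenerate_gene_flagged(self):
        rng = np.random.default_rng(14)
        values = rng.standard_normal((5, 10))
        values[0] = 3.14
        expr = _expr(values)
        res = differential_expression(expr, self._groups(5, 5), "A", "B")
        assert res.loc["g0", "degenerate"] and res.loc["g0", "p"] == 1.0

    def test_small_groups_error(self):
        rng = np.random.default_rng(15)
        expr = _expr(rng.standard_normal((5, 4)))
        with pytest.raises(BloodtxError):
            differential_expression(expr, self._groups(2, 2), "A", "B")


class TestGroupAnova:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(16)
        scores = ScoreTable(pd.DataFrame(
            {"s": rng.standard_normal(40)},
            index=[f"s{j}" for j in range(40)]))
        groups = pd.Series(["a"] * 20 + ["b"] * 20, index=scores.scores.index)
        res = group_anova(scores, groups)
        t, _ = stats.ttest_ind(scores.scores["s"][:20], scores.scores["s"][20:])
        assert res.loc["s", "F"] == pytest.approx(t ** 2, abs=1e-10)

    def test_null_p_distribution_uniform(self):
        rng = np.random.default_rng(17)
        n_rep = 500
        scores = ScoreTable(pd.DataFrame(
            rng.standard_normal((90, n_rep)),
            index=[f"s{j}" for j in range(90)],
            columns=[f"r{j}" for j in range(n_rep)]))
        groups = pd.Series(np.repeat(["a", "b", "c"], 30),
                           index=scores.scores.index)
        res = group_anova(scores, groups)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_group_separation_is_significant(self):
        rng = np.random.default_rng(18)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30),
                               rng.normal(2, 1, 30)])
        scores = ScoreTable(pd.DataFrame(
            {"s": vals}, index=[f"s{j}" for j in range(90)]))
        groups = pd.Series(np.repeat(["a", "b", "c"], 30),
                           index=scores.scores.index)
        res = group_anova(scores, groups)
        assert res.loc["s", "p"] < 1e-6

    def test_single_group_errors(self):
        scores = ScoreTable(pd.DataFrame({"s": [1.0, 2.0, 3.0]},
                                         index=["s0", "s1", "s2"]))
        groups = pd.Series(["a", "a", "a"], index=scores.scores.index)
        with pytest.raises(BloodtxError):
            group_anova(scores, groups)
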