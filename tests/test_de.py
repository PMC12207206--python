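import numpy as np
import pandas as pd
import pytest
import scipy.stats

from rwe_ici.de import (
    bh_adjust, fit_gene_linear_models, paired_difference_test,
    preranked_enrichment,
)
from rwe_ici.expression import GeneSignature, normalize_counts


def nb_norm(G=2000, n=40, seed=5, shift_gene=None, shift=0.0):
    """Null NB count matrix -> normalized, optional planted group shift."""
    rng = np.random.default_rng(seed)
    mu = np.clip(2.0 ** rng.normal(5, 1.5, G), 2, None)
    r = 10.0
    counts = rng.negative_binomial(r, r / (r + mu[:, None]), (G, n)).astype(float)
    grp = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    if shift_gene is not None:
        m = mu[shift_gene] * 2.0 ** shift
        counts[shift_gene, grp == "b"] = rng.negative_binomial(
            r, r / (r + m), (grp == "b").sum()
        )
    df = pd.DataFrame(counts, index=[f"g{i:04d}" for i in range(G)],
                      columns=[f"s{j:02d}" for j in range(n)])
    return normalize_counts(df), list(grp)


class TestGeneLinearModels:
    def test_null_type_one_error_calibrated(self):
        norm, grp = nb_norm(G=2000, n=40, seed=5)
        res = fit_gene_linear_models(norm, grp)
        frac = (res["p_value"] < 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(9)
        n = 40
        G = 200
        vals = rng.normal(5, 0.2, (G, n))
        vals[0, n // 2:] += 1.0
        norm = pd.DataFrame(vals, index=[f"g{i}" for i in range(G)],
                            columns=[f"s{j}" for j in range(n)])
        grp = ["a"] * (n // 2) + ["b"] * (n // 2)
        res = fit_gene_linear_models(norm, grp)
        assert 0.8 <= res.loc["g0", "log2_fc"] <= 1.2
        assert res.loc["g0", "q_value"] < 0.01

    def test_permuted_labels_yield_no_discoveries(self):
        norm, grp = nb_norm(G=500, n=30, seed=2)
        rng = np.random.default_rng(17)
        clean = 0
        reps = 100
        for _ in range(reps):
            perm = list(rng.permutation(grp))
            res = fit_gene_linear_models(norm, perm)
            if (res["q_value"] < 0.05).sum() == 0:
                clean += 1
        assert clean >= 0.95 * reps

    def test_matches_two_sample_t_test(self):
        norm, grp = nb_norm(G=50, n=24, seed=8)
        res = fit_gene_linear_models(norm, grp)
        a = norm.loc[:, np.array(grp) == "a"].to_numpy()
        b = norm.loc[:, np.array(grp) == "b"].to_numpy()
        t, p = scipy.stats.ttest_ind(b, a, axis=1, equal_var=True)
        np.testing.assert_allclose(res["t_stat"].to_numpy(), t, rtol=1e-10)
        np.testing.assert_allclose(res["p_value"].to_numpy(), p, rtol=1e-10)

    def test_invariant_to_sample_order_and_gene_shift(self):
        norm, grp = nb_norm(G=100, n=20, seed=3)
        res1 = fit_gene_linear_models(norm, grp)
        order = list(reversed(range(20)))
        res2 = fit_gene_linear_models(
            norm.iloc[:, order], [grp[i] for i in order]
        )
        np.testing.assert_allclose(
            res1["t_stat"].to_numpy(), res2["t_stat"].to_numpy(), atol=1e-10
        )
        shifted = norm.copy()
        shifted.iloc[0] += 7.0
        res3 = fit_gene_linear_models(shifted, grp)
        assert res3["t_stat"].iloc[0] == pytest.approx(res1["t_stat"].iloc[0])
        assert res3["log2_fc"].iloc[0] == pytest.approx(res1["log2_fc"].iloc[0])

    def test_zero_variance_gene_flagged(self):
        norm, grp = nb_norm(G=20, n=10, seed=1)
        norm.iloc[0] = 3.0
        res = fit_gene_linear_models(norm, grp)
        assert bool(res["zero_variance"].iloc[0])
        assert res["p_value"].iloc[0] == 1.0
        assert res["t_stat"].iloc[0] == 0.0

    def test_variance_moderation_tempers_low_variance_outliers(self):
        rng = np.random.default_rng(6)
        n = 12
        vals = rng.normal(5, 1.0, (100, n))
        # a gene with a tiny shift but near-zero noise: huge ordinary t
        vals[0] = 5.0 + np.r_[np.zeros(6), np.full(6, 0.05)]
        vals[0] += rng.normal(0, 1e-3, n)
        norm = pd.DataFrame(vals, index=[f"g{i}" for i in range(100)],
                            columns=[f"s{j}" for j in range(n)])
        grp = ["a"] * 6 + ["b"] * 6
        plain = fit_gene_linear_models(norm, grp)
        mod = fit_gene_linear_models(norm, grp, moderation=True)
        assert abs(mod["t_stat"].iloc[0]) < abs(plain["t_stat"].iloc[0])
        assert (mod["df"] > plain["df"]).all()

    def test_covariate_adjustment_removes_confounding(self):
        rng = np.random.default_rng(21)
        n = 60
        site = np.where(rng.random(n) < 0.5, "lung", "liver")
        grp = np.where(
            rng.random(n) < np.where(site == "lung", 0.8, 0.2), "a", "b"
        )
        vals = rng.normal(0, 0.3, (30, n)) + 2.0 * (site == "liver")
        norm = pd.DataFrame(vals, index=[f"g{i}" for i in range(30)],
                            columns=[f"s{j}" for j in range(n)])
        raw = fit_gene_linear_models(norm, list(grp))
        adj = fit_gene_linear_models(
            norm, list(grp), covariates=pd.DataFrame({"site": site})
        )
        # site drives expression and correlates with group: adjustment kills it
        assert (adj["p_value"] < 0.05).sum() < (raw["p_value"] < 0.05).sum()


class TestPairedTest:
    def make_pairs(self, n=10, shift=1.0, noise=1e-3, seed=0):
        rng = np.random.default_rng(seed)
        pre = rng.normal(5, 1, (50, n))
        post = pre + shift + rng.normal(0, noise, (50, n))
        cols = [f"pre{i}" for i in range(n)] + [f"post{i}" for i in range(n)]
        norm = pd.DataFrame(np.hstack([pre, post]),
                            index=[f"g{i}" for i in range(50)], columns=cols)
        pairs = {f"p{i}": (f"pre{i}", f"post{i}") for i in range(n)}
        return norm, pairs

    def test_identical_pre_post_all_p_one(self):
        norm, pairs = self.make_pairs(shift=0.0, noise=0.0)
        res = paired_difference_test(norm, pairs)
        assert (res["p_value"] == 1.0).all()

    def test_constant_shift_recovered(self):
        norm, pairs = self.make_pairs(shift=1.0, noise=1e-3)
        res = paired_difference_test(norm, pairs)
        np.testing.assert_allclose(res["log2_fc"], 1.0, atol=0.01)
        assert (res["p_value"] < 1e-4).all()

    def test_matches_scipy_one_sample_t(self):
        norm, pairs = self.make_pairs(shift=0.3, noise=0.5, seed=4)
        res = paired_difference_test(norm, pairs)
        d = np.column_stack(
            [norm[b].to_numpy() - norm[a].to_numpy() for a, b in pairs.values()]
        )
        t, p = scipy.stats.ttest_1samp(d, 0.0, axis=1)
        np.testing.assert_allclose(res["t_stat"].to_numpy(), t, rtol=1e-10)
        np.testing.assert_allclose(res["p_value"].to_numpy(), p, rtol=1e-10)

    def test_incomplete_pair_dropped_with_report(self):
        norm, pairs = self.make_pairs(n=5)
        pairs["broken"] = ("missing_pre", "missing_post")
        res = paired_difference_test(norm, pairs)
        assert res.attrs["dropped_pairs"] == ["broken"]
        assert res.attrs["n_pairs"] == 5

    def test_two_pairs_error(self):
        norm, pairs = self.make_pairs(n=2)
        with pytest.raises(ValueError):
            paired_difference_test(norm, pairs)


class TestBHAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_identity(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_reordering_stability(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1.0, 50)
        q = bh_adjust(p)
        perm = rng.permutation(50)
        q2 = bh_adjust(p[perm])
        np.testing.assert_allclose(q2, q[perm])

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.2], [-0.1]])
    def test_out_of_range_error(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)


# ---------------------------------------------------------------------------
# Preranked enrichment


def running_sum_oracle(ranked_stats, hit_mask, weight_exp=1.0):
    """Full O(N) walk of the weighted running-sum statistic."""
    w = np.abs(ranked_stats) ** weight_exp
    wsum = w[hit_mask].sum()
    n_miss = (~hit_mask).sum()
    walk, cur = [], 0.0
    for i in range(len(ranked_stats)):
        cur += w[i] / wsum if hit_mask[i] else -1.0 / n_miss
        walk.append(cur)
    walk = np.array(walk)
    es = walk[np.argmax(np.abs(walk))]
    return es, walk


class TestPrerankedEnrichment:
    RANK = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0],
                     index=["g1", "g2", "g3", "g4", "g5"])

    def test_top_gene_set_es_plus_one(self):
        tab, res = preranked_enrichment(
            self.RANK, [GeneSignature("top", ["g1"])], min_size=1, n_perm=50,
            seed=0,
        )
        assert tab["es"].iloc[0] == pytest.approx(1.0)
        assert res[0].leading_edge == ("g1",)

    def test_bottom_gene_set_es_minus_one(self):
        tab, _ = preranked_enrichment(
            self.RANK, [GeneSignature("bot", ["g5"])], min_size=1, n_perm=50,
            seed=0,
        )
        assert tab["es"].iloc[0] == pytest.approx(-1.0)

    def test_es_matches_full_walk_oracle_and_ends_at_zero(self):
        rng = np.random.default_rng(13)
        stats = pd.Series(rng.normal(0, 2, 300),
                          index=[f"g{i:03d}" for i in range(300)])
        for k in (5, 20, 80):
            genes = list(rng.choice(stats.index.to_numpy(), k, replace=False))
            tab, _ = preranked_enrichment(
                stats, [GeneSignature("s", genes)], n_perm=10, seed=1
            )
            order = stats.sort_values(ascending=False).index
            ranked = stats.loc[order].to_numpy()
            mask = np.isin(order.to_numpy(), genes)
            es, walk = running_sum_oracle(ranked, mask)
            assert tab["es"].iloc[0] == pytest.approx(es, abs=1e-12)
            assert -1.0 <= tab["es"].iloc[0] <= 1.0
            assert walk[-1] == pytest.approx(0.0, abs=1e-9)

    def test_sign_of_nes_matches_es(self):
        rng = np.random.default_rng(3)
        stats = pd.Series(rng.normal(0, 1, 200),
                          index=[f"g{i}" for i in range(200)])
        top = list(stats.sort_values(ascending=False).index[:20])
        bot = list(stats.sort_values().index[:20])
        tab, _ = preranked_enrichment(
            stats, [GeneSignature("up", top), GeneSignature("dn", bot)],
            n_perm=200, seed=2,
        )
        assert np.sign(tab.loc["up", "nes"]) == np.sign(tab.loc["up", "es"]) == 1
        assert np.sign(tab.loc["dn", "nes"]) == np.sign(tab.loc["dn", "es"]) == -1

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(11)
        N = 1000
        stats = pd.Series(rng.normal(0, 1, N),
                          index=[f"g{i:04d}" for i in range(N)])
        ps = []
        for i in range(500):
            genes = list(rng.choice(stats.index.to_numpy(), 30, replace=False))
            tab, _ = preranked_enrichment(
                stats, [GeneSignature(f"r{i}", genes)], n_perm=300,
                seed=1000 + i,
            )
            ps.append(tab["p_value"].iloc[0])
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_set_size_bounds_skipped_with_warning(self):
        tab, _ = preranked_enrichment(
            self.RANK, [GeneSignature("small", ["g1"])], min_size=2, n_perm=10,
            seed=0,
        )
        assert len(tab) == 0
        assert any("small" in w for w in tab.attrs["warnings"])

    def test_set_covering_all_genes_error(self):
        with pytest.raises(ValueError):
            preranked_enrichment(
                self.RANK, [GeneSignature("all", list(self.RANK.index))],
                min_size=1, n_perm=10, seed=0,
            )

    def test_planted_module_detected_in_synthetic_cohort(self, cohort300, norm300):
        truth = cohort300.truth
        s2p = cohort300.sample_to_patient
        cols, grp = [], []
        for s in norm300.columns:
            arm = truth.arm_by_patient[s2p[s]]
            if arm in ("naive", "acquired"):
                cols.append(s)
                grp.append(arm)
        res = fit_gene_linear_models(norm300[cols], grp, reference="naive")
        tab, _ = preranked_enrichment(
            res["t_stat"], cohort300.signatures, n_perm=500, seed=7
        )
        assert tab.loc["IFNG", "nes"] > 0
        assert tab.loc["IFNG", "q_value"] < 0.05
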