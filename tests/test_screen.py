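import numpy as np
import pandas as pd
import pytest
import scipy.stats

from rwe_ici.endpoints import SurvivalOutcome
from rwe_ici.screen import (
    ScreenConfig, _cox_univariate, dichotomize_and_km, intersect_cohort_hits,
    per_gene_cox_screen, project_hits_to_celltypes,
)


def outcomes_from(time, event, prefix="P"):
    return [
        SurvivalOutcome(f"{prefix}{i}", "os", int(t), bool(e), 1)
        for i, (t, e) in enumerate(zip(time, event))
    ]


def norm_frame(X, prefix="P"):
    """samples x genes array -> genes x samples DataFrame named like patients."""
    G = X.shape[1]
    return pd.DataFrame(
        X.T, index=[f"g{j}" for j in range(G)],
        columns=[f"{prefix}{i}" for i in range(X.shape[0])],
    )


class TestUnivariateCoxSolver:
    def test_log_hr_recovery(self):
        rng = np.random.default_rng(31)
        n = 200
        x = rng.normal(0, 1, n)
        time = np.ceil(rng.exponential(1.0 / (0.002 * np.exp(1.0 * x)))) + 1
        event = np.ones(n, bool)
        res = per_gene_cox_screen(
            norm_frame(x[:, None]), outcomes_from(time, event)
        )
        assert 0.7 <= res["log_hr"].iloc[0] <= 1.3
        assert res["p_value"].iloc[0] < 0.05

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(7)
        n = 120
        X = rng.normal(0, 1, (n, 5))
        time = rng.exponential(100, n) + rng.random(n)  # continuous, no ties
        event = rng.random(n) < 0.7
        beta, se, ok = _cox_univariate(X, time, event)
        for j in range(5):
            cph = CoxPHFitter().fit(
                pd.DataFrame({"t": time, "e": event.astype(int), "x": X[:, j]}),
                "t", "e",
            )
            assert beta[j] == pytest.approx(cph.params_["x"], abs=1e-4)
            assert se[j] == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_null_type_one_error(self):
        hits = total = 0
        for rep in range(100):
            rng = np.random.default_rng(500 + rep)
            n, G = 150, 200
            X = rng.normal(0, 1, (n, G))
            t_ev = rng.exponential(100, n)
            t_cens = rng.exponential(200, n)
            time = np.minimum(t_ev, t_cens)
            event = t_ev <= t_cens
            beta, se, ok = _cox_univariate(X, time, event)
            p = 2 * scipy.stats.norm.sf(np.abs(beta / se))
            hits += int((p[ok] < 0.05).sum())
            total += int(ok.sum())
        assert 0.035 <= hits / total <= 0.065

    def test_constant_gene_flagged_nonconverged(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.full(50, 3.0), rng.normal(0, 1, 50)])
        res = per_gene_cox_screen(
            norm_frame(X),
            outcomes_from(rng.exponential(50, 50) + 1, np.ones(50)),
        )
        assert not res["converged"].iloc[0]
        assert res["direction"].iloc[0] == "na"
        assert res.attrs["n_nonconverged"] == 1

    def test_results_invariant_to_gene_and_patient_order(self):
        rng = np.random.default_rng(3)
        n, G = 80, 10
        X = rng.normal(0, 1, (n, G))
        time = rng.exponential(100, n)
        event = rng.random(n) < 0.8
        norm = norm_frame(X)
        outs = outcomes_from(time, event)
        res1 = per_gene_cox_screen(norm, outs)
        res2 = per_gene_cox_screen(
            norm.iloc[::-1, ::-1], list(reversed(outs))
        )
        joined = res1.join(res2, rsuffix="_r")
        np.testing.assert_allclose(
            joined["log_hr"], joined["log_hr_r"], atol=1e-10
        )

    def test_min_events_precondition(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (30, 3))
        with pytest.raises(ValueError, match="events"):
            per_gene_cox_screen(
                norm_frame(X),
                outcomes_from(rng.exponential(50, 30), np.zeros(30)),
            )

    def test_covariate_adjusted_mode(self):
        rng = np.random.default_rng(8)
        n = 200
        stage = np.where(rng.random(n) < 0.5, "III", "IV")
        x = 0.3 * rng.normal(0, 1, n) + 1.0 * (stage == "IV")
        time = rng.exponential(
            1.0 / (0.002 * np.exp(1.0 * (stage == "IV")))
        ) + rng.random(n)
        event = np.ones(n)
        covs = pd.DataFrame({"stage": stage}, index=[f"P{i}" for i in range(n)])
        unadj = per_gene_cox_screen(
            norm_frame(x[:, None]), outcomes_from(time, event)
        )
        adj = per_gene_cox_screen(
            norm_frame(x[:, None]), outcomes_from(time, event),
            ScreenConfig(covariates=("stage",)), covariate_table=covs,
        )
        # expression only proxies stage; adjustment should shrink its effect
        assert abs(adj["log_hr"].iloc[0]) < abs(unadj["log_hr"].iloc[0])


class TestIntersectHits:
    def make(self, rows):
        df = pd.DataFrame(rows).set_index("gene")
        df["converged"] = True
        return df

    def test_concordant_intersection(self):
        a = self.make([
            {"gene": "a", "p_value": 0.01, "direction": "favorable"},
            {"gene": "b", "p_value": 0.01, "direction": "favorable"},
            {"gene": "c", "p_value": 0.01, "direction": "unfavorable"},
            {"gene": "d", "p_value": 0.50, "direction": "unfavorable"},
        ])
        b = self.make([
            {"gene": "a", "p_value": 0.90, "direction": "favorable"},
            {"gene": "b", "p_value": 0.02, "direction": "favorable"},
            {"gene": "c", "p_value": 0.03, "direction": "unfavorable"},
            {"gene": "d", "p_value": 0.01, "direction": "unfavorable"},
        ])
        hits = intersect_cohort_hits(a, b, alpha=0.05)
        assert hits["favorable"] == ["b"]
        assert hits["unfavorable"] == ["c"]
        assert hits["discordant"] == []

    def test_discordant_gene_excluded_and_counted(self):
        a = self.make([{"gene": "x", "p_value": 0.01, "direction": "favorable"}])
        b = self.make([{"gene": "x", "p_value": 0.01, "direction": "unfavorable"}])
        hits = intersect_cohort_hits(a, b)
        assert hits["favorable"] == [] and hits["unfavorable"] == []
        assert hits["discordant"] == ["x"]

    def test_disjoint_hit_sets_empty_result(self):
        a = self.make([
            {"gene": "x", "p_value": 0.01, "direction": "favorable"},
            {"gene": "y", "p_value": 0.9, "direction": "favorable"},
        ])
        b = self.make([
            {"gene": "x", "p_value": 0.9, "direction": "favorable"},
            {"gene": "y", "p_value": 0.01, "direction": "favorable"},
        ])
        hits = intersect_cohort_hits(a, b)
        assert hits["favorable"] == [] and hits["unfavorable"] == []

    def test_self_intersection_idempotent(self):
        a = self.make([
            {"gene": "x", "p_value": 0.01, "direction": "favorable"},
            {"gene": "y", "p_value": 0.2, "direction": "unfavorable"},
            {"gene": "z", "p_value": 0.001, "direction": "unfavorable"},
        ])
        hits = intersect_cohort_hits(a, a)
        assert hits["favorable"] == ["x"]
        assert hits["unfavorable"] == ["z"]

    def test_empty_universe_error(self):
        a = self.make([{"gene": "x", "p_value": 0.01, "direction": "favorable"}])
        b = self.make([{"gene": "y", "p_value": 0.01, "direction": "favorable"}])
        with pytest.raises(ValueError):
            intersect_cohort_hits(a, b)


class TestDichotomizeKM:
    def test_null_logrank_p_uniform(self):
        ps = []
        for rep in range(200):
            rng = np.random.default_rng(900 + rep)
            n = 60
            scores = pd.Series(rng.normal(0, 1, n),
                               index=[f"P{i}" for i in range(n)])
            outs = outcomes_from(rng.exponential(100, n), np.ones(n))
            res = dichotomize_and_km(scores, outs)
            ps.append(res["logrank_p"])
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_protective_score_hr_recovered(self):
        rng = np.random.default_rng(77)
        n = 300
        high = rng.random(n) < 0.5
        scores = pd.Series(np.where(high, 1.0, 0.0) + rng.normal(0, 0.01, n),
                           index=[f"P{i}" for i in range(n)])
        lam = np.where(high, 0.005, 0.01)  # hazard halved in high arm
        outs = outcomes_from(rng.exponential(1 / lam), np.ones(n))
        res = dichotomize_and_km(scores, outs)
        assert 0.4 <= res["hazard_ratio"] <= 0.65
        assert res["hr_p"] < 0.05

    def test_tertile_extremes_split_drops_middle(self):
        rng = np.random.default_rng(15)
        n = 90
        scores = pd.Series(rng.normal(0, 1, n), index=[f"P{i}" for i in range(n)])
        outs = outcomes_from(rng.exponential(100, n), np.ones(n))
        res = dichotomize_and_km(scores, outs, split="tertile-extremes")
        assert res["n_high"] + res["n_low"] == pytest.approx(2 * n / 3, abs=2)

    def test_small_arms_error(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(0, 1, 10),
                           index=[f"P{i}" for i in range(10)])
        outs = outcomes_from(rng.exponential(100, 10), np.ones(10))
        with pytest.raises(ValueError):
            dichotomize_and_km(scores, outs)

    def test_constant_scores_error(self):
        scores = pd.Series(1.0, index=[f"P{i}" for i in range(40)])
        outs = outcomes_from(np.arange(1, 41), np.ones(40))
        with pytest.raises(ValueError):
            dichotomize_and_km(scores, outs)


class TestCrossCohortRecovery:
    def test_planted_prognostic_genes_recovered(self, cohort300, norm300):
        from rwe_ici import endpoints, expression, synth

        def screen_cohort(cohort, norm):
            lines = cohort.tables.lines_by_patient()
            outs = [
                endpoints.derive_os(p, lines[p.patient_id][0])
                for p in cohort.tables.patients
            ]
            return per_gene_cox_screen(
                norm, outs, sample_to_patient=cohort.sample_to_patient
            )

        res_a = screen_cohort(cohort300, norm300)
        cohort_b = synth.generate_all(
            synth.SynthConfig(n_patients=300, n_genes=2000, seed=1007)
        )
        res_b = screen_cohort(cohort_b, expression.normalize_counts(cohort_b.counts))
        hits = intersect_cohort_hits(res_a, res_b)
        planted = cohort300.truth.prognostic
        recovered = sum(
            1 for g, v in planted.items() if g in hits[v["direction"]]
        )
        assert recovered >= 0.8 * len(planted)
        assert not any(g in hits["discordant"] for g in planted)


class TestProjection:
    def test_favorable_hits_rank_myeloid_top(self, cohort300):
        from rwe_ici.expression import pseudobulk_aggregate
        from rwe_ici.synth import MYELOID_TYPES

        pb, _ = pseudobulk_aggregate(
            cohort300.cell_counts, cohort300.cell_meta, min_cells=1
        )
        fav = list(cohort300.truth.module_genes.get("_f", [])) or [
            g for g, v in cohort300.truth.prognostic.items()
            if v["direction"] == "favorable"
        ]
        proj = project_hits_to_celltypes({"favorable": fav}, pb)
        assert proj["favorable"]["summary"].index[0] in MYELOID_TYPES

    def test_all_hits_absent_error(self, cohort300):
        from rwe_ici.expression import pseudobulk_aggregate

        pb, _ = pseudobulk_aggregate(
            cohort300.cell_counts, cohort300.cell_meta, min_cells=1
        )
        with pytest.raises(ValueError):
            project_hits_to_celltypes({"favorable": ["NOT_A_GENE"]}, pb)

    def test_matches_manual_composition(self, cohort300):
        from rwe_ici.expression import (
            GeneSignature, celltype_signature_profile, pseudobulk_aggregate,
        )

        pb, _ = pseudobulk_aggregate(
            cohort300.cell_counts, cohort300.cell_meta, min_cells=1
        )
        fav = [g for g, v in cohort300.truth.prognostic.items()
               if v["direction"] == "favorable"][:5]
        unf = [g for g, v in cohort300.truth.prognostic.items()
               if v["direction"] == "unfavorable"][:5]
        proj = project_hits_to_celltypes(
            {"favorable": fav, "unfavorable": unf}, pb
        )
        for part, genes in (("favorable", fav), ("unfavorable", unf)):
            _, manual = celltype_signature_profile(
                pb, GeneSignature(f"{part}_hits", genes)
            )
            pd.testing.assert_frame_equal(proj[part]["summary"], manual)
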