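import numpy as np
import pandas as pd
import pytest

from radbench import survival as sv
from radbench.synthdata import ClinicalCohortSet, SimulationConfig, simulate_clinical_cohorts, DEFAULT_COHORT_SPEC

from conftest import brute_force_cox_beta


def _group(time, event, cohort, scores, label="OS_RT"):
    pats = pd.DataFrame(
        {"cohort_id": cohort, "outcome_type": label.split("_")[0],
         "rt": int(label.endswith("_RT")), "time": time, "event": event},
        index=[f"s{i}" for i in range(len(time))])
    return (sv.AnalysisGroup(label=label, patients=pats),
            pd.Series(scores, index=pats.index))


class TestGroupPatients:
    def test_table_shaped_input_preserves_cohort_ns(self):
        cfg = SimulationConfig(n_genes=20, seed=0)
        cohorts = simulate_clinical_cohorts(cfg, DEFAULT_COHORT_SPEC)
        groups = {g.label: g for g in sv.group_patients(cohorts)}
        assert set(groups) == {"FR_RT", "FR_noRT", "OS_RT", "OS_noRT"}
        assert groups["OS_RT"].n == 186 + 77 + 65
        assert groups["OS_noRT"].n == 55 + 82 + 364
        assert groups["FR_RT"].n == 282 + 77
        assert groups["FR_noRT"].n == 62 + 82
        counts = groups["OS_RT"].patients["cohort_id"].value_counts()
        assert counts["gbm_os_rt"] == 186

    def test_single_cohort_single_group(self):
        cfg = SimulationConfig(n_genes=20, seed=1)
        cohorts = simulate_clinical_cohorts(cfg, [("c1", "OS", 1, 30)])
        groups = sv.group_patients(cohorts)
        assert [g.label for g in groups] == ["OS_RT"]

    def test_mixed_rt_cohort_splits_across_groups(self):
        cfg = SimulationConfig(n_genes=20, seed=2)
        cohorts = simulate_clinical_cohorts(cfg, [("c1", "OS", 1, 30)])
        cl = cohorts.clinical.copy()
        cl.loc[cl.index[:10], "rt"] = 0
        mixed = ClinicalCohortSet(expr=cohorts.expr, clinical=cl)
        labels = {g.label: g.n for g in sv.group_patients(mixed)}
        assert labels == {"OS_RT": 20, "OS_noRT": 10}


class TestZscore:
    def test_basic(self):
        assert np.allclose(sv.zscore([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        x = sv.zscore(np.random.default_rng(0).normal(5, 3, 100))
        assert np.allclose(sv.zscore(x), x, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            sv.zscore([2.0, 2.0, 2.0])


class TestFitCox:
    def test_beta_matches_bruteforce_oracle(self, toy_group):
        group, scores = toy_group
        fit = sv.fit_cox(group, scores, zscore_scores=False)
        oracle = brute_force_cox_beta(group.patients["time"],
                                      group.patients["event"], scores)
        assert fit.beta == pytest.approx(oracle, abs=1e-6)

    def test_matches_lifelines_with_strata_and_ties(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(1)
        n = 150
        time = np.round(rng.exponential(1, n), 1) + 0.1  # induces ties
        event = rng.integers(0, 2, n)
        x = rng.standard_normal(n)
        stratum = rng.choice(["a", "b", "c"], n)
        group, scores = _group(time, event, stratum, x)
        fit = sv.fit_cox(group, scores, zscore_scores=False)
        df = pd.DataFrame({"time": time, "event": event, "x": x,
                           "stratum": stratum})
        cph = lifelines.CoxPHFitter()
        cph.fit(df, "time", "event", strata=["stratum"])
        assert fit.beta == pytest.approx(cph.params_.iloc[0], abs=1e-4)
        assert fit.se == pytest.approx(cph.standard_errors_.iloc[0], rel=1e-4)

    def test_scale_invariance_via_zscoring(self, toy_group):
        group, scores = toy_group
        a = sv.fit_cox(group, scores)
        b = sv.fit_cox(group, scores * 137.0)
        assert a.hr_per_sd == pytest.approx(b.hr_per_sd, rel=1e-12)

    def test_breslow_equals_efron_without_ties(self, toy_group):
        group, scores = toy_group
        a = sv.fit_cox(group, scores, ties="efron")
        b = sv.fit_cox(group, scores, ties="breslow")
        assert a.beta == pytest.approx(b.beta, abs=1e-10)

    def test_stratified_fit_matches_stratified_oracle(self):
        rng = np.random.default_rng(2)
        n = 40
        time = rng.exponential(1, n)
        event = rng.integers(0, 2, n) | (np.arange(n) % 5 == 0)
        x = rng.standard_normal(n)
        strata = np.where(np.arange(n) < 20, "c1", "c2")
        group, scores = _group(time, event, strata, x)
        fit = sv.fit_cox(group, scores, zscore_scores=False)
        oracle = brute_force_cox_beta(time, event, x, strata=strata)
        assert fit.beta == pytest.approx(oracle, abs=1e-6)

    def test_all_censored_rejected(self):
        group, scores = _group([1.0, 2.0, 3.0], [0, 0, 0], "c1",
                               [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="censored"):
            sv.fit_cox(group, scores)

    def test_monotone_likelihood_flagged_not_raised(self):
        # perfectly separating score: event risk ordering follows the score
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.ones(6, dtype=int)
        x = -time  # later events have ever smaller scores
        group, scores = _group(time, event, "c1", x)
        fit = sv.fit_cox(group, scores, zscore_scores=False)
        assert not fit.converged
        assert "monotone" in fit.diagnostics

    def test_null_score_gives_hr_near_one(self):
        rng = np.random.default_rng(3)
        n = 500
        group, scores = _group(rng.exponential(1, n),
                               rng.integers(0, 2, n), "c1",
                               rng.standard_normal(n))
        fit = sv.fit_cox(group, scores)
        assert 0.8 < fit.hr_per_sd < 1.25
        assert fit.ci_lower <= fit.hr_per_sd <= fit.ci_upper

    def test_per_cohort_zscore_scope_absorbs_cohort_scale(self):
        rng = np.random.default_rng(11)
        n = 80
        time = rng.exponential(1, n)
        event = (rng.random(n) < 0.7).astype(int)
        strata = np.where(np.arange(n) < 40, "c1", "c2")
        x = rng.standard_normal(n)
        group, scores = _group(time, event, strata, x)
        # inflate cohort c2's score scale; per-cohort z-scoring undoes it
        inflated = scores.copy()
        inflated[strata == "c2"] *= 50.0
        base = sv.fit_cox(group, scores, zscore_scope="cohort")
        infl = sv.fit_cox(group, inflated, zscore_scope="cohort")
        assert infl.beta == pytest.approx(base.beta, abs=1e-10)
        # group-level z-scoring does not
        assert sv.fit_cox(group, inflated).beta != pytest.approx(
            base.beta, abs=1e-6)

    def test_wald_ci_consistency(self, toy_group):
        group, scores = toy_group
        f = sv.fit_cox(group, scores)
        assert f.hr_per_sd == pytest.approx(np.exp(f.beta))
        assert f.ci_lower == pytest.approx(np.exp(f.beta - 1.96 * f.se))
        assert f.ci_upper == pytest.approx(np.exp(f.beta + 1.96 * f.se))


class TestCohortCovariate:
    @staticmethod
    def _two_cohort_group(seed=4, n=60):
        rng = np.random.default_rng(seed)
        time = rng.exponential(1, n)
        event = (rng.random(n) < 0.7).astype(int)
        strata = np.where(np.arange(n) < n // 2, "c1", "c2")
        scores = rng.standard_normal(n)
        return _group(time, event, strata, scores)

    def test_constant_covariate_leaves_fit_unchanged(self):
        group, scores = self._two_cohort_group()
        base = sv.fit_cox(group, scores)
        const = pd.Series(5.0, index=group.patients.index)
        aug = sv.attach_cohort_covariate(group, "mgmt", const, ["c1"])
        assert np.allclose(aug.covariates["mgmt"], 0.0)
        fit = sv.fit_cox(aug, scores)
        assert fit.beta == pytest.approx(base.beta, abs=1e-9)

    def test_all_cohorts_equals_ordinary_adjustment(self):
        lifelines = pytest.importorskip("lifelines")
        group, scores = self._two_cohort_group(seed=5)
        rng = np.random.default_rng(6)
        cov = pd.Series(rng.standard_normal(group.n),
                        index=group.patients.index)
        aug = sv.attach_cohort_covariate(group, "cov", cov, ["c1", "c2"])
        fit = sv.fit_cox(aug, scores, zscore_scores=False)
        df = pd.DataFrame({
            "time": group.patients["time"], "event": group.patients["event"],
            "x": scores, "cov": aug.covariates["cov"],
            "stratum": group.patients["cohort_id"]})
        cph = lifelines.CoxPHFitter()
        cph.fit(df, "time", "event", strata=["stratum"])
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-4)
        assert fit.covariate_results["cov"]["beta"] == pytest.approx(
            cph.params_["cov"], abs=1e-4)

    def test_cohort_restricted_covariate_matches_oracle_refit(self):
        from scipy.optimize import minimize

        rng = np.random.default_rng(7)
        n = 60
        c = rng.standard_normal(n)
        x = rng.standard_normal(n)
        time = rng.exponential(1.0 / np.exp(0.5 * x + 0.8 * c))
        event = (rng.random(n) < 0.75).astype(int)
        strata = np.where(np.arange(n) < n // 2, "c1", "c2")
        group, scores = _group(time, event, strata, x)
        pats = group.patients
        # a genuinely prognostic covariate, observed only in cohort c1
        cov = pd.Series(c, index=pats.index)
        aug = sv.attach_cohort_covariate(group, "risk", cov, ["c1"])
        fit = sv.fit_cox(aug, scores, zscore_scores=False)

        time = pats["time"].to_numpy()
        event = pats["event"].to_numpy()
        strata = pats["cohort_id"].to_numpy()
        X = np.column_stack([scores.to_numpy(),
                             aug.covariates["risk"].to_numpy()])

        def negpl(b):
            ll = 0.0
            for s in np.unique(strata):
                m = strata == s
                t, e, Z = time[m], event[m], X[m]
                eta = Z @ b
                for tt in np.unique(t[e == 1]):
                    dead = (t == tt) & (e == 1)
                    risk = t >= tt
                    ll += eta[dead].sum() - dead.sum() * np.log(
                        np.exp(eta[risk]).sum())
            return -ll

        res = minimize(negpl, np.zeros(2), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 5000})
        assert fit.beta == pytest.approx(res.x[0], abs=1e-5)
        assert fit.covariate_results["risk"]["beta"] == pytest.approx(
            res.x[1], abs=1e-5)

    def test_missing_covariate_value_rejected(self):
        group, scores = self._two_cohort_group(seed=8)
        cov = pd.Series(1.0, index=group.patients.index[:-5])
        with pytest.raises(ValueError, match="missing"):
            sv.attach_cohort_covariate(group, "cov", cov,
                                       ["c1", "c2"])


class TestCoxScan:
    def test_scan_agrees_with_single_fits(self):
        rng = np.random.default_rng(9)
        n, G = 80, 6
        time = rng.exponential(1, n)
        event = (rng.random(n) < 0.7).astype(int)
        strata = rng.choice(["c1", "c2"], n)
        Z = rng.standard_normal((n, G))
        beta, se, p, conv = sv.cox_scan(time, event, Z, strata)
        for j in range(G):
            group, scores = _group(time, event, strata, Z[:, j])
            fit = sv.fit_cox(group, scores, zscore_scores=False)
            assert beta[j] == pytest.approx(fit.beta, abs=1e-6)
            assert se[j] == pytest.approx(fit.se, rel=1e-5)

    def test_scan_handles_ties_like_fit_cox(self):
        rng = np.random.default_rng(10)
        n = 60
        time = np.round(rng.exponential(1, n), 1) + 0.1
        event = (rng.random(n) < 0.7).astype(int)
        Z = rng.standard_normal((n, 3))
        beta, *_ = sv.cox_scan(time, event, Z, np.repeat("c", n))
        for j in range(3):
            group, scores = _group(time, event, "c", Z[:, j])
            fit = sv.fit_cox(group, scores, zscore_scores=False)
            assert beta[j] == pytest.approx(fit.beta, abs=1e-6)
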