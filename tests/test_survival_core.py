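import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from cnaprog import (
    FitError,
    SimulationConfig,
    ValidationError,
    concordance,
    fit_constrained_cox,
    gene_pvalue,
    harrell_compare,
    logrank_test,
    simulate_cohort,
)
from cnaprog.survival_core import build_design, clinical_nonneg_mask

from conftest import make_cox_data


class TestBuildDesign:
    @pytest.mark.parametrize("stage,expected", [
        ("IA", (0, 0, 0)), ("IB", (1, 0, 0)), ("IIA", (1, 1, 0)), ("IIB", (1, 1, 1)),
    ])
    def test_incremental_stage_encoding(self, stage, expected):
        clin = pd.DataFrame(
            {"age": [65.0], "sex": ["female"], "stage": [stage]}, index=["P1"]
        )
        X = build_design(clin)
        assert tuple(X.loc["P1", ["stage_ge_IB", "stage_ge_IIA", "stage_ge_IIB"]]) == expected

    def test_full_row(self):
        clin = pd.DataFrame(
            {"age": [65.0], "sex": ["female"], "stage": ["IB"]}, index=["P1"]
        )
        assert list(build_design(clin).loc["P1"]) == [65.0, 0.0, 1.0, 0.0, 0.0]

    def test_incomplete_rows_excluded(self):
        clin = pd.DataFrame(
            {"age": [65.0, np.nan], "sex": ["male", "male"], "stage": ["IA", "IA"]},
            index=["P1", "P2"],
        )
        assert list(build_design(clin).index) == ["P1"]


class TestConstrainedCox:
    def test_matches_unconstrained_oracle_when_feasible(self):
        rng = np.random.default_rng(31)
        compared = 0
        for _ in range(25):
            X, t, e = make_cox_data(rng, n=150, beta=(0.6, 0.4, 0.3))
            df = X.copy()
            df["T"], df["E"] = t, e
            oracle = CoxPHFitter().fit(df, "T", "E").params_.to_numpy()
            if (oracle < 0).any():
                continue  # constraint would bind; not comparable
            fit = fit_constrained_cox(X, t, e, np.ones(3, bool))
            assert np.allclose(fit.coef.to_numpy(), oracle, atol=1e-4)
            compared += 1
        assert compared >= 10

    def test_protective_effect_pinned_at_zero(self):
        rng = np.random.default_rng(37)
        X, t, e = make_cox_data(rng, n=300, beta=(-0.8, 0.5))
        fit = fit_constrained_cox(X, t, e, np.array([True, False]))
        assert fit.coef["x0"] == 0.0
        assert bool(fit.active[0])
        assert fit.n_free == 1

    def test_exchangeable_groups_give_null_coefficient(self):
        # survival independent of the binary covariate: the average fitted
        # coefficient over replicates must vanish (se of the mean ~ 0.022)
        rng = np.random.default_rng(41)
        n = 400
        betas = []
        for _ in range(20):
            X = pd.DataFrame({"g": rng.integers(0, 2, n).astype(float)})
            t = -np.log(rng.uniform(size=n))
            betas.append(fit_constrained_cox(X, t, np.ones(n)).coef["g"])
        assert abs(np.mean(betas)) < 0.05

    def test_kkt_conditions_hold(self):
        rng = np.random.default_rng(43)
        for _ in range(20):
            p = rng.integers(2, 5)
            X, t, e = make_cox_data(rng, n=120, beta=rng.normal(0, 0.5, p))
            mask = rng.uniform(size=p) < 0.5
            fit = fit_constrained_cox(X, t, e, mask)
            assert fit.kkt_ok(1e-5)

    def test_constrained_never_beats_unconstrained(self):
        rng = np.random.default_rng(47)
        for _ in range(10):
            X, t, e = make_cox_data(rng, n=120, beta=(-0.5, 0.4))
            con = fit_constrained_cox(X, t, e, np.ones(2, bool))
            unc = fit_constrained_cox(X, t, e)
            assert con.log_likelihood <= unc.log_likelihood + 1e-8
            if not con.active.any():
                assert con.log_likelihood == pytest.approx(unc.log_likelihood, abs=1e-6)

    def test_aic_excludes_pinned_coefficients(self):
        rng = np.random.default_rng(53)
        X, t, e = make_cox_data(rng, n=200, beta=(-0.8, 0.5))
        fit = fit_constrained_cox(X, t, e, np.array([True, False]))
        assert fit.aic == pytest.approx(2 * 1 - 2 * fit.log_likelihood)

    def test_no_events_is_an_error(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(FitError, match="events"):
            fit_constrained_cox(X, np.array([1.0, 2.0, 3.0]), np.zeros(3))

    def test_zero_variance_column_rejected(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        with pytest.raises(FitError, match="zero-variance"):
            fit_constrained_cox(X, np.array([1.0, 2.0, 3.0]), np.ones(3))


class TestGenePvalue:
    def _clinical_design(self, rng, n):
        clin = pd.DataFrame({
            "age": rng.normal(65, 8, n),
            "sex": np.where(rng.uniform(size=n) < 0.5, "male", "female"),
            "stage": rng.choice(["IA", "IB", "IIA", "IIB"], n),
        }, index=[f"P{i}" for i in range(n)])
        return build_design(clin)

    def test_redundant_column_gives_p_near_one(self):
        rng = np.random.default_rng(59)
        X = self._clinical_design(rng, 150)
        t = -np.log(rng.uniform(size=150)) / np.exp(0.03 * (X["age"] - 65))
        gene = X["age"].rename("G")  # duplicates an existing covariate
        p = gene_pvalue(X, gene, t, np.ones(150))
        assert p > 0.95

    def test_planted_gene_detected(self):
        rng = np.random.default_rng(61)
        ps = []
        for _ in range(20):
            n = 200
            X = self._clinical_design(rng, n)
            g = pd.Series(rng.normal(0, 0.5, n), index=X.index, name="G")
            eta = 0.8 * g.to_numpy()
            t = -np.log(rng.uniform(size=n)) / np.exp(eta)
            c = rng.uniform(0, np.quantile(t, 0.8) * 2, n)
            ps.append(gene_pvalue(X, g, np.minimum(t, c), (t <= c).astype(float)))
        assert np.median(ps) < 0.01


class TestLogrank:
    def test_identical_groups_give_p_one(self):
        t = np.array([1.0, 2, 3, 1, 2, 3])
        e = np.ones(6)
        stat, p = logrank_test(t, e, np.array([0, 0, 0, 1, 1, 1]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_risk_set_table(self):
        # groups {1,2,3} vs {4,5,6}, all events: O-E and V accumulated by hand
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.ones(6)
        g = np.array([0, 0, 0, 1, 1, 1])
        obs_minus_exp, var = 0.0, 0.0
        for u in np.unique(t):
            at_risk = t >= u
            n_total = at_risk.sum()
            n_g0 = (at_risk & (g == 0)).sum()
            d = ((t == u) & (e == 1)).sum()
            d_g0 = ((t == u) & (e == 1) & (g == 0)).sum()
            obs_minus_exp += d_g0 - d * n_g0 / n_total
            if n_total > 1:
                var += d * (n_g0 / n_total) * (1 - n_g0 / n_total) * (n_total - d) / (n_total - 1)
        expected_stat = obs_minus_exp ** 2 / var
        stat, _ = logrank_test(t, e, g)
        assert stat == pytest.approx(expected_stat, rel=1e-10)

    def test_invariant_to_group_relabeling_and_monotone_time(self):
        rng = np.random.default_rng(67)
        t = rng.exponential(10, 40)
        e = (rng.uniform(size=40) < 0.7).astype(float)
        g = rng.integers(0, 2, 40)
        s1, p1 = logrank_test(t, e, g)
        s2, p2 = logrank_test(t, e, 1 - g)
        s3, p3 = logrank_test(np.sqrt(t), e, g)
        assert s1 == pytest.approx(s2) and s1 == pytest.approx(s3)

    def test_single_group_is_an_error(self):
        with pytest.raises(ValidationError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])


class TestConcordance:
    def test_perfect_score_orders_all_pairs(self):
        t = np.array([5.0, 4, 3, 2, 1])
        scores = np.array([1.0, 2, 3, 4, 5])  # highest risk dies first
        assert concordance(scores, t, np.ones(5)) == 1.0

    def test_constant_score_is_half(self):
        t = np.array([1.0, 2, 3, 4])
        assert concordance(np.zeros(4), t, np.ones(4)) == 0.5

    def test_random_score_near_half(self):
        rng = np.random.default_rng(71)
        n = 500
        t = rng.exponential(10, n)
        s = rng.normal(size=n)
        assert abs(concordance(s, t, np.ones(n)) - 0.5) < 0.05

    def test_agrees_with_lifelines(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(73)
        n = 200
        s = rng.normal(size=n)
        t = rng.exponential(10, n) / np.exp(0.5 * s)
        e = (rng.uniform(size=n) < 0.7).astype(float)
        ours = concordance(s, t, e)
        theirs = concordance_index(t, -s, e)  # lifelines wants higher = longer survival
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestHarrellCompare:
    def test_self_comparison_is_half(self):
        rng = np.random.default_rng(79)
        t = rng.exponential(10, 50)
        s = rng.normal(size=50)
        delta, p = harrell_compare(s, s, t, np.ones(50))
        assert delta == 0.0 and p == 0.5

    def test_strong_signal_beats_noise(self):
        rng = np.random.default_rng(83)
        wins = 0
        for _ in range(20):
            n = 300
            risk = rng.normal(size=n)
            t = -np.log(rng.uniform(size=n)) / np.exp(1.5 * risk)
            noise = rng.normal(size=n)
            _, p = harrell_compare(noise, risk, t, np.ones(n))
            wins += p < 0.01
        assert wins >= 19

    def test_swapping_models_flips_p(self):
        rng = np.random.default_rng(89)
        n = 100
        risk = rng.normal(size=n)
        t = -np.log(rng.uniform(size=n)) / np.exp(risk)
        noise = rng.normal(size=n)
        _, p1 = harrell_compare(noise, risk, t, np.ones(n))
        _, p2 = harrell_compare(risk, noise, t, np.ones(n))
        assert p1 + p2 == pytest.approx(1.0, abs=1e-12)


class TestParameterRecovery:
    def test_fitted_coefficients_near_truth_on_cohort(self):
        cfg = SimulationConfig(
            n_genes=50, n_labeled=500, n_unlabeled=10, n_planted_corr=10,
            n_planted_prog=3, n_chromosomes=2, censoring_rate=0.3, seed=97,
        )
        cohort = simulate_cohort(cfg)
        lab = cohort.clinical[cohort.clinical["labeled"]]
        X = build_design(lab, cohort.cn_true[lab.index.tolist()].loc[
            cohort.truth["planted_prog"]])
        mask = clinical_nonneg_mask(X.columns)
        fit = fit_constrained_cox(
            X, lab["os_time"].to_numpy(), lab["os_event"].to_numpy(), mask
        )
        for g in cohort.truth["planted_prog"]:
            assert fit.coef[g] == pytest.approx(cohort.truth["gamma"][g], abs=0.35)
        assert fit.coef["age"] == pytest.approx(cfg.age_loghr, abs=0.02)
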