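import numpy as np
import pandas as pd
import pytest

from cnaprog import (
    PipelineConfig,
    ValidationError,
    akaike_weights,
    build_candidate_models,
    derive_signature,
    dichotomize,
    ensemble_risk_score,
    evaluate_signature,
    harrell_compare,
)
from cnaprog.genomic_io import SignatureDocument
from cnaprog.survival_core import build_design


class TestAkaikeWeights:
    def test_single_model(self):
        assert akaike_weights([123.4]) == pytest.approx([1.0])

    def test_frozen_pair(self, fixtures):
        fx = fixtures["akaike_pair"]
        w = akaike_weights(fx["aics"])
        assert w == pytest.approx(fx["expected"], abs=5e-5)

    def test_equal_aics_share_weight(self):
        assert akaike_weights([10.0, 10.0, 10.0]) == pytest.approx([1 / 3] * 3)

    def test_weights_sum_to_one_and_best_is_max(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            aics = rng.uniform(50, 150, size=rng.integers(1, 10))
            w = akaike_weights(aics)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.argmax(w) == np.argmin(aics)

    def test_non_finite_model_dropped(self):
        w = akaike_weights([100.0, np.inf, 102.0])
        assert w[1] == 0.0
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


def clinical_frame(rng, n):
    return pd.DataFrame({
        "age": rng.normal(65, 8, n),
        "sex": np.where(rng.uniform(size=n) < 0.5, "male", "female"),
        "stage": rng.choice(["IA", "IB", "IIA", "IIB"], n),
    }, index=[f"P{i}" for i in range(n)])


class TestBuildCandidateModels:
    def _setup(self, rng, n=200, gene_effects=()):
        X_clin = build_design(clinical_frame(rng, n))
        genes = [f"G{i}" for i in range(max(len(gene_effects), 5))]
        cn = pd.DataFrame(rng.normal(0, 0.5, (len(genes), n)),
                          index=genes, columns=X_clin.index)
        eta = 0.03 * (X_clin["age"].to_numpy() - 65)
        for g, eff in zip(genes, gene_effects):
            eta = eta + eff * cn.loc[g].to_numpy()
        t = -np.log(rng.uniform(size=n)) / np.exp(eta)
        c = rng.uniform(0, np.quantile(t, 0.8) * 2, n)
        return X_clin, cn, genes, np.minimum(t, c), (t <= c).astype(float)

    def test_k_zero_gives_single_clinical_model(self):
        rng = np.random.default_rng(3)
        X_clin, cn, genes, t, e = self._setup(rng)
        models = build_candidate_models(genes, X_clin, cn, t, e, k_max=0)
        assert len(models) == 1
        assert models[0].k == 0 and models[0].weight == 1.0

    def test_single_signal_gene_dominates(self):
        rng = np.random.default_rng(5)
        X_clin, cn, genes, t, e = self._setup(rng, n=300, gene_effects=(1.5,))
        models = build_candidate_models(genes, X_clin, cn, t, e, k_max=5)
        weight_with_g0 = sum(m.weight for m in models if "G0" in m.genes)
        best = max(models, key=lambda m: m.weight)
        assert best.k >= 1 and "G0" in best.genes
        assert weight_with_g0 > 0.5

    def test_pure_noise_keeps_clinical_model_competitive(self):
        # with 5 pure-noise genes the clinical-only model stays within
        # Delta-AIC 2 of the best in ~86% of cohorts (pilot estimate over
        # 200 replicates); assert a 2.3-sigma lower bound on that rate
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            X_clin, cn, genes, t, e = self._setup(rng, n=150)
            models = build_candidate_models(genes, X_clin, cn, t, e, k_max=5)
            m0 = next((m for m in models if m.k == 0), None)
            if m0 is not None and m0.delta_aic <= 2.0:
                hits += 1
        assert hits >= 78

    def test_nested_prefixes(self):
        rng = np.random.default_rng(7)
        X_clin, cn, genes, t, e = self._setup(rng, gene_effects=(0.8, 0.5))
        models = build_candidate_models(genes, X_clin, cn, t, e, k_max=4)
        for m in models:
            assert m.genes == genes[:m.k]


def make_doc(models, weights, centering=None, median=0.0):
    genes = sorted({g for m in models for g in m["genes"]})
    return SignatureDocument(
        histology="ADC", clinical_coef={}, genes=genes, reported_genes=genes,
        models=models, akaike_weights=weights, training_median=median,
        centering=centering or {},
    )


class TestEnsembleScore:
    def test_single_model_score_is_its_linear_predictor(self):
        doc = make_doc([{"k": 1, "genes": ["G1"], "coef": {"G1": 2.0}}], [1.0])
        X = pd.DataFrame({"G1": [0.5, -0.5]})
        assert list(ensemble_risk_score(doc, X)) == [1.0, -1.0]

    def test_weighted_mean_of_two_models(self):
        doc = make_doc(
            [{"k": 1, "genes": ["G1"], "coef": {"G1": 1.0}},
             {"k": 1, "genes": ["G1"], "coef": {"G1": 3.0}}],
            [0.75, 0.25],
        )
        X = pd.DataFrame({"G1": [1.0]})
        assert ensemble_risk_score(doc, X).iloc[0] == pytest.approx(1.5)

    def test_dominance_is_preserved(self):
        rng = np.random.default_rng(11)
        models = [
            {"k": 1, "genes": ["G1"], "coef": {"G1": float(rng.uniform(0.5, 2))}}
            for _ in range(3)
        ]
        w = list(akaike_weights(rng.uniform(90, 100, 3)))
        doc = make_doc(models, w)
        X = pd.DataFrame({"G1": [2.0, 1.0]})  # row 0 dominates row 1 in every model
        s = ensemble_risk_score(doc, X)
        assert s.iloc[0] >= s.iloc[1]

    def test_missing_column_named(self):
        doc = make_doc([{"k": 1, "genes": ["G1"], "coef": {"G1": 1.0}}], [1.0])
        with pytest.raises(ValidationError, match="G1"):
            ensemble_risk_score(doc, pd.DataFrame({"other": [1.0]}))

    def test_centering_constant_shift_invariance(self):
        # shifting a covariate and its centering together leaves scores unchanged
        doc1 = make_doc([{"k": 1, "genes": ["G1"], "coef": {"G1": 2.0}}], [1.0],
                        centering={"G1": 0.0})
        doc2 = make_doc([{"k": 1, "genes": ["G1"], "coef": {"G1": 2.0}}], [1.0],
                        centering={"G1": 5.0})
        X1 = pd.DataFrame({"G1": [0.5]})
        X2 = pd.DataFrame({"G1": [5.5]})
        assert ensemble_risk_score(doc1, X1).iloc[0] == pytest.approx(
            ensemble_risk_score(doc2, X2).iloc[0]
        )


class TestDichotomize:
    def test_even_cohort_splits_in_half(self, fixtures):
        fx = fixtures["dichotomize"]["even"]
        groups = dichotomize(fx["scores"], float(np.median(fx["scores"])))
        assert list(groups) == fx["expected"]

    def test_odd_cohort_strict_inequality(self, fixtures):
        fx = fixtures["dichotomize"]["odd"]
        groups = dichotomize(fx["scores"], float(np.median(fx["scores"])))
        assert list(groups) == fx["expected"]

    def test_all_equal_scores_all_low(self):
        assert list(dichotomize([1.0, 1.0, 1.0], 1.0)) == ["low"] * 3

    def test_median_split_is_balanced_for_even_n(self):
        rng = np.random.default_rng(13)
        s = rng.normal(size=100)
        groups = dichotomize(s, float(np.median(s)))
        assert (groups == "high").sum() == (groups == "low").sum()


class TestDeriveAndEvaluate:
    def test_planted_genes_recovered_on_small_cohort(self, small_cohort, small_cn):
        cohort = small_cohort
        sig = derive_signature(
            small_cn[cohort.labeled_samples], small_cn[cohort.unlabeled_samples],
            cohort.expression, cohort.clinical, cohort.evidence,
            PipelineConfig(), seed=42,
        )
        planted = set(cohort.truth["planted_prog"])
        reported = set(sig.document.reported_genes)
        assert len(reported & planted) / len(planted) >= 0.6
        assert abs(sum(sig.document.akaike_weights) - 1.0) < 1e-9

    def test_rerun_is_byte_identical(self, small_cohort, small_cn):
        import json

        cohort = small_cohort
        args = (small_cn[cohort.labeled_samples], small_cn[cohort.unlabeled_samples],
                cohort.expression, cohort.clinical, cohort.evidence, PipelineConfig())
        d1 = derive_signature(*args, seed=42).document
        d2 = derive_signature(*args, seed=42).document
        assert json.dumps(d1.to_dict(), sort_keys=True) == \
            json.dumps(d2.to_dict(), sort_keys=True)

    def test_evaluation_report_on_training_cohort(self, small_cohort, small_cn):
        cohort = small_cohort
        sig = derive_signature(
            small_cn[cohort.labeled_samples], small_cn[cohort.unlabeled_samples],
            cohort.expression, cohort.clinical, cohort.evidence,
            PipelineConfig(), seed=42,
        )
        report = evaluate_signature(sig, small_cn, cohort.clinical)
        assert report["hr_per_sd"] > 1.0
        assert report["cox_p_onetailed"] < 0.05
        assert 0.5 < report["c_index"] <= 1.0
        assert report["logrank_p"] < 0.05

    def test_self_comparison_probability_is_half(self):
        rng = np.random.default_rng(17)
        t = rng.exponential(10, 40)
        s = rng.normal(size=40)
        _, p = harrell_compare(s, s, t, np.ones(40))
        assert p == 0.5
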