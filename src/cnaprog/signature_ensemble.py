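"""AIC model averaging: nested candidate models, Akaike weights, risk scores.

The NetRank ordering defines nested candidate models M_0, M_1, ..., M_k:
M_0 is the clinical model (age, sex, stage increments, all bounded at zero
from below) and M_k adds the top-k ranked genes with sign-free coefficients.
Models within Delta-AIC <= delta_aic_max of the best are retained and
averaged with Akaike weights w_i proportional to exp(-Delta_i / 2); a
patient's risk score is the weight-averaged linear predictor, with every
covariate centered at its training mean so predictors are comparable
across member models.  The flat reported signature is the ranking prefix
whose models carry cumulative Akaike weight >= 0.5.  Patients are split
into low/high risk at the median training risk score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .candidate_filters import correlation_filter, intersect_candidates, prognostic_filter
from .config import PipelineConfig
from .errors import FitError, PipelineError, ValidationError
from .genomic_io import SignatureDocument
from .netrank import rank_genes
from .survival_core import (
    ConstrainedCoxFit,
    build_design,
    clinical_nonneg_mask,
    concordance,
    fit_constrained_cox,
    gene_pvalue,
    harrell_compare,
    logrank_test,
)

logger = logging.getLogger("cnaprog")


@dataclass
class CandidateModel:
    """Clinical + top-k genes constrained Cox fit with its AIC support."""

    k: int
    genes: list[str]
    fit: ConstrainedCoxFit
    aic: float
    delta_aic: float = np.nan
    weight: float = np.nan


@dataclass
class EnsembleSignature:
    """Fitted clinical-genomic signature: retained candidate models, their
    Akaike weights, and the serializable document."""

    document: SignatureDocument
    models: list[CandidateModel]

    @property
    def training_median(self) -> float:
        return self.document.training_median


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2) with
    Delta_i = AIC_i - min AIC.  Non-finite AICs get weight 0 (dropped with
    a warning); the rest renormalize to sum 1."""
    aics = np.asarray(list(aics), dtype=float)
    finite = np.isfinite(aics)
    if not finite.any():
        raise ValidationError("akaike_weights needs at least one finite AIC")
    if not finite.all():
        logger.warning("dropping %d models with non-finite AIC", int((~finite).sum()))
    delta = aics - aics[finite].min()
    w = np.where(finite, np.exp(-0.5 * np.where(finite, delta, 0.0)), 0.0)
    return w / w.sum()


def build_candidate_models(
    ranking: list[str],
    X_clin: pd.DataFrame,
    cn: pd.DataFrame,
    time,
    event,
    *,
    k_max: int = 15,
    delta_aic_max: float = 10.0,
) -> list[CandidateModel]:
    """Fit the nested models M_0..M_k along the ranking, retain those within
    ``delta_aic_max`` of the best AIC, and assign Akaike weights."""
    n_events = int(np.asarray(event).sum())
    limit = min(k_max, len(ranking), max(0, n_events - len(X_clin.columns) - 1))
    if limit < min(k_max, len(ranking)):
        logger.warning("k_max reduced to %d so events exceed parameters", limit)
    mask_clin = clinical_nonneg_mask(X_clin.columns)
    models: list[CandidateModel] = []
    for k in range(limit + 1):
        genes = list(ranking[:k])
        X = X_clin.copy()
        for g in genes:
            X[g] = cn.loc[g].reindex(X.index).to_numpy(dtype=float)
        mask = np.append(mask_clin, np.zeros(k, dtype=bool))
        try:
            fit = fit_constrained_cox(X, time, event, mask)
        except FitError as exc:
            logger.warning("model M_%d failed to fit: %s", k, exc)
            continue
        if not (fit.converged or fit.kkt_ok(1e-4)):
            logger.warning("model M_%d non-convergent; excluded", k)
            continue
        models.append(CandidateModel(k=k, genes=genes, fit=fit, aic=fit.aic))
    if not models:
        raise PipelineError("no candidate model converged")
    best = min(m.aic for m in models)
    retained = [m for m in models if m.aic - best <= delta_aic_max]
    w = akaike_weights([m.aic for m in retained])
    for m, wi in zip(retained, w):
        m.delta_aic = m.aic - best
        m.weight = float(wi)
    return retained


def linear_predictor(coef: dict, centering: dict, X: pd.DataFrame) -> np.ndarray:
    """Centered linear predictor sum_j beta_j (x_j - mean_j)."""
    eta = np.zeros(len(X))
    for col, beta in coef.items():
        if col not in X.columns:
            raise ValidationError(f"design matrix is missing column {col!r}")
        eta += beta * (X[col].to_numpy(dtype=float) - centering.get(col, 0.0))
    return eta


def ensemble_risk_score(doc: SignatureDocument, X: pd.DataFrame) -> pd.Series:
    """Akaike-weighted average of the member models' linear predictors."""
    score = np.zeros(len(X))
    for model, w in zip(doc.models, doc.akaike_weights):
        score += w * linear_predictor(model["coef"], doc.centering, X)
    return pd.Series(score, index=X.index, name="risk_score")


def dichotomize(scores, threshold: float) -> np.ndarray:
    """Risk groups: 'high' iff score > threshold, else 'low'.  With the
    cohort's own median and even n this yields equal-sized groups."""
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValidationError("risk scores must be finite")
    return np.where(s > threshold, "high", "low")


def _reported_prefix(ranking: list[str], models: list[CandidateModel]) -> list[str]:
    """Flat signature: genes whose member models carry cumulative Akaike
    weight >= 0.5.  Because the models are nested prefixes, the cumulative
    weight of the rank-r gene is the total weight of models with k >= r,
    which is non-increasing in r — so the reported list is a prefix."""
    reported = []
    for r, gene in enumerate(ranking, start=1):
        tail_weight = sum(m.weight for m in models if m.k >= r)
        if tail_weight >= 0.5:
            reported.append(gene)
        else:
            break
    return reported


def derive_signature(
    cn_labeled: pd.DataFrame,
    cn_unlabeled: pd.DataFrame,
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    evidence,
    config: PipelineConfig = PipelineConfig(),
    *,
    seed: int | None = None,
) -> EnsembleSignature:
    """Run the full model-selection pipeline and return the fitted signature.

    Stages: correlation filter (CN vs expression, all samples with both),
    prognostic filter (external evidence), per-candidate constrained Cox
    p-values on the labeled samples, NetRank re-ranking over the unlabeled-
    sample network, nested-model AIC ensemble, and the training-median risk
    threshold.  Deterministic given inputs and config.
    """
    cn_all = pd.concat([cn_labeled, cn_unlabeled], axis=1)
    _, corr_pass = correlation_filter(
        cn_all, expr, q_threshold=config.q_threshold,
        method=config.corr_method, fdr_method=config.fdr_method,
    )
    prog_pass, flags = prognostic_filter(set(cn_all.index), evidence, alpha=config.alpha)
    candidates = intersect_candidates(
        corr_pass, prog_pass, histology=config.histology, flags=flags
    )
    logger.info(
        "filters: %d correlation-pass, %d prognostic-pass, %d candidates",
        len(corr_pass), len(prog_pass), len(candidates),
    )
    if not len(candidates):
        raise PipelineError("empty candidate set: the two filters do not intersect")

    labeled = clinical[clinical["labeled"]]
    X_clin = build_design(labeled)
    y = labeled.loc[X_clin.index]
    time = y["os_time"].to_numpy(dtype=float)
    event = y["os_event"].to_numpy(dtype=float)

    pvals = pd.Series(
        {
            g: gene_pvalue(X_clin, cn_labeled.loc[g].rename(g), time, event)
            for g in candidates.gene_ids
        }
    )
    ranking, _ = rank_genes(
        candidates.gene_ids, pvals, cn_unlabeled,
        damping=config.damping, edge_threshold=config.edge_threshold,
        transform=config.relevance_transform, dangling=config.dangling,
    )
    models = build_candidate_models(
        ranking, X_clin, cn_labeled, time, event,
        k_max=config.k_max, delta_aic_max=config.delta_aic_max,
    )
    reported = _reported_prefix(ranking, models)
    member_genes = sorted({g for m in models for g in m.genes})

    # training means anchor every member model's linear predictor
    all_cols = list(X_clin.columns) + member_genes
    X_full = X_clin.copy()
    for g in member_genes:
        X_full[g] = cn_labeled.loc[g].reindex(X_clin.index).to_numpy(dtype=float)
    centering = {c: float(X_full[c].mean()) for c in all_cols}

    weights = [m.weight for m in models]
    clinical_coef = {
        col: float(sum(m.weight * m.fit.coef.get(col, 0.0) for m in models))
        for col in X_clin.columns
    }
    model_dicts = [
        {
            "k": m.k,
            "genes": m.genes,
            "coef": {c: float(v) for c, v in m.fit.coef.items()},
            "log_likelihood": m.fit.log_likelihood,
            "aic": m.aic,
            "delta_aic": m.delta_aic,
            "weight": m.weight,
        }
        for m in models
    ]

    aux: dict[str, dict[str, float]] = {}
    clin_only = next((m for m in models if m.k == 0), None)
    if clin_only is None:
        fit0 = fit_constrained_cox(X_clin, time, event, clinical_nonneg_mask(X_clin.columns))
        aux["clinical_only"] = {c: float(v) for c, v in fit0.coef.items()}
    else:
        aux["clinical_only"] = {c: float(v) for c, v in clin_only.fit.coef.items()}
    if reported:
        Xg = X_full[reported]
        try:
            fitg = fit_constrained_cox(Xg, time, event)
            aux["genomic_only"] = {c: float(v) for c, v in fitg.coef.items()}
        except FitError as exc:
            logger.warning("genomic-only reference model failed: %s", exc)

    doc = SignatureDocument(
        histology=config.histology,
        clinical_coef=clinical_coef,
        genes=member_genes,
        reported_genes=reported,
        models=model_dicts,
        akaike_weights=[float(w) for w in weights],
        training_median=np.nan,  # filled below
        centering=centering,
        aux_models=aux,
        provenance={"config_hash": config.hash(), "seed": seed,
                    "config": config.to_dict(),
                    "n_correlation_pass": len(corr_pass),
                    "n_prognostic_pass": len(prog_pass),
                    "n_candidates": len(candidates)},
    )
    scores = ensemble_risk_score(doc, X_full)
    doc.training_median = float(np.median(scores))
    return EnsembleSignature(document=doc, models=models)


def _auxiliary_score(doc: SignatureDocument, name: str, X: pd.DataFrame) -> np.ndarray | None:
    coef = doc.aux_models.get(name)
    if not coef:
        return None
    return linear_predictor(coef, doc.centering, X)


def evaluate_signature(
    sig: EnsembleSignature | SignatureDocument,
    cn_val: pd.DataFrame,
    clinical_val: pd.DataFrame,
    *,
    threshold_mode: str = "training-median",
) -> dict:
    """Evaluate a fitted signature on a labeled cohort.

    Reports the univariate Cox fit on the (unit-variance standardized)
    continuous risk score — hazard ratio with 95% CI and the one-tailed
    p-value for HR > 1 — plus the log-rank test on the dichotomized risk
    groups, Harrell's c-index, and the paired Harrell comparisons of the
    clinical-genomic score against the clinical-only and genomic-only
    reference scores.
    """
    doc = sig.document if isinstance(sig, EnsembleSignature) else sig
    labeled = clinical_val[clinical_val["labeled"]]
    X = build_design(labeled, cn_val.loc[[g for g in doc.genes if g in cn_val.index]])
    missing = [g for g in doc.genes if g not in X.columns]
    if missing:
        raise ValidationError(f"validation CN matrix is missing genes {missing[:5]}")
    y = labeled.loc[X.index]
    time = y["os_time"].to_numpy(dtype=float)
    event = y["os_event"].to_numpy(dtype=float)

    scores = ensemble_risk_score(doc, X).to_numpy()
    sd = scores.std()
    z_scores = scores / sd if sd > 0 else scores
    df = pd.DataFrame({"time": time, "event": event, "score": z_scores})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["score"])
    se = float(cph.standard_errors_["score"])
    report = {
        "n": int(len(df)),
        "n_events": int(event.sum()),
        "hr_per_sd": float(np.exp(beta)),
        "hr_ci95": [float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))],
        "cox_p_onetailed": float(stats.norm.sf(beta / se)) if se > 0 else np.nan,
        "c_index": float(concordance(scores, time, event)),
    }

    if threshold_mode == "training-median":
        threshold = doc.training_median
    elif threshold_mode == "cohort-median":
        threshold = float(np.median(scores))
    else:
        raise ValidationError(f"unknown threshold mode {threshold_mode!r}")
    groups = dichotomize(scores, threshold)
    if len(np.unique(groups)) == 2:
        lr_stat, lr_p = logrank_test(time, event, groups == "high")
        report["logrank_stat"], report["logrank_p"] = lr_stat, lr_p
        g_high = groups == "high"
        cph2 = CoxPHFitter()
        cph2.fit(
            pd.DataFrame({"time": time, "event": event, "high": g_high.astype(float)}),
            duration_col="time", event_col="event",
        )
        report["hr_high_vs_low"] = float(np.exp(cph2.params_["high"]))
    else:
        logger.warning("degenerate risk grouping (single group); log-rank skipped")
        report["logrank_p"] = None
        report["degenerate_grouping"] = True

    for name, key in (("clinical_only", "harrell_p_vs_clinical"),
                      ("genomic_only", "harrell_p_vs_genomic")):
        ref = _auxiliary_score(doc, name, X)
        if ref is not None:
            delta, p = harrell_compare(ref, scores, time, event)
            report[key] = float(p)
            report[key.replace("_p_", "_dc_")] = float(delta)
    return report
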