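"""Constrained Cox proportional-hazards fitting and survival statistics.

The signature models are Cox PH fits in which clinically established
directions are enforced: the coefficients for age, male sex and each
incremental stage risk are bounded below by zero (risk must not decrease
with age or stage, nor be lower in men).  Stage enters as monotone
indicator increments — IA is the reference, and a patient's stage
log-hazard is the cumulative sum of the increments for every stage up to
their own — so stage risk is monotone by construction.

Fitting maximizes the Efron-tie partial log-likelihood with a bound-
constrained quasi-Newton (L-BFGS-B) started at beta = 0; the problem is
convex, so the KKT conditions at the reported optimum (zero gradient on
free coordinates, non-positive gradient on coordinates pinned at the
bound) certify the solution.  Coefficients pinned at an active bound are
not counted as free parameters in the AIC.

Evaluation statistics live here too: the log-rank test, Harrell's
concordance index (tied scores count 1/2), and a paired comparison of two
risk scores via the jackknife variance of the concordance difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import optimize, stats

from .errors import FitError, ValidationError
from .genomic_io import STAGES

logger = logging.getLogger("cnaprog")

CLINICAL_COLUMNS = ["age", "sex_male", "stage_ge_IB", "stage_ge_IIA", "stage_ge_IIB"]

#: snap tolerance: a masked coefficient below this is an active constraint
_ACTIVE_TOL = 1e-7


@dataclass
class ConstrainedCoxFit:
    """One fitted candidate model."""

    coef: pd.Series                 # per-column coefficients, original scale
    nonneg_mask: np.ndarray         # which columns were bounded below by 0
    active: np.ndarray              # which masked columns sit at the bound (coef exactly 0)
    log_likelihood: float           # Cox partial log-likelihood at the optimum
    aic: float                      # 2q - 2 logPL, q = coefficients not at an active bound
    n_free: int
    converged: bool
    gradient: np.ndarray            # partial-likelihood gradient at the optimum
    n: int
    n_events: int

    def kkt_ok(self, tol: float = 1e-5) -> bool:
        g = self.gradient
        free = ~(self.nonneg_mask & self.active)
        return bool(np.all(np.abs(g[free]) < tol) and np.all(g[~free] <= tol))


def build_design(clinical: pd.DataFrame, cn: pd.DataFrame | None = None) -> pd.DataFrame:
    """Build the model design matrix from a labeled clinical table and an
    optional genes x samples CN matrix.

    Columns: age (years), sex_male (0/1, female reference), the monotone
    stage indicators (IA -> 0,0,0; IB -> 1,0,0; IIA -> 1,1,0; IIB -> 1,1,1),
    then one column per gene.  Samples with missing age, sex or stage — or a
    missing CN value for a requested gene — are excluded with a warning.
    """
    df = clinical.copy()
    complete = df[["age", "sex", "stage"]].notna().all(axis=1)
    if not complete.all():
        logger.warning("build_design: excluding %d samples with missing clinical data",
                       int((~complete).sum()))
        df = df[complete]
    if not df["stage"].isin(STAGES).all():
        raise ValidationError("unknown stage in clinical table")
    stage_rank = df["stage"].map({s: i for i, s in enumerate(STAGES)}).astype(int)
    X = pd.DataFrame(index=df.index)
    X["age"] = df["age"].astype(float)
    X["sex_male"] = (df["sex"] == "male").astype(float)
    X["stage_ge_IB"] = (stage_rank >= 1).astype(float)
    X["stage_ge_IIA"] = (stage_rank >= 2).astype(float)
    X["stage_ge_IIB"] = (stage_rank >= 3).astype(float)
    if cn is not None and len(cn):
        genes = cn.reindex(columns=X.index).T
        X = X.join(genes.astype(float))
        ok = X.notna().all(axis=1)
        if not ok.all():
            logger.warning("build_design: excluding %d samples with missing CN",
                           int((~ok).sum()))
            X = X[ok]
    return X


def clinical_nonneg_mask(columns) -> np.ndarray:
    """Non-negativity mask: clinical columns constrained, gene columns free."""
    return np.array([c in CLINICAL_COLUMNS for c in columns], dtype=bool)


class _CoxProblem:
    """Precomputed time ordering and tie structure of one dataset, so that
    repeated likelihood evaluations during optimization cost O(n p)."""

    def __init__(self, X: np.ndarray, time: np.ndarray, event: np.ndarray):
        order = np.argsort(time, kind="mergesort")
        self.t = time[order]
        self.e = event[order].astype(bool)
        self.X = np.ascontiguousarray(X[order])
        ev_times = self.t[self.e]  # already sorted
        uniq, self.d = np.unique(ev_times, return_counts=True)
        self.k0 = np.searchsorted(self.t, uniq, side="left")   # risk-set start per event time
        self.ev_idx = np.nonzero(self.e)[0]                    # event rows, time-ordered
        self.group_starts = np.concatenate([[0], np.cumsum(self.d)[:-1]])
        # Efron fractions l/d for every (event time, l) pair, flattened
        self.frac = np.concatenate([np.arange(d) / d for d in self.d])
        self.term_group = np.repeat(np.arange(len(uniq)), self.d)
        self.x_event_sum = self.X[self.ev_idx].sum(axis=0)

    def loglik_grad(self, beta: np.ndarray) -> tuple[float, np.ndarray]:
        eta = self.X @ beta
        shift = eta.max()  # PL is invariant to a common shift; guards exp overflow
        w = np.exp(eta - shift)
        W = np.cumsum(w[::-1])[::-1]            # sum of w over the risk set {t_i >= t_k}
        Wx = np.cumsum((w[:, None] * self.X)[::-1], axis=0)[::-1]
        S_D = np.add.reduceat(w[self.ev_idx], self.group_starts)
        V_D = np.add.reduceat((w[:, None] * self.X)[self.ev_idx], self.group_starts, axis=0)
        denom = W[self.k0][self.term_group] - self.frac * S_D[self.term_group]
        inv = 1.0 / denom
        a = np.zeros(len(self.k0))
        b = np.zeros(len(self.k0))
        np.add.at(a, self.term_group, inv)
        np.add.at(b, self.term_group, self.frac * inv)
        loglik = float((eta - shift)[self.ev_idx].sum() - np.log(denom).sum())
        grad = self.x_event_sum - (a[:, None] * Wx[self.k0]).sum(axis=0) \
            + (b[:, None] * V_D).sum(axis=0)
        return loglik, grad


def cox_loglik_grad(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                    beta: np.ndarray) -> tuple[float, np.ndarray]:
    """Efron partial log-likelihood and its gradient (single evaluation)."""
    return _CoxProblem(np.asarray(X, float), np.asarray(time, float),
                       np.asarray(event, float)).loglik_grad(np.asarray(beta, float))


def fit_constrained_cox(
    X: pd.DataFrame,
    time,
    event,
    nonneg_mask: np.ndarray | None = None,
    *,
    max_iter: int = 500,
) -> ConstrainedCoxFit:
    """Maximize the Cox partial likelihood subject to beta_j >= 0 on masked
    columns.  Columns are internally centered and scaled for conditioning;
    the fit starts at beta = 0."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if event.sum() < 1:
        raise FitError("no events in the outcome")
    A = X.to_numpy(dtype=float)
    n, p = A.shape
    if nonneg_mask is None:
        nonneg_mask = np.zeros(p, dtype=bool)
    nonneg_mask = np.asarray(nonneg_mask, dtype=bool)
    sd = A.std(axis=0)
    if (sd == 0).any():
        col = X.columns[int(np.argmax(sd == 0))]
        raise FitError(f"zero-variance column {col!r}")
    mean = A.mean(axis=0)
    Ac = (A - mean) / sd
    problem = _CoxProblem(Ac, time, event)

    def neg(beta_std):
        ll, g = problem.loglik_grad(beta_std)
        return -ll, -g

    bounds = [(0.0, None) if m else (None, None) for m in nonneg_mask]
    res = optimize.minimize(
        neg, np.zeros(p), jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9},
    )
    beta_std = res.x
    active = nonneg_mask & (beta_std < _ACTIVE_TOL)
    beta_std = np.where(active, 0.0, beta_std)
    ll, _ = problem.loglik_grad(beta_std)
    beta = beta_std / sd
    # gradient wrt the original-scale coefficients (centered design, same PL)
    _, grad = cox_loglik_grad(A - mean, time, event, beta)
    n_free = int(p - active.sum())
    fit = ConstrainedCoxFit(
        coef=pd.Series(beta, index=X.columns),
        nonneg_mask=nonneg_mask,
        active=active,
        log_likelihood=ll,
        aic=2.0 * n_free - 2.0 * ll,
        n_free=n_free,
        converged=bool(res.success),
        gradient=grad,
        n=n,
        n_events=int(event.sum()),
    )
    if not fit.converged and not fit.kkt_ok(1e-4):
        logger.warning("constrained Cox did not converge: %s", res.message)
    return fit


def gene_pvalue(X_clin: pd.DataFrame, gene_cn: pd.Series, time, event) -> float:
    """Likelihood-ratio p-value (1 df) for adding one gene's copy number to
    the constrained clinical model.  The gene coefficient is unconstrained
    in sign; the clinical coefficients stay bounded at zero in both fits.
    Non-convergent fits yield p = 1."""
    mask_clin = clinical_nonneg_mask(X_clin.columns)
    X_full = X_clin.copy()
    X_full[gene_cn.name or "gene"] = gene_cn.reindex(X_clin.index).to_numpy(dtype=float)
    mask_full = np.append(mask_clin, False)
    try:
        fit0 = fit_constrained_cox(X_clin, time, event, mask_clin)
        fit1 = fit_constrained_cox(X_full, time, event, mask_full)
    except FitError:
        return 1.0
    if not (fit0.converged or fit0.kkt_ok(1e-4)) or not (fit1.converged or fit1.kkt_ok(1e-4)):
        logger.warning("gene_pvalue: non-convergent fit, reporting p = 1")
        return 1.0
    lrt = max(0.0, 2.0 * (fit1.log_likelihood - fit0.log_likelihood))
    return float(stats.chi2.sf(lrt, df=1))


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test (chi-square, 1 df).  Groups must both be
    non-empty."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValidationError("log-rank test needs two non-empty groups")
    g1 = group == levels[0]
    res = _ll_logrank(times[g1], times[~g1], events[g1], events[~g1])
    return float(res.test_statistic), float(res.p_value)


def _pair_stats(scores, times, events):
    """Pairwise concordance bookkeeping for Harrell's c.

    A pair is usable iff the sample with the shorter time had an event.
    Returns (num, den, num_i, den_i): totals and per-sample involvements,
    with tied scores contributing 1/2."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    shorter = (t[:, None] < t[None, :]) & e[:, None]          # i shorter, with event
    conc = (s[:, None] > s[None, :]) + 0.5 * (s[:, None] == s[None, :])
    num_m = shorter * conc
    den_i = shorter.sum(axis=1) + shorter.sum(axis=0)
    num_i = num_m.sum(axis=1) + num_m.sum(axis=0)
    return float(num_m.sum()), float(shorter.sum()), num_i, den_i


def concordance(scores, times, events) -> float:
    """Harrell's concordance index of a risk score (higher score should mean
    shorter survival); score ties count 1/2."""
    num, den, _, _ = _pair_stats(scores, times, events)
    if den == 0:
        raise ValidationError("no usable pairs for the concordance index")
    return num / den


def harrell_compare(scores_ref, scores_alt, times, events) -> tuple[float, float]:
    """One-sided paired comparison of two risk scores on the same samples.

    Returns (delta_c, p) where delta_c = c(alt) - c(ref) and p is the
    one-sided normal p-value that the alternative score is more concordant,
    using the leave-one-out jackknife variance of the paired c difference.
    """
    scores_ref = np.asarray(scores_ref, dtype=float)
    scores_alt = np.asarray(scores_alt, dtype=float)
    if scores_ref.shape != scores_alt.shape:
        raise ValidationError("score vectors must cover the same samples")
    n = len(scores_ref)
    num_a, den, num_ai, den_i = _pair_stats(scores_alt, times, events)
    num_r, _, num_ri, _ = _pair_stats(scores_ref, times, events)
    if den == 0:
        raise ValidationError("no usable pairs")
    c_alt, c_ref = num_a / den, num_r / den
    delta = c_alt - c_ref
    den_loo = den - den_i
    safe = np.where(den_loo > 0, den_loo, 1.0)
    theta = np.where(
        den_loo > 0, ((num_a - num_ai) - (num_r - num_ri)) / safe, delta
    )
    var = (n - 1) / n * np.sum((theta - theta.mean()) ** 2)
    se = np.sqrt(var)
    if se == 0:
        if delta == 0:
            return delta, 0.5
        return delta, (0.0 if delta > 0 else 1.0)
    return float(delta), float(stats.norm.sf(delta / se))
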