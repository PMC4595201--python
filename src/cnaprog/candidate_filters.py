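"""Candidate-gene selection: correlation filter x prognostic-evidence filter.

The correlation filter keeps genes whose copy number correlates *positively*
with their own expression (a CNA that does not change expression is unlikely
to act).  Per gene, a Pearson correlation over paired samples is mapped to a
Fisher z statistic; the one-sided significance of all genes is then judged
jointly with a two-groups local false discovery rate (theoretical N(0,1)
null, marginal density by Lindsey's Poisson-regression fit), and the tail-
averaged lfdr serves as a q-value.  Genes with q below 0.2 pass.

The prognostic filter keeps genes with external survival evidence: membership
in a curated outcome gene list, or a significant Stouffer meta-analysis of
per-study survival z-scores.  Candidates are the intersection of the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger("cnaprog")


@dataclass(frozen=True)
class PrognosticEvidence:
    """External survival evidence: a curated outcome-associated gene list and
    a per-(gene, study) table of signed survival z-scores."""

    curated_genes: frozenset
    study_stats: pd.DataFrame  # columns: gene_id, study_id, z_score

    def __post_init__(self) -> None:
        df = self.study_stats
        for col in ("gene_id", "study_id", "z_score"):
            if col not in df.columns:
                raise ValidationError(f"study_stats missing column {col!r}")
        if df.duplicated(["gene_id", "study_id"]).any():
            raise ValidationError("duplicate (gene_id, study_id) in study_stats")
        if len(df) and not np.isfinite(df["z_score"].astype(float)).all():
            raise ValidationError("non-finite study z-score")


@dataclass
class CandidateSet:
    """Genes passing both filters, with per-gene provenance flags."""

    histology: str
    gene_ids: list[str]
    provenance: pd.DataFrame  # index gene_id; bool columns corr_pass, curated, meta_significant

    def __len__(self) -> int:
        return len(self.gene_ids)


def local_fdr(z: np.ndarray, *, n_bins: int = 60, poly_degree: int = 5) -> np.ndarray:
    """Two-groups local false discovery rate of z-statistics.

    The marginal density f(z) is estimated by Lindsey's method (Poisson GLM
    of histogram counts on a polynomial of the bin midpoints); the null is
    the theoretical N(0,1), with the null proportion estimated by central
    matching at z = 0 and capped at 1.  Returns lfdr in [0, 1] per input z.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 2:
        return np.ones_like(z)
    lo = min(z.min(), -4.0) - 0.1
    hi = max(z.max(), 4.0) + 0.1
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    scale = np.std(mids)
    design = np.vander((mids - mids.mean()) / scale, poly_degree + 1, increasing=True)
    fit = sm.GLM(counts, design, family=sm.families.Poisson()).fit()
    # density of the marginal at an arbitrary point
    def f_hat(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        d = np.vander((x - mids.mean()) / scale, poly_degree + 1, increasing=True)
        return np.exp(d @ fit.params) / (z.size * width)

    pi0 = min(1.0, float(f_hat(0.0)[0] / stats.norm.pdf(0.0)))
    lfdr = pi0 * stats.norm.pdf(z) / np.maximum(f_hat(z), 1e-300)
    return np.clip(lfdr, 0.0, 1.0)


def tail_q_values(z: np.ndarray, lfdr: np.ndarray) -> np.ndarray:
    """q(gene) = mean lfdr over genes at least as extreme (z >= z(gene));
    monotone non-decreasing along the p-value ranking by construction."""
    order = np.argsort(-z, kind="mergesort")
    q_sorted = np.cumsum(lfdr[order]) / np.arange(1, len(z) + 1)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def correlation_filter(
    cn: pd.DataFrame,
    expr: pd.DataFrame,
    *,
    q_threshold: float = 0.2,
    method: str = "pearson",
    fdr_method: str = "lfdr",
) -> tuple[pd.DataFrame, list[str]]:
    """Test each gene for positive copy-number/expression correlation.

    Returns ``(results, retained)``: a per-gene table with columns
    ``r, n, z, p_onesided, lfdr, q`` and the list of gene ids with
    ``q < q_threshold``.  Genes with fewer than 4 paired samples or with
    zero variance on either side are skipped with a warning.
    ``fdr_method="bh"`` replaces the local-fdr q with Benjamini-Hochberg.
    """
    shared_samples = [s for s in cn.columns if s in expr.columns]
    shared_genes = [g for g in cn.index if g in expr.index]
    if len(shared_samples) < 10:
        logger.warning("correlation filter: only %d paired samples", len(shared_samples))
    rows = []
    skipped = 0
    for g in shared_genes:
        x = cn.loc[g, shared_samples].to_numpy(dtype=float)
        y = expr.loc[g, shared_samples].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < 4 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            skipped += 1
            continue
        if method == "spearman":
            r = stats.spearmanr(x[ok], y[ok]).statistic
        else:
            r = stats.pearsonr(x[ok], y[ok]).statistic
        r = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        z = np.arctanh(r) * np.sqrt(n - 3)
        rows.append((g, r, n, z, stats.norm.sf(z)))
    if skipped:
        logger.warning("correlation filter: skipped %d degenerate genes", skipped)
    res = pd.DataFrame(rows, columns=["gene_id", "r", "n", "z", "p_onesided"]).set_index(
        "gene_id"
    )
    if not len(res):
        res["lfdr"] = res["q"] = []
        return res, []
    z = res["z"].to_numpy()
    if fdr_method == "bh":
        from statsmodels.stats.multitest import multipletests

        res["lfdr"] = np.nan
        res["q"] = multipletests(res["p_onesided"], method="fdr_bh")[1]
    else:
        res["lfdr"] = local_fdr(z)
        res["q"] = tail_q_values(z, res["lfdr"].to_numpy())
    retained = res.index[res["q"] < q_threshold].tolist()
    return res, retained


def stouffer_meta(z_scores) -> tuple[float, float]:
    """Unweighted Stouffer combination of signed per-study z-scores.

    Returns (z_meta, two-sided p).  z_meta = sum(z) / sqrt(k).
    """
    z = np.asarray(list(z_scores), dtype=float)
    if z.size == 0:
        raise ValidationError("stouffer_meta needs at least one study")
    z_meta = float(z.sum() / np.sqrt(z.size))
    p = float(2.0 * stats.norm.sf(abs(z_meta)))
    return z_meta, p


def prognostic_filter(
    genes, evidence: PrognosticEvidence, *, alpha: float = 0.05
) -> tuple[set, pd.DataFrame]:
    """Keep genes with external survival evidence: curated, or meta-significant
    (two-sided Stouffer p < alpha, any direction of association).

    Returns (retained set restricted to ``genes``, per-gene flags).
    """
    genes = set(genes)
    stats_by_gene = evidence.study_stats.groupby("gene_id")["z_score"]
    meta_sig = set()
    for gene_id, zs in stats_by_gene:
        _, p = stouffer_meta(zs.to_numpy())
        if p < alpha:
            meta_sig.add(gene_id)
    curated = set(evidence.curated_genes)
    retained = genes & (curated | meta_sig)
    flags = pd.DataFrame(
        {
            "curated": [g in curated for g in sorted(genes)],
            "meta_significant": [g in meta_sig for g in sorted(genes)],
        },
        index=sorted(genes),
    )
    return retained, flags


def intersect_candidates(
    correlation_pass, prognostic_pass, *, histology: str = "", flags: pd.DataFrame | None = None
) -> CandidateSet:
    """Candidate set = correlation filter pass AND prognostic filter pass,
    ordered deterministically by gene id."""
    corr = set(correlation_pass)
    prog = set(prognostic_pass)
    members = sorted(corr & prog)
    if not members:
        logger.warning("empty candidate set: the two filters do not intersect")
    universe = sorted(corr | prog)
    prov = pd.DataFrame(index=universe)
    prov["corr_pass"] = [g in corr for g in universe]
    if flags is not None:
        prov = prov.join(flags, how="left").fillna(False)
    else:
        prov["curated"] = False
        prov["meta_significant"] = False
    return CandidateSet(histology=histology, gene_ids=members, provenance=prov.loc[members])
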