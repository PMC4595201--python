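"""Semi-supervised gene re-ranking over an unlabeled-sample correlation network.

Candidate genes are first scored by the significance of their copy number in
the multivariate survival model (small p = high relevance).  Unlabeled
samples — those without outcome data — then contribute through a gene-gene
network whose edges are strong absolute CN correlations among those samples.
A PageRank-style fixed point redistributes relevance along the network:

    r = (1 - d) * s + d * M^T r

with s the normalized intrinsic relevance, M the row-normalized edge-weight
matrix and d the damping factor.  At d = 0 the ranking is exactly the
p-value ranking; larger d lets a gene borrow relevance from correlated
neighbours.  Rows of isolated (dangling) nodes donate nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PipelineError, ValidationError

logger = logging.getLogger("cnaprog")


@dataclass
class GeneNetwork:
    """Symmetric non-negative weighted gene graph (zero diagonal)."""

    genes: list[str]
    weights: np.ndarray  # (n, n) symmetric, w_ii = 0

    def __post_init__(self) -> None:
        w = self.weights
        if w.shape != (len(self.genes), len(self.genes)):
            raise ValidationError("weight matrix shape does not match gene list")
        if (w < 0).any() or not np.allclose(w, w.T) or np.diag(w).any():
            raise ValidationError("weights must be symmetric, non-negative, zero-diagonal")

    @property
    def out_weight(self) -> np.ndarray:
        return self.weights.sum(axis=1)


@dataclass
class NetRankResult:
    genes: list[str]
    initial: np.ndarray       # normalized relevance s (sums to 1)
    damping: float
    scores: np.ndarray        # converged r
    n_iter: int
    ranking: list[str]        # descending score, ties broken by gene id


def build_network(cn_unlabeled: pd.DataFrame, threshold: float = 0.5) -> GeneNetwork:
    """Gene network from unlabeled-sample CN: edge (i, j) iff |Pearson r| of
    the two genes' CN vectors reaches the threshold, weighted |r|."""
    if cn_unlabeled.shape[0] < 2:
        raise ValidationError("network needs at least 2 genes")
    if cn_unlabeled.shape[1] < 10:
        logger.warning(
            "building the gene network from only %d unlabeled samples; "
            "correlations will be noisy", cn_unlabeled.shape[1],
        )
    X = cn_unlabeled.to_numpy(dtype=float)
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr[~np.isfinite(corr)] = 0.0  # zero-variance genes stay isolated
    w = np.abs(corr)
    w[w < threshold] = 0.0
    np.fill_diagonal(w, 0.0)
    w[sd == 0, :] = 0.0
    w[:, sd == 0] = 0.0
    w = 0.5 * (w + w.T)
    return GeneNetwork(genes=list(cn_unlabeled.index), weights=w)


def relevance_from_pvalues(pvalues: np.ndarray, transform: str = "neglog10") -> np.ndarray:
    """Map per-gene p-values to a normalized relevance vector (sums to 1).

    ``neglog10`` uses -log10(p) (order-preserving, mass on strong genes);
    ``one_minus_p`` uses 1 - p.  All-null input (every p = 1) falls back to
    the uniform vector.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        tiny = np.finfo(float).tiny
        if (p > 1).any() or (p < 0).any():
            raise ValidationError("p-values must lie in (0, 1]")
        logger.warning("p-value of 0 clipped to machine minimum")
        p = np.clip(p, tiny, 1.0)
    if transform == "neglog10":
        s = -np.log10(p)
    elif transform == "one_minus_p":
        s = 1.0 - p
    else:
        raise ValidationError(f"unknown relevance transform {transform!r}")
    total = s.sum()
    if total <= 0:
        return np.full_like(s, 1.0 / len(s))
    return s / total


def netrank_scores(
    network: GeneNetwork,
    pvalues,
    damping: float = 0.3,
    *,
    transform: str = "neglog10",
    dangling: str = "drop",
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> NetRankResult:
    """Iterate r <- (1-d) s + d M^T r to convergence (L1 change < tol).

    ``dangling="drop"`` lets isolated nodes donate nothing (their score still
    receives (1-d) s); ``dangling="uniform"`` redistributes their mass
    uniformly, as classic PageRank does.
    """
    if not 0.0 <= damping < 1.0:
        raise ValidationError(f"damping must lie in [0, 1), got {damping}")
    s = relevance_from_pvalues(np.asarray(list(pvalues), dtype=float), transform)
    if len(s) != len(network.genes):
        raise ValidationError("p-value vector does not match network nodes")
    n = len(s)
    out = network.out_weight
    dangling_nodes = out == 0
    safe_out = np.where(dangling_nodes, 1.0, out)
    M = network.weights / safe_out[:, None]  # row-normalized; dangling rows all zero
    r = s.copy()
    for it in range(1, max_iter + 1):
        r_new = (1.0 - damping) * s + damping * (M.T @ r)
        if dangling == "uniform" and dangling_nodes.any():
            r_new += damping * r[dangling_nodes].sum() / n
        delta = np.abs(r_new - r).sum()
        r = r_new
        if delta < tol:
            break
    order = sorted(range(n), key=lambda i: (-r[i], network.genes[i]))
    return NetRankResult(
        genes=list(network.genes),
        initial=s,
        damping=damping,
        scores=r,
        n_iter=it,
        ranking=[network.genes[i] for i in order],
    )


def rank_genes(
    candidate_genes: list[str],
    pvalues: pd.Series,
    cn_unlabeled: pd.DataFrame,
    *,
    damping: float = 0.3,
    edge_threshold: float = 0.5,
    transform: str = "neglog10",
    dangling: str = "drop",
) -> tuple[list[str], NetRankResult]:
    """Full ranking step: build the unlabeled-sample network over the
    candidate genes and re-rank their survival p-values by NetRank.
    Deterministic given fixed inputs."""
    if not candidate_genes:
        raise PipelineError("cannot rank an empty candidate set")
    genes = sorted(candidate_genes)
    if len(genes) == 1:  # nothing to propagate over
        res = NetRankResult(genes, np.array([1.0]), damping, np.array([1.0]), 0, genes)
        return genes, res
    network = build_network(cn_unlabeled.loc[genes], threshold=edge_threshold)
    p = pvalues.reindex(genes).to_numpy(dtype=float)
    result = netrank_scores(
        network, p, damping, transform=transform, dangling=dangling
    )
    pre = pd.Series(p, index=genes).rank()
    post = pd.Series(result.scores, index=genes).rank(ascending=False)
    if len(genes) > 2 and pre.std() > 0 and post.std() > 0:
        rho = stats.spearmanr(pre, post).statistic
        logger.info("NetRank: Spearman(pre, post ranking) = %.3f", rho)
    return result.ranking, result
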