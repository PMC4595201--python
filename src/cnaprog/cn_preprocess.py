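"""Tumor-purity correction and gene-level copy-number summarization.

An observed log2 ratio from an impure tumor sample is modeled as a two-
population mixture of diploid stroma and tumor at purity ``p``:

    observed = log2((p * c_t + 2 * (1 - p)) / 2)

where ``c_t`` is the tumor copy number.  ``purity_correct`` inverts this
admixture to recover ``log2(c_t / 2)``, clamping the tumor copy number at a
small positive floor so homozygous-deletion segments in low-purity samples
stay finite.  Corrected segment values are then collapsed to one value per
(gene, sample): a gene fully inside one segment takes that segment's value;
a gene spanning a breakpoint takes the weighted median of its internal
segments, weighted by base-pair overlap (lower median on ties).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genomic_io import GeneAnnotation

logger = logging.getLogger("cnaprog")

#: floor on the tumor copy number before taking the log, in copies
MIN_TUMOR_COPIES = 0.02


def purity_correct(seg_mean, purity):
    """Invert the stromal admixture: map observed log2 ratio(s) to tumor
    log2 ratio(s) ``log2(c_t / 2)`` at the given tumor purity.

    Purity 1 is the identity and seg_mean 0 (diploid) is a fixed point for
    every purity.  Vectorized over ``seg_mean``.
    """
    purity = np.asarray(purity, dtype=float)
    if np.any((purity <= 0) | (purity > 1)):
        raise ValidationError(f"purity must lie in (0, 1], got {purity}")
    seg_mean = np.asarray(seg_mean, dtype=float)
    c_t = (np.exp2(seg_mean + 1.0) - 2.0 * (1.0 - purity)) / purity
    c_t = np.maximum(c_t, MIN_TUMOR_COPIES)
    out = np.log2(c_t / 2.0)
    return out if out.ndim else float(out)


def weighted_median(values, weights):
    """Lower weighted median: the smallest value v such that the cumulative
    weight of values <= v reaches half the total weight."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0 or weights.sum() <= 0:
        raise ValidationError("weighted_median needs positive total weight")
    order = np.argsort(values, kind="mergesort")
    cum = np.cumsum(weights[order])
    idx = int(np.searchsorted(cum, cum[-1] / 2.0))
    return float(values[order][idx])


def genes_from_segments(
    segments: pd.DataFrame,
    genes: list[GeneAnnotation],
    purity: pd.Series,
    *,
    weight_by: str = "bases",
    max_missing_frac: float = 0.10,
) -> pd.DataFrame:
    """Collapse purity-corrected segments to a genes x samples log2-ratio matrix.

    Parameters
    ----------
    segments
        SegmentTable (0-based half-open, validated).
    genes
        Gene annotations defining the rows of the output.
    purity
        Per-sample tumor purity in (0, 1]; every sample in ``segments`` must
        be present.
    weight_by
        ``"bases"`` weights each internal segment by its base-pair overlap
        with the gene (default); ``"markers"`` weights by the segment's
        marker count instead.
    max_missing_frac
        Genes with no overlapping segment in more than this fraction of
        samples are dropped (with a logged count); remaining missing cells
        stay NaN.
    """
    if weight_by not in ("bases", "markers"):
        raise ValidationError(f"weight_by must be 'bases' or 'markers', got {weight_by!r}")
    samples = segments["sample_id"].unique().tolist()
    missing_purity = [s for s in samples if s not in purity.index]
    if missing_purity:
        raise ValidationError(f"samples absent from the purity table: {missing_purity[:5]}")

    gene_ids = [g.gene_id for g in genes]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError("duplicate gene ids in annotation")
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for row, g in enumerate(genes):
        by_chrom.setdefault(g.chromosome, []).append((g.start, g.end, row))

    grouped = {
        key: (grp["start"].to_numpy(), grp["end"].to_numpy(),
              grp["seg_mean"].to_numpy(), grp["num_markers"].to_numpy())
        for key, grp in segments.groupby(["sample_id", "chromosome"], sort=False)
    }
    out = np.full((len(genes), len(samples)), np.nan)
    for col, sample in enumerate(samples):
        p = float(purity.loc[sample])
        for chrom, gene_list in by_chrom.items():
            if (sample, chrom) not in grouped:
                continue
            starts, ends, seg_means, markers = grouped[(sample, chrom)]
            corrected = purity_correct(seg_means, p)
            gs = np.array([g[0] for g in gene_list])
            ge = np.array([g[1] for g in gene_list])
            rows = np.array([g[2] for g in gene_list])
            # segments are sorted and disjoint: locate the overlap window
            lo = np.searchsorted(ends, gs, side="right")
            hi = np.searchsorted(starts, ge, side="left")
            single = hi == lo + 1  # gene touches exactly one segment
            out[rows[single], col] = corrected[lo[single]]
            for k in np.nonzero(hi > lo + 1)[0]:
                sl = slice(lo[k], hi[k])
                if weight_by == "bases":
                    w = np.minimum(ends[sl], ge[k]) - np.maximum(starts[sl], gs[k])
                else:
                    w = markers[sl].astype(float)
                out[rows[k], col] = weighted_median(corrected[sl], w)

    cn = pd.DataFrame(out, index=gene_ids, columns=samples)
    n_missing = int(cn.isna().to_numpy().sum())
    if n_missing:
        logger.warning("gene-level CN: %d (gene, sample) cells without coverage", n_missing)
    frac_missing = cn.isna().mean(axis=1)
    drop = frac_missing > max_missing_frac
    if drop.any():
        logger.warning(
            "dropping %d genes missing in more than %.0f%% of samples",
            int(drop.sum()), 100 * max_missing_frac,
        )
        cn = cn.loc[~drop]
    return cn
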