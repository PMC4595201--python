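"""Synthetic cohorts with the statistical structure the pipeline assumes.

A cohort mimics a multi-dataset early-stage lung-cancer series: labeled
samples carry overall-survival outcomes, unlabeled samples contribute copy
number only.  Per sample, a piecewise-constant tumor copy profile is drawn
from a random breakpoint process on a gene grid; a subset of "planted"
genes receives recurrent focal gains/losses in a fraction of tumors.
Observed segment means mix the tumor profile with diploid stroma at a
per-sample purity — exactly the admixture the preprocessing step inverts —
and expression tracks true tumor copy number (slope b, Gaussian noise) for
the planted-correlation genes only.  Survival follows a Weibull-baseline
Cox model whose linear predictor combines age, incremental stage risks and
the planted prognostic genes' true copy numbers; censoring times are
calibrated to a target censoring rate.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .candidate_filters import PrognosticEvidence
from .errors import ValidationError
from .genomic_io import STAGES, GeneAnnotation, validate_clinical

logger = logging.getLogger("cnaprog")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort generator settings.

    The defaults define the standard study conditions used throughout the
    test-bench: 1,000 genes on 10 chromosomes, 200 labeled plus 300
    unlabeled samples, 100 genes with copy-number-driven expression of
    which 8 also carry a survival effect of |log-HR| 0.6 per unit log2
    ratio, follow-up on a months scale with a ~60-month baseline median
    and 40% censoring.
    """

    n_genes: int = 1000
    n_labeled: int = 200
    n_unlabeled: int = 300
    n_planted_corr: int = 100
    n_planted_prog: int = 8

    # genome model: genes on a regular grid, breakpoints between genes
    n_chromosomes: int = 10
    gene_spacing: int = 100_000       # bp between gene starts
    gene_length: int = 20_000         # bp

    # segment process (tumor log2 ratios)
    mean_segments_per_chrom: float = 3.0
    background_alt_prob: float = 0.3  # chance a background segment is altered
    background_alt_sd: float = 0.35   # log2 sd of altered background segments
    planted_alt_frac: float = 0.4     # fraction of tumors with the planted CNA
    planted_shift: float = 1.0        # |log2 shift| of a planted gain/loss

    # expression coupling for planted-correlation genes
    expr_slope: float = 1.0
    expr_noise_sd: float = 0.5

    # survival model
    age_loghr: float = 0.03           # per year
    sex_loghr: float = 0.0            # male vs female
    stage_increments: tuple = (0.4, 0.2, 0.3)  # IB, IIA, IIB increments
    gene_loghr: float = 0.6           # |log-HR| per unit log2 ratio
    weibull_shape: float = 1.2
    weibull_scale: float = 81.4       # months; baseline median ~60 months
    censoring_rate: float = 0.4
    purity_range: tuple = (0.4, 0.9)

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_prog > self.n_planted_corr:
            raise ValidationError("planted prognostic genes must be planted-correlated")
        if self.n_planted_corr > self.n_genes:
            raise ValidationError("more planted genes than genes")
        lo, hi = self.purity_range
        if not 0 < lo <= hi <= 1:
            raise ValidationError("purity range must lie in (0, 1]")
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError("censoring rate must lie in [0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
        return cls(**data)


@dataclass
class SyntheticCohort:
    segments: pd.DataFrame          # observed, purity-mixed SegmentTable
    purity: pd.Series
    cn_true: pd.DataFrame           # genes x samples true tumor log2 ratios
    expression: pd.DataFrame
    clinical: pd.DataFrame          # labeled + unlabeled rows
    genes: list[GeneAnnotation]
    evidence: PrognosticEvidence
    truth: dict = field(default_factory=dict)

    @property
    def labeled_samples(self) -> list[str]:
        return self.clinical.index[self.clinical["labeled"]].tolist()

    @property
    def unlabeled_samples(self) -> list[str]:
        return self.clinical.index[~self.clinical["labeled"]].tolist()


def make_gene_annotation(config: SimulationConfig) -> list[GeneAnnotation]:
    """Genes on a regular grid: gene j of a chromosome occupies the middle
    of cell [j*spacing, (j+1)*spacing), so any run of cells is a valid
    segment fully covering its genes."""
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    pad = (config.gene_spacing - config.gene_length) // 2
    genes = []
    for i in range(config.n_genes):
        chrom = f"chr{i // per_chrom + 1}"
        j = i % per_chrom
        start = j * config.gene_spacing + pad
        genes.append(GeneAnnotation(f"G{i + 1:04d}", chrom, start, start + config.gene_length))
    return genes


def _plant_truth(config: SimulationConfig, rng: np.random.Generator) -> dict:
    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    planted_corr = sorted(map(str, rng.choice(gene_ids, size=config.n_planted_corr, replace=False)))
    planted_prog = sorted(map(str, rng.choice(planted_corr, size=config.n_planted_prog, replace=False)))
    sign = {g: int(s) for g, s in zip(planted_corr, rng.choice([-1, 1], len(planted_corr)))}
    gamma = {g: config.gene_loghr * int(rng.choice([-1, 1])) for g in planted_prog}
    return {
        "gene_ids": gene_ids,
        "planted_corr": list(planted_corr),
        "planted_prog": list(planted_prog),
        "cna_sign": sign,
        "gamma": gamma,
    }


def _simulate_cn(
    config: SimulationConfig, truth: dict, sample_ids: list[str], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Tumor profiles, purity mixing, and the observed SegmentTable."""
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    spacing = config.gene_spacing
    planted_idx: dict[str, list[tuple[int, str]]] = {}
    for g in truth["planted_corr"]:
        i = int(g[1:]) - 1
        chrom = f"chr{i // per_chrom + 1}"
        planted_idx.setdefault(chrom, []).append((i % per_chrom, g))

    lo, hi = config.purity_range
    purity = pd.Series(rng.uniform(lo, hi, len(sample_ids)), index=sample_ids, name="purity")
    cn_true = np.zeros((config.n_genes, len(sample_ids)))
    rows = []
    for col, sample in enumerate(sample_ids):
        p = purity.iloc[col]
        for c in range(config.n_chromosomes):
            chrom = f"chr{c + 1}"
            m = min(per_chrom, config.n_genes - c * per_chrom)
            if m <= 0:
                break
            n_break = min(m - 1, rng.poisson(max(config.mean_segments_per_chrom - 1, 0)))
            cuts = np.sort(rng.choice(np.arange(1, m), size=n_break, replace=False)) if n_break else np.array([], dtype=int)
            bounds = np.concatenate([[0], cuts, [m]]).astype(int)
            cells = np.empty(m)
            for a, b in zip(bounds[:-1], bounds[1:]):
                altered = rng.uniform() < config.background_alt_prob
                cells[a:b] = rng.normal(0.0, config.background_alt_sd) if altered else 0.0
            for j, g in planted_idx.get(chrom, []):
                if j < m and rng.uniform() < config.planted_alt_frac:
                    shift = truth["cna_sign"][g] * abs(rng.normal(config.planted_shift, 0.15))
                    cells[j] = cells[j] + shift
            first = c * per_chrom
            cn_true[first:first + m, col] = cells
            # compress runs of equal value into observed segments
            change = np.nonzero(np.diff(cells) != 0)[0] + 1
            seg_bounds = np.concatenate([[0], change, [m]]).astype(int)
            for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
                c_t = 2.0 * np.exp2(cells[a])
                observed = np.log2((p * c_t + 2.0 * (1.0 - p)) / 2.0)
                rows.append((sample, chrom, a * spacing, b * spacing,
                             max(1, (b - a) * spacing // 10_000), observed))
    segments = pd.DataFrame(
        rows, columns=["sample_id", "chromosome", "start", "end", "num_markers", "seg_mean"]
    )
    cn = pd.DataFrame(cn_true, index=truth["gene_ids"], columns=sample_ids)
    return segments, purity, cn


def _simulate_expression(
    config: SimulationConfig, truth: dict, cn_true: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    expr = pd.DataFrame(
        rng.normal(0.0, 1.0, cn_true.shape), index=cn_true.index, columns=cn_true.columns
    )
    for g in truth["planted_corr"]:
        noise = rng.normal(0.0, config.expr_noise_sd, cn_true.shape[1])
        expr.loc[g] = config.expr_slope * cn_true.loc[g].to_numpy() + noise
    return expr


def _linear_predictor(config: SimulationConfig, truth: dict, clinical: pd.DataFrame,
                      cn_true: pd.DataFrame) -> np.ndarray:
    stage_rank = clinical["stage"].map({s: i for i, s in enumerate(STAGES)}).astype(int).to_numpy()
    inc = np.concatenate([[0.0], np.cumsum(config.stage_increments)])
    eta = (
        config.age_loghr * (clinical["age"].to_numpy(dtype=float) - 65.0)
        + config.sex_loghr * (clinical["sex"] == "male").to_numpy(dtype=float)
        + inc[stage_rank]
    )
    for g, gamma in truth["gamma"].items():
        eta = eta + gamma * cn_true.loc[g, clinical.index].to_numpy(dtype=float)
    return eta


def _calibrate_censoring(event_times: np.ndarray, target: float) -> float:
    """Upper bound c of Uniform(0, c) censoring such that the expected
    censored fraction mean_i min(T_i / c, 1) hits the target."""
    if target <= 0:
        return float("inf")
    lo, hi = 1e-6, 100.0 * event_times.max()
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        rate = float(np.minimum(event_times / mid, 1.0).mean())
        if rate > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _simulate_clinical(
    config: SimulationConfig, truth: dict, cn_true: pd.DataFrame,
    sample_ids: list[str], labeled: np.ndarray, rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(sample_ids)
    clinical = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    clinical["age"] = rng.normal(65.0, 8.0, n)
    clinical["sex"] = np.where(rng.uniform(size=n) < 0.6, "male", "female")
    clinical["stage"] = rng.choice(list(STAGES), size=n, p=[0.35, 0.35, 0.15, 0.15])
    eta = _linear_predictor(config, truth, clinical, cn_true)
    u = rng.uniform(size=n)
    t_event = config.weibull_scale * (-np.log(u) / np.exp(eta)) ** (1.0 / config.weibull_shape)
    c_max = _calibrate_censoring(t_event[labeled], config.censoring_rate)
    t_cens = rng.uniform(0.0, c_max, n) if np.isfinite(c_max) else np.full(n, np.inf)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(float)
    clinical["os_time"] = np.where(labeled, os_time, np.nan)
    clinical["os_event"] = np.where(labeled, os_event, np.nan)
    clinical["true_eta"] = eta
    return validate_clinical(clinical)


def _simulate_evidence(
    config: SimulationConfig, truth: dict, rng: np.random.Generator,
    *, n_curated_noise: int = 60, n_study_noise: int = 150, n_studies: int = 3,
) -> PrognosticEvidence:
    """External-evidence surrogate: the curated list holds every planted
    prognostic gene plus unrelated noise genes; the study table gives the
    planted genes strong signed z-scores and noise genes null z-scores."""
    others = [g for g in truth["gene_ids"] if g not in truth["planted_prog"]]
    curated = set(truth["planted_prog"]) | set(
        rng.choice(others, size=min(n_curated_noise, len(others)), replace=False)
    )
    rows = []
    for g in truth["planted_prog"]:
        direction = np.sign(truth["gamma"][g]) or 1.0
        for k in range(n_studies):
            rows.append((g, f"study{k + 1}", direction * abs(rng.normal(3.5, 0.7))))
    for g in rng.choice(others, size=min(n_study_noise, len(others)), replace=False):
        for k in range(n_studies):
            rows.append((g, f"study{k + 1}", rng.normal(0.0, 1.0)))
    stats = pd.DataFrame(rows, columns=["gene_id", "study_id", "z_score"])
    return PrognosticEvidence(curated_genes=frozenset(curated), study_stats=stats)


def simulate_cohort(config: SimulationConfig = SimulationConfig()) -> SyntheticCohort:
    """Generate a full cohort (labeled + unlabeled) from the config seed."""
    rng = np.random.default_rng(config.seed)
    truth = _plant_truth(config, rng)
    n = config.n_labeled + config.n_unlabeled
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    labeled = np.arange(n) < config.n_labeled
    segments, purity, cn_true = _simulate_cn(config, truth, sample_ids, rng)
    expr = _simulate_expression(config, truth, cn_true, rng)
    clinical = _simulate_clinical(config, truth, cn_true, sample_ids, labeled, rng)
    evidence = _simulate_evidence(config, truth, rng)
    return SyntheticCohort(
        segments=segments, purity=purity, cn_true=cn_true, expression=expr,
        clinical=clinical, genes=make_gene_annotation(config),
        evidence=evidence, truth=truth,
    )


def simulate_validation(
    config: SimulationConfig, cohort: SyntheticCohort, n: int, seed: int
) -> SyntheticCohort:
    """An independent labeled cohort drawn from the same planted truth —
    the synthetic analogue of an external validation series."""
    rng = np.random.default_rng(seed)
    sample_ids = [f"V{i + 1:04d}" for i in range(n)]
    labeled = np.ones(n, dtype=bool)
    segments, purity, cn_true = _simulate_cn(config, cohort.truth, sample_ids, rng)
    expr = _simulate_expression(config, cohort.truth, cn_true, rng)
    clinical = _simulate_clinical(config, cohort.truth, cn_true, sample_ids, labeled, rng)
    return SyntheticCohort(
        segments=segments, purity=purity, cn_true=cn_true, expression=expr,
        clinical=clinical, genes=cohort.genes, evidence=cohort.evidence,
        truth=cohort.truth,
    )


def known_answer_fixtures() -> dict:
    """Small hand-checkable fixtures with their expected outputs.

    - ``weighted_median``: two internal segments, overlaps 600/400 bp -> the
      heavier value; the 500/500 tie resolves to the lower value.
    - ``netrank_path``: 3-node path A-B-C, unit weights, s = (.5, .3, .2),
      d = 0.5; expected scores from the dense solve of (I - d M^T) r = (1-d) s.
    - ``akaike_pair``: AICs (100, 102) -> weights (0.7311, 0.2689).
    - ``dichotomize``: scores 1..4 split 2/2 at their median; 1..5 split 3/2.
    """
    M = np.array([[0.0, 1.0, 0.0], [0.5, 0.0, 0.5], [0.0, 1.0, 0.0]])
    s = np.array([0.5, 0.3, 0.2])
    d = 0.5
    r = np.linalg.solve(np.eye(3) - d * M.T, (1 - d) * s)
    return {
        "weighted_median": {
            "values": [0.1, 0.9], "weights": [600, 400], "expected": 0.1,
            "tie_values": [0.1, 0.9], "tie_weights": [500, 500], "tie_expected": 0.1,
        },
        "netrank_path": {
            "genes": ["A", "B", "C"], "M": M, "s": s, "damping": d, "expected": r,
        },
        "akaike_pair": {"aics": [100.0, 102.0], "expected": [0.7311, 0.2689]},
        "dichotomize": {
            "even": {"scores": [1, 2, 3, 4], "expected": ["low", "low", "high", "high"]},
            "odd": {"scores": [1, 2, 3, 4, 5],
                    "expected": ["low", "low", "low", "high", "high"]},
        },
        "purity_point": {"seg_mean": 0.5, "purity": 0.5,
                         "expected": float(np.log2(((2 ** 1.5 - 1.0) / 0.5) / 2.0))},
    }
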