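import numpy as np
import pandas as pd
import pytest

from cnaprog import SimulationConfig, genes_from_segments, known_answer_fixtures, simulate_cohort

SMALL = SimulationConfig(
    n_genes=200, n_labeled=120, n_unlabeled=120,
    n_planted_corr=30, n_planted_prog=5, n_chromosomes=5, seed=42,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort shared across unit tests."""
    return simulate_cohort(SMALL)


@pytest.fixture(scope="session")
def small_cn(small_cohort):
    """Purity-corrected gene-level CN matrix of the small cohort."""
    return genes_from_segments(small_cohort.segments, small_cohort.genes, small_cohort.purity)


@pytest.fixture(scope="session")
def fixtures():
    return known_answer_fixtures()


def make_cox_data(rng, n=150, beta=(0.5, 0.3), censor=0.2):
    """Small Cox cohort with known coefficients for fit tests."""
    beta = np.asarray(beta, dtype=float)
    X = pd.DataFrame(
        rng.normal(size=(n, len(beta))), columns=[f"x{i}" for i in range(len(beta))]
    )
    eta = X.to_numpy() @ beta
    t = -np.log(rng.uniform(size=n)) / np.exp(eta)
    c = rng.uniform(0, np.quantile(t, 1 - censor) * 2, size=n) if censor > 0 else np.full(n, np.inf)
    time = np.minimum(t, c)
    event = (t <= c).astype(float)
    return X, time, event
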