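import numpy as np
import pytest

from netgain import ExpressionDataset, SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def noise_dataset(rng):
    """Pure-noise expression with balanced random labels: a global null."""
    n, m = 30, 40
    return ExpressionDataset(
        matrix=rng.standard_normal((n, m)),
        gene_ids=[f"g{i}" for i in range(n)],
        sample_ids=[f"s{j}" for j in range(m)],
        phenotype=np.array([1] * (m // 2) + [0] * (m // 2)),
    )


@pytest.fixture(scope="session")
def interaction_sim():
    """One scale-free differential co-expression replicate at desk scale."""
    return simulate_dataset(SimulationConfig(n_genes=60, n_samples=40, n_targets=6, seed=7))


def make_dataset(matrix, phenotype, covariates=None):
    matrix = np.asarray(matrix, dtype=float)
    n, m = matrix.shape
    return ExpressionDataset(
        matrix=matrix,
        gene_ids=[f"g{i}" for i in range(n)],
        sample_ids=[f"s{j}" for j in range(m)],
        phenotype=np.asarray(phenotype),
        covariates=covariates,
    )
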