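import numpy as np
import pytest

from corrbic.matrix import ExpressionMatrix
from corrbic.synthetic import GeneratorConfig, generate_single


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """20 genes x 30 samples of plain Gaussian noise."""
    values = rng.normal(size=(20, 30))
    return ExpressionMatrix(values, [f"g{i}" for i in range(20)], [f"s{j}" for j in range(30)])


@pytest.fixture
def planted_matrix(rng):
    """60 genes x 40 samples with an exact rank-1 bicluster: genes 0..29 follow
    +/- the profile on samples 0..19, everything else is unit noise."""
    values = rng.normal(size=(60, 40))
    profile = rng.normal(size=20) * 2 + 3
    signs = np.where(rng.random(30) < 0.5, -1.0, 1.0)
    weights = np.abs(rng.normal(3, 1, size=30)) * signs
    values[:30, :20] = np.outer(weights, profile)
    gene_ids = [f"g{i}" for i in range(60)]
    sample_ids = [f"s{j}" for j in range(40)]
    return ExpressionMatrix(values, gene_ids, sample_ids), profile, weights


@pytest.fixture
def noiseless_dataset():
    """Single implanted bicluster with an exact pattern (noise only in the
    background): infinite signal-to-noise."""
    cfg = GeneratorConfig(
        n_genes=120,
        n_samples=90,
        bicluster_genes=40,
        bicluster_samples=30,
        noise_sd=0.0,
        background_sd=1.0,
        count_jitter=False,
    )
    return generate_single(cfg, np.random.default_rng(7))
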