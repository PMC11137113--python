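import numpy as np
import pytest

from coslir import StageSample, estimate_moments, generate_truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_sample(rng):
    """5 genes x 40 cells from a fixed multivariate normal."""
    mean = rng.normal(0, 3, 5)
    M = rng.standard_normal((5, 5))
    cov = M @ M.T + np.eye(5)
    values = rng.multivariate_normal(mean, cov, size=40).T
    return StageSample(values=values,
                       gene_names=[f"g{i}" for i in range(5)],
                       stage_label="t")


@pytest.fixture
def oracle_instance():
    """Zero-noise p=10 truth with exact propagated moments."""
    truth = generate_truth(p=10, sparsity=0.1, seed=0,
                           noise_mean=0.0, noise_var=0.0)
    m_t, m_t1 = truth.moment_summaries()
    return truth, m_t, m_t1


@pytest.fixture
def sample_moments(small_sample):
    return estimate_moments(small_sample)
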