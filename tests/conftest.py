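import numpy as np
import pandas as pd
import pytest

from stromasig import CohortConfig, ExpressionMatrix, simulate_cohort


@pytest.fixture
def toy_matrix():
    """3 genes x 4 samples, two per class."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [5.0, 5.0, 5.0, 5.0],
         [8.0, 7.0, 2.0, 1.0]],
        index=["gA", "gB", "gC"], columns=["s1", "s2", "s3", "s4"])
    return ExpressionMatrix(values, ["cancer", "cancer", "normal", "normal"])


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale config used by pipeline-level tests (fast)."""
    return CohortConfig(
        n_genes=400, n_epithelial_up=20, n_epithelial_down=20,
        n_stromal=30, n_cn_gain=10, n_cn_loss=10, amplicon_genes=5,
        seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_928)
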