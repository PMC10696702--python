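import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from metabrisk import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Scaled-down study conditions for fast structural tests."""
    return SimulationConfig(n_features=300, n_identified=80, n_network=23,
                            n_biomarkers=5, n_snps=60, n_risk_snps=10,
                            n_gwas_pool=400, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


def exact_covariance_sample(S: np.ndarray, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Draw an n x p matrix whose *sample* covariance equals S exactly:
    whiten an i.i.d. draw empirically, then recolor with chol(S)."""
    p = S.shape[0]
    Z = rng.standard_normal((n, p))
    Z = Z - Z.mean(axis=0)
    Cz = np.cov(Z, rowvar=False, ddof=1)
    Z = Z @ np.linalg.inv(np.linalg.cholesky(Cz)).T
    return Z @ np.linalg.cholesky(S).T
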