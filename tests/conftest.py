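import numpy as np
import pytest

from deepkern import MarkerMatrix, SimConfig, impute_and_scale, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_markers(rng):
    """Standardized 20-line x 60-marker matrix from the synthetic generator."""
    cfg = SimConfig(n_lines=20, n_markers=60, seed=7)
    return impute_and_scale(simulate_genotypes(cfg), scaling="standardized")


def raw_marker_matrix(X, ids=None):
    """Wrap a plain array as a MarkerMatrix without centering/scaling."""
    X = np.asarray(X, dtype=float)
    ids = ids or [f"L{i}" for i in range(X.shape[0])]
    return MarkerMatrix(X=X, line_ids=ids, scaling="raw")
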