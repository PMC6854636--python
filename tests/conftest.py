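import numpy as np
import pytest

from rfnet.cohort import build_ground_truth, sample_score_panel
from rfnet.network import EstimatorConfig, NetworkModel


@pytest.fixture(scope="session")
def fast_config():
    """Estimator settings with a reduced penalty grid for test speed."""
    return EstimatorConfig(n_lambda=40)


@pytest.fixture(scope="session")
def adversity_truth():
    return build_ground_truth("adversity")


@pytest.fixture(scope="session")
def null_truth():
    return build_ground_truth("null")


@pytest.fixture(scope="session")
def small_panel(adversity_truth):
    return sample_score_panel(adversity_truth, {"CA+": 150, "CA-": 150}, seed=11)


def make_network(weights, labels=None):
    """Hand-built NetworkModel for statistic-level tests."""
    W = np.asarray(weights, dtype=float)
    labels = labels or [f"v{i}" for i in range(W.shape[0])]
    return NetworkModel(
        node_labels=list(labels), weights=W, lambda_selected=0.0, gamma=0.5, n=100
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
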