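import numpy as np
import pytest

from tdgf.synthetic_data import SimulationConfig, generate_bundle
from tdgf.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition synthetic bundle shared across the suite."""
    return generate_bundle(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_pipeline_result(default_bundle):
    """Full pipeline run on the default bundle (alignment-heavy; run once)."""
    return run_pipeline(default_bundle, si_threshold=80.0, replicates=2000, perm_seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
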