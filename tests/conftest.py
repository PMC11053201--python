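import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def skeleton_graph():
    from fusefall import build_skeleton_graph

    return build_skeleton_graph("spatial")


@pytest.fixture(scope="session")
def micro_dataset():
    """Tiny paired corpus shared by the slower integration tests."""
    from fusefall import SimConfig, gen_dataset

    return gen_dataset(SimConfig(n_per_class=6, seed=7))
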