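import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def grid4():
    """4x4 all-configurable instance with easily hand-summed layers."""
    from beezone import SuitabilityGrid

    eco = np.array([
        [0.10, 0.20, 0.30, 0.40],
        [0.50, 0.60, 0.70, 0.80],
        [0.90, 1.00, 0.00, 0.15],
        [0.25, 0.35, 0.45, 0.55],
    ])
    dev = np.array([
        [0.90, 0.80, 0.70, 0.60],
        [0.50, 0.40, 0.30, 0.20],
        [0.10, 0.00, 1.00, 0.85],
        [0.75, 0.65, 0.55, 0.45],
    ])
    return SuitabilityGrid(eco=eco, dev=dev)
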