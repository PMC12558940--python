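import pytest

from sclc_cea import default_inputs
from sclc_cea.survival import SurvivalDistribution


@pytest.fixture(scope="session")
def inputs():
    return default_inputs()


@pytest.fixture(scope="session")
def base_curves(inputs):
    """(os, pfs) base-case distributions per arm name."""
    values = inputs.base_values()
    return {
        arm.name: (arm.os_dist(values), arm.pfs_dist(values)) for arm in inputs.arms
    }


@pytest.fixture
def loglogistic_os():
    return SurvivalDistribution("loglogistic", {"scale": 16.50756, "shape": 1.70402})
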