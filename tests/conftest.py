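import numpy as np
import pytest

from cytotype.simulate import DEFAULT_CYTOTYPES


@pytest.fixture(scope="session")
def group_means():
    return np.array([c.gs_mean for c in DEFAULT_CYTOTYPES])


@pytest.fixture(scope="session")
def group_sds():
    return np.array([c.gs_sd for c in DEFAULT_CYTOTYPES])


@pytest.fixture(scope="session")
def eight_group_sample(group_means, group_sds):
    """1200 genome sizes drawn from the eight published components, equal weights."""
    rng = np.random.default_rng(42)
    comp = rng.integers(0, 8, 1200)
    return rng.normal(group_means[comp], group_sds[comp]), comp
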