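import numpy as np
import pytest

from gravident import OgdenParams, make_recovery_bundle


@pytest.fixture(scope="session")
def true_params():
    return OgdenParams(mu=1250.0, alpha=-20.0, K=254000.0)


@pytest.fixture(scope="session")
def cube_bundle(true_params):
    """Noise-free cube recovery bundle at the default fixture settings."""
    bundle, p_true, fwd = make_recovery_bundle("cube", true_params)
    return bundle, p_true, fwd


@pytest.fixture(scope="session")
def small_cube_bundle(true_params):
    """Cheap n=3 variant for tests that rebuild bundles repeatedly."""
    bundle, p_true, fwd = make_recovery_bundle("cube", true_params, n=3)
    return bundle, p_true, fwd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
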