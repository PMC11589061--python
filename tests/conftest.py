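import numpy as np
import pytest

import kernelfuse as kf


@pytest.fixture(scope="session")
def default_spec():
    return kf.PhantomSpec()


@pytest.fixture(scope="session")
def phantom(default_spec):
    """Noise-free default head phantom (512 grid), shared across tests."""
    return kf.make_phantom(default_spec, seed=1)


@pytest.fixture(scope="session")
def roi_plan(default_spec):
    return kf.default_roi_plan(default_spec)


@pytest.fixture(scope="session")
def small_dataset(default_spec):
    """Three-slice dataset for fast structural tests."""
    examples, manifest = kf.make_dataset(default_spec, n_slices=3, seed=11)
    return examples, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(0)
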