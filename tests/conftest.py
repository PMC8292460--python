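import numpy as np
import pytest

import spheropick as sp


@pytest.fixture(scope="session")
def clean_set():
    """Small clean-profile benchmark set with scene specs."""
    return sp.make_benchmark_set(10, "clean", seed=11, return_specs=True)


@pytest.fixture(scope="session")
def artifact_set():
    return sp.make_benchmark_set(10, "artifact", seed=12)


@pytest.fixture()
def disk_mask():
    """Digital disk of radius 50 px centred in a 200x200 frame."""
    spec = sp.ObjectSpec(center_px=(100.0, 100.0), radius_px=50.0)
    return sp.render_object_mask(spec, (200, 200))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
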