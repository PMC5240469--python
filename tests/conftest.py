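import numpy as np
import pytest

from armik import build_reference_model


@pytest.fixture(scope="session")
def reference_model():
    """Synthetic reference model with the published-scale shoulder obliquity."""
    return build_reference_model(obliquity_deg=0.0029, seed=10)


@pytest.fixture(scope="session")
def exact_model():
    """Model with exactly orthonormal shoulder axes (obliquity zero)."""
    return build_reference_model(obliquity_deg=0.0, seed=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_in_range_angles(model, rng, n):
    """Uniform joint-angle draws within the model's limits, (n, 7) degrees."""
    lims = model.limits_array()
    return rng.uniform(lims[:, 0], lims[:, 1], size=(n, 7))
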