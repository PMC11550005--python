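import numpy as np
import pytest

from sbpconf import synthetic


@pytest.fixture(scope="session")
def two_lobe_pair():
    """Closed (0°) and 23°-open two-lobe toys from the same seed."""
    closed, truth_closed = synthetic.make_two_lobe(
        synthetic.TwoLobeSpec(hinge_angle=0.0, seed=1))
    opened, truth_open = synthetic.make_two_lobe(
        synthetic.TwoLobeSpec(hinge_angle=23.0, seed=1))
    return closed, truth_closed, opened, truth_open


@pytest.fixture(scope="session")
def sphere_model_2000():
    return synthetic.make_sphere_cloud(2000, 30.0, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240930)
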