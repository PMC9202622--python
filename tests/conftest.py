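import numpy as np
import pytest

from angioseg import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_vessel_sample():
    """A clean single-vessel phantom shared by preprocessing tests."""
    cfg = phantom.PhantomConfig(
        size=128,
        n_branches=(1, 1),
        child_probability=0.0,
        stenosis_probability=0.0,
        noise_sigma=0.0,
        background_amplitude=10.0,
        rib_amplitude=4.0,
    )
    return phantom.generate_tree(cfg, seed=3)


@pytest.fixture(scope="session")
def noisy_samples():
    """Ten small noisy phantoms shared across property tests."""
    cfg = phantom.PhantomConfig(size=96, noise_sigma=10.0, n_branches=(1, 3))
    return [phantom.generate_tree(cfg, seed=100 + i) for i in range(10)]
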