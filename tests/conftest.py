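import numpy as np
import pytest

from activedisc import SyntheticSpec, generate_fundus_image


@pytest.fixture(scope="session")
def noiseless_spec():
    """Clean rendering: no sensor noise, no vessels."""
    return SyntheticSpec(noise_sigma=0.0, n_vessels=0, seed=5)


@pytest.fixture(scope="session")
def noiseless_case(noiseless_spec):
    return generate_fundus_image(noiseless_spec)


@pytest.fixture(scope="session")
def default_case_seed11():
    """Default rendering conditions (noise + vessels), seed 11."""
    return generate_fundus_image(SyntheticSpec(seed=11))


def smooth_field(rng, shape, sigma, mean=0.0, std=0.5):
    """Random smooth test image: Gaussian-blurred white noise."""
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(rng.normal(mean, std, shape), sigma)
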