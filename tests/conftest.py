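"""Shared fixtures: small, fast synthetic configurations.

Unit tests run on a coarse 48x36x28 grid at 3 mm spacing (the anatomy and
signal chain are identical to the default configuration, just cheaper);
end-to-end checks in test_acceptance.py use the full default grids.
"""

import numpy as np
import pytest

from nephna import synthkid as sk


SMALL_GRID = dict(grid_shape=(48, 36, 28), spacing=(3.0, 3.0, 3.0))


@pytest.fixture(scope="session")
def small_cfg():
    """Small human-style config with default noise/B1/saturation."""
    return sk.human_config(**SMALL_GRID)


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Small config with every corruption turned off: signal == truth."""
    return sk.human_config(noise_sigma=0.0, b1_amplitude=0.0,
                           calib_slope_true=1.0, apply_saturation=False,
                           **SMALL_GRID)


@pytest.fixture(scope="session")
def clean_cfg():
    """Small noiseless config but with B1 inhomogeneity and saturation on."""
    return sk.human_config(noise_sigma=0.0, **SMALL_GRID)


@pytest.fixture(scope="session")
def noiseless_subject(noiseless_cfg):
    return sk.generate_subject(noiseless_cfg, seed=7)


@pytest.fixture(scope="session")
def clean_subject(clean_cfg):
    return sk.generate_subject(clean_cfg, seed=7)


@pytest.fixture(scope="session")
def noisy_subject(small_cfg):
    return sk.generate_subject(small_cfg, seed=7)


def sphere_mask(shape, center, radius, spacing=(1.0, 1.0, 1.0)):
    idx = np.indices(shape).astype(float)
    r2 = sum((((idx[i] + 0.5) * spacing[i] - center[i]) / radius) ** 2
             for i in range(3))
    return r2 <= 1.0
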