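import dataclasses

import numpy as np
import pytest

from gliavasc.synthetic import FovConfig, generate_fov


@pytest.fixture(scope="session")
def clean_config():
    """Default 3D acquisition geometry, noise switched off."""
    return FovConfig(seed=11, noise_sigma=0.0, poisson=False)


@pytest.fixture(scope="session")
def clean_fov(clean_config):
    return generate_fov(clean_config, fov_index=0)


@pytest.fixture(scope="session")
def noisy_fov(clean_config):
    cfg = dataclasses.replace(clean_config, noise_sigma=5.0, poisson=True)
    return generate_fov(cfg, fov_index=0)


@pytest.fixture(scope="session")
def flat_config_2d():
    """2D human-style FOV with widely separated, branch-sparse cells."""
    return FovConfig(
        shape=(192, 192),
        voxel_size=(1.25, 1.25),
        n_vessels=0,
        n_cells=3,
        branches_per_cell=(3, 4),
        branch_length_range=(15.0, 25.0),
        vam_fraction=0.0,
        leakage_fraction=0.0,
        noise_sigma=0.0,
        poisson=False,
        seed=7,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
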