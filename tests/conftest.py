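"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from vepfield.epileptor import SimulationConfig
from vepfield.geometry import build_regular_grid
from vepfield.synthetic import (
    build_scenario,
    generate_brain,
    generate_connectome,
    generate_sensors,
)


@pytest.fixture(scope="session")
def small_brain():
    """12 regions per hemisphere (3 cortical + 9 subcortical), level-2 mesh."""
    return generate_brain(n_regions_per_hemi=12, mesh_level=2, seed=7)


@pytest.fixture(scope="session")
def small_connectome(small_brain):
    return generate_connectome(small_brain, seed=8)


@pytest.fixture(scope="session")
def small_sensors(small_brain):
    return generate_sensors(
        small_brain, n_electrodes=3, contacts_per_electrode=4, near_regions=[0, 1, 13], seed=9
    )


@pytest.fixture(scope="session")
def small_scenario(small_brain, small_connectome, small_sensors):
    """A fast end-to-end scenario: coarse mesh, degree-8 grid, short run."""
    return build_scenario(
        small_brain,
        small_connectome,
        small_sensors,
        ez_regions=[0, 12],  # one cortical + one subcortical
        grid_degree=8,
        tau=20.0,
        sim_config=SimulationConfig(dt=0.05, n_steps=400, subsample_s=0.1),
        n_augment=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def grid16():
    return build_regular_grid(16)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
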