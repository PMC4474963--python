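"""Shared fixtures: meshes and solvers are expensive, so build them once."""

import numpy as np
import pytest

from pseudopod_ad.config import SimConfig, reduced_profile
from pseudopod_ad.geometry import CellShapeParams, build_cell_mesh


@pytest.fixture(scope="session")
def sphere_mesh_96():
    return build_cell_mesh(CellShapeParams(
        dimensionless_pseudopod_length=0.0, mesh_resolution=96))


@pytest.fixture(scope="session")
def sphere_mesh_24():
    return build_cell_mesh(CellShapeParams(
        dimensionless_pseudopod_length=0.0, mesh_resolution=24))


@pytest.fixture(scope="session")
def pseudopod_mesh_96():
    return build_cell_mesh(CellShapeParams(mesh_resolution=96))


@pytest.fixture(scope="session")
def pseudopod_mesh_default():
    """Full-resolution (384-element) pseudopod mesh."""
    return build_cell_mesh(CellShapeParams())


@pytest.fixture
def fast_config():
    """A cheap engine configuration for short dynamic tests."""
    cfg = reduced_profile()
    return cfg.replace(
        geometry=CellShapeParams(mesh_resolution=24),
        total_receptors=5_000,
        max_steps=200,
    )
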