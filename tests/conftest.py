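"""Shared fixtures: coarse meshes and short simulations.

Heavy objects are session-scoped; simulation fixtures use coarse meshes
and enlarged time steps where the property under test does not depend on
fine resolution.
"""

import numpy as np
import pytest

import shrimpdry as sd
from shrimpdry.geometry import (
    build_cylinder_geometry,
    build_shrimp_geometry,
    generate_mesh,
)


@pytest.fixture(scope="session")
def cylinder_solid():
    return build_cylinder_geometry()


@pytest.fixture(scope="session")
def shrimp_solid():
    return build_shrimp_geometry()


@pytest.fixture(scope="session")
def cyl_mesh_3mm(cylinder_solid):
    return generate_mesh(cylinder_solid, 3e-3)


@pytest.fixture(scope="session")
def cyl_mesh_4mm(cylinder_solid):
    return generate_mesh(cylinder_solid, 4e-3)


@pytest.fixture(scope="session")
def shrimp_mesh_3mm(shrimp_solid):
    return generate_mesh(shrimp_solid, 3e-3)


@pytest.fixture(scope="session")
def baseline60_coarse(cyl_mesh_3mm):
    """Full-length 60 °C baseline on a coarse equal-volume cylinder."""
    cfg = sd.baseline_config(60)
    return sd.simulate(cyl_mesh_3mm, cfg)


@pytest.fixture(scope="session")
def quick_cfg_60():
    """Short, large-step 60 °C configuration for plumbing tests."""
    return sd.baseline_config(60, duration=1800.0, max_time_step=60.0,
                              output_interval=120.0)
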