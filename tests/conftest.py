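"""Shared fixtures.

Expensive artifacts are session-scoped; the small suite (4 models at
reduced angular resolution) is used by unit/property tests, while the
acceptance tests build the full 28-model suite themselves.
"""

import numpy as np
import pytest
import trimesh

from spiculo.geometry import as_mesh
from spiculo.masks import voxelize
from spiculo.phantoms import generate_suite

SMALL_SPACING = (1.0, 1.0, 2.0)


@pytest.fixture(scope="session")
def small_suite():
    """Four models spanning the spiculatedness range, coarse resolution."""
    return generate_suite(11, 92, 27, n_theta=64, n_phi=128)


@pytest.fixture(scope="session")
def small_masks(small_suite):
    return [voxelize(mesh, SMALL_SPACING) for _, mesh in small_suite]


@pytest.fixture(scope="session")
def icosphere():
    ico = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return as_mesh(ico.vertices, ico.faces)


@pytest.fixture()
def unit_cube():
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    box.apply_translation((0.5, 0.5, 0.5))
    return as_mesh(box.vertices, box.faces)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
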