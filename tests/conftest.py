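"""Shared fixtures: small meshes and materials reused across the suite."""

import numpy as np
import pytest

from tissuecal import Material, ProbeSpec
from tissuecal.synthetic import PhantomSpec, make_box_mesh, make_limb_phantom


@pytest.fixture(scope="session")
def soft_material() -> Material:
    return Material.coupled(0.01, k_ratio=1000.0)


@pytest.fixture(scope="session")
def unit_box_coarse():
    """1 mm cube, one hex split into six quadratic tets."""
    return make_box_mesh((1.0, 1.0, 1.0), (1, 1, 1), order=2)


@pytest.fixture(scope="session")
def unit_box():
    """1 mm cube, 2x2x2 hex grid of quadratic tets."""
    return make_box_mesh((1.0, 1.0, 1.0), (2, 2, 2), order=2)


@pytest.fixture(scope="session")
def phantom_spec() -> PhantomSpec:
    """Upper-leg-scale phantom: 21 mm of flesh around a 12 mm bone."""
    return PhantomSpec(outer_radius=33.0, bone_radius=12.0, length=40.0)


@pytest.fixture(scope="session")
def tiny_phantom(phantom_spec):
    """Coarse quadratic phantom small enough for repeated solves."""
    return make_limb_phantom(phantom_spec, order=2, divisions=(2, 14, 3))


@pytest.fixture(scope="session")
def phantom_probe() -> ProbeSpec:
    """Flat 50 x 10 mm probe face touching the phantom at theta = 0."""
    return ProbeSpec(
        face_center=(33.0, 0.0, 20.0),
        face_normal=(-1.0, 0.0, 0.0),
        face_half_lengths=(25.0, 5.0),
        total_displacement=3.0,
        n_increments=6,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
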