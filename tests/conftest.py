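"""Shared fixtures: small meshes, toy lesions, seeded generators."""

from __future__ import annotations

import numpy as np
import pytest

from ecogdist import CorticalSurface, LesionVolume, make_surface


@pytest.fixture(scope="session")
def plane():
    """Flat 200 x 200 mm triangulated sheet at z = 0."""
    return make_surface("plane", extent=200.0, spacing=5.0)


@pytest.fixture(scope="session")
def sphere50():
    """Icosphere of radius 50 mm with ~10k vertices (analytic geodesics)."""
    return make_surface("sphere", min_vertices=5000, radius=50.0)


@pytest.fixture(scope="session")
def sphere80():
    return make_surface("sphere", min_vertices=2500, radius=80.0)


@pytest.fixture(scope="session")
def origin_lesion():
    """Single foreground voxel whose centre is the world origin."""
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[2, 2, 2] = True
    affine = np.eye(4)
    affine[:3, 3] = -2.0
    return LesionVolume(mask=mask, affine=affine)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def ball_lesion(radius_vox: int = 4, voxel: float = 1.0, origin=(-10.0, -10.0, -10.0)):
    """Convex (ball) lesion helper used by several invariance tests."""
    n = 2 * radius_vox + 3
    idx = np.indices((n, n, n)).transpose(1, 2, 3, 0)
    c = (n - 1) / 2
    mask = ((idx - c) ** 2).sum(axis=-1) <= radius_vox**2
    affine = np.eye(4)
    affine[:3, :3] *= voxel
    affine[:3, 3] = origin
    return LesionVolume(mask=mask, affine=affine)
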