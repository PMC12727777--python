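"""Shared fixtures: mesh builders and module-scoped phantoms (generated, not stored)."""

from __future__ import annotations

import numpy as np
import pytest

from microdomain3d.meshing import SurfaceMesh
from microdomain3d.synthetic import PhantomSpec, generate_paper_scale_scene, generate_phantom


def grid_plane(half_extent: float, pitch: float, z: float = 0.0, role: str = "") -> SurfaceMesh:
    """A square triangulated plane grid in the z=const plane, centred on the origin."""
    g = np.arange(-half_extent, half_extent + pitch / 2, pitch, dtype=float)
    X, Y = np.meshgrid(g, g)
    verts = np.stack([X.ravel(), Y.ravel(), np.full(X.size, float(z))], axis=1)
    n = len(g)
    idx = np.arange(n * n).reshape(n, n)
    f1 = np.stack([idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(), idx[1:, 1:].ravel()], axis=1)
    f2 = np.stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()], axis=1)
    return SurfaceMesh(verts, np.vstack([f1, f2]), role)


def random_point_mesh(rng: np.random.Generator, n: int, scale: float = 100.0,
                      offset=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """A faceless vertex cloud (ASD is defined on vertex sets)."""
    return SurfaceMesh(rng.normal(size=(n, 3)) * scale + np.asarray(offset),
                       np.empty((0, 3), dtype=np.int64))


@pytest.fixture(scope="session")
def icc_phantom():
    """Small ICC phantom at the default anisotropic spacing (shared, read-only)."""
    return generate_phantom(PhantomSpec(archetype="ICC", rng_seed=1))


@pytest.fixture(scope="session")
def paper_scene():
    """The nine-caveola study-regime scene (shared, read-only)."""
    return generate_paper_scale_scene(11)
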