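"""Spherical microdomains around caveolae: definition and cropping.

A microdomain is the sphere of radius 400 nm (default) centred on a caveola.
Meshes are cropped by clipping triangles exactly at the sphere (cut points
solve the edge-sphere quadratic, so they lie on the boundary); label volumes
are cropped by the voxel-centre-inside test, which is unbiased at radii far
larger than a voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ._clip import clip_triangles, compact_mesh
from .io_volumes import MITO, LabelVolume
from .meshing import SurfaceMesh

DEFAULT_RADIUS_NM = 400.0


@dataclass(frozen=True)
class SphereROI:
    """One microdomain: centre in nm (a caveola), radius in nm."""

    centre: tuple[float, float, float]
    radius: float = DEFAULT_RADIUS_NM
    sphere_id: str = ""
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"sphere radius must be positive, got {self.radius}")

    @property
    def volume_nm3(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3

    def contains(self, points_xyz: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_xyz, dtype=float))
        return np.linalg.norm(pts - np.asarray(self.centre), axis=1) <= self.radius


@dataclass
class CroppedScene:
    """Everything inside one microdomain: cropped meshes and per-role voxel tallies."""

    roi: SphereROI
    meshes: dict[str, SurfaceMesh]          # key: role, or "MITO:<label>" per instance
    labels_in_roi: dict[str, int]           # role -> voxel count inside the sphere
    volumes_in_roi: dict[str, float]        # role -> voxel volume in nm^3


def crop_mesh(mesh: SurfaceMesh, roi: SphereROI) -> SurfaceMesh:
    """Clip a mesh to a sphere.

    Triangles fully inside are kept, fully outside dropped; crossing
    triangles are cut with new vertices exactly on the sphere. Partial
    triangles are retained as clipped polygons (triangulated), so cropped
    areas converge to the analytic values instead of being biased by
    whole-triangle inclusion/exclusion at the boundary.
    """
    if mesh.is_empty:
        return SurfaceMesh.empty(mesh.structure_role)
    centre = np.asarray(roi.centre, dtype=float)
    v = mesh.vertices
    inside = np.linalg.norm(v - centre, axis=1) <= roi.radius

    def isect(i_in: int, i_out: int) -> np.ndarray:
        a, b = v[i_in] - centre, v[i_out] - centre
        d = b - a
        # |a + t d|^2 = r^2, increasing through the boundary at the root in (0, 1]
        A = float(d @ d)
        B = 2.0 * float(a @ d)
        C = float(a @ a) - roi.radius**2
        disc = max(B * B - 4.0 * A * C, 0.0)
        t = (-B + np.sqrt(disc)) / (2.0 * A)
        t = min(max(t, 0.0), 1.0)
        return v[i_in] + t * (v[i_out] - v[i_in])

    verts, faces, _ = clip_triangles(v, mesh.faces, inside, isect)
    verts, faces = compact_mesh(verts, faces)
    return SurfaceMesh(verts, faces, mesh.structure_role)


def _inside_sphere_mask(vol: LabelVolume, roi: SphereROI) -> tuple[np.ndarray, tuple[slice, slice, slice]]:
    """Boolean mask (over a bounding subvolume) of voxels whose centre lies in the sphere."""
    cx, cy, cz = roi.centre
    dx, dy, dz = vol.spacing.dx, vol.spacing.dy, vol.spacing.dz
    nz, ny, nx = vol.shape
    k0 = max(int(np.floor((cz - roi.radius) / dz - 0.5)), 0)
    k1 = min(int(np.ceil((cz + roi.radius) / dz - 0.5)) + 1, nz)
    j0 = max(int(np.floor((cy - roi.radius) / dy - 0.5)), 0)
    j1 = min(int(np.ceil((cy + roi.radius) / dy - 0.5)) + 1, ny)
    i0 = max(int(np.floor((cx - roi.radius) / dx - 0.5)), 0)
    i1 = min(int(np.ceil((cx + roi.radius) / dx - 0.5)) + 1, nx)
    kk = (np.arange(k0, k1) + 0.5) * dz - cz
    jj = (np.arange(j0, j1) + 0.5) * dy - cy
    ii = (np.arange(i0, i1) + 0.5) * dx - cx
    r2 = kk[:, None, None] ** 2 + jj[None, :, None] ** 2 + ii[None, None, :] ** 2
    return r2 <= roi.radius**2, (slice(k0, k1), slice(j0, j1), slice(i0, i1))


def crop_labels(vol: LabelVolume, roi: SphereROI) -> dict[str, float]:
    """Per-role voxel volume (nm^3) inside the sphere (voxel-centre-inside test)."""
    ext = vol.physical_extent_nm
    c = np.asarray(roi.centre)
    if (c < 0).any() or (c > np.asarray(ext)).any():
        raise ValueError(f"sphere centre {roi.centre} lies outside the volume extent {ext}")
    counts = crop_label_counts(vol, roi)
    vv = vol.spacing.voxel_volume_nm3
    return {role: n * vv for role, n in counts.items()}


def crop_label_counts(vol: LabelVolume, roi: SphereROI, per_instance: bool = False) -> dict:
    """Voxel counts inside the sphere, per role (default) or per instance label."""
    in_sphere, box = _inside_sphere_mask(vol, roi)
    sub = vol.data[box]
    labels, counts = np.unique(sub[in_sphere], return_counts=True)
    per_label = {int(l): int(n) for l, n in zip(labels, counts) if l != 0}
    if per_instance:
        return per_label
    out: dict[str, int] = {role: 0 for role in set(vol.label_map.values())}
    for lab, n in per_label.items():
        out[vol.label_map[lab]] += n
    return out


def crop_scene(vol: LabelVolume, meshes: Mapping[str, SurfaceMesh], roi: SphereROI) -> CroppedScene:
    """Crop a set of meshes and the label volume to one microdomain."""
    cropped = {key: crop_mesh(m, roi) for key, m in meshes.items()}
    counts = crop_label_counts(vol, roi)
    vv = vol.spacing.voxel_volume_nm3
    return CroppedScene(
        roi=roi,
        meshes=cropped,
        labels_in_roi=counts,
        volumes_in_roi={role: n * vv for role, n in counts.items()},
    )


def has_mitochondria(scene: CroppedScene) -> bool:
    """True iff any mitochondrial voxel centre lies inside the sphere."""
    return scene.labels_in_roi.get(MITO, 0) > 0
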