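"""Per-microdomain analysis: meshes, cropping, distances, MAM, in one pass.

``analyze_scene`` reproduces the study workflow on a labelled volume: build
the PM/ER meshes and one mesh per mitochondrion, place a sphere on each
caveola seed, crop everything to the sphere, and record per sphere the ASD
(PM -> ER), ER voxel volume, mitochondrion presence, total MAM area on the
mitochondrial side (absent, not zero, when the sphere holds no mitochondrion)
and the number of sub-threshold ER-PM proximity events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .contacts import (
    CAVEOLA_NEIGHBOURHOOD_NM,
    MAM_THRESHOLD_NM,
    PROXIMITY_THRESHOLD_NM,
    asd,
    mam_patches,
    proximity_events,
    total_contact_area,
)
from .io_volumes import ER, MITO, PM, LabelVolume, SeedPointSet
from .meshing import SurfaceMesh, mesh_from_instance, mesh_from_labels
from .microdomain import DEFAULT_RADIUS_NM, SphereROI, crop_mesh, crop_scene, has_mitochondria


@dataclass
class MicrodomainMetrics:
    """One row of the per-sphere results table."""

    sphere_id: str
    centre: tuple[float, float, float]
    radius_nm: float
    asd_nm: float
    n_pm_vertices: int
    er_volume_nm3: float
    has_mito: bool
    mam_area_total_nm2: Optional[float]      # None when the sphere has no mitochondrion
    mam_area_er_side_nm2: Optional[float]    # same contact measured on the ER surface
    n_proximity_events: int


def analyze_scene(
    vol: LabelVolume,
    seeds: SeedPointSet,
    radius_nm: float = DEFAULT_RADIUS_NM,
    mam_threshold_nm: float = MAM_THRESHOLD_NM,
    proximity_threshold_nm: float = PROXIMITY_THRESHOLD_NM,
    neighbourhood_nm: float = CAVEOLA_NEIGHBOURHOOD_NM,
) -> list[MicrodomainMetrics]:
    """Run the full per-sphere analysis for every seed point."""
    seeds.check_inside(vol)
    pm_mesh = mesh_from_labels(vol, PM)
    er_mesh = mesh_from_labels(vol, ER)
    mito_meshes = {
        lab: mesh_from_instance(vol, lab) for lab in vol.labels_for_role(MITO)
    }

    results = []
    for i, centre in enumerate(np.atleast_2d(seeds.points)):
        roi = SphereROI(tuple(float(v) for v in centre), radius_nm, sphere_id=f"sphere_{i:02d}")
        meshes = {PM: pm_mesh, ER: er_mesh}
        meshes.update({f"{MITO}:{lab}": m for lab, m in mito_meshes.items()})
        scene = crop_scene(vol, meshes, roi)
        pm_c, er_c = scene.meshes[PM], scene.meshes[ER]

        dist = asd(pm_c, er_c)
        events = proximity_events(
            pm_c, er_c, proximity_threshold_nm, caveola_seeds=seeds, neighbourhood_nm=neighbourhood_nm
        )
        mito_present = has_mitochondria(scene)
        mam_total = mam_er_side = None
        if mito_present:
            mam_total = 0.0
            mam_er_side = 0.0
            for lab in vol.labels_for_role(MITO):
                mito_c = scene.meshes[f"{MITO}:{lab}"]
                if mito_c.is_empty or er_c.is_empty:
                    continue
                mam_total += total_contact_area(mam_patches(mito_c, er_c, mam_threshold_nm))
                mam_er_side += total_contact_area(mam_patches(er_c, mito_c, mam_threshold_nm))
        results.append(
            MicrodomainMetrics(
                sphere_id=roi.sphere_id,
                centre=roi.centre,
                radius_nm=radius_nm,
                asd_nm=dist.asd,
                n_pm_vertices=dist.n_vertices,
                er_volume_nm3=scene.volumes_in_roi.get(ER, 0.0),
                has_mito=mito_present,
                mam_area_total_nm2=mam_total,
                mam_area_er_side_nm2=mam_er_side,
                n_proximity_events=len(events),
            )
        )
    return results
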