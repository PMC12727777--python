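"""Label-volume I/O with physical voxel spacing and structure-role semantics.

Segmented FIB/SEM stacks arrive as 3D integer arrays indexed ``(z, y, x)``
with anisotropic spacing: the milling step along z (20 nm in the acquisition
this package targets) is typically coarser than the in-plane pixel size.
Structures are identified by a label map assigning each nonzero integer one
of the roles below; mitochondria and caveolae carry per-instance labels.

Supported containers: multi-page TIFF with a JSON sidecar, or HDF5 with
``spacing_nm`` / ``label_map`` attributes. Background is always label 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import h5py
import tifffile
from scipy import ndimage

# Structure roles
PM = "PM"
ER = "ER"
MITO = "MITO"
CAVEOLA = "CAVEOLA"
NUCLEUS = "NUCLEUS"
ROLES = (PM, ER, MITO, CAVEOLA, NUCLEUS)

#: default section (milling) step along z in nm, used only when no metadata
#: and no override provide dz
DEFAULT_DZ_NM = 20.0


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical size of one voxel in nm: ``dx``/``dy`` in-plane, ``dz`` the section step."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"VoxelSpacing.{name} must be positive and finite, got {v!r}")

    def as_zyx(self) -> tuple[float, float, float]:
        return (self.dz, self.dy, self.dx)

    def as_xyz(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)

    @property
    def voxel_volume_nm3(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def diagonal_nm(self) -> float:
        """Length of one voxel's space diagonal — the natural discretisation scale."""
        return float(np.sqrt(self.dx**2 + self.dy**2 + self.dz**2))


def voxel_to_physical(indices_zyx: np.ndarray, spacing: VoxelSpacing) -> np.ndarray:
    """Physical (x, y, z) nm coordinates of voxel centres.

    The centre of voxel index ``(k, j, i)`` is ``((i+0.5)dx, (j+0.5)dy, (k+0.5)dz)``.
    This single convention is used everywhere in the package.
    """
    idx = np.atleast_2d(np.asarray(indices_zyx, dtype=float))
    out = np.empty_like(idx)
    out[:, 0] = (idx[:, 2] + 0.5) * spacing.dx
    out[:, 1] = (idx[:, 1] + 0.5) * spacing.dy
    out[:, 2] = (idx[:, 0] + 0.5) * spacing.dz
    return out if np.asarray(indices_zyx).ndim == 2 else out[0]


def physical_to_voxel(points_xyz: np.ndarray, spacing: VoxelSpacing) -> np.ndarray:
    """Inverse of :func:`voxel_to_physical`: nearest voxel index ``(k, j, i)``."""
    pts = np.atleast_2d(np.asarray(points_xyz, dtype=float))
    out = np.empty_like(pts)
    out[:, 0] = pts[:, 2] / spacing.dz - 0.5
    out[:, 1] = pts[:, 1] / spacing.dy - 0.5
    out[:, 2] = pts[:, 0] / spacing.dx - 0.5
    out = np.rint(out).astype(np.int64)
    return out if np.asarray(points_xyz).ndim == 2 else out[0]


@dataclass
class LabelVolume:
    """A segmented stack: integer labels, physical spacing, and role semantics.

    ``label_map`` maps each nonzero integer present in ``data`` to a role
    string (:data:`PM`, :data:`ER`, :data:`MITO`, :data:`CAVEOLA`,
    :data:`NUCLEUS`). Several labels may share the MITO or CAVEOLA role;
    each such label is one instance.
    """

    data: np.ndarray
    spacing: VoxelSpacing
    label_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D (z, y, x), got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label volume must hold integers, got dtype {self.data.dtype}")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative (background is 0)")
        self.label_map = {int(k): str(v) for k, v in self.label_map.items()}
        if 0 in self.label_map:
            raise ValueError("label 0 is reserved for background and may not appear in label_map")
        bad = {v for v in self.label_map.values() if v not in ROLES}
        if bad:
            raise ValueError(f"unknown roles in label_map: {sorted(bad)}; valid roles: {ROLES}")
        present = set(np.unique(self.data).tolist()) - {0}
        missing = sorted(present - set(self.label_map))
        if missing:
            raise ValueError(f"labels present in data but absent from label_map: {missing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def physical_extent_nm(self) -> tuple[float, float, float]:
        """(x, y, z) size of the imaged block in nm."""
        nz, ny, nx = self.data.shape
        return (nx * self.spacing.dx, ny * self.spacing.dy, nz * self.spacing.dz)

    def labels_for_role(self, role: str) -> list[int]:
        return sorted(k for k, v in self.label_map.items() if v == role)

    def role_mask(self, role: str) -> np.ndarray:
        """Boolean mask of all labels carrying ``role`` (union over instances)."""
        if role not in self.label_map.values():
            raise KeyError(f"role {role!r} not present in label_map")
        labels = self.labels_for_role(role)
        return np.isin(self.data, labels)

    def instance_mask(self, label: int) -> np.ndarray:
        if label not in self.label_map:
            raise KeyError(f"label {label} not in label_map")
        return self.data == label

    def validate_instances(self) -> None:
        """Warn when a MITO/CAVEOLA instance label is not one 6-connected component."""
        structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        for role in (MITO, CAVEOLA):
            for lab in self.labels_for_role(role):
                _, n = ndimage.label(self.data == lab, structure=structure)
                if n > 1:
                    warnings.warn(
                        f"{role} instance label {lab} splits into {n} 6-connected components",
                        stacklevel=2,
                    )


@dataclass
class SeedPointSet:
    """Points in physical nm used as microdomain centres (typically caveola centroids)."""

    points: np.ndarray  # (n, 3) float, columns x, y, z in nm
    source_labels: np.ndarray | None = None  # caveola instance label per point

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size and self.points.shape[1] != 3:
            raise ValueError("seed points must be (n, 3) with columns x, y, z in nm")
        if self.source_labels is not None:
            self.source_labels = np.asarray(self.source_labels)
            if len(self.source_labels) != len(self.points):
                raise ValueError("source_labels length must match points")

    def __len__(self) -> int:
        return len(self.points)

    def check_inside(self, vol: LabelVolume) -> None:
        ext = np.array(vol.physical_extent_nm)
        if self.points.size and ((self.points < 0).any() or (self.points > ext).any()):
            raise ValueError("seed points fall outside the physical bounding box of the volume")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.points, columns=["x_nm", "y_nm", "z_nm"])
        df["caveola_label"] = self.source_labels if self.source_labels is not None else -1
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SeedPointSet":
        df = pd.read_csv(path)
        pts = df[["x_nm", "y_nm", "z_nm"]].to_numpy(float)
        labs = df["caveola_label"].to_numpy() if "caveola_label" in df else None
        if labs is not None and (labs < 0).all():
            labs = None
        return cls(pts, labs)


# ---------------------------------------------------------------------------
# container I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write a :class:`LabelVolume` as multi-page TIFF + JSON sidecar, or HDF5.

    The format is chosen by extension (``.tif``/``.tiff`` vs ``.h5``/``.hdf5``);
    a read after write reproduces data, spacing and label map exactly.
    """
    path = Path(path)
    meta = {
        "spacing_nm": {"dx": vol.spacing.dx, "dy": vol.spacing.dy, "dz": vol.spacing.dz},
        "label_map": {str(k): v for k, v in vol.label_map.items()},
    }
    if path.suffix.lower() in (".tif", ".tiff"):
        max_label = int(vol.data.max()) if vol.data.size else 0
        dtype = np.uint8 if max_label < 256 else np.uint16
        if max_label >= 2**16:
            raise ValueError("TIFF container limited to uint16 labels; use HDF5")
        tifffile.imwrite(path, vol.data.astype(dtype))
        _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("labels", data=vol.data, compression="gzip", compression_opts=4)
            ds.attrs["spacing_nm"] = np.array(vol.spacing.as_zyx(), dtype=float)
            ds.attrs["label_map"] = json.dumps({str(k): v for k, v in vol.label_map.items()})
    else:
        raise ValueError(f"unsupported container {path.suffix!r}; use .tif/.tiff or .h5/.hdf5")


def read_label_volume(
    path: str | Path,
    spacing_override: VoxelSpacing | None = None,
    label_map: Mapping[int, str] | None = None,
) -> LabelVolume:
    """Read a label stack from TIFF+sidecar or HDF5.

    Spacing resolution priority: explicit ``spacing_override`` > file
    metadata > default. There is no default for the in-plane pixel size
    (the acquisition records it per dataset); only ``dz`` falls back to
    :data:`DEFAULT_DZ_NM`. A label map must come from the file metadata or
    the ``label_map`` argument, and every nonzero label in the data must be
    covered by it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_spacing: VoxelSpacing | None = None
    meta_map: dict[int, str] | None = None
    if path.suffix.lower() in (".tif", ".tiff"):
        data = np.asarray(tifffile.imread(path))
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            s = meta.get("spacing_nm", {})
            if {"dx", "dy", "dz"} <= set(s):
                meta_spacing = VoxelSpacing(s["dx"], s["dy"], s["dz"])
            if "label_map" in meta:
                meta_map = {int(k): v for k, v in meta["label_map"].items()}
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ds = f["labels"]
            data = ds[...]
            if "spacing_nm" in ds.attrs:
                dz, dy, dx = (float(v) for v in ds.attrs["spacing_nm"])
                meta_spacing = VoxelSpacing(dx, dy, dz)
            if "label_map" in ds.attrs:
                meta_map = {int(k): v for k, v in json.loads(ds.attrs["label_map"]).items()}
    else:
        raise ValueError(f"unsupported container {path.suffix!r}; use .tif/.tiff or .h5/.hdf5")

    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"label data must be integer, got dtype {data.dtype}")
    if data.ndim == 2:
        data = data[None]

    spacing = spacing_override or meta_spacing
    if spacing is None:
        raise ValueError(
            "no voxel spacing available: provide spacing_override or file metadata "
            f"(only dz has a default, {DEFAULT_DZ_NM} nm)"
        )
    lm = dict(label_map) if label_map is not None else meta_map
    if lm is None:
        lm = {}
    return LabelVolume(data=data, spacing=spacing, label_map=lm)


# ---------------------------------------------------------------------------
# caveola seed extraction


def caveola_centroids(vol: LabelVolume) -> SeedPointSet:
    """Centroids (physical nm) of every caveola instance, ordered by label.

    Each distinct CAVEOLA label is one instance. Only when the volume
    carries a *single* CAVEOLA label (instances not pre-separated) is that
    label split into 6-connected components, one instance per component.
    """
    labels = vol.labels_for_role(CAVEOLA)
    if not labels:
        return SeedPointSet(np.empty((0, 3)), np.empty((0,), dtype=int))
    if len(labels) == 1:
        structure = ndimage.generate_binary_structure(3, 1)
        comp, n = ndimage.label(vol.data == labels[0], structure=structure)
        groups = [(labels[0], comp == i) for i in range(1, n + 1)]
    else:
        groups = [(lab, vol.data == lab) for lab in labels]
    pts, src = [], []
    for lab, g in groups:
        centre_zyx = np.argwhere(g).mean(axis=0)  # indices are (z, y, x)
        pts.append(voxel_to_physical(centre_zyx, vol.spacing))
        src.append(lab)
    return SeedPointSet(np.array(pts), np.array(src))


def extract_caveola_seeds(vol: LabelVolume, rng_seed: int, n: int) -> SeedPointSet:
    """Select ``n`` caveola centroids uniformly at random without replacement.

    Deterministic for a fixed ``rng_seed`` (PCG64 via ``numpy.random.default_rng``).
    """
    all_seeds = caveola_centroids(vol)
    if len(all_seeds) < n:
        raise ValueError(f"requested {n} caveolae but only {len(all_seeds)} instances are present")
    rng = np.random.default_rng(rng_seed)
    pick = np.sort(rng.choice(len(all_seeds), size=n, replace=False))
    return SeedPointSet(all_seeds.points[pick], all_seeds.source_labels[pick])
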