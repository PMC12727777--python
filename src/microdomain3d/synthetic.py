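"""Synthetic organelle phantoms with analytic ground truth.

Three archetypes emulate the ER/SR morphologies seen in gut-motility cells:

* ``SMC``    — smooth muscle cell: a capsule-shaped cell whose peripheral SR
  forms discrete longitudinal strands beneath the plasma membrane (pairwise
  disconnected), plus a nucleus wrapped in a perinuclear SR shell.
* ``ICC``    — interstitial cell of Cajal: a spherical cell with a continuous
  peripheral ER shell at a known gap beneath the PM, an interior lattice of
  ER rods (one connected component together with the shell), and mitochondria
  embedded near the ER.
* ``PDGFRA`` — PDGFRα+ fibroblast-like cell: parallel ER sheets through the
  deep cytoplasm.

Every quantity a test may recover — the ER-PM gap, per-mitochondrion MAM
facet areas, caveola centres, structure volumes — is constructed analytically
first and only then rasterised; ground truth is never read back from voxels.

Construction conventions
------------------------
* The ER-PM gap is the distance from the cell boundary (the PM's outer face;
  the PM label itself is the one-voxel boundary rind of the cell mask) to the
  ER's PM-facing surface.
* Mito-ER appositions are axis-aligned and snapped to the voxel grid, so the
  rasterised mesh gap equals the specified gap exactly. Each apposition is a
  flat rectangular facet on the mitochondrion (a slab fused to an ellipsoid
  body) facing a dedicated ER sheet inset 10 nm laterally. The inset bounds
  how far the contact region spreads onto the mitochondrion's side walls, so
  the measured mito-side contact area realises the analytic facet area: the
  small wall rim it admits offsets the half-voxel bevel marching cubes
  shaves off the facet edges.
* Caveolae are flask invaginations (neck + bulb) carved into the cell at
  axis-aligned surface normals; the recorded caveola centre is the bulb
  centre. Default flask dimensions (neck radius 15 nm, bulb radius 35 nm,
  depth 70 nm) are typical caveolar dimensions from the general
  ultrastructure literature, not measured values of this pipeline's targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io_volumes import (
    CAVEOLA,
    ER,
    MITO,
    NUCLEUS,
    PM,
    LabelVolume,
    SeedPointSet,
    VoxelSpacing,
)

SMC = "SMC"
ICC = "ICC"
PDGFRA = "PDGFRA"
ARCHETYPES = (SMC, ICC, PDGFRA)

LABEL_PM = 1
LABEL_ER = 2
LABEL_NUCLEUS = 3
CAVEOLA_LABEL_BASE = 10
MITO_LABEL_BASE = 100

#: surface normals (axis-aligned first — mito assemblies attach to these; -z
#: is reserved for the lattice-to-shell strut) then diagonals
_AXIS_DIRS = np.array([(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1)], float)
_DIAG_DIRS = np.array([(1, 1, 1), (-1, -1, 1), (-1, 1, -1), (1, -1, -1)], float) / np.sqrt(3.0)

# assembly geometry (nm); see module docstring
_SHEET_THICKNESS = 30.0
_SHEET_INSET = 10.0
_SLAB_DEPTH = 30.0          # protrusion of the facet slab in front of the ellipsoid body
_PLATE_CROSS = 60.0         # connector plate width
_ASSEMBLY_DEPTH = 310.0     # facet-centre depth beneath the cell boundary; deep enough
                            # that slab corners stay clear of the curved peripheral shell
                            # (>20 nm + discretisation) yet the facet stays inside a 400 nm sphere
_MITO_SEMI = (120.0, 150.0, 80.0)  # ellipsoid body semi-axes along (facet normal, lateral, radial)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom; defaults are the regime the pipeline targets.

    ``er_pm_gap`` is 100 nm by default (ER-PM distances of about 100 nm are
    the regime of interest); the MAM apposition gap defaults to 10 nm, i.e.
    under the 20 nm contact criterion. ``volume_shape`` (z, y, x) is derived
    from the cell size plus ``margin`` when not given.
    """

    archetype: str = ICC
    spacing: VoxelSpacing = VoxelSpacing(10.0, 10.0, 20.0)
    volume_shape: tuple[int, int, int] | None = None
    er_pm_gap: float = 100.0
    er_thickness: float = 40.0
    mito_count: int | None = None          # archetype default: ICC/PDGFRA 1, SMC 0
    mito_er_gap: float = 10.0
    caveola_count: int = 3
    caveola_neck_radius: float = 15.0
    caveola_bulb_radius: float = 35.0
    caveola_depth: float = 70.0
    rng_seed: int = 0
    cell_radius: float = 700.0             # sphere radius, or capsule tube radius for SMC
    cell_length: float = 2400.0            # cylindrical section length (SMC)
    margin: float = 100.0
    facet_dims: tuple[float, float] = (300.0, 200.0)   # (lateral, radial) facet extent
    jitter_facets: bool = False            # rng-vary facet dims per mitochondrion
    n_strands: int = 8                     # SMC peripheral strand count
    strand_width: float = 300.0            # SMC strand arc width at mid-depth
    caveola_spacing: float = 600.0         # SMC inter-caveola spacing along the long axis
    include_nucleus: bool = True           # SMC nucleus + perinuclear shell
    nucleus_radius: float = 250.0
    interior_lattice: bool = True          # ICC deep ER lattice
    lattice_clearance: float = 150.0       # min depth of the ICC lattice beneath the boundary
    lattice_pitch: float = 300.0
    sheet_pitch: float = 400.0             # PDGFRA sheet spacing
    sheet_thickness: float = 40.0          # PDGFRA sheet thickness
    sheet_clearance: float | None = None   # min depth of PDGFRA sheets; default: er_pm_gap

    def resolved_mito_count(self) -> int:
        if self.mito_count is not None:
            return self.mito_count
        return 1 if self.archetype == ICC else 0


@dataclass
class GroundTruth:
    """Analytic ground truth, fixed before rasterisation."""

    true_er_pm_gap: float
    true_mam_area_per_mito: dict[int, float]       # mito label -> facet area (nm^2); 0 above threshold
    caveola_centres: SeedPointSet                  # bulb centres, label order
    true_volumes: dict[str, float]                 # role -> nm^3
    true_mito_volumes: dict[int, float]            # mito label -> nm^3
    per_sphere_er_volume_nm3: list[float] | None   # analytic ER per default 400 nm sphere (ICC only)
    mam_positive: list[bool]                       # per caveola: mito assembly within its sphere
    spec: PhantomSpec

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_er_pm_gap_nm": self.true_er_pm_gap,
            "true_mam_area_per_mito_nm2": {str(k): v for k, v in self.true_mam_area_per_mito.items()},
            "caveola_centres_nm": self.caveola_centres.points.tolist(),
            "caveola_labels": (
                self.caveola_centres.source_labels.tolist()
                if self.caveola_centres.source_labels is not None
                else None
            ),
            "true_volumes_nm3": self.true_volumes,
            "true_mito_volumes_nm3": {str(k): v for k, v in self.true_mito_volumes.items()},
            "per_sphere_er_volume_nm3": self.per_sphere_er_volume_nm3,
            "mam_positive": self.mam_positive,
            "archetype": self.spec.archetype,
            "rng_seed": self.spec.rng_seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# small analytic/raster helpers


def _gsnap(value: float, step: float) -> float:
    """Snap a coordinate to the voxel-boundary grid of one axis."""
    return float(np.floor(value / step + 0.5)) * step


def _lens_volume(r1: float, r2: float, d: float) -> float:
    """Intersection volume of two balls (radii r1, r2, centre distance d)."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return 4.0 / 3.0 * np.pi * min(r1, r2) ** 3
    return float(
        np.pi * (r1 + r2 - d) ** 2 * (d * d + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2) / (12 * d)
    )


def _ellipsoid_cap_volume(semi: tuple[float, float, float], cut_rel: float) -> float:
    """Volume of an ellipsoid beyond the plane ``u = cut_rel * semi_u`` along its first axis."""
    u = float(np.clip(cut_rel, -1.0, 1.0))
    a, b, c = semi
    return float(np.pi * a * b * c * (2.0 / 3.0 - u + u**3 / 3.0))


class _Canvas:
    """A label volume under construction, with grid-aware painters."""

    def __init__(self, shape: tuple[int, int, int], spacing: VoxelSpacing):
        self.shape = shape
        self.spacing = spacing
        self.data = np.zeros(shape, dtype=np.uint16)
        nz, ny, nx = shape
        self.xs = (np.arange(nx) + 0.5) * spacing.dx
        self.ys = (np.arange(ny) + 0.5) * spacing.dy
        self.zs = (np.arange(nz) + 0.5) * spacing.dz

    def _index_range(self, lo: float, hi: float, axis: int) -> tuple[int, int]:
        # voxel centres (i + 0.5) * d inside [lo, hi)
        d = (self.spacing.dx, self.spacing.dy, self.spacing.dz)[axis]
        n = (self.shape[2], self.shape[1], self.shape[0])[axis]
        i0 = int(np.ceil(lo / d - 0.5 - 1e-9))
        i1 = int(np.ceil(hi / d - 0.5 - 1e-9))
        return max(i0, 0), min(i1, n)

    def box_mask_slices(self, lo_xyz, hi_xyz):
        i0, i1 = self._index_range(lo_xyz[0], hi_xyz[0], 0)
        j0, j1 = self._index_range(lo_xyz[1], hi_xyz[1], 1)
        k0, k1 = self._index_range(lo_xyz[2], hi_xyz[2], 2)
        return (slice(k0, k1), slice(j0, j1), slice(i0, i1))

    def paint_box(self, target: np.ndarray, lo_xyz, hi_xyz, value=True) -> None:
        sl = self.box_mask_slices(lo_xyz, hi_xyz)
        target[sl] = value

    def paint_ellipsoid(
        self,
        target: np.ndarray,
        centre_xyz,
        semi_xyz,
        value=True,
        min_coord: tuple[int, float] | None = None,
    ) -> None:
        """Paint voxels whose centre satisfies the ellipsoid equation.

        ``min_coord=(axis, bound)`` additionally requires centre >= bound on
        that axis (used for the fused mitochondrion body).
        """
        lo = [centre_xyz[a] - semi_xyz[a] for a in range(3)]
        hi = [centre_xyz[a] + semi_xyz[a] for a in range(3)]
        if min_coord is not None:
            lo[min_coord[0]] = max(lo[min_coord[0]], min_coord[1])
        sl = self.box_mask_slices(lo, hi)
        x = (self.xs[sl[2]] - centre_xyz[0]) / semi_xyz[0]
        y = (self.ys[sl[1]] - centre_xyz[1]) / semi_xyz[1]
        z = (self.zs[sl[0]] - centre_xyz[2]) / semi_xyz[2]
        eq = z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2 <= 1.0
        if min_coord is not None:
            axis, bound = min_coord
            coord = (self.xs, self.ys, self.zs)[axis][sl[2 - axis]]
            cond = coord >= bound - 1e-9
            shp = [1, 1, 1]
            shp[2 - axis] = len(coord)
            eq &= cond.reshape(shp)
        target[sl][eq] = value

    def paint_capsule_segment(
        self, target: np.ndarray, p0_xyz, p1_xyz, radius: float, value=True
    ) -> None:
        """Paint a cylinder-with-round-caps around the segment p0-p1 (any orientation)."""
        p0, p1 = np.asarray(p0_xyz, float), np.asarray(p1_xyz, float)
        lo = np.minimum(p0, p1) - radius
        hi = np.maximum(p0, p1) + radius
        sl = self.box_mask_slices(lo, hi)
        X, Y, Z = np.meshgrid(self.xs[sl[2]], self.ys[sl[1]], self.zs[sl[0]], indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1)  # (nx, ny, nz, 3)
        seg = p1 - p0
        L2 = float(seg @ seg)
        t = ((pts - p0) @ seg) / L2 if L2 > 0 else np.zeros(pts.shape[:-1])
        t = np.clip(t, 0.0, 1.0)
        closest = p0 + t[..., None] * seg
        d2 = ((pts - closest) ** 2).sum(axis=-1)
        inside = (d2 <= radius**2).transpose(2, 1, 0)  # back to (z, y, x)
        target[sl][inside] = value


# ---------------------------------------------------------------------------
# validation and layout


def _validate(spec: PhantomSpec) -> None:
    sp = spec.spacing
    if spec.archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {spec.archetype!r}; choose from {ARCHETYPES}")
    if spec.er_pm_gap < 0:
        raise ValueError("er_pm_gap must be >= 0")
    max_sp = max(sp.dx, sp.dy, sp.dz)
    if spec.er_pm_gap > 0 and spec.er_pm_gap < 2 * max_sp:
        raise ValueError(
            f"er_pm_gap {spec.er_pm_gap} nm is not resolvable at spacing {sp.as_xyz()} "
            f"(needs >= 2 voxels along every axis, i.e. >= {2 * max_sp} nm)"
        )
    if spec.er_thickness < 2 * max_sp:
        raise ValueError(f"er_thickness {spec.er_thickness} nm needs >= {2 * max_sp} nm at this spacing")
    if spec.resolved_mito_count() > 0:
        if spec.archetype == PDGFRA:
            raise ValueError(
                "mito-ER appositions are constructed for ICC/SMC phantoms; PDGFRA sheets "
                "fill the cytoplasm and would collide with an assembly"
            )
        if abs(sp.dx - sp.dy) > 1e-9:
            raise ValueError("mito-ER appositions require dx == dy (facet normals are in-plane)")
        if spec.mito_er_gap <= 0 or abs(spec.mito_er_gap / sp.dx - round(spec.mito_er_gap / sp.dx)) > 1e-6:
            raise ValueError(
                f"mito_er_gap {spec.mito_er_gap} nm must be a positive multiple of the in-plane "
                f"spacing {sp.dx} nm (appositions are grid-snapped so the rasterised gap is exact)"
            )
    inplane = min(sp.dx, sp.dy)
    if spec.caveola_count > 0:
        if spec.caveola_bulb_radius < 2 * inplane or spec.caveola_neck_radius < 1.5 * inplane:
            raise ValueError("caveola bulb/neck radii are not resolvable at this in-plane spacing")
        if spec.caveola_depth <= spec.caveola_bulb_radius:
            raise ValueError("caveola_depth must exceed the bulb radius")
        if spec.caveola_depth + max_sp > spec.er_pm_gap:
            raise ValueError("caveolae would collide with the peripheral ER: depth + 1 voxel > er_pm_gap")
    if spec.archetype == SMC:
        n_max = spec.caveola_count
        if (n_max - 1) * spec.caveola_spacing / 2 + 400 > spec.cell_length / 2:
            raise ValueError("SMC caveolae (plus a 400 nm microdomain) do not fit on the cylindrical section")
    else:
        if spec.caveola_count > len(_AXIS_DIRS) + len(_DIAG_DIRS):
            raise ValueError(f"at most {len(_AXIS_DIRS) + len(_DIAG_DIRS)} caveolae on a spherical cell")
    if spec.resolved_mito_count() > min(spec.caveola_count, len(_AXIS_DIRS)):
        raise ValueError(
            "each mitochondrion is attached beneath an axis-aligned caveola: "
            f"mito_count <= min(caveola_count, {len(_AXIS_DIRS)})"
        )


def _layout(spec: PhantomSpec) -> tuple[tuple[int, int, int], np.ndarray]:
    """Volume shape (z, y, x) and cell centre (x, y, z) in nm."""
    sp = spec.spacing
    hx = hz = spec.cell_radius + spec.margin
    hy = hx if spec.archetype != SMC else spec.cell_length / 2 + spec.cell_radius + spec.margin
    if spec.volume_shape is not None:
        shape = tuple(int(v) for v in spec.volume_shape)
    else:
        shape = (
            int(np.ceil(2 * hz / sp.dz)),
            int(np.ceil(2 * hy / sp.dy)),
            int(np.ceil(2 * hx / sp.dx)),
        )
    nz, ny, nx = shape
    centre = np.array([nx * sp.dx, ny * sp.dy, nz * sp.dz]) / 2.0
    ext = centre * 2
    need = np.array([hx, hy, hz])
    if ((centre - need) < -1e-6).any():
        raise ValueError(f"volume_shape {shape} too small for the cell (+margin): needs extent {2 * need}, has {ext}")
    return shape, centre


def _caveola_directions(spec: PhantomSpec) -> np.ndarray:
    if spec.archetype == SMC:
        return np.tile(np.array([1.0, 0.0, 0.0]), (spec.caveola_count, 1))
    dirs = np.vstack([_AXIS_DIRS, _DIAG_DIRS])
    return dirs[: spec.caveola_count]


def _caveola_surface_points(spec: PhantomSpec, centre: np.ndarray) -> np.ndarray:
    """Outer-surface anchor point of each caveola, (n, 3) xyz nm."""
    dirs = _caveola_directions(spec)
    if spec.archetype == SMC:
        n = spec.caveola_count
        ys = (np.arange(n) - (n - 1) / 2.0) * spec.caveola_spacing
        pts = np.tile(centre, (n, 1))
        pts[:, 0] += spec.cell_radius
        pts[:, 1] += ys
        return pts
    return centre[None, :] + dirs * spec.cell_radius


# ---------------------------------------------------------------------------
# MAM assembly (sheet + connector plate + mitochondrion with facet)


def _local_frame(direction: np.ndarray) -> tuple[int, int, int, int]:
    """(radial_axis, sign, facet_axis u, lateral_axis v) for an axis-aligned normal."""
    a = int(np.argmax(np.abs(direction)))
    sign = 1 if direction[a] > 0 else -1
    u = 1 if a == 0 else 0   # facet normal: y if caveola along x, else x
    v = 3 - a - u
    return a, sign, u, v


def _interval_along_normal(anchor: float, sign: int, d_lo: float, d_hi: float) -> tuple[float, float]:
    """Absolute interval on the radial axis for depth range [d_lo, d_hi] beneath the anchor."""
    if sign > 0:
        return anchor - d_hi, anchor - d_lo
    return anchor + d_lo, anchor + d_hi


@dataclass
class _Assembly:
    """Snapped absolute geometry of one apposition; all analytic bookkeeping lives here."""

    sheet_lo: np.ndarray
    sheet_hi: np.ndarray
    plate_lo: np.ndarray          # rasterised extent (reaches into the ER shell)
    plate_hi: np.ndarray
    plate_gt_volume: float        # counted only outside the shell band
    slab_lo: np.ndarray
    slab_hi: np.ndarray
    mito_centre: np.ndarray
    mito_semi_xyz: np.ndarray
    mito_cut: tuple[int, float]   # (axis, bound): ellipsoid body restricted beyond the slab
    facet_area: float
    mito_volume: float
    er_volume: float              # sheet + plate (ground-truth part)


def _build_assembly(
    spec: PhantomSpec,
    canvas: _Canvas,
    surface_pt: np.ndarray,
    direction: np.ndarray,
    facet_dims: tuple[float, float],
) -> _Assembly:
    sp = spec.spacing
    steps = (sp.dx, sp.dy, sp.dz)
    a, sign, u, v = _local_frame(direction)
    fv, fd = facet_dims
    gap = spec.mito_er_gap
    inset = _SHEET_INSET
    dc = _ASSEMBLY_DEPTH

    def interval(axis: int, lo: float, hi: float) -> tuple[float, float]:
        lo_s, hi_s = _gsnap(lo, steps[axis]), _gsnap(hi, steps[axis])
        if hi_s <= lo_s:
            raise ValueError("assembly geometry collapses at this spacing")
        return lo_s, hi_s

    def box(u_rng, v_rng, depth_rng) -> tuple[np.ndarray, np.ndarray]:
        lo = np.empty(3)
        hi = np.empty(3)
        lo[u], hi[u] = interval(u, surface_pt[u] + u_rng[0], surface_pt[u] + u_rng[1])
        lo[v], hi[v] = interval(v, surface_pt[v] + v_rng[0], surface_pt[v] + v_rng[1])
        d_lo, d_hi = _interval_along_normal(surface_pt[a], sign, depth_rng[0], depth_rng[1])
        lo[a], hi[a] = interval(a, d_lo, d_hi)
        return lo, hi

    # facet slab: front face at local u = 0, snapped by construction
    slab_lo, slab_hi = box((0.0, _SLAB_DEPTH), (-fv / 2, fv / 2), (dc - fd / 2, dc + fd / 2))
    fv_s = slab_hi[v] - slab_lo[v]
    fd_s = slab_hi[a] - slab_lo[a]
    facet_area = fv_s * fd_s
    # dedicated ER sheet across the gap, inset laterally
    sheet_lo, sheet_hi = box(
        (-gap - _SHEET_THICKNESS, -gap),
        (-fv / 2 + inset, fv / 2 - inset),
        (dc - fd / 2 + inset, dc + fd / 2 - inset),
    )
    # connector plate from the sheet up into the peripheral ER shell
    shell_inner_depth = spec.er_pm_gap + spec.er_thickness
    plate_lo, plate_hi = box(
        (-gap - 2 * _SHEET_THICKNESS, -gap - _SHEET_THICKNESS),
        (-_PLATE_CROSS / 2, _PLATE_CROSS / 2),
        (shell_inner_depth - 1.5 * max(steps), dc),
    )
    plate_gt = (
        (plate_hi[u] - plate_lo[u])
        * (plate_hi[v] - plate_lo[v])
        * max(dc - shell_inner_depth, 0.0)
    )
    # mitochondrion: ellipsoid body fused behind the slab
    au, av, ad = _MITO_SEMI
    cut = slab_hi[u] if sign >= 0 or u != a else slab_lo[u]  # u is never the radial axis
    mito_centre = np.empty(3)
    mito_centre[u] = cut + 0.5 * au
    mito_centre[v] = 0.5 * (slab_lo[v] + slab_hi[v])
    mito_centre[a] = 0.5 * (slab_lo[a] + slab_hi[a])
    semi = np.empty(3)
    semi[u], semi[v], semi[a] = au, av, ad
    cap_vol = _ellipsoid_cap_volume((au, av, ad), (cut - mito_centre[u]) / au)
    slab_vol = float(np.prod(slab_hi - slab_lo))
    sheet_vol = float(np.prod(sheet_hi - sheet_lo))
    return _Assembly(
        sheet_lo=sheet_lo,
        sheet_hi=sheet_hi,
        plate_lo=plate_lo,
        plate_hi=plate_hi,
        plate_gt_volume=plate_gt,
        slab_lo=slab_lo,
        slab_hi=slab_hi,
        mito_centre=mito_centre,
        mito_semi_xyz=semi,
        mito_cut=(u, float(cut)),
        facet_area=float(facet_area),
        mito_volume=slab_vol + cap_vol,
        er_volume=sheet_vol + plate_gt,
    )


# ---------------------------------------------------------------------------
# archetype ER builders (paint into er_mask, return analytic volume)


def _radial_field(spec: PhantomSpec, canvas: _Canvas, centre: np.ndarray) -> np.ndarray:
    """Distance (nm) of each voxel centre from the cell centre/axis-segment."""
    if spec.archetype == SMC:
        half = spec.cell_length / 2.0
        dyc = np.maximum(np.abs(canvas.ys - centre[1]) - half, 0.0) ** 2
        dx2 = (canvas.xs - centre[0]) ** 2
        dz2 = (canvas.zs - centre[2]) ** 2
        r2 = dz2[:, None, None] + dyc[None, :, None] + dx2[None, None, :]
    else:
        dx2 = (canvas.xs - centre[0]) ** 2
        dy2 = (canvas.ys - centre[1]) ** 2
        dz2 = (canvas.zs - centre[2]) ** 2
        r2 = dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :]
    return np.sqrt(r2, dtype=np.float32)


def _build_er_icc(spec: PhantomSpec, canvas: _Canvas, centre, r_field, er_mask) -> float:
    R, g, t = spec.cell_radius, spec.er_pm_gap, spec.er_thickness
    er_mask |= (r_field <= R - g) & (r_field > R - g - t)
    total = 4.0 / 3.0 * np.pi * ((R - g) ** 3 - (R - g - t) ** 3)
    if not spec.interior_lattice:
        return total
    sp = spec.spacing
    R_lat = R - spec.lattice_clearance
    if R_lat < 2 * spec.lattice_pitch:
        return total
    half = 30.0
    xb = (_gsnap(centre[0] - half, sp.dx), _gsnap(centre[0] + half, sp.dx))
    yb = (_gsnap(centre[1] - half, sp.dy), _gsnap(centre[1] + half, sp.dy))
    zb = (_gsnap(centre[2] - half, sp.dz), _gsnap(centre[2] + half, sp.dz))
    boxes: list[tuple[np.ndarray, np.ndarray]] = []

    def clipped_len(lateral1: float, lateral2: float) -> float:
        rem = R_lat**2 - lateral1**2 - lateral2**2
        return np.sqrt(rem) if rem > 0 else 0.0

    # spine along x through the cell centre
    Lx = _gsnap(clipped_len(half, half), sp.dx)
    boxes.append((np.array([centre[0] - Lx, yb[0], zb[0]]), np.array([centre[0] + Lx, yb[1], zb[1]])))
    m_max = int((R_lat - 2 * half) // spec.lattice_pitch)
    for m in range(-m_max, m_max + 1):
        x0 = _gsnap(centre[0] + m * spec.lattice_pitch - half, sp.dx)
        x1 = _gsnap(centre[0] + m * spec.lattice_pitch + half, sp.dx)
        lat_x = max(abs(x0 - centre[0]), abs(x1 - centre[0]))
        # rods along y, abutting the spine's y faces
        Ly = _gsnap(clipped_len(lat_x, half), sp.dy)
        if Ly - half > 2 * sp.dy:
            boxes.append((np.array([x0, yb[1], zb[0]]), np.array([x1, centre[1] + Ly, zb[1]])))
            boxes.append((np.array([x0, centre[1] - Ly, zb[0]]), np.array([x1, yb[0], zb[1]])))
        # rods along z, abutting the spine's z faces (skip m=0: the strut runs there)
        Lz = _gsnap(clipped_len(lat_x, half), sp.dz)
        if m != 0 and Lz - half > 2 * sp.dz:
            boxes.append((np.array([x0, yb[0], zb[1]]), np.array([x1, yb[1], centre[2] + Lz])))
            boxes.append((np.array([x0, yb[0], centre[2] - Lz]), np.array([x1, yb[1], zb[0]])))
    # strut from the spine down the -z pole into the peripheral shell
    shell_inner = centre[2] - (R - g - t)
    strut_lo = np.array([xb[0], yb[0], _gsnap(shell_inner - 1.5 * sp.dz, sp.dz)])
    strut_hi = np.array([xb[1], yb[1], zb[0]])
    canvas.paint_box(er_mask, strut_lo, strut_hi)
    total += (strut_hi[0] - strut_lo[0]) * (strut_hi[1] - strut_lo[1]) * (zb[0] - shell_inner)
    for lo, hi in boxes:
        canvas.paint_box(er_mask, lo, hi)
        total += float(np.prod(hi - lo))
    return total


def _build_er_smc(spec: PhantomSpec, canvas: _Canvas, centre, r_field, er_mask) -> tuple[float, float]:
    """Peripheral strands + perinuclear shell; returns (strand volume, perinuclear volume)."""
    R, g, t = spec.cell_radius, spec.er_pm_gap, spec.er_thickness
    r_mid = R - g - t / 2.0
    theta_half = spec.strand_width / (2.0 * r_mid)
    pitch = 2.0 * np.pi / spec.n_strands
    if 2 * theta_half >= pitch - 2 * max(spec.spacing.dx, spec.spacing.dz) / r_mid:
        raise ValueError("SMC strands would merge: reduce n_strands or strand_width")
    theta = np.arctan2(canvas.zs[:, None] - centre[2], canvas.xs[None, :] - centre[0])  # (nz, nx)
    frac = np.mod(theta + theta_half, pitch)
    in_band_zx = frac <= 2 * theta_half  # band centred on theta = 0 and its rotations
    in_cyl = np.abs(canvas.ys - centre[1]) <= spec.cell_length / 2.0
    shell = (r_field <= R - g) & (r_field > R - g - t)
    er_mask |= shell & in_cyl[None, :, None] & in_band_zx[:, None, :]
    strand_vol = (
        spec.n_strands * 2 * theta_half / (2 * np.pi)
        * np.pi * ((R - g) ** 2 - (R - g - t) ** 2) * spec.cell_length
    )
    peri_vol = 0.0
    if spec.include_nucleus:
        rn = spec.nucleus_radius
        dn = np.sqrt(
            (canvas.zs[:, None, None] - centre[2]) ** 2
            + (canvas.ys[None, :, None] - centre[1]) ** 2
            + (canvas.xs[None, None, :] - centre[0]) ** 2
        )
        er_mask |= (dn <= rn + 70.0) & (dn > rn + 30.0)
        peri_vol = 4.0 / 3.0 * np.pi * ((rn + 70.0) ** 3 - (rn + 30.0) ** 3)
    return strand_vol, peri_vol


def _build_er_pdgfra(spec: PhantomSpec, canvas: _Canvas, centre, r_field, er_mask) -> float:
    R = spec.cell_radius
    clearance = spec.sheet_clearance if spec.sheet_clearance is not None else spec.er_pm_gap
    R_in = R - clearance
    if R_in <= spec.sheet_thickness:
        return 0.0
    sp = spec.spacing
    deep = r_field <= R_in
    total = 0.0
    m_max = int(R_in // spec.sheet_pitch)
    slab_ok = np.zeros(canvas.shape[2], dtype=bool)
    for m in range(-m_max, m_max + 1):
        x0 = _gsnap(centre[0] + m * spec.sheet_pitch - spec.sheet_thickness / 2, sp.dx)
        x1 = _gsnap(centre[0] + m * spec.sheet_pitch + spec.sheet_thickness / 2, sp.dx)
        slab_ok |= (canvas.xs >= x0 - 1e-9) & (canvas.xs < x1 - 1e-9)
        a = np.clip(x0 - centre[0], -R_in, R_in)
        b = np.clip(x1 - centre[0], -R_in, R_in)
        total += np.pi * (R_in**2 * (b - a) - (b**3 - a**3) / 3.0)
    er_mask |= deep & slab_ok[None, None, :]
    return float(total)


# ---------------------------------------------------------------------------
# main generator


def generate_phantom(spec: PhantomSpec) -> tuple[LabelVolume, GroundTruth]:
    """Rasterise one phantom and return it with its analytic ground truth.

    Deterministic for a fixed ``spec.rng_seed`` (the rng only drives facet-size
    jitter when ``jitter_facets`` is on).
    """
    _validate(spec)
    rng = np.random.default_rng(spec.rng_seed)
    shape, centre = _layout(spec)
    canvas = _Canvas(shape, spec.spacing)
    sp = spec.spacing
    R = spec.cell_radius

    r_field = _radial_field(spec, canvas, centre)
    cell = r_field <= R

    # --- ER ---------------------------------------------------------------
    er_mask = np.zeros(shape, dtype=bool)
    volumes: dict[str, float] = {}
    if spec.archetype == ICC:
        volumes[ER] = _build_er_icc(spec, canvas, centre, r_field, er_mask)
    elif spec.archetype == SMC:
        strand_vol, peri_vol = _build_er_smc(spec, canvas, centre, r_field, er_mask)
        volumes[ER] = strand_vol + peri_vol
    else:
        volumes[ER] = _build_er_pdgfra(spec, canvas, centre, r_field, er_mask)

    # --- caveolae + mito assemblies ----------------------------------------
    surface_pts = _caveola_surface_points(spec, centre)
    directions = _caveola_directions(spec)
    n_cav = spec.caveola_count
    n_mito = spec.resolved_mito_count()
    mam_positive = [i < n_mito for i in range(n_cav)]

    assemblies: list[_Assembly | None] = [None] * n_cav
    mito_volumes: dict[int, float] = {}
    mam_areas: dict[int, float] = {}
    for i in range(n_mito):
        if spec.jitter_facets:
            # bounded so worst-case slab corners clear the curved shell and the
            # facet stays within the 400 nm microdomain
            fv = float(rng.choice([240.0, 260.0, 280.0, 300.0]))
            fd = float(rng.choice([160.0, 180.0, 200.0]))
        else:
            fv, fd = spec.facet_dims
        asm = _build_assembly(spec, canvas, surface_pts[i], directions[i], (fv, fd))
        assemblies[i] = asm
        canvas.paint_box(er_mask, asm.sheet_lo, asm.sheet_hi)
        canvas.paint_box(er_mask, asm.plate_lo, asm.plate_hi)
        volumes[ER] += asm.er_volume
        label = MITO_LABEL_BASE + i
        mito_volumes[label] = asm.mito_volume
        mam_areas[label] = asm.facet_area if spec.mito_er_gap < 20.0 else 0.0

    # --- carve caveola flasks ----------------------------------------------
    cavity_per_cav: list[np.ndarray | None] = [None] * n_cav
    cavity_all = np.zeros(shape, dtype=bool)
    bulb_centres = np.empty((n_cav, 3))
    for i in range(n_cav):
        n_hat = directions[i]
        p_s = surface_pts[i]
        bulb_c = p_s - n_hat * (spec.caveola_depth - spec.caveola_bulb_radius)
        bulb_centres[i] = bulb_c
        cav = np.zeros(shape, dtype=bool)
        canvas.paint_ellipsoid(cav, bulb_c, (spec.caveola_bulb_radius,) * 3)
        mouth = p_s + n_hat * 2.0 * max(sp.as_xyz())
        canvas.paint_capsule_segment(cav, mouth, bulb_c, spec.caveola_neck_radius)
        cavity_per_cav[i] = cav
        cavity_all |= cav

    cell_carved = cell & ~cavity_all
    interior = ndimage.binary_erosion(
        cell_carved, structure=ndimage.generate_binary_structure(3, 1), border_value=1
    )
    boundary = cell_carved & ~interior

    # --- compose labels -----------------------------------------------------
    data = canvas.data
    label_map: dict[int, str] = {LABEL_PM: PM, LABEL_ER: ER}
    data[er_mask] = LABEL_ER
    if spec.archetype == SMC and spec.include_nucleus:
        nuc = np.zeros(shape, dtype=bool)
        canvas.paint_ellipsoid(nuc, centre, (spec.nucleus_radius,) * 3)
        data[nuc & (data == 0)] = LABEL_NUCLEUS
        label_map[LABEL_NUCLEUS] = NUCLEUS
        volumes[NUCLEUS] = 4.0 / 3.0 * np.pi * spec.nucleus_radius**3
    for i, asm in enumerate(assemblies):
        if asm is None:
            continue
        label = MITO_LABEL_BASE + i
        mito = np.zeros(shape, dtype=bool)
        canvas.paint_box(mito, asm.slab_lo, asm.slab_hi)
        canvas.paint_ellipsoid(mito, asm.mito_centre, asm.mito_semi_xyz, min_coord=asm.mito_cut)
        data[mito] = label
        label_map[label] = MITO
    if n_mito:
        volumes[MITO] = float(sum(mito_volumes.values()))

    dil = ndimage.generate_binary_structure(3, 3)  # 26-connectivity catches diagonal lining
    six = ndimage.generate_binary_structure(3, 1)
    cup_any = np.zeros(shape, dtype=bool)
    for i in range(n_cav):
        cup = boundary & ndimage.binary_dilation(cavity_per_cav[i], structure=dil, iterations=2)
        # a caveola instance is one 6-connected membrane cup; stray lining
        # fragments (thin far-side voxels at coarse z) stay plasma membrane
        comp, ncomp = ndimage.label(cup, structure=six)
        if ncomp > 1:
            cup = comp == (np.bincount(comp.ravel())[1:].argmax() + 1)
        data[cup & ~cup_any] = CAVEOLA_LABEL_BASE + i
        label_map[CAVEOLA_LABEL_BASE + i] = CAVEOLA
        cup_any |= cup
    data[boundary & ~cup_any & (data == 0)] = LABEL_PM

    vol = LabelVolume(data=data, spacing=sp, label_map=label_map)

    # --- per-sphere analytic ER volume (ICC, default 400 nm spheres) --------
    from .microdomain import DEFAULT_RADIUS_NM

    per_sphere: list[float] | None = None
    if spec.archetype == ICC:
        d_cav = spec.caveola_depth - spec.caveola_bulb_radius  # bulb-centre depth
        d_c = R - d_cav
        lattice_reach = R - spec.lattice_clearance if spec.interior_lattice else 0.0
        if d_c - lattice_reach > DEFAULT_RADIUS_NM:
            g, t = spec.er_pm_gap, spec.er_thickness
            shell_part = _lens_volume(R - g, DEFAULT_RADIUS_NM, d_c) - _lens_volume(
                R - g - t, DEFAULT_RADIUS_NM, d_c
            )
            per_sphere = []
            for asm in assemblies:
                extra = asm.er_volume if asm is not None else 0.0
                per_sphere.append(shell_part + extra)

    gt = GroundTruth(
        true_er_pm_gap=spec.er_pm_gap,
        true_mam_area_per_mito=mam_areas,
        caveola_centres=SeedPointSet(
            bulb_centres, np.arange(CAVEOLA_LABEL_BASE, CAVEOLA_LABEL_BASE + n_cav)
        ),
        true_volumes=volumes,
        true_mito_volumes=mito_volumes,
        per_sphere_er_volume_nm3=per_sphere,
        mam_positive=mam_positive,
        spec=spec,
    )
    return vol, gt


def generate_paper_scale_scene(rng_seed: int = 0) -> tuple[LabelVolume, GroundTruth]:
    """An ICC phantom dimensioned to the study regime.

    Nine caveolae on a 1 um-radius cell; five carry a mitochondrion with a
    MAM apposition inside their 400 nm microdomain and four do not, so the
    MAM-positive omission rule is exercised. Facet sizes are jittered around
    300 x 200 nm; the analytic per-sphere ER volume lands in the low 1e7 nm^3
    range. The interior lattice sits deeper than any microdomain reaches, so
    per-sphere ER ground truth stays closed-form.
    """
    spec = PhantomSpec(
        archetype=ICC,
        spacing=VoxelSpacing(10.0, 10.0, 20.0),
        cell_radius=1000.0,
        caveola_count=9,
        mito_count=5,
        er_pm_gap=100.0,
        er_thickness=40.0,
        interior_lattice=True,
        lattice_clearance=460.0,
        jitter_facets=True,
        rng_seed=rng_seed,
    )
    return generate_phantom(spec)
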