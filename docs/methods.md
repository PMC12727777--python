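# Methods

## Input model

The pipeline consumes already-segmented label volumes: 3D non-negative
integer arrays indexed `(z, y, x)` with background 0 and a label map
assigning each nonzero label one role — PM, ER, NUCLEUS, or per-instance
MITO / CAVEOLA labels. Physical scale is carried as nm-per-voxel spacing
`(dx, dy, dz)`; volume-EM stacks are anisotropic (the targeted acquisition
mills 20 nm sections with finer in-plane pixels), so `dz` defaults to 20 nm
when metadata is absent, while the in-plane pixel size has **no** default —
it varies per dataset and a silent guess would scale every metric wrongly.

One coordinate convention is used everywhere: voxel `(k, j, i)` is centred at
`((i+0.5)·dx, (j+0.5)·dy, (k+0.5)·dz)`. Centroids and meshes are therefore
unbiased with respect to array orientation, and voxel→physical→voxel is the
identity (property-tested).

## Surfaces and morphometry

Surfaces are marching-cubes isosurfaces at level 0.5 of the binary role
mask, computed with the anisotropic spacing and padded by one voxel so
surfaces close at the block boundary. **No smoothing or decimation is
applied by default**: the ASD is defined on mesh vertices, so vertex density
is part of the statistic; any remeshing would silently change it. (An
isosurface of a 1-voxel structure is the octahedral dual — its enclosed
volume is d³/6, far below the voxel volume, which is one reason voxel
counting, not mesh volume, is the canonical volume measure here. Mesh
volume is reported alongside for watertight meshes and converges to the
analytic value for structures many voxels across; area and volume
convergence with refinement is tested.)

## Microdomains and cropping

A microdomain is the sphere of radius 400 nm (configurable) centred on a
caveola; by default the centre is the caveola instance's voxel centroid,
which is reproducible from the segmentation alone, and alternative centres
can be supplied as a seed CSV. Label cropping uses the voxel-centre-inside
test — unbiased when the radius is tens of voxels, as here. Mesh cropping
clips triangles exactly at the sphere: cut points solve the edge–sphere
quadratic, so they lie on the boundary, boundary triangles contribute their
inside part, and cropped areas converge to analytic values (a plane through
the centre yields πr² to well under 5%). Whole-triangle inclusion would bias
boundary-adjacent contact areas upward; nested crops (r₁ < r₂) agree with
direct crops to 1e-9 relative as long as triangles are small against
r₂ − r₁. Caveolae other than the central one are retained in the cropped
scene but spawn no nested analyses.

## Distances and contacts

ASD is vertex-to-vertex: for each PM vertex, the minimum Euclidean distance
to the ER vertex set, averaged over PM vertices; it is one-directional
(PM → ER) and never symmetrised. Nearest neighbours come from a k-d tree
(`scipy.spatial.cKDTree`), which is an exact algorithm — equality with the
O(n·m) double loop at 1e-9 relative is part of the acceptance suite. Ties
between equidistant ER vertices do not affect the distance and no
nearest-vertex identity is reported, so no tie-break is needed. A
point-to-triangle mode (`mode="surface"`) is provided and documented as a
lower bound of the vertex mode.

MAM patches live on the mitochondrial surface: faces whose three vertices
all lie within the threshold (default 20 nm, strict `<`) of the ER vertex
set belong fully; faces straddling the threshold contribute the
sub-threshold part of their area by linear interpolation of vertex
distances. This conservative-plus-clipping rule makes areas reproducible and
monotone non-decreasing in the threshold (tested). Patches are connected
components of the involved faces over shared edges. Which side of the
ER–mito interface carries "the" contact area is not derivable from a
sheet-like manual segmentation, so the mito-side figure is primary (patches
are compact on the convex mitochondrial surface) and the ER-side figure is
reported alongside. Spheres containing a mitochondrion but no ER return an
empty patch list, not an error.

Proximity events cluster PM vertices with nearest-ER distance under a
threshold (default 20 nm) into mesh-connected components; an event is
caveola-associated when its centroid lies within a Euclidean neighbourhood
(default 200 nm — a configuration choice, not a measured constant) of a
seed. Per-vertex distance fields can be exported as ASCII PLY with the
standard `quality` property for external heat-map rendering; only numeric
export is in scope.

## Summary statistics

CV = SD / sample mean. SD is the sample standard deviation (n−1); the
denominator is a documented choice with a population-SD switch for
sensitivity checks, and n = 1 yields missing SD/CV rather than zero. Median
is reported alongside the mean. MAM areas are summarised under the
`mam_positive_only` rule: microdomains without mitochondria have no MAM by
definition and are omitted — counting them as zeros would drag the mean.
Reports are deterministic; identical inputs give byte-identical CSVs, and
summary rows carry provenance (radius, thresholds, seeds, version).

## The phantom generator

Phantoms exist so every stage is testable against exact ground truth without
microscope data. All ground-truth quantities are fixed analytically *before*
rasterisation and never read back from voxels.

**Cell and membrane.** The cell is a sphere (ICC, PDGFRα⁺; default radius
700 nm, 1000 nm for the study-regime scene) or a capsule (SMC; tube radius
600 nm). The PM label is the one-voxel boundary rind of the cell mask
(6-connected erosion difference). The ER–PM gap `g` is defined from the cell
boundary to the ER's PM-facing surface; the rasterised ASD then lands within
one voxel diagonal of `g`, with the residual (the rind thickness plus
half-voxel marching-cubes offsets) shrinking as the grid refines — this is
the parameter-recovery contract the acceptance suite checks at
g = 100 nm, spacing (10, 10, 20) nm and its halved grid.

**Archetype ER.** ICC: a complete peripheral shell at depth [g, g+40) plus a
deep lattice of grid-snapped, face-abutting boxes (one connected component
with the shell via a polar strut; abutting boxes make the analytic union
volume exact). SMC: the shell restricted to angular bands — 8 longitudinal
strands, 300 nm wide, pairwise disconnected — plus a nucleus with a
perinuclear shell; strand pitch keeps the inter-strand gap small against the
gap `g`, so per-sphere ASD stays within the recovery bound. PDGFRα⁺:
parallel sheets (pitch 400 nm, thickness 40 nm) filling the interior up to
depth `g`. Real ICC ER porosity statistics are not quantified anywhere
usable, so the lattice is an explicitly parameterised stand-in, not a claim
of realism.

**Caveolae.** Flask cavities (neck radius 15 nm, bulb radius 35 nm, depth
70 nm — typical caveolar dimensions from the general ultrastructure
literature, configurable) carved into the cell at axis-aligned surface
normals; the instance label is the largest 6-connected lining cup, and the
recorded ground-truth centre is the bulb centre. The peripheral ER is built
from the uncarved cell, so flasks do not distort the gap geometry (the cup
occupies ≲2 % of a microdomain's PM area, biasing per-sphere ASD by ~1 nm).

**Mito–ER appositions.** Each designated caveola gets, at 310 nm depth, an
axis-aligned assembly: a dedicated ER sheet, a connector plate joining it to
the peripheral shell (keeping ICC ER one component), and a mitochondrion
built as a rectangular facet slab fused to an ellipsoid body. The facet
normal lies in-plane and every box bound is snapped to the voxel grid, so
the rasterised mesh gap equals the specified gap exactly (hence the gap must
be a multiple of the in-plane spacing). The sheet is inset 10 nm laterally
relative to the facet: the inset bounds how far the contact spreads onto the
mitochondrion's side walls, and the small admitted wall rim offsets the
half-voxel bevel marching cubes shaves from facet edges, so the measured
mito-side area realises the analytic facet area (within ±3 % at default
spacing on the 300 × 200 nm default facet; the 15 % recovery band in the
acceptance suite covers both spacings). The assembly depth keeps slab
corners clear of the curved shell by more than the 20 nm criterion plus
discretisation, and the facet inside the 400 nm sphere. PDGFRα⁺ phantoms
reject assemblies (sheets fill the cytoplasm and would collide); SMC
phantoms default to zero mitochondria, matching their sparse peripheral
mitochondria.

**Study-regime scene.** `generate_paper_scale_scene` fixes a 1 µm ICC with
nine caveolae — five axis-aligned ones carrying an apposition (facet sizes
rng-jittered over 240–300 × 160–200 nm) and four diagonal ones without, so
exactly 5/9 microdomains are MAM-positive and the omission rule is
exercised. The lattice sits deeper than any microdomain reaches, so the
per-sphere ER ground truth is closed-form (difference of sphere–sphere lens
volumes for the shell cap, plus the sheet and plate boxes) and lands in
[5 × 10⁶, 2.5 × 10⁷] nm³ — the generator self-check in the test suite. Per-
sphere ASD, ER volume and MAM area then fall in the regime such studies
report (distances near 100 nm, ER volumes of order 10⁷ nm³, MAM areas of
order 5 × 10⁴ nm²).

**What the phantoms do not emulate.** No raw image contrast, noise, PSF or
segmentation error — the pipeline consumes labels, and passing recovery
tests demonstrates correctness of the *geometry pipeline*, not robustness to
segmentation quality. Organelle shapes are idealised (spheres, capsules,
boxes, ellipsoids); membrane thickness is one voxel rather than a measured
bilayer; ER topology is schematic. Consequently, agreement on phantoms
bounds discretisation and algorithmic error, and says nothing about
biological variability.

## Numerical choices and degenerate inputs

* Sphere–edge intersections solve the quadratic exactly; cut points are
  cached per directed edge so adjacent faces share identical boundary
  vertices. Faces with all vertices outside are dropped even if their
  interior grazes the sphere — negligible for triangles small against the
  radius, which marching-cubes output guarantees here.
* Problem sizes: the study-regime scene is a 110 × 220 × 220 stack
  (~5.3 M voxels); generation plus the full nine-sphere analysis takes a few
  seconds, and the halved-spacing recovery check (~16 M voxels) runs in
  under half a minute. These sizes were chosen as the smallest at which the
  discretisation error curves are clearly resolved.
* Empty meshes: ASD raises, naming the empty side; MAM with empty ER returns
  no patches (legal degenerate microdomain); empty masks yield empty meshes
  and zero morphometry.
* An instance label that is not one 6-connected component triggers a
  warning, not an error — fragmented instances are a data-quality signal,
  and hard failure would block triage of exactly such data.
* TIFF containers hold up to uint16 labels; beyond that, HDF5 is required.

## Known limitations

* The vertex-based ASD depends on mesh vertex density; meshes produced by
  other reconstruction software (different smoothing/decimation) will shift
  the statistic by up to the typical inter-vertex spacing. Compare only ASD
  values produced under the same meshing policy, or use `mode="surface"`.
* MAM area is threshold-sensitive near the criterion; the threshold sweep in
  the tests quantifies this monotone dependence.
* Voxel-centre cropping under-counts partial boundary voxels; at r = 400 nm
  and ≤20 nm voxels the bias is below one percent, but it grows for radii
  approaching the voxel size.
* The caveola-association neighbourhood (200 nm) is a configuration default
  with no measured basis; report it with any proximity-event counts.
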