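# microdomain3d

Quantitative 3D geometry of ER–plasma-membrane junctions, caveolar
microdomains and mitochondria-associated membranes (MAM) in segmented
volume-EM label stacks.

Serial FIB/SEM imaging of gut-motility cells — smooth muscle cells (SMC),
interstitial cells of Cajal (ICC) and PDGFRα⁺ cells — yields manually
segmented 3D label volumes of the plasma membrane (PM), ER/SR, mitochondria
and caveolae. Around each caveola, the Ca²⁺-relevant geometry is confined to
a spherical **microdomain** of radius 400 nm. This package measures, per
microdomain:

* the **average surface distance** from the PM to the ER. With S(PM), S(ER)
  the vertex sets of the two triangle meshes and ‖·‖ the Euclidean norm,

      d(p, S(ER)) = min over s in S(ER) of ‖p − s‖
      ASD(PM, ER) = (1 / |S(PM)|) · Σ over p in S(PM) of d(p, S(ER))

  The statistic is one-directional (PM → ER) and defined on vertices; a
  point-to-triangle variant is available as a documented lower bound.
* the **ER volume** inside the sphere (voxel counting),
* the **MAM contact area**: the part of each mitochondrial surface within
  20 nm of the ER, as connected patches with clipped boundary faces.
  Spheres without mitochondria have *no* MAM by definition and are omitted
  from — not zeroed in — MAM summaries,
* sub-20 nm **ER–PM proximity events**, flagged when they sit near a caveola,
* summary statistics across spheres: mean, median, sample SD, and the
  **coefficient of variation** CV = SD / mean.

Because the microscopy data behind this kind of study are typically not
deposited, the package ships a first-class **synthetic phantom generator**:
rasterised cells with line-like (SMC), mesh-like (ICC) or sheet-like
(PDGFRα⁺) ER, flask-shaped caveolae, and mitochondria with flat apposition
facets — all constructed analytically first, so the ER–PM gap, per-facet MAM
area, structure volumes and caveola centres are exact ground truth for
parameter-recovery tests.

## Worked example

```python
import numpy as np
from microdomain3d import (
    generate_paper_scale_scene, extract_caveola_seeds, analyze_scene, summarize,
)

vol, gt = generate_paper_scale_scene(rng_seed=1)     # 9 caveolae, 5 with a MAM
seeds = extract_caveola_seeds(vol, rng_seed=1, n=9)  # random caveola centroids
metrics = analyze_scene(vol, seeds)                  # one record per 400 nm sphere

asd = summarize([m.asd_nm for m in metrics])
mam = summarize(
    [m.mam_area_total_nm2 or np.nan for m in metrics],
    rule="mam_positive_only", flags=[m.has_mito for m in metrics],
)
print(f"ASD {asd.mean:.1f} nm (CV {asd.cv:.3f}) over {asd.n} spheres")
print(f"MAM {mam.mean/1e3:.1f} x 10^3 nm^2 over {mam.n} MAM-positive spheres")
```

prints (phantom generated with `rng_seed=1`):

```
ASD 90.3 nm (CV 0.029) over 9 spheres
MAM 47.7 x 10^3 nm^2 over 5 MAM-positive spheres
```

The ASD of ~90 nm recovers the phantom's constructed 100 nm ER–PM offset to
within half a voxel diagonal (the residual is the one-voxel PM rind plus
marching-cubes discretisation); 5 of 9 spheres contain a mitochondrion, so
only those enter the MAM mean — the generator places apposition facets of
~38–60 × 10³ nm² beneath five caveolae and none beneath the other four.

The same pipeline runs from the shell:

```sh
microdomain3d simulate --archetype icc --seed 7 --out scene.h5
microdomain3d analyze --volume scene.h5 --out-dir results/ --n-spheres 3 --seed 0
```

`analyze` writes `per_sphere.csv` (one row per microdomain) and
`summary.csv` (one row per metric with n, mean, median, sd, cv and full
provenance). Re-runs with the same seeds are byte-identical.

## Layout

| module | contents |
| --- | --- |
| `io_volumes` | TIFF+sidecar / HDF5 label stacks, voxel spacing, caveola seed extraction |
| `meshing` | marching-cubes surfaces in nm, surface-area / volume morphometry |
| `microdomain` | 400 nm sphere ROIs, exact triangle clipping, label cropping |
| `contacts` | ASD, proximity events, MAM patches, per-vertex distance-map export |
| `stats` | summary statistics, MAM-positive-only rule, CSV reports |
| `synthetic` | phantom generator with analytic ground truth |
| `pipeline` | per-sphere orchestration (`analyze_scene`) |
| `cli` | `microdomain3d simulate` / `microdomain3d analyze` |

See `docs/methods.md` for the geometric conventions, parameter defaults and
known limitations.
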