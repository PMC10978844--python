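# cristakit

3D quantification of mitochondrial ultrastructure — cristae widths,
inter-crista distances, membrane roughness, and classical shape measures —
from isotropic-voxel electron-microscopy label volumes (e.g. FIB-SEM at
~5 nm/voxel).

## Who this is for

Groups studying mitochondrial dynamics segment the organelle into four
classes per voxel — background, mitochondrion interior, crista membrane
(CM), and intracristal space (ICS) — and then need reproducible,
orientation-free 3D statistics for hundreds of organelles.  Manual
distance measurements between membranes are ill-defined (where do the
endpoints go?) and 2D profile measurements are biased by the slicing
direction.  `cristakit` provides the measurement layer: it consumes label
volumes (multi-page TIFF or HDF5) from any segmentation pipeline and emits
per-mitochondrion CSV reports.

## The method

**Count-curve persistence.**  The CM ∪ ICS mask of each mitochondrion is
grown (or shrunk) by PDE-based subpixel morphology — the first-order
upwind scheme for unit-speed front propagation, extended to 3D over the
six face neighbours:

```
dilation:  U ← clip₀¹( U + λ·√( Σ_d max(0, U_d − U)² ) )
erosion:   U ← clip₀¹( U − λ·√( Σ_d max(0, U − U_d)² ) )
```

With λ = 0.1, ten subpixel iterations advance the 0.5-level front by one
voxel (one *full round*).  After every iteration the fuzzy state is
binarized at 0.5 and topological features are counted: **holes** under
dilation (26-connected components of the inverted mask, clipped to the
organelle, minus the outer background), **objects** under erosion.  The
smoothed count-vs-iteration curve peaks where most membrane surface makes
contact, so

* dilation peak location  = ½ · mean inter-crista distance,
* erosion peak location = ½ · mean crista width,
* the curve's FWHM grows with membrane roughness/curvature.

**Shape measures.**  Volumes are voxel counts × voxel³ (125 nm³ at 5 nm);
`matrix = mitochondrion − CM − ICS` holds exactly per instance.  Surface
areas come from the marching-cubes mesh of each mask (with a
shrink-resistant mesh regularisation that puts a digitized ball within
~2% of 4πr²).  Instances touching the volume border or smaller than 25³
voxels are flagged and excluded.

**Multiplanar fusion.**  For segmentation itself the package provides the
nine-plane geometry (three axis-aligned + six diagonal reslicing planes,
pairwise ≥ 45°): reslice, run any per-slice classifier, and fuse the
per-plane softmax scores back on the canonical grid by weighted averaging
and argmax.  The classifier is pluggable; a seeded noisy oracle is included
for testing.

**2D → 3D error analysis.**  Random plane/slice profiles of each instance
pair 2D area/perimeter with true 3D volume/surface; a sliding window
(ω = 0.025·max, ≥ 10 points per window) estimates the conditional mean μ
and spread σ, and the **average error** (1/T)·Σ (upper−lower)/(2·mean)
— σ/μ when no clamping occurs — quantifies how unreliable single-profile
2D estimates are and how the error shrinks ≈ 1/√n when n profiles are
averaged.

## Worked example

```python
from cristakit import (RunConfig, make_crista_phantom, extract_instances,
                       persistence_curve, summarize_curve, apply_validity_filters)

cfg = RunConfig()                       # lambda=0.1, threshold 0.5, skip 5 iters
ph = make_crista_phantom(envelope_radius=26, sheet_width_voxels=6,
                         sheet_spacing_voxels=6, n_sheets=3,
                         roughness_amplitude_voxels=1.0, rng_seed=42)
records, instances = extract_instances(ph.volume)
rec = records[0]
print(f"mito volume   : {rec.mito_volume_nm3/1e6:.2f} x 10^6 nm^3")
for mode, name in [("erosion_objects", "crista width"),
                   ("dilation_holes", "intercristal distance")]:
    curve = persistence_curve(instances[0], mode, cfg, max_full_rounds=8)
    s = apply_validity_filters(summarize_curve(curve, cfg), curve,
                               rec.cm_voxels, rec.ics_voxels)
    print(f"{name}: {s.distance_nm:.1f} nm "
          f"(max at round {s.max_location_rounds:.1f}, FWHM {s.fwhm_nm:.1f} nm)")
```

prints

```
mito volume   : 9.23 x 10^6 nm^3
crista width: 27.0 nm (max at round 2.7, FWHM 4.4 nm)
intercristal distance: 31.0 nm (max at round 3.1, FWHM 5.0 nm)
```

The phantom's sheets are 6 voxels (30 nm) wide and 6 voxels apart; the
erosion and dilation peaks at rounds 2.7 and 3.1 recover both to within
half a round (±2.5 nm), the resolution of one voxel layer of morphology.

A CLI mirrors the library: `cristakit phantom|measure|persist|fuse|relate2d3d`
(see `cristakit --help`); `measure` and `persist` write one CSV row per
mitochondrion.

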