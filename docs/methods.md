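# Methods

This note records the models, numerical choices and study conditions
behind `cristakit`, and what its synthetic benchmarks do and do not show
about real electron-microscopy data.

## Subpixel morphology

Binary masks are evolved as fuzzy fields U ∈ [0,1] under the explicit
first-order upwind scheme for front propagation at unit normal speed,
summed over the six face-neighbour directions and clamped to [0,1] after
each update.  Updates are synchronous: Uⁿ⁺¹ is computed entirely from Uⁿ.

* **Time step λ** (default 0.1, must divide 1 exactly): the front advances
  λ voxels per iteration, so 1/λ iterations form one *full round* — the
  subpixel analogue of adding/removing one voxel layer.  Smaller λ refines
  the distance resolution of the filtration at proportional cost.
* **Boundary handling**: out-of-grid neighbours are treated as equal to
  the centre voxel (zero flux).  This keeps erosion and dilation exact
  algebraic mirrors — eroding M equals 1 − dilating (1 − M), asserted to
  1e-12 in the tests — and prevents fronts from leaking through the
  volume border.
* **Binarization** uses ≥ 0.5 (ties to foreground, fixed for
  determinism).  The fuzzy state is never overwritten by its binarization;
  only the counting step sees the thresholded mask.
* **Accuracy**: against a Euclidean distance-transform oracle, k full
  rounds agree with the k-voxel offset surface up to a one-voxel shell on
  cubes and balls; a planar front advances 1.0 ± 0.15 voxels per round.
  Like all first-order upwind schemes, corners round off: the scheme
  propagates the Euclidean (not chessboard) distance.

## Count-curve persistence

For one mitochondrion, the filtration seed is CM ∪ ICS and the bounding
mask is the whole organelle.  After every subpixel iteration:

* **dilation/holes**: the binarized state is clipped to the organelle mask
  (so growth cannot escape the organelle), inverted, and its 26-connected
  components counted; 1 is subtracted for the component surrounding the
  organelle, flooring at 0.
* **erosion/objects**: 26-connected foreground components are counted
  directly.

26-connectivity is applied to the inverted mask as well, although the
usual digital-topology pairing would use 6-connectivity for the
complement; the convention is exposed as `RunConfig.connectivity`.

The raw integer curve is smoothed with a Gaussian of **σ = 2 subpixel
iterations** — wide enough to suppress single-iteration jitter, narrow
enough to move a symmetric peak by < 0.5 iteration.  The first
**5 subpixel iterations** (half a round) are excluded from the search:
they count staircase artefacts of the initial voxelization.  The summary
reports:

* `max_location_rounds` — index of the smoothed maximum (first index on
  ties) × λ.  Interpreted as half the average minimum distance across the
  region, so `distance_nm = 2 · max_location_rounds · voxel_size` and
  `half_distance_nm` is also emitted for comparison with conventions that
  report half-widths.
* `fwhm_iters` / `fwhm_nm` — distance between the two half-maximum
  crossings, located by linear interpolation around the peak.  If the
  curve never falls back to half maximum within the computed range the
  right crossing is taken at the last index and the summary is flagged
  `truncated` (excluded from population statistics by default).
* Validity filters: distance summaries require a maximum raw hole count
  ≥ 1 (there must be distinct membrane branches to measure between);
  width summaries require non-empty CM **and** ICS volumes.

`max_full_rounds` defaults to 20 (100 nm of growth at 5 nm voxels), enough
to close all gaps at the scale of mammalian cristae.  Runs stop early at
fixed points (e.g. fully eroded seeds).

## Phantoms and the corrugation floor

The generators produce label volumes with analytically known geometry;
ground truth is always derived from the generating parameters, never from
the voxelization.

A geometric fact discovered during development and honoured throughout:
**perfectly flat parallel membranes are degenerate for count-curve
persistence.**  If the gap between two surfaces is constant, contact under
dilation happens simultaneously everywhere, so no cavity is ever enclosed
and the hole count stays 0; likewise a perfectly uniform sheet erodes away
in one instant without fragmenting, so the object-count curve has no
interior peak.  The measurement is well defined exactly because real
membranes undulate: contact is progressive, rings of early contact enclose
pockets of late contact, and the count peaks where *most* of the surface
meets — half the mean separation.

The generators therefore apply a small deterministic zero-mean egg-carton
corrugation (`A·sin(2πx/P)·sin(2πy/P)`, period P = 14 voxels) to the
membrane surfaces:

* **plate pair**: amplitude 1 voxel on the second plate; the realised mean
  facing-surface gap equals `separation_voxels` exactly (a −0.5 offset
  cancels the ceiling bias of voxelization).
* **crista phantom**: base amplitude 0.75 voxels on every sheet surface,
  with consecutive surfaces in phase quadrature so each local width and
  gap varies with amplitude √2·A about its nominal value.
  `roughness_amplitude_voxels` adds on top of this floor; feasibility
  requires √2·(base + added) below the sheet width and spacing, enforced
  at construction.  Both corrugations can be set to 0 for truly planar
  geometry (with the degeneracy above).

Recovery under the defaults: spacings/widths of 4, 6, 8 voxels are read
out to within 0.1–0.3 rounds of s/2 and w/2, and the FWHM increases
strictly with added roughness amplitude 0 → 1 → 2.

**What the phantoms do not emulate**: grayscale EM texture and noise
(phantoms are label volumes; the fusion stage has its own noisy synthetic
classifier), curved/branching crista sheets, crista junctions, anisotropic
voxels, or segmentation errors.  Passing tests show the *measurement*
layer recovers known geometry; they say nothing about segmentation quality
on real micrographs.

## Shape measures

Volumes are voxel counts × voxel³; the matrix volume identity
(mito − CM − ICS) is exact in voxel units by construction.  Surface areas
are marching-cubes mesh areas at iso-level 0.5 with the mask padded by one
background voxel so meshes close at crop borders.  The raw mesh of a
binary volume is a chamfered staircase that overestimates smooth surfaces
by ~9%; the default therefore applies 3 iterations of shrink-resistant
(Humphrey/HC) Laplacian smoothing (α = 0.1, β = 0.5), bringing digitized
balls (r = 8–20) within ~2% of 4πr² while keeping blocky shapes above the
equal-volume-sphere lower bound.  `smoothing_iterations=0` recovers the
raw mesh (a single voxel is then exactly the √3-area octahedron).

The matrix-facing crista surface is realised as the mesh of CM ∪ ICS (the
union's boundary is the CM face toward the matrix); the intracristal-side
surface is the mesh of ICS alone.  Cleanup fills background cavities
< 100 voxels that are fully enclosed by CM/ICS (relabelled as ICS) and
opens the organelle mask with a radius-1 ball; both sizes are parameters,
as no principled universal value exists.  Instance extraction uses
26-connectivity; organelles touching any volume face or smaller than 25³
voxels are reported but flagged excluded.

## Multiplanar fusion

The nine reslicing planes are the three axis-aligned normals plus the six
axis-pair diagonals — the canonical set with pairwise angles ≥ 45°.
Reslicing uses rotation about the volume centre into a cube large enough
to contain any rotation (parity-matched so axis-aligned reslicing is an
exact integer shift); nearest interpolation for labels, trilinear for
probabilities.  Fusion resamples each plane's class scores back to the
canonical grid, averaging with per-sample in-volume weights so that
out-of-view samples are excluded rather than counted as background votes,
then renormalises and takes the argmax (averaging in the canonical frame).
The per-slice classifier is an interface; the bundled synthetic predictor
one-hot-encodes ground truth and flips each pixel to a uniformly chosen
wrong class with a given probability, seeded for reproducibility.

## 2D → 3D error analysis

Profiles are drawn uniformly over the nine planes and, within a plane,
uniformly over slices intersecting the instance.  2D area is the pixel
count × voxel²; 2D perimeter is the 0.5-level marching-squares contour
length of the profile after a light Gaussian pre-smoothing (σ = 0.8 px) —
the raw staircase contour overestimates a digitized disc's circumference
by ~6–7%, the smoothed one is within ~1–2%.

The sliding window has width ω = 0.025 · max(2D values) and stride ω/4
(results change < 1% between strides ω/2 and ω/8).  Windows with fewer
than 10 points terminate the sweep once data has begun; sparse windows
*before* the first retained one are skipped rather than aborting the map.
Negative lower bounds (μ − σ < 0) are clamped to 0.  The average error is
the mean of (upper − lower)/(2·mean) over retained windows — equal to σ/μ
per window when no clamping occurs.  `subset_error` repeats the analysis
on averages of n randomly drawn profile pairs (without replacement within
a repetition); on a benchmark of spheres with radii uniform in [5, 15]
voxels the error falls monotonically with n and the error ratio between
n = 1 and n = 25 is ≈ 5, the 1/√n law.  Benchmark sizes in the test suite
(40 spheres × 30 profiles, 1 000 repetitions) were chosen to estimate
these ratios stably at desk scale.

## Known limitations

* Anisotropic voxels are rejected; all statistics assume isotropy.
* Hole counting follows the 26/26 connectivity convention above, which is
  not a strict digital-topology complement pairing.
* The max-location read-out quantises to the λ grid; summaries inherit a
  ±½-round resolution on distances (±2.5 nm at λ = 0.1 and 5 nm voxels).
* Mesh regularisation slightly shrinks thin-sheet meshes (~10–15% for
  1-voxel sheets); for ratio-style analyses on thin structures use the
  raw mesh and compare like with like.
* Organelles with touching membranes merge into one instance; the
  instance layer has no splitting heuristic.
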