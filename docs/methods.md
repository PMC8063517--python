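# Methods

This note documents the models, conventions and numerical choices behind
each measurement, what the synthetic phantoms do and do not emulate, and
the known limitations.  All voxel grids are `(z, y, x)`-indexed, origin 0;
calibration (physical voxel size and unit) is carried, never converted, and
every statistic reports in the calibration unit.

## Image model and preprocessing

Input stacks are 8-bit, 16-bit or float32 multi-page TIFFs.  Calibration is
read from the TIFF X/Y resolution tags and, where present, ImageJ-style
`spacing`/`unit` metadata for the z axis; missing tags fall back to unit
spacing with a warning.  Binary masks use foreground = bone.

**Gaussian blur.** Separable convolution with the kernel truncated at
radius ⌈3σ⌉ (renormalised) and reflective borders, computed in float64 and
rounded back for integer depths.  Constant images are fixed points and
total intensity is conserved to float tolerance.

**Auto-threshold ("Default", dark background).** The iterative-intermeans
selector on the full-stack histogram, binned at native depth (65536 bins
for 16-bit): ascend the split point while `t(s) ≥ s + 2`, where
`t(s) = (mean below s + mean above s)/2`, and return the first bin above
the rounded stopping value as the lower bound; the upper bound is the
maximum representable intensity.  This reproduces the classic ImageJ loop
including its early stop, which on strongly mass-skewed bimodal histograms
can sit one or two bins below the textbook intermeans fixed point (the test
suite pins this behaviour).  Note that interactive ImageJ buckets 16-bit
histograms into 256 bins between the display limits before thresholding,
so absolute levels from that dialog can differ; the full-depth histogram is
the better-defined contract.  The threshold is invariant under uniform
scaling of histogram counts.

**Connected components and Purify.** Foreground uses 26-connectivity and
background 6-connectivity throughout (the standard dual pair).  Components
are labelled in decreasing size with ties broken by the first voxel in
raster order.  Purify keeps the largest foreground particle, then keeps the
largest background region and fills every other background component
(enclosed marrow cavities) as bone; the result always has exactly one
component of each phase and Purify is idempotent.  When several
boundary-touching background regions exist only the largest survives — a
deliberate, deterministic choice documented here because legacy tools are
ambiguous on this corner case.

## Connectivity (Euler characteristic)

The bone phase is modelled as the union of closed unit voxel cubes (the
continuous counterpart of 26-connected digital foreground).  Then

χ = V − E + F − C

over the distinct vertices, edges, faces and cubes of that union.  The
implementation assigns every cell to its minimal lattice corner, which
turns χ into a sum over 2×2×2 neighbourhoods of a 256-entry lookup table.
The table is generated programmatically from this definition at import
time — there is nothing transcribed — and a second, independent code path
(vectorised distinct-cell counting) is cross-checked against it in the
tests together with a set-based brute-force oracle.

**Edge correction.** A scanned specimen continues beyond the stack, so χ of
the image overcounts cells lying on the bounding-box planes.  Weighting
every cell by 1/2 per box plane containing it (1/2 on a face, 1/4 on a box
edge, 1/8 at a box corner — its share when space is tiled with abutting
subvolumes) gives the corrected χ − Δχ, computed in exact integer eighths
(`fractions.Fraction` in the API).  Interior-only structures have Δχ = 0.
Connectivity and its density follow as

Conn = 1 − (χ − Δχ),  Conn.D = Conn / TV,

with TV the full calibrated stack volume.  Conn is only meaningful on a
purified (single-particle, cavity-free) mask; the functions themselves
accept any mask.

## Volume fraction and surface area

BV/TV is plain voxel counting times voxel volume; BV/TV is
calibration-invariant while BV and TV scale with it.  The surface mesh is
marching cubes at the 0.5 iso-level of the zero-padded binary field
(midpoint vertex placement).  The raw staircase mesh of a digitised sphere
overstates area by a resolution-independent ≈9 %, so the area measurement
applies 20 Taubin smoothing passes (λ = 0.5, ν = −0.53) to the mesh first:
staircase bumps flatten while planar faces stay planar.  Measured errors:
+0.5 % on a radius-20 digitised ball, −2 % on a stack-spanning slab (the
residual comes from chamfered edges).  `surface_area(mask,
smooth_iterations=0)` returns the raw-mesh value.  Area assertions anywhere
should use relative tolerances; meshing choices legitimately differ at the
percent level between implementations.

## Local thickness (Tb.Th) and separation (Tb.Sp)

Model-independent maximal-sphere thickness in three exact, deterministic
stages (no RNG anywhere in this path):

1. **Distance transform** — exact Euclidean distance to the nearest
   background voxel centre, held as squared integers internally.
2. **Distance ridge** — voxels whose inscribed sphere is not contained in a
   26-neighbour's sphere (`r_q ≥ r_p + |q−p|`).  This local criterion keeps
   a superset of the true ridge, which leaves painted values unchanged and
   only costs time.
3. **Sphere painting** — every ridge sphere writes its diameter into all
   voxels strictly inside it; each voxel keeps the maximum.

The reported diameter is `(2d − 1) · spacing` for EDT value `d`: the
distance to a background voxel *centre* overshoots the phase boundary by
half a voxel per side.  This makes odd-thickness slabs exact and
even-thickness slabs one voxel low (the unshifted convention errs in the
opposite direction); a digitised ball of radius r reports `2r` to within
one voxel.  `mask_artefacts` (default on) masks the painted map to the
measured phase, removing sphere-overhang values outside it, so statistics
(mean, SD with n-denominator, max over finite voxels) cover the phase
exactly.  Tb.Sp is the identical computation on the inverted mask.  At the
stack border the distance transform sees no background beyond the image, so
border-bounded cavities measure as if the structure continued — the
standard convention, worth remembering when specimens do not fill the
field of view.  Isotropic calibration is required; anisotropic inputs are
rejected rather than silently mis-measured.

## Degree of anisotropy (MIL)

For each of `n_directions` random unit vectors (normalised Gaussian
triples, seeded), a bundle of `n_lines` parallel lines covers the stack
cross-section on a jittered grid and is walked at `increment` voxels
(defaults 2000 / 10000 / 1.73 — the recommended minimums).  MIL(ω) = total
bone path length / number of bone intercepts, where a foreground run
truncated by the volume border counts half (it may be a partial
trabecula).  The point cloud ω·MIL(ω), augmented with its antipodes, is
fitted with a least-squares quadric constrained to an ellipsoid
(recentring at −A⁻¹b, eigendecomposition of the recentred form; non
positive-definite fits are rejected), and

DA = 1 − r_min / r_max ∈ [0, 1).

MIL sampling is stochastic: across-seed spread shrinks as directions and
lines grow (tested), and different MIL implementations carry systematic
biases of a few percent, so DA values should be compared within one
implementation and settings chosen by sensitivity analysis.

## Ellipsoid factor

EF = a/b − b/c for the semi-axes a ≤ b ≤ c of locally maximal inscribed
ellipsoids: +1 in the rod limit, −1 in the plate limit, 0 for a sphere.
Seeds come from the distance ridge (normalised distance ≥
`distance_threshold`, default 0.6) and/or a topology-preserving 3D
skeleton, decimated to every `skip_ratio`-th point.  Growth from each seed
has three phases, each dilating by `vector_increment` and probing
`n_vectors` seeded-uniform surface directions until `contact_sensitivity`
probes hit background: a sphere (whose centre may drift up to `max_drift`
away from first contact), a circular expansion perpendicular to the
contact axis, and expansion of the last axis.  Because a stopping
iteration may carry a single contact vector, axes are oriented from a
denser probe ring at the stopping radius via the dominant eigenvector of
the contact covariance — robust to the antipodal contacts of plates.  The
whole fit repeats `runs` times; each bone voxel averages the EF of the
`weighted_average_n` largest (by volume) ellipsoids containing it
(volume-ranked, unweighted mean), voxels covered by none stay NaN, and the
median is the headline statistic.  Flinn ratios (a/b, b/c) per ellipsoid
are exported for fabric diagrams; plotting is left to the caller.
Defaults follow the standard worked-example parameter set (100 vectors,
increment 0.435, skip 10, sensitivity 1, 50 iterations, drift 1.73, 3
runs, average over 3, minimum semi-axis 1).  With a fixed seed the map is
bit-for-bit reproducible; across seeds the phantom sign contract (rod
median > 0.5, plate median < −0.5, ball within ±0.1 of 0) holds at every
tested seed.

## Fractal dimension

Box counting: tile the stack from the origin with cubes of the given edge
lengths (default: powers of 2 from min(shape)/4 down to 1), count occupied
boxes, and take the negative least-squares slope of log N against log
size.  A jitter mode averages counts over 8 half-box-shifted origins to
reduce grid-placement bias and makes the estimate translation-stable.  The
dimension of voxel structures lies in [0, 3]; a fully recursed order-4
Menger sponge (81³, holes down to single voxels) yields log 20 / log 3 to
three decimals because its box-count series is exactly geometric.

## Phantoms

`phantoms.generate` digitises analytic shapes — a voxel is foreground iff
its centre satisfies the shape inequality, centred on an integer voxel so
digitised radii match their analytic values — and returns the mask together
with an expectation record (χ, voxel counts, thickness, DA/EF signs,
fractal dimension where defined) that the test suite verifies against the
corresponding measurement module.  The `blurred_noise` phantom (Gaussian
random field, σ = 3 voxels, periodic boundaries, thresholded at its median
so BV/TV = 0.5) is the isotropy reference.  Phantoms emulate geometry and
topology only: there is no scanner noise, beam hardening, partial-volume
greyscale, or biological irregularity, so passing phantom tests
demonstrates algorithmic correctness, not robustness to acquisition
artefacts — that is what sensitivity analyses on real data are for.

## Pipelines, seeding, determinism

A pipeline (INI config or CLI) executes steps in order against a shared
results table and writes CSV with full float precision (`repr`
round-trip).  The single global seed fans out per step as
`crc32(f"{seed}:{step}") & 0x7FFFFFFF`, so adding a step never perturbs
earlier steps' randomness; a run is a pure function of (input bytes,
config, seed) and reruns are byte-identical.  Thickness, volume fraction,
surface area, connectivity and fractal dimension contain no randomness at
all.

## Problem sizes used in validation

The shipped tests and the acceptance script run on desk-scale phantoms
chosen to exercise every code path with comfortable analytic margins:
32–81³ volumes, DA at 150–400 directions × 300–400 lines, EF with single
runs over decimated seeds.  These finish in seconds to a few minutes on
one CPU; the defaults users get (recommended minimums for DA, the standard
EF schedule) are the full-strength settings.

## Known limitations

- Anisotropic voxels are rejected by thickness, DA and EF rather than
  resampled; resample upstream if needed.
- The threshold reproduces the legacy interactive loop, including its
  early-stop quirk; histograms with extreme mass skew can threshold a bin
  or two away from the textbook intermeans fixed point.
- Surface area carries residual mesh bias at sharp edges (≈2 % on boxes)
  even after Taubin smoothing.
- The EF growth schedule is a compact reimplementation of the
  seeded-ellipsoid idea; absolute EF values are implementation-dependent
  (as they are between published tools), and only seeded reproducibility
  and the phantom sign contract are guaranteed.
- Images are strictly 3D spatial; channels, time axes and 2D variants are
  out of scope.
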