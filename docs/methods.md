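# Methods

`cordprop` propagates spinal-cord contours drawn on a planning kVCT scan
onto daily MVCT guidance scans by intensity-based deformable image
registration, scores the resulting auto-contours slice by slice against
reference contours, and accumulates the delivered dose to the cord
through the recovered transforms.  This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Registration model

Registration estimates a map `T(x)` from planning-frame (fixed) to
guidance-frame (moving) patient coordinates, in millimetres, by
maximising the mutual information (MI) between the fixed intensities at
sample points `x` and the moving intensities at `T(x)`.  The fixed and
moving roles follow the Transformix convention: because `T` maps fixed
points into the moving frame, the planning contour vertices are carried
to the guidance scan by applying `T` directly.

Transform stages are composed left to right; each stage is fitted with
its predecessors frozen.  The available models are

| stage        | parameters | notes |
|--------------|-----------:|-------|
| translation  | 3          | mm offsets |
| rigid        | 6          | Euler angles about the fixed-volume centre, then translation |
| affine       | 12         | centred 3×3 matrix + translation |
| bspline      | 3 / control point | cubic free-form deformation, isotropic lattice |
| couch_shift  | 3 (fixed)  | a recorded radiographer shift, never optimised |

The default stage list is `affine, bspline` with a 15 mm control-point
spacing, the combination that maximises contour conformity; the spacing
is swept over 5–25 mm by `spacing_sweep`.

### Metric

The public `mattes_mutual_information` hard-bins both intensity axes
(64 bins over the in-overlap range, HU clamped to [−1024, 3071]) so
that, for a volume against itself under dense sampling, MI equals the
marginal histogram entropy exactly — the oracle identity the tests
assert to 1e-6.  The optimiser instead uses the Mattes formulation: a
zero-order window on the fixed axis and a cubic-B-spline Parzen window
on the moving axis, which makes the estimate differentiable in the
moving values and yields an analytic gradient with respect to every
transform parameter.  Samples that map outside the moving volume are
discarded, never zero-filled; an overlap below 10 % is an error.

64 bins (not the more conventional 32) are the default because the
deformation signal inside uniform soft tissue is carried by ±25 HU
texture: at 32 bins over the full HU range that texture falls inside a
single bin and is invisible to the metric, and nonrigid recovery in
tissue degrades measurably.

Moving-image values (and gradients) are read through a (¼, ½, ¼)
stencil at ±half a fixed-slice width in continuous z.  Without it, the
effective through-slice blur of trilinear interpolation depends on
where a sample falls between two 6 mm guidance slices, which imprints a
periodic ripple on the metric and biases the recovered z-alignment by
up to ±1.5 mm — a systematic error larger than everything else in the
pipeline.  The stencil makes the effective blur phase-independent; the
residual z bias on ground-truth phantoms is below 0.25 mm.

### Optimiser

Plain gradient ascent with a scalar step stalls here: the MI gradient
components span orders of magnitude between in-plane and through-slice
directions and between global and local parameters.  The optimiser is
therefore iRprop⁻ — per-parameter step sizes, grown 20 % while the
gradient sign is stable and halved on a sign flip, with angles and
matrix entries scaled to mm-equivalent units.  It runs over a
multi-resolution pyramid (default shrink 4/2/1) whose per-axis shrink
factors are scaled by voxel spacing so the coarse grids are roughly
isotropic and the already-coarse guidance z-axis is not degraded
further.  Coarse levels redraw their sample set (default 4096 in-mask
voxel centres) every iteration; the finest level uses a single large
fixed draw (≥32 768) so its ascent is deterministic and terminates
cleanly on a relative-plateau test.  The best-metric parameter vector
seen within a level, not the last one, is carried forward.  All
randomness flows from the config seed; a fixed seed reproduces the
fitted parameters bit for bit.

### B-spline regularisation

An unregularised free-form deformation overfits: control points in
featureless tissue drift without bound on gradients generated by image
noise (tens of mm on phantoms).  A discrete bending-energy penalty —
the mean squared second difference of the coefficient lattice — is
subtracted from the objective with weight 1.0 (config
`bspline_bending_weight`).  The weight is the joint operating point of
two ground-truth requirements: recovering a 5 mm smooth warp to better
than 1 mm mean landmark error, and not inventing deformation where
there is none (sub-0.15 mm wobble at the 4 mm-radius cord in the
zero-deformation limit).  Weaker weights favour the former, stronger
ones the latter.

## Body mask

The registration samples only inside the patient: the mask is the
largest 26-connected component of voxels ≥ −400 HU on the planning
scan, which separates patient from air and drops the treatment couch (a
disjoint above-threshold component).  The threshold sits between air
(≈ −1000 HU) and tissue (≳ −200 HU); ties between equal-size components
break deterministically to the lowest raster index, with a warning.
The mask is computed in 3D; no morphological closing is applied by
default.

## Contour propagation

Every vertex (x, y, z) of every planning contour is mapped through the
chain.  Mapped polygons generally leave their plane; each is reassigned
to the nearest guidance slice plane (within half a slice spacing — 
polygons beyond the stack are dropped with a warning) and its vertices
are orthogonally projected onto that plane.  When two 3 mm planning
slices land on one 6 mm guidance slice their union polygon is taken.
Mapped polygons with fewer than three distinct vertices or area below
1 mm² are dropped; if nothing survives, the propagation errors rather
than returning an empty structure.

## Conformity metrics

Per matched slice pair (planes within half the reference slice gap):

* **CI** — Jaccard ratio of intersection to union area;
* **DBC** — Euclidean distance between area centroids;
* **DTC** — the two regions are rasterised at 0.1 mm; over pixels of
  the symmetric difference, the distance to the nearest intersection
  pixel is averaged.  For disjoint regions the distance is taken to the
  other region instead, and the record is flagged;
* **left–right / anterior–posterior differences** — signed differences
  of the x- and y-extents (test minus reference), +x patient left,
  +y patient posterior.

Areas and centroids use exact polygon clipping; only DTC is rasterised.
Aggregation reports median, mean and sample SD per metric, SD/√n as the
uncertainty on the mean, and a seeded 2000-resample bootstrap SD as the
uncertainty on the median.  The inter-observer analysis compares every
unordered pair of observers (15 pairs for six observers), averages each
observer's N−1 comparisons with that observer as test (signed metrics
flip for the reversed orientation), and reports the plain mean of the
pairwise values as the cohort estimate.

## Dose accumulation

Cord voxels are the planning-grid voxel centres inside the slice
polygons (boundary inclusive).  For each fraction the voxel centre is
mapped by that fraction's chain, any recorded couch shift is added
after the mapping, and the fraction dose grid is sampled trilinearly.
Doses are summed over fractions; a voxel whose mapped position leaves
any fraction's grid is flagged and excluded from summary statistics —
only the region covered by every fraction is scored.  D2%, the
near-maximum dose, is the smallest dose among the ⌈0.02 n⌉
highest-dose voxels (equal voxel volumes); a DVH-interpolated variant
is available behind a flag.  The DVH is tabulated on a 0.1 Gy grid.

## The synthetic phantom

No patient data accompany the method, so every ground-truth check runs
on a synthetic neck phantom.  The phantom is a *continuous* analytic HU
model: an elliptical soft-tissue body (semi-axes 75 × 58 mm) tapering
25 % toward superior slices, a 4 mm-radius cord inside a 7 mm spinal
canal and an 8–13 mm bony ring whose density undulates sinusoidally
along z with a 24 mm period (vertebral bodies and discs), a detached
couch slab, and a smooth random texture field (±25 HU, 4 mm in-plane /
9 mm through-slice correlation) built from a sum of 160 random cosines
so it can be evaluated at any point without a preferred lattice.

Both scan analogues *sample* this continuous model, as real scanners
sample a continuous patient.  The planning analogue (2.148 × 2.148 ×
3 mm voxels) is block-averaged from a 2× finer rasterisation, emulating
archival down-sampling.  Each guidance analogue (0.754 × 0.754 × 6 mm)
evaluates the model at the pre-deformation position `T⁻¹(y)` of each
voxel — the inverse of the analytic ground-truth chain is computed by
fixed-point iteration, with residuals below 10⁻³ mm — and adds
independent Gaussian HU noise (default SD 20) to emulate the poor
signal-to-noise of megavoltage imaging.  An earlier design that
resampled the discretised planning volume instead was abandoned: the
double discretisation aliases the two grids against each other and
biases every alignment metric by more than 1 mm in z, an artifact real
acquisitions do not share.  All z-structure (taper, bone undulation,
texture) is kept smooth at scales above the 6 mm slice spacing for the
same reason.

Ground-truth deformations combine a translation, optional rigid or
affine parts, and a cubic-B-spline field with two components: a random
field whose coefficients are clipped to the stated amplitude (bounding
the displacement, since the basis is a convex combination) and capped
at 45 % of the control spacing so the field stays invertible; and an
optional deterministic *flex* — an anterior–posterior displacement
varying sinusoidally along z, the phantom's analogue of a change in
neck curvature.  The flex is the deformation that motivates the
B-spline registration stage: it varies along the cord, so no
translation, rigid or affine map can absorb it, and on flexed phantoms
every rigid-family strategy improves markedly when a B-spline
refinement is appended (median CI rising from ≈0.6–0.78 to ≈0.81–0.86
in the strategy comparison).  Truth contours are the analytic
circles mapped through the exact chain — never rasterised masks — and
the fraction dose is a Gaussian falloff (σ = 12 mm, ≈2.17 Gy per
fraction) about the *deformed* cord axis, i.e. constant in the
anatomy-following frame.  Everything derives from `(seed,
fraction_index)` seed sequences and is bit-reproducible.

### What the phantom does and does not emulate

It reproduces the geometry, voxel spacings, modality noise levels and
deformation scales of the clinical setting, so passing tests show the
pipeline recovers known deformations and doses under realistic
sampling.  It does not contain MVCT streak or beam-hardening artifacts,
kV/MV contrast differences (both scans share one HU model), swallowing
or other discontinuous motion, or anatomically realistic shape change;
conformity numbers on the phantom are therefore an upper bound on —
not a prediction of — clinical performance.  One known limitation:
for some texture/shift combinations the through-slice information is
weak enough that the MI surface is nearly flat over ±1 mm in z, and
recovery to better than half a millimetre in z is not guaranteed in
general; it holds for the study conditions exercised in the tests.

## Problem sizes

The test and acceptance runs use a 16-slice planning volume
(80 × 80 × 16 at 2.148/3 mm) and 10-slice guidance volumes
(224 × 224 × 10 at 0.754/6 mm), with one to three fractions per run and
50-landmark recovery checks — small enough that a full affine +
B-spline registration takes about a minute on one core while leaving
every grid at its clinically motivated spacing.

## Numerical details

* Intensities are clamped to [−1024, 3071] HU before histogramming.
* Trilinear interpolation everywhere; out-of-volume moving samples are
  discarded from the histogram (coverage rule in dose accumulation).
* B-spline displacement outside the lattice's full-support box is
  identity; lattices are built to cover the (pre-stage-mapped) fixed
  volume plus a two-control-point margin, so this only affects points
  outside the scan.
* Polygon closure is implicit (first vertex not repeated); degenerate
  or self-intersecting mapped polygons are repaired via a zero-width
  buffer or dropped if empty.
* Voxel centres exactly on a contour count as inside (closed region).
* The divergence path of the optimiser (oversized steps that lose
  image overlap) restores the best-seen parameters, halves all step
  sizes and records a warning on the returned chain.
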