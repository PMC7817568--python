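# Methods

`sulcmorph` analyses the morphology of the central and subcentral sulci on
cortical surface meshes and relates it to somatomotor activation peaks.
Because the cohort it was designed around is not redistributable, the
package ships a synthetic-cohort generator whose defaults encode the
study conditions (50 structural participants, 20 of them functional,
both hemispheres), and every pipeline stage is exercised and validated on
that synthetic cohort.  This note documents the models, the generator,
the numerical choices and what the synthetic validation does and does not
establish.

## Geometry and geodesics

Cortical sheets are triangle meshes with a linked unit-sphere embedding
per vertex (the registration and resampling domain).  Geodesic distances
are shortest paths on a graph: mesh edges weighted by Euclidean length,
augmented with one-triangle *unfolding shortcuts* — for every pair of
faces sharing an edge, the two opposite vertices are connected with the
distance obtained after rotating the second face into the plane of the
first, kept only when the unfolded straight segment crosses the shared
edge.  The plain edge graph overestimates surface distance by ~5–6% on an
icosphere (paths are forced onto edge directions) and does not converge
with refinement; with the shortcuts the error versus the analytic
great-circle length is −0.63 / −0.16 / −0.04% at subdivision levels
2/3/4 (slightly negative because the polyhedron is inscribed in the
sphere).  Exact polyhedral geodesics (MMD/heat method) are out of scope.

Scalar fields are smoothed with a geodesic-Gaussian kernel
(σ = FWHM / (2√(2 ln 2)), truncated at 3σ, weights renormalised per
vertex); the operator is assembled once per (mesh, FWHM) pair and cached,
so cohort-scale smoothing is a sparse mat-vec.  Volumes are smoothed with
a separable 3D Gaussian, σ per axis from the affine's voxel sizes.
Surface-to-volume projection marks a voxel with a segment when the mesh
vertex nearest to its world centre carries that segment, capped at 2× the
mean edge length so voxels far from the sheet stay background; the cap is
a declared choice — the corresponding behaviour of standard tooling
between the two banks of a sulcus is undocumented.  Nearest-vertex ties
resolve to the lowest index; argmax ties to the lowest linear index.

## The synthetic cohort

The cortical sheet is an icosphere (subdivision 5, 10 242 vertices,
radius 100 mm); realistic folding geometry is deliberately not modelled.
Both hemispheres are represented in a common coordinate frame (+z dorsal,
+y anterior); hemisphere is carried as metadata, and no analysis mixes
world coordinates across hemispheres.  Labels are regions in spherical
coordinates:

* the central sulcus is a strip along a meridian, constant 10 mm arc
  width (7 mm for cs_4/cs_5), cut into five elevation bands; cs_2 is the
  widest band, making it the largest segment (the hand-knob segment is
  the largest in real cohorts), and cs_4/cs_5 are small;
* cs_3 spans elevations asin(0.3)–asin(0.5), i.e. z = 30–50 mm at the
  100 mm radius, so the dorsal-larynx ROI slab (default 30–50 mm,
  following the z-bounds used for that representation) covers exactly
  that segment;
* ascs_op and pscs are opercular bands ventral of the strip, anterior and
  posterior respectively; an auxiliary `iprs` band (not a scored segment)
  sits anteriorly as the merge target of Type 4;
* ascs_lat is a 5°-radius disc whose centre position defines the five
  morphotypes: separate (Type 1), overlapping the cs_5 band (Type 2),
  overlapping ascs_op (Type 3), overlapping iprs (Type 4), or anterior to
  ascs_op without contact (Type 5).  Bands are assigned first and the
  disc takes the remaining vertices, so overlaps become contiguous
  (merged) but disjoint patches.

Sulcal depth is a signed per-vertex field, negative inside labels
(deepest in cs_1–cs_3, shallowest in ascs_lat) and positive on the
crowns, in normalised units.  Thickness increases linearly
dorsal→ventral (1.6–2.9 mm), making the subcentral segments thickest.

Inter-individual variability has three seeded sources:

* a smooth random tangential warp of the evaluation coordinates — a sum
  of 10 Gaussian bumps (30° width) with random amplitudes, normalised to
  `warp_sd` RMS angular displacement (default 2°) and amplified toward
  the ventral pole by `1 + ventral_gradient·(1−z)/2` (default gradient
  1.0): the ventral central-sulcus segments and the subcentral sulci are
  the anatomically more variable ones, and this gradient is what makes
  the probability-map consistency ordering (cs_1–cs_3 > cs_4/cs_5 >
  ascs_lat) reproducible across seeds, which is the one qualitative
  cohort-level pattern the generator is calibrated to;
* an independent jitter of the ascs_lat disc centre with
  σ = `ascs_jitter_factor` × `warp_sd` (factor 1.0) — coupling the jitter
  to `warp_sd` means `warp_sd = 0` switches off *all* positional
  variability, which is the regime in which classification is required to
  be exact;
* a constant 3° posterior azimuth offset of all left-hemisphere labels,
  standing in for the hemispheric (Yakovlevian) torque; its magnitude is
  a config default, not a measured value.

Morphotypes are drawn per hemisphere from the published 100-hemisphere
frequency table (left: .40/.34/.18/.06/.02, right: .48/.06/.18/.18/.10
for Types 1–5), which ships with the package as input data.  Activation
anchors are deterministic (hand→cs_2 centroid, dorsal larynx→cs_3, lip→
ventral half of cs_3, tongue→cs_4) except the ventral larynx, whose
anchor is drawn between cs_5 and ascs_lat with the published 14/40
ratio.  Peaks are the anchors jittered tangentially by `peak_noise_sd`
(default 2 mm).  Stat volumes are Gaussian blobs (FWHM 7 mm, amplitude
8) centred on the true peak plus i.i.d. background noise (σ 0.05), on a
1.5 mm grid covering the labelled strip; ROI masks follow the effector
definitions (whole central sulcus for hand/lip/tongue, the z-slab
intersection for the dorsal larynx, the dilated cs_5 ∪ ascs_lat union —
a 3 mm corridor covering the interposed gyrus — for the ventral larynx).
All randomness descends from one seed through explicit
`SeedSequence([seed, participant, hemisphere(, effector)])` splitting, so
any participant is regenerable in isolation.

What the generator does **not** emulate: folded geometry (depth is a
label-derived field, not a geometric quantity), partial or ambiguous
manual labels, within-segment shape variation (the "wall pinches" and
gyral-bridge criteria of manual labelling have no computable definition
and exist only as the generator's construction rules), BOLD physics, or
spatially structured fMRI noise.  Passing recovery tests therefore shows
the pipeline's operations are correct and internally consistent on data
with the assumed statistical structure — not that the pipeline would
reach the same numbers on real cohorts.

## Probability maps

Surface maps: per-vertex percentage of participants labelling the vertex
after nearest-neighbour resampling to the common mesh.  Volume maps: per
participant, nearest-vertex projection into a common grid, Gaussian
smoothing (FWHM 2 mm), threshold *strictly greater than* 0.1 (the
boundary value is excluded; the convention was ambiguous), binarise, sum.
Both raw counts and per-n fractions are emitted.  Summaries report the
maximum (ties → lowest index) and the intensity-weighted centre of
gravity computed on the *unthresholded* summed map (whether thresholding
precedes the centre of gravity was unstated; computing it unthresholded
uses all the information).  Default probability-map grids are 2 mm and
cover the labelled strip's bounding box; sub-millimetre grids work on
small ROIs but full-hemisphere 0.5 mm grids are needlessly large for the
synthetic template.

## Morphometry and classification

Per segment: minimum depth, mean thickness, vertex count (area proxy).
Two segments are *merged* when an edge connects them through the sulcal
bed — both endpoints below a configurable depth threshold (default 0,
i.e. negative depth; pial continuation across a gyral crown does not
count).  Classification precedence when several predicates fire:
Type 2 (merge with any cs segment) > Type 3 (merge with ascs_op) >
Type 4 (merge with iprs) > Type 5 (ascs_lat centroid anterior of the
ascs_op centroid along +y) > Type 1.  The rare posterior variant in
which ascs_lat merges with pscs instead of ascs_op is reported as Type 3
with a `pscs_variant` evidence flag, since it was never scored as a
separate type.  The anterior axis is the template's +y; per-participant
it is meaningful because participants live in the template frame (for
externally loaded data the sphere registration supplies the frame).

## Registration

The group reference is the voxelwise mean of the cohort's binary segment
maps on the common sphere, kept where strictly above 0.4 (a channel that
empties — typical for ascs_lat, whose morphotype mixing caps the mean
near 0.44 — is retained empty with a warning).  The depth-driven
baseline uses the mean min-max-normalised depth as a single channel.

The optimiser is a discrete coarse-to-fine local search in the spirit of
multimodal surface matching.  Default schedule: 3 levels; smoothing
σ_in = σ_ref = 10, 5, 2 mm (geodesic Gaussian standard deviations on the
100 mm sphere convention — the source configuration does not state
units); λ = 0.1, 0.01, 0.01; 10, 10, 3 sweeps; control grids icosphere
2, 3, 4; data grids 4, 5, 6.  An `SGgrid` parameter appears in the
source configuration with no documented role distinct from the data grid
and is ignored; likewise the source mentions six driving data arrays
while listing eight labels — all eight are used here.  Control points
carry tangential displacements interpolated to the data grid by
truncated spherical Gaussians (σ = half the control spacing, so the
nearest control point dominates); the cost is the mean squared channel
difference — source channels compared against the reference sampled at
the warped positions by Gaussian k-NN interpolation, with the source
passed through the same kernel so identical inputs cost exactly zero —
plus λ × the mean squared displacement gradient across control edges
(normalised by the squared control spacing).  Each sweep proposes, per
control point, its six neighbour directions at two step sizes (¼ and
1/16 of the control spacing), accepts only strict cost decreases, and
rejects any move that would flip a warped face's orientation (the
no-folding guard).  The cost is therefore non-increasing within each
level by construction; across levels it changes discontinuously because
smoothing and grids change.  The exact discrete-MRF optimisation of the
reference tool is not reproduced; correctness is assessed by recovery
properties (a 5°-rotated label set re-registers to per-channel
Dice ≥ 0.9) rather than warp equality.

`RegistrationConfig.fast()` (2 levels, control grids 1–2, data grids
3–4) is the scaled-down schedule used for cohort-scale experiments; the
recovery test uses the default schedule with the final data grid capped
at subdivision 5, matching the synthetic mesh resolution.

A caveat observed on the synthetic cohort: because the data term is a
squared difference summed over channels, a hemisphere whose large
channels are badly misaligned can be improved at a small cost to
already-well-aligned small channels, so the unweighted mean per-channel
Dice occasionally decreases slightly (~2 in 20 participants, margins
≲ 0.03) even though the optimised cost always decreases — echoing the
observation that anatomical registration can increase the spread of some
effectors while reducing others.

## Peaks and spread

The peak is the voxel of maximal intensity in the uncorrected statistic
volume within the effector's ROI (ties → lowest linear index), mapped to
the nearest surface vertex; a configurable z-cutoff (default 3.1) sets a
`suprathreshold` flag, and sub-threshold peaks are kept in all spread
statistics but flagged.  The surface patch is a delta at the peak vertex
smoothed at FWHM 1 mm and binarised above zero.  Label assignment takes
the segment at the peak vertex, else the nearest segment within a 3 mm
geodesic radius, else `gyral_gap`.  Spread is the median of the
n(n−1)/2 pairwise geodesic distances between an effector's peaks on the
common mesh (20 peaks → 190 pairs); an even pair count takes the mean of
the central pair (unstated in the source; this is the standard
convention).  A percentile-bootstrap CI over peaks is provided but
non-normative (the source's CI method is unstated).  The hand effector
is analysed in the left hemisphere only (the hand localizer existed only
there); the generator still simulates it bilaterally.

## Problem sizes used in the validation suite

Mesh subdivision 5 (10 242 vertices) for cohorts; activation grids
1.5–3 mm over the labelled strip; morphotype recovery on 100 (zero-warp)
and 200 (default-warp) hemispheres; noiseless effector recovery on 3
participants × 2 hemispheres × 5 effectors; the spread comparison on 10
cohort seeds × 20 functional left hemispheres with the `fast()`
registration schedule.  These sizes were chosen so the full validation
runs comfortably on a single CPU while keeping every statistical check
at a scale where its expected effect clears sampling noise.

## Known limitations

* Graph geodesics are accurate to ≪1% on sphere-like meshes but remain
  approximations on meshes with strongly anisotropic triangles.
* The registration is a greedy local search: it inherits the level
  schedule but not the optimiser of the reference tool, and offers no
  global optimality guarantee.
* Generator realism is deliberately minimal (see above); cohort-level
  numbers (coordinates, millimetre spreads) are not comparable to real
  data, only the qualitative patterns and the arithmetic identities are.
* Classification at strong warps degrades gracefully (≈98% recovery at
  the default 2° warp, 100% only in the zero-variability limit).
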