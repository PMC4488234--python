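# Methods

`morphoface` builds population average faces from colored 3D surface
scans and quantifies deviation from that average. This note documents the
models and numerical choices behind each stage, what the synthetic data
generator does and does not emulate, and the limitations a user should
keep in mind.

## Problem setting

Stereophotogrammetric face scans (e.g. 3dMD) are colored triangle meshes
in millimetres, one per subject per session, with scan defects: holes
where the cameras were occluded, non-manifold "fin" triangles, floating
debris. To compare faces point-by-point across subjects, every scan must
be put in dense correspondence with every other. The pipeline does this
by (1) repairing each scan to a closed genus-zero surface, (2) mapping it
to the unit sphere, (3) deforming the spheres onto a reference subject's
sphere so that anatomy lines up, (4) resampling all subjects onto one
shared triangulation, and (5) averaging with similarity Procrustes.
Deviation maps and per-vertex statistics then read directly off the
shared topology.

## Topology correction

**Non-manifold repair.** Edges with more than two incident faces keep
their two largest faces; pinched vertices keep their largest face fan
(a pinch whose fan is edge-connected through two boundary loops is eroded
one smallest face at a time). Only the largest connected component by
surface area survives, which removes floating debris robustly even when
the debris is vertex-dense.

**Boundary closure.** Each boundary loop is sewn with a fan of triangles
about the loop centroid; the new vertex is flagged `filler`. The patch is
then refined: interior patch vertices solve a discrete-harmonic Laplace
system with the loop fixed, then patch faces are subdivided 1-to-4 and
the solve repeats, until the relative area reduction per round falls
below `rel_tol` (default 1e-3), `max_rounds` (default 6) is reached, or
the patch would exceed `max_patch_faces` (default 2048) — refinement of
filler geometry is cosmetic, and unbounded subdivision of a large,
slowly-converging patch (an open neck spans hundreds of square
millimetres) would otherwise dwarf the anatomy it is stitched to.
The Laplace weights are cotangent weights recomputed from the current
patch geometry and clipped positive. We chose adaptive weights over
uniform ones after measuring that the uniform-weight patch never
converges under refinement (its area keeps shrinking ~10% per round as
the parameterization degenerates), whereas the adaptive solve drives the
patch to a stable minimal (soap-film) surface within 3–4 rounds; the
positive clipping keeps the solve well-posed on the badly shaped
triangles a fresh sewing fan contains. Every solve is backtracked if it
would increase patch area, so each patch's area history is non-increasing
after the first relaxation by construction.

Midpoints created on loop edges during subdivision would leave
T-junction cracks against the surrounding surface; the adjacent original
faces are fan-split to keep the mesh manifold. All vertices created by
sewing or subdivision are `filler = true` and colored by the mean of
their parent vertices; filler geometry is excluded from every matching
and alignment cost downstream, so its color is cosmetic.

Handle (genus > 0) removal is a different algorithm and out of scope: a
closed result with nonzero genus raises an error rather than being
silently "fixed".

**Smoothing.** Optional Taubin λ|μ smoothing (pass-band k = 0.1) removes
acquisition noise without the shrinkage of plain Laplacian smoothing;
connectivity and filler flags are untouched.

## Spherical parameterization

Three stages, all flip-guarded (a step that reverses any spherical
triangle's orientation is halved and retried):

1. **Seeding + conformal relaxation.** The seed is the central projection
   from the area centroid — exactly bijective for star-shaped surfaces,
   which intact head scans are. Deep flat hole patches (a sewn neck
   membrane) can fold under projection, so a geometry *copy* is
   progressively inflated (uniform Laplacian smoothing) until its
   projection unfolds, and that projection seeds the map. Projected
   cotangent-Laplacian smoothing (weights from the source geometry,
   clipped positive against skinny patch triangles, tangential component
   only, re-centred each step) then runs until the maximum vertex
   displacement is below 1e-7, driving the map toward the
   harmonic-energy minimizer, i.e. conformal up to Möbius factors; any
   residual folds are cleared by local Gauss-Seidel averaging over the
   flipped region (with stencil widening on stagnation) alternated with
   the guarded smoothing.
2. **Möbius centering.** The Möbius ambiguity is fixed by spherical
   inversions that move the *source-area-weighted* centroid of the image
   to the origin (tolerance 1e-6). The weighting matters: weighting by
   spherical areas would integrate x over the sphere and vanish for any
   bijection, measuring nothing.
3. **Area relaxation.** Explicit tangential gradient descent on
   sum((area_ratio − 1)^2), where area_ratio is each face's spherical
   area fraction over its surface area fraction. The descent direction
   comes from the analytic planar-triangle-area gradient (a good
   surrogate at these mesh resolutions); acceptance tests the true
   spherical-area objective, so monotone decrease is enforced exactly.
   Default 100 iterations, early stop at 1e-6 relative improvement. On a
   2:1:1 ellipsoid this stage reduces the maximum area ratio from ~1.7
   to ~1.02.

The paper-level trade-off between conformality and area uniformity is
exposed through `area_relax_iters`; the quality report (`map_quality`)
gives both distortions per face rather than collapsing them into one
number.

**Point location.** Queries are located in a spherical triangulation via
a KD-tree over face centroids with determinant-sign containment tests
(tolerance 1e-12, ties to the lower face index) and an exhaustive
fallback; attribute interpolation is barycentric.

## Features and registration

Matching channels per vertex: R, G, B in [0, 1], plus mean and Gaussian
curvature robust-z-normalized (zero median, unit MAD over non-filler
vertices). Curvature uses the cotangent-Laplacian mean-curvature normal
and the angle deficit, both over Meyer mixed vertex areas; mixed areas
(rather than the simpler 1/3-barycentric split) are what make the
estimates converge pointwise at irregular vertices while keeping the
discrete Gauss–Bonnet identity exact.

**Curve initialization.** Matched named curves (the synthetic protocol
traces ten: midline, nose bridge, eye rims, nostril lines, lip lines,
jawlines) are resampled at equal normalized arclength measured on the 3D
surface polyline — this makes the pairing invariant to how densely an
operator clicked the curve. The point pairs first determine a best-fit
global rotation (orthogonal Procrustes on the directions), which removes
a shared head rotation exactly; the residual per-pair great-circle
rotations are then blended with normalized spherical-Gaussian weights
(default sigma 0.2 rad) into a dense rotation-vector field, applied by
Rodrigues' formula, with global amplitude halving if any triangle flips.

**Fluid refinement.** The mismatch cost is

    cost = − w_tex · Σ_{c∈RGB} MI(moving_c, fixed_c∘warp)
           + w_geo · MSD(curvature channels)

evaluated over vertex pairs valid on both sides (filler excluded — this
is what lets extraneous tissue in one scan match filler in another at
zero cost). MI is the plug-in estimate on a bins×bins equal-width joint
histogram over each channel's observed range, in bits, summed per channel
rather than estimated jointly (sample efficiency at 10^3–10^4 vertices).
The per-channel sum is exactly order-symmetric because the entropy terms
are accumulated with compensated summation.

Each fluid iteration computes the per-vertex force as the negative
central-difference gradient (h = 1e-3 rad) of the cost with respect to
that vertex's tangential displacement. Moving one vertex moves exactly
one sample between histogram cells, so the MI change is evaluated
incrementally from the affected column marginals — algebraically
identical to re-evaluating the full cost, at O(V·bins) per sweep instead
of O(V²·bins²). The force field is smoothed with a spherical Gaussian
(default sigma 0.1 rad) into a velocity, and the warp is composed with a
tangential step of that velocity (`step` = maximum vertex motion in
radians, default 0.5). A step is accepted only if the warped
triangulation stays flip-free *and* the cost decreases; otherwise it is
halved up to 10 times. The accepted-cost trace is therefore strictly
decreasing, and the warp remains a bijection surrogate throughout.
Termination: `max_iters` (default 200) or relative cost change below
`tol` (1e-5).

Defaults: w_tex = w_geo = 1, 32 bins, registering one 642-vertex subject
takes a few seconds on one core. The reference subject for group
registration is the first by input order; an option to iterate with the
evolving average as reference exists for reference-bias reduction.

**Resampling.** Each reference vertex direction is located in the
subject's *warped* triangulation (inverting the warp) and position,
colour and filler are interpolated; a resampled vertex is filler if any
contributing vertex is filler. The result is a cohort matrix on a single
topology with correspondence by index.

## Averaging and morphometry

**7-parameter Procrustes.** Closed-form weighted similarity fit
(3 translations, 3 rotations, 1 uniform scale): weighted centroids, SVD
of the weighted cross-covariance with determinant correction (reflections
are refused), scale from the trace ratio. Weights are 1 − filler, so
synthesized patches never steer alignment. Generalized Procrustes
iterates subject-to-mean alignment with the mean held at unit centroid
size, then rescales everything once to the cohort's mean centroid size so
outputs stay in millimetres while cohorts of different absolute size
remain comparable.

**Average model.** Per-vertex arithmetic mean, scalar per-vertex variance
(mean squared deviation about the mean, mm²; a full 3×3 tensor variant is
a possible extension but the scalar is what the p-maps consume), mean
colour over non-filler contributions, and the per-vertex filler fraction.

**Distance maps.** Signed projection of the corresponded subject's offset
onto the average's outward vertex normal — signed rather than Euclidean
because the display semantics need a direction: green = no deviation,
red = outward, blue = inward, linear between anchors and clamped outside.
Default display ranges: ±5 mm for individual-to-average, ±3 mm for
average-to-average. An unsigned variant is available. Note that a
uniform normal offset of a closed, nearly star-shaped surface is mostly a
rescaling, which the 7-parameter alignment legitimately absorbs; on such
shapes an "inflation" reads as a uniformly positive but attenuated map.

**TBM.** Per-face log(area_subject / area_average) — the surface analogue
of the log Jacobian determinant — aggregated to vertices by
average-area-weighted mean. Exactly rigid-invariant; a uniform scale s
shifts every face by 2·log s. Zero-area average faces are flagged
undefined and excluded from aggregation.

**Permutation p-maps.** Per-vertex statistic |mean signed distance in A −
mean in B| against the pooled average; null from seeded random
relabelings into the original group sizes;
p = (1 + #{null ≥ observed}) / (n_perm + 1), floor 1/(n_perm+1). Raw
p-values by default, Benjamini–Hochberg adjustment on request.
Cluster-extent inference and covariate models are out of scope.

## Synthetic study conditions

The generator emulates a 3dMD-like cohort: a subdivided icosphere head
(default level 3, 642 vertices, radius 80 mm) with Gaussian radial
features (nose +12 mm, eye sockets −3 mm, brows +2 mm, chin +6 mm, lips
+2.5 mm, cheeks +3 mm), procedural skin/lip/eye colouring, and ten
anatomical curves traced through the feature anchors. Per-subject
variation: feature height jitter (SD 1 mm) and angular position jitter
(SD 0.02 rad), log-scale jitter (SD 0.02), pose jitter (rotation SD
0.1 rad, translation SD 5 mm), and channel-correlated colour gain jitter
(SD 0.04 on luminance and red/blue balance) — the colour jitter is what
makes mutual information genuinely necessary over a fixed transfer
function. Defects on request: punched holes (kept off the face so the
anatomy survives), fin triangles, a floating island, an open neck.
Everything is deterministic in (seed, subject index); a "T4" re-imaging
session redraws pose and colour while keeping each subject's shape
parameters.

All subjects share the template's vertex indexing, so ground-truth
correspondence is vertex identity and registration error is measurable
exactly. What passing these fixtures does **not** show: robustness to
hair, specular highlights, expression change, landmark-free acquisition
noise, or meshes two orders of magnitude denser than the default —
the fixtures validate the algorithms, not any particular scanner.

Default problem sizes in the test-and-acceptance runs (chosen to keep a
full run on one core in the minutes range): 642-vertex subjects, cohorts
of 10, 100 defect fixtures, 10 registration-recovery seeds, 999
permutations.

## Numerical choices and degenerate inputs

- Vertex indexing is 0-based internally; OBJ's 1-based indices are
  converted at the I/O boundary. Colour is float [0,1] internally, uchar
  in PLY.
- Zero-area faces contribute nothing to normals/areas (with a warning);
  degenerate (repeated-index) faces are rejected at construction.
- Spherical triangle areas use l'Huilier's formula; arc lengths through
  arcsin of half-chords for stability near zero.
- Collinear or coincident Procrustes support raises an error (the
  rotation is not identifiable).
- Constant channels make MI degenerate; the estimate is 0 with a flag.
- All randomness flows through explicit seeds; a pipeline rerun with the
  same config reproduces the average bit-identically.

## Known limitations

- Registration quality is bounded by mesh resolution: at 642 vertices,
  sub-vertex anatomical detail cannot be matched.
- The greedy fluid scheme finds local minima; it relies on the curve
  initialization for global placement (as the protocol intends). With no
  curves and large pose differences it can converge to a wrong basin.
- Area relaxation trades conformality for area uniformity gradually;
  it does not reach an exactly area-preserving (optimal-transport) map.
- The scalar per-vertex variance ignores anisotropy of the residual
  cloud.
- Genus > 0 after closure is an error by design (no handle removal).
- On scans whose defects differ strongly across subjects (e.g. holes in
  different places), correspondence near the filler boundaries is loose
  by construction — those regions carry no anatomy to match — and
  residuals there are larger than on intact scans.
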