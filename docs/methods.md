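# Methods

`cortiparc` parcellates a cortical hemisphere surface by registering it,
in a spherical domain, to a feature atlas that carries population labels.
This note documents the models, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## Input model and surface post-processing

The pipeline operates on a closed, consistently oriented, genus-zero
triangle mesh of one hemisphere's gray/white boundary, in AC-PC-aligned
RAS millimetre coordinates with the AC and PC landmark positions given.
Surface extraction, topology correction and landmark detection are
upstream concerns; `mesh_core` only *validates* the topology (every edge
shared by exactly two consistently wound triangles, Euler characteristic
2).

Raw surfaces are decimated to 70,000 triangles by incremental edge
collapse and then smoothed with five iterations of uniform-weight
Laplacian smoothing at relaxation 0.1.  The collapse priority is
shortest-edge-first with midpoint placement; a collapse is rejected if it
violates the edge link condition (which would alter genus or create a
non-manifold edge) or flips any incident triangle normal by more than
90°.  The cost function is a deliberate simplification: shape fidelity
beyond what the geometry features need is not required, and the link
condition alone guarantees the topological invariants the spherical map
depends on.

## Geometry features

Four per-vertex scalars drive registration, ordered coarse to fine:

* **IS-distance** (mm, signed): the superior (z) component of the vector
  from the vertex's orthogonal projection on the AC-PC line to the
  vertex.  Superior positive; the temporal pole is the most negative
  region.  A signed offset rather than a Euclidean distance, because the
  feature must distinguish superior from inferior.
* **AP-distance** (mm, signed): offset from PC along the posterior
  direction (the unit vector from AC to PC).  Posterior positive, so the
  frontal pole is most negative and the occipital pole most positive.
* **Hull depth** (mm, ≥ 0): distance to the surface's convex hull.  For a
  point inside a convex polytope this equals the minimum plane distance
  over hull facets, which is computed exactly from the facet equations —
  no sampling or nearest-vertex approximation.  Deep sulci and the insula
  score high.
* **Mean curvature** (1/mm): ‖ΔP‖/2 from the cotangent Laplace–Beltrami
  operator with barycentric (one-third) vertex areas, signed against the
  outward area-weighted vertex normal so a sphere of radius R scores
  +1/R.  Convex-outward positive is a convention; registration only
  requires that atlas and subject agree on it.

On each registration grid a feature is smoothed by one pass of
s′ = (s + λ·ringmean)/(1 + λ) — λ = 0.5 on the IC4/IC5/IC6 levels, 1.0 on
IC7 where curvature is noisiest — and then normalized: the two signed
distances by a two-sided piecewise-linear rescale onto [−1, 1] that keeps
the anatomical zero fixed, hull depth by empirical-quantile histogram
matching to the atlas's field (all-vertex quantiles, averaged ranks on
ties), and curvature by clamping to [−1, 1].

## Spherical parameterization

A genus-zero mesh is mapped bijectively to the unit sphere in five steps:
split into two halves by a plane through the area centroid normal to the
longest principal axis (snapped to mesh edges); fix the shared boundary
cycle; map each half to the unit disk by the uniform-weight (Tutte)
convex-combination system with the boundary fixed on the circle at
arc-length-proportional angles; lift each disk to a hemisphere by inverse
stereographic projection; stitch at the equator.  Boundary vertices are
shared and both halves use the identical circular parameterization, so
the equator images coincide exactly.  For a perfect hemisphere the
harmonic disk map is essentially the stereographic projection, so the
disk-then-inverse-stereographic composition is close to the identity and
distortion enters only through the folding pattern.

Two choices make the parameterization *canonical* across a cohort: the
split plane's normal sign is fixed anatomically (anterior positive,
falling back to superior and then right when nearly orthogonal), and the
boundary cycle is anchored at its most superior vertex.  Without these
the azimuthal origin and the hemisphere assignment of each subject's
sphere would be arbitrary, inter-subject sphere maps would differ by
rotations of tens of degrees, and the rotational registration stage —
whose regular-step optimizer travels at most max_step × iterations ≈ 17°
at the first level — could not absorb them.  With them, residual
misalignments are a few degrees, the regime the rotational stage is
designed for.  The boundary polyline is smoothed (ten cyclic averaging
iterations) only to compute arc-length spacing; the cut itself stays on
mesh edges.  Any flipped spherical triangle after stitching is repaired
by up to 50 iterations of on-sphere Laplacian relaxation restricted to
flipped neighborhoods; the map is rejected if flips persist.

## Registration

Registration aligns two scalar fields on an icosahedral grid hierarchy
(IC4 2,562 → IC7 163,842 vertices; canonical golden-ratio icosahedron
with poles on ±z so grids are bit-identical across runs).  Each level
runs a rotational stage then a spherical demons stage, and concatenates
the result with the running warp; the warp is carried between levels by
componentwise barycentric resampling of the tangent field followed by
tangent-plane projection.

**Rotational (versor) stage.** Minimizes the mean-squared feature
difference over global rotations by regular-step gradient descent
(central-difference gradient in the rotation-vector chart): gradient
tolerance 1e-6, initial step 0.01 (divided by 2^(i−1) at level i),
minimum step 1e-9, relaxation 0.9 on gradient reversal, 30 iterations.
The best rotation seen is returned, so the result never scores worse
than the identity.

**Spherical demons stage.** The deformation is one tangent vector per
grid vertex, applied through the spherical exponential map.  Per
iteration: (a) the moving field is resampled through the current warp;
(b) the velocity update in each vertex's tangent chart is
u = (f − m∘φ)·g / (‖g‖² + ε (f − m∘φ)²), with g the least-squares 1-ring
surface gradient of the warped moving field and ε = 1/σ², σ equal to the
grid's shortest edge length h (this bounds any update at σ/2; the
self-regulated mode additionally hard-caps ‖u‖ at 0.5 h, keeping a
single exponential step well inside the injectivity radius); (c) the
update is exponentiated and composed with the running warp by resampling
the warped positions; (d) the composed tangent field is regularized by
40 iterations of parallel-transport 1-ring averaging with per-iteration
blend weight λ/(4(1+λ)) — a compact, approximately Gaussian kernel of
about two edge lengths at λ = 1.  Fields generated by a global
infinitesimal rotation are preserved by the smoother up to a
discretization error that shrinks under grid refinement (≈ 2% of the
field after a full pass at IC4), so global alignment is essentially
untouched by regularization.  After every iteration the warped grid must
have zero inverted spherical triangles; a violating step is halved up to
five times, then the stage stops with a warning.  Iteration stops when
the *relative* improvement of the mean-squared metric falls below 0.05,
or at 500 iterations.  The relative reading is deliberate: on features
normalized to [−1, 1] the mean-squared metric is typically far below
0.05, so an absolute threshold of that size would stop after one
iteration and leave the iteration budget meaningless, whereas a 5%
relative stagnation test is scale-free and engages the budget.

The metric averages over all grid vertices with uniform weights (the
sphere is fully covered; no cortex mask is needed).

## Atlas building and parcellation

Atlas building registers every training subject (moving) to a chosen
template (fixed; the template is an explicit input, not drawn at
random), averages the normalized per-level features over the template
and all successfully registered subjects, carries each subject's labels
into atlas space through its warp, and labels each finest-grid vertex by
majority vote with ties resolved toward the lowest label id; the full
per-label probability fields are retained.  Subjects that fail
registration are excluded with a logged reason.

Parcellation swaps the roles: the new subject's features (histogram-
matched toward the atlas) are the fixed side and the atlas sphere is the
moving surface, so the recovered correspondence sends every subject
sphere vertex into atlas space, where it takes the nearest atlas label —
every vertex is labeled, with no holes by construction.

## Evaluation

Per-region Dice D = 2|A∩B| / (|A|+|B|) is computed on labeled surface
area, with region areas accumulated from one-third-of-incident-triangle
vertex areas so borders with mixed triangles are handled consistently;
regions absent from both labelings are reported as missing and excluded
from the mean (reported with and without the unlabeled region, weighting
subjects equally).  Vertex accuracy is the percentage of test subjects
whose automated label matches the gold standard at a vertex, summarized
in ten 10-point bins with 100% counted in the top bin.

## Synthetic cohorts

Real inputs (MRI-derived surfaces with manual parcellations) cannot ship
with the package, so validation runs on generated cohorts that emulate
exactly the properties the pipeline consumes.  A template is an
icosphere (level 5, 10,242 vertices by default) with radius
60 mm modulated by 40 signed Gaussian bumps (width 0.25 rad, amplitude
5% of the radius) that create hull-depth and curvature structure; labels
come from a 24-seed spherical Voronoi partition plus an unlabeled polar
cap (0.45 rad around −x); AC and PC sit on the centerline.  A cohort
member places each template vertex at an exponentiated smooth random
tangential warp of its parameter direction — maximum magnitude half the
IC4 edge length (≈ 2°, the injectivity-safe bound), correlation scale
0.6 rad, i.e. lobe-scale variability — plus 0.05 mm radial noise.
Because warps are tangential-only, subject vertex i corresponds exactly
to template vertex i: anatomy, labels and features all ride the warp,
giving ground truth that real data cannot provide.  A drawn warp that
inverts a triangle is redrawn at half magnitude.

What this does *not* emulate: anatomically realistic sulcal topography,
topological noise, variable mesh connectivity across subjects (all
cohort members share the template's triangulation, though each is
spherically mapped independently), or appearance differences between
manual raters.  Passing the synthetic suite demonstrates that the
machinery recovers known smooth deformations and propagates labels
accurately under those conditions, not that it reaches any particular
accuracy on clinical data.

## Problem sizes and defaults used in validation

The shipped default schedule is the full four-level IC4–IC7 table.  The
test suite and the end-to-end validation run the IC4–IC6 three-level
schedule on level-5 template meshes with an 8-member cohort (5 training,
3 held-out), which exercises every stage at a size a single CPU handles
in minutes; the demons-recovery checks run at IC4–IC5.  The acceptance
script rebuilds the registration grids and decimates a ~250,000-triangle
synthetic surface with the shipped default target.

## Known limitations

* The decimation collapse cost (shortest edge) and the boundary
  smoothing of the split cycle are stand-ins where the pipeline's
  upstream references leave the construction unspecified.
* The demons force is the single-direction (warped-moving gradient)
  variant; symmetric or inverse-consistent forces are not implemented.
* Histogram matching at parcellation time matches the subject toward the
  atlas; the atlas side is then re-matched toward the already-matched
  subject field, which is idempotent in the aligned limit but not an
  exact no-op.
* One scalar feature per level cannot constrain motion along its own
  level sets (the aperture problem); the schedule relies on successive
  features having complementary gradients, and recovery of warps much
  rougher than the ~0.6 rad correlation scale degrades accordingly.
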