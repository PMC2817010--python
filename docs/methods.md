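# Methods

This note documents the models, estimators, defaults and numerical
choices behind `lensmetry`, and what the synthetic validation does and
does not establish.

## Lens model

The pristine crystalline lens is a biconvex solid of revolution: two
spherical caps (anterior radius `R_a`, posterior radius `R_p`) joined at a
shared base circle of radius `r_e`.  With cap heights `h_a + h_p = T`
(axial thickness), the shared base makes the closing condition
`h_a (2R_a − h_a) = h_p (2R_p − h_p)` linear in `h_a`:

    h_a = T (2R_p − T) / (2 (R_a + R_p − T)),

with the degenerate full-sphere case `R_a = R_p = T/2` handled separately.
Feasibility demands `0 < h_a < T` and caps no larger than hemispheres
(otherwise the equator would not be the widest section).  The analytic
volume is the sum of the cap volumes `π/3 · h²(3R − h)`.  This solver is
validated against brute-force Monte-Carlo integration of the two-cap
solid.

## Fixation-shrinkage (kidney) artifact

Chemical fixation dehydrates the central anterior lens cortex; the
phantom models the resulting shape change as a posterior displacement of
the surface that is Gaussian in the polar angle θ of the anterior cap:

    δ(θ) = D · exp(−θ² / (2 σ_θ²)),

followed by an optional global isotropic shrink `s` about the lens
centre.  θ is measured at the anterior centre of curvature, so the dent's
lateral scale on the surface is `R_a σ_θ`; measured at the lens centre the
same angular width would collapse into an unresolvable spike at the
shallow anterior pole, which is why the curvature-centre parametrisation
was chosen.  The displacement fades to zero at the equatorial plane with
a smoothstep ramp, leaving the posterior cap exactly untouched; on the
axis the anterior pole moves posteriorly by exactly `D`, so the true
post-artifact thickness is `s (T − D)`.  Voxelisation applies the dent by
inverse mapping (a point is inside the deformed solid iff displacing it
anteriorly by the local δ lands inside the pristine solid), which is
exact on the axis and accurate to O(δ·∂δ/∂θ) elsewhere.

Defaults: `σ_θ = 0.15` rad (dent bowl roughly 1 mm across on a 4.7 mm
lens, the visually kidney-like regime), `D` per bird from the hatch
mixture below, `s = 1`.  The dent is required to stay below `0.8 h_a s`
(warning otherwise): deeper dents approach the posterior cap and break
the simple-closed-surface assumption shared by the mesh and the
classifier.  No quantitative shrinkage magnitudes are available for this
preparation, so these are tunable model choices, not measured values.

## Phantom imaging

Eyes are spheroidal globes (defaults: axial length 9.5 mm, equatorial
diameter 10.5 mm, scleral shell 0.4 mm) with the lens base circle 18% of
the axial length anterior of the globe centre.  Tissue intensities are
arbitrary units (lens 200, sclera 90, humor 60, agarose 30; lens
brightest, as on T2-weighted fixed-eye images).  Rasterisation samples
voxel centres and re-evaluates every voxel whose 6-neighbourhood is not
uniform with `supersample³` sub-voxel points (default 3³), giving exact
partial-volume fractions for piecewise-constant tissue.  Noise is Rician
(magnitude MRI): the complex channels receive Gaussian noise of standard
deviation `lens_intensity / SNR`; default SNR 15.  All randomness flows
from a single top-level seed through `numpy.random.SeedSequence`.

Array volumes place 16 eyes on a 2×2×4 grid inside a 38 mm agarose
cylinder, one eye inverted, ids assigned in raster order with the
inverted eye receiving the highest id; the auto-cropper re-derives that
assignment from the inverted eye's lens offset, so a shifted inverted
cell rotates the whole id map.

## Cohort simulation

Nine in vivo traits (lens volume, lens equatorial diameter, lens
thickness, axial length, corneal radius, eye weight, eye equatorial
diameter, body mass, body length) are sampled with normal marginals and a
target Spearman matrix through a Gaussian copula (latent Pearson
`r = 2 sin(π ρ_s / 6)`).  The default matrix is constructed from a
single latent size factor plus a volume vector that loads almost entirely
on the diameter and thickness latents — encoding the geometric fact that
a biconvex lens's volume is nearly determined by its diameter and
thickness.  Being a Gram matrix, it is positive semidefinite by
construction; arbitrary user matrices are validated (symmetry, unit
diagonal, eigenvalues).

Per bird, the cap asymmetry is solved from the sampled `(V, d, T)` by
inverting `V = π/6 (3 r_e² T + h_a³ + h_p³)` with bisection; sampled
volumes outside the feasible window (bounded below by the symmetric lens
and above by an anterior radius cap of 6.5 mm) are clipped to its edge.
This yields anterior radii that are broader and more right-skewed than
posterior radii, as observed on fixed lenses.

The artifact depth `D` carries a hatch-level random effect from a
two-component mixture: with probability 0.30 a hatch is "affected"
(mean `D` ~ N(0.38, 0.08²) mm), otherwise nearly clean
(|N(0, 0.02²)|); birds add N(0, 0.07²) noise, clipped to
`[0, min(0.6, 0.75 h_a)]`.  With the 0.15 mm call threshold this yields a
roughly one-third kidney prevalence concentrated in a minority of
hatches, while MRI scan groups of 16 are assigned by randomised order and
carry no effect.  The in vivo ultrasound thickness is the pre-shrinkage
`T` plus N(0, 0.03²) measurement noise, so the rank correlation between
ultrasound and post-shrinkage (MRI) thickness degrades as the shrinkage
variance grows.

Trait means/SDs (body mass 450 ± 60 g, axial length 9.5 ± 0.35 mm,
corneal radius 3.4 ± 0.15 mm, lens thickness 2.35 ± 0.08 mm, lens
diameter 4.7 ± 0.18 mm, lens volume 22.7 ± 1.5 mm³, ...) are plausible
values for 3-week broiler–layer cross chicks.

## Segmentation

The seed defaults to a centroid-proximal voxel of the brightest
(Gaussian-stabilised) structure; the threshold is Otsu's method inside a
spherical ROI (default radius 3.5 mm) around the seed, with a global mode
available and a midpoint fallback (with warning) for degenerate or
unimodal ROIs.  The lens is the 26-connected supra-threshold component
containing the seed; touching the volume border is an error ("lens
clipped"), and volumes outside 5–60 mm³ warn.  Repair applies
morphological closing (ball, radius 2 voxels) and slice-wise 2D hole
filling: a voxel is added only when it is 2D-enclosed in at least two of
the three slice orientations, because a genuine interior void is enclosed
in several orientations whereas the open bowl of a kidney dent is
enclosed only in slices perpendicular to the axis and must not be filled.
The repair is idempotent.

## Surface meshing

The mesh is an octahedron subdivided k times (8·4^k faces; 32,768 at
k = 6) projected to the unit sphere, then shrink-wrapped by radial ray
casting from the mask centroid: each vertex lands on the outermost
sub-voxel 0.5-crossing of a lens occupancy field, found by dense sampling
(0.25 voxel steps) with linear refinement.  Rays crossing the surface
more than once indicate a non-star-shaped mask; they are counted and a
warning is raised above 1%.

The occupancy field is derived from the smoothed intensity image when
available: partial-volume fractions inferred from robust lens/surround
levels (medians of the eroded mask core and of a shell just outside the
mask), clipped to a narrow band around the mask, lightly softened
(σ = 0.4 voxel).  A binary mask quantises locally flat surface patches to
±0.5 voxel no matter how it is softened, which is why the image-based
field is the default whenever an intensity volume exists; the
binary+soften path (σ = 1 voxel) remains as fallback.

Vertex smoothing is the Taubin λ|µ two-step (λ = 0.33, µ = −0.34,
10 iterations) with uniform umbrella weights; plain Laplacian smoothing
is available by flag but shrinks volume.

## Measurements

* **Axis** — through the area-weighted surface centroid toward a
  user-supplied anterior point (within 0.3 mm of the surface), or, in
  automatic mode, the smallest-variance principal axis of the
  area-weighted vertices oriented by an anterior hint.
* **Axial thickness** — distance between the two intersections of the
  axis line with the mesh (vectorised Möller–Trumbore over all faces);
  any intersection count other than two is an error.
* **Equatorial diameter** — maximum caliper width (diameter of the convex
  hull) of the vertices projected orthogonally to the axis;
  plane-position-independent by construction.
* **Volume** — divergence theorem over signed tetrahedra; requires a
  watertight mesh; an inward-wound mesh is corrected with a warning.
  The pipeline also reports a voxel-count volume defined as the number of
  voxels inside the same 0.5-occupancy surface (partial-volume
  corrected); the raw flood-fill count is kept in the extras since it
  inherits the threshold placement.
* **Surface radii** — least squares on `Σ(‖v − c‖ − r)²` with the centre
  constrained to the axis (free-centre fit by flag), minimised by
  Powell's direction-set method from a Kåsa algebraic initialisation,
  parameter tolerance 1e−6 mm.  The fitted cap is the surface region
  whose outward normals lie within 30° of the axis (half the 60°
  subtended angle): selecting by position angle from the centroid leaves
  flat caps a sliver of surface and makes the fit ill-conditioned, while
  the normal criterion coincides with it exactly on a sphere.
* **Kidney classification** — depression depth is the maximum inward
  deviation, over anterior vertices within 15° of the axis, from a
  reference sphere fitted to the dent-free shoulder annulus (lateral
  distance 55–80% of the anterior cap extent; selection by position, not
  normals, because deep dent walls tilt their normals into any normal
  band).  A lens is kidney-shaped when the depth exceeds 0.15 mm
  (≈1.3 voxels: above surface-localisation noise, below visually obvious
  dents).  On dented phantoms the plain 60°-cap anterior radius is
  strongly inflated — the same behaviour seen in real fixed-lens radius
  histograms — so the annulus reference, not the plain fit, anchors the
  depth.

## Statistics

Spearman correlations use midranks and pairwise-complete deletion, with
the t approximation for p (exhaustive permutation enumeration below
n = 10).  Normality screening is the Lilliefors-corrected
Kolmogorov–Smirnov test (parameters estimated from the sample); the naive
fixed-parameter variant is available and is demonstrably conservative.
The kidney-vs-batch association is a likelihood-ratio test from binomial
GLMs (intercept vs one parameter per factor level) fitted by IRLS on
per-level counts; completely separated levels use the exact limiting
deviance (zero contribution from a saturated level) with a warning.  The
p-value applies Williams' correction to the deviance before the
chi-squared lookup: with many sparse levels (e.g. 32 scan groups of ~16
eyes) the raw deviance over-rejects at roughly 9% for a nominal 5%,
and the correction restores calibration; the reported statistic itself
is the uncorrected likelihood-ratio deviance.  No
multiple-testing correction is applied by default (raw p at α = 0.05);
correlation maps report all pairwise results plus the p < 0.05 edge
graph, stratifiable (e.g. all lenses vs non-kidney).

## Validation scope and problem sizes

All validation is synthetic: 20-phantom recovery studies at 0.115 mm
voxels and SNR 15 with 32,768-face meshes, 10+10 kidney classification
sets plus a 6-point depth sweep, 19-eye repeat-scan pairs, cohorts of
25 hatches × 20 birds, 100-replicate batch-effect power runs and
1000-replicate null calibrations.  Phantoms share the real data's
geometry, resolution, partial-volume blur, Rician noise and batch
structure, but not its biological texture: no refractive-index gradients,
no sutures or zonules, no intensity inhomogeneity, no motion or
susceptibility artifacts, and a strictly axisymmetric artifact model.
Passing these studies therefore establishes the correctness and internal
consistency of the estimators under the stated imaging model — not that
real fixed-tissue measurements are unbiased, which the shrinkage artifact
itself precludes.
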