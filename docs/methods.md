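# Methods

This note records the models, conventions, parameters and numerical
choices behind `femurmap`, and what the synthetic test bed does and does
not establish about real data.

## Mesh model and conventions

A surface is an indexed triangle mesh (`TriMesh`): vertices in mm, faces
counterclockwise viewed from outside, optional named per-vertex scalar
fields. Validation enforces edge-manifoldness (every edge borders one or
two faces), consistent orientation (no repeated directed edge) and
non-degenerate faces; readers repair inconsistent winding by breadth-first
propagation. Discrete Gaussian curvature is the angle deficit
`2π − Σθ` at interior vertices and the geodesic-curvature deficit
`π − Σθ` at boundary vertices, so `Σ K = 2πχ` holds to within the cost
of the angle computations (~1e−13 on our fixtures). Genus is solved from
`χ = 2 − 2g − b` with `b` the number of boundary loops.

Face aspect ratio is the longest edge over its altitude,
`l_max² / (2·area)`; an equilateral triangle scores `2/√3 ≈ 1.1547`.
Quality thresholds ("aspect ratio < 20") refer to this convention —
quality-ratio formulas differ between mesh tools, so the convention is
part of the contract.

Point-to-surface distance evaluates the exact point-to-triangle minimum
against *every* face (vectorised over faces, chunked over points), so it
equals the brute-force answer by construction; no spatial-index
approximation error enters cortical thickness.

Mesh I/O covers PLY/OBJ/OFF/STL. PLY and OFF are written by this package
in double precision (binary PLY with per-vertex fields as custom double
properties; OFF with 17-significant-digit decimals), so write/read
round-trips are bit-identical.

## Discrete Ricci flow

The conformal structure is discrete vertex scaling:
`l_ij(u) = l_ij(0)·e^{(u_i+u_j)/2}`. Driving the curvature to a target
`K̄` is a convex problem whose gradient is `K̄ − K` and whose Hessian is
the half-cotangent-weight Laplacian of the *current* metric (verified
against finite differences to ~1e−6 absolute on O(1) entries). Each
Newton step is one sparse SPD solve; a step-halving line search rejects
steps that violate a triangle inequality or fail to reduce
`max|K − K̄|`. Defaults: tolerance `1e−8`, at most 50 Newton steps; the
femur fixtures converge in 3–7 steps with residuals `1e−10`–`1e−13`.

Boundary conditions:

* `disk_free_boundary` (χ = 1): target `K = 0` at interior vertices only;
  boundary `u` is fixed at 0, which is this package's reading of "leave
  the boundary metric unchanged".
* `annulus_zero` (χ = 0, b = 2): target `K = 0` at every vertex,
  including the boundaries, which makes both loops geodesic — the flat
  surface is a right cylinder whose modulus is conformally determined.
  One vertex is pinned (`u_0 = 0`) to remove the global scale gauge;
  constants do not change `K`, so the pin is harmless.

## Planar layout

Sequential face-by-face propagation of a flat metric is numerically
unstable here: placement error is amplified by a factor up to
`l_leg / l_base` per step, and the annulus metric contains slivers with
angles down to ~0.02° near the slit tips where the conformal factor
concentrates. Instead the layout:

1. develops the single boundary polygon by integrating metric edge
   lengths and turning angles along the loop (a short chain, so roundoff
   cannot compound through the interior);
2. solves the Dirichlet problem of the metric's cotangent Laplacian for
   the interior — the exact development satisfies it identically;
3. polishes with ≤ 3 Gauss–Newton passes on relative edge-length
   residuals (column-scaled normal equations, tiny Tikhonov damping).

Achieved relative edge-length error is ~1e−12 (contract: 1e−6), with no
flipped faces. The layout gauge (translation/rotation) is fixed by the
boundary start vertex and removed entirely by the strip normalisation.

## Surgery and normalisation

The FH–GT slit is performed as an exact straight segment in the disk
embedding: crossed edges are split (new vertices interpolate 3D
position, fields and planar position linearly along the edge), crossing
points within 1e−9 of an existing vertex snap to it, and edges nearly
collinear with the segment are excluded from intersection (their
endpoints enter as vertex events) because their intersection parameters
are ill-conditioned. Splitting then slitting duplicates path-interior
vertices (and path endpoints that lie on an existing boundary); slit
tips stay single. Provenance arrays map every vertex of every derived
mesh back to the input surface (−1 for synthesised split points), which
is how per-vertex fields and feature identities travel through the
chain.

The cut graph is the Dijkstra-shortest edge path (3D lengths) from the
GT vertex to the distal boundary, constrained to keep its interior off
all boundaries so it can be slit.

Strip normalisation is the unique similarity mapping the two GT slit
copies to `0` and `2πi` with the domain at `Re ≤ 0`; being
complex-linear it preserves orientation and conformality. The FH
imaginary coordinate is then a *checked output*: it equals `π` exactly
when the two slit sides are conformally congruent (true for the
mirror-symmetric default generator, to ~1e−15), and deviates with
anisometric shape variation — the deviation itself measures asymmetry
across the FH–GT line. `z ↦ e^z` maps the strip to the annulus; the
imaginary period matches the `[0, 2π]` scaling, so the two cut copies
land on identical points.

## Feature detection

The conformal factor (stored as `−u`, the log area concentration of the
3D surface relative to the flat domain) peaks over protruding processes.
Peaks are 1-ring local maxima ranked by topographic prominence computed
by a descending watershed sweep with union-find (deterministic; ties
break on vertex index). FH and GT are the two most prominent interior
disk peaks, with **FH = the higher peak**: the head concentrates the most
area and dominates by > 2 log units on every fixture. (Disambiguation by
fitted-support area was considered and rejected: a shallow peak's
Gaussian fit is near-flat and its 1σ ellipse unstable.) Default minimum
prominence 0.25 log units for disk detection, 0.1 for LT.

LT is the most prominent interior peak of the annulus parametrisation
outside two exclusion zones: the supplied FH/GT region supports, and the
**conformal collar** `−log|z| < 1.25`. On the normalised annulus,
`−log|z|` is conformal depth below the FH–GT slit in
circumference-normalised units; the head and greater trochanter hug the
slit within an order-one collar however much 3D area they carry, while
the LT sits 2.5–3.5 units deeper. This is the scale-free exclusion that
survives shaft-length and jitter variation (42/42 fixtures detect all
three features within one graph ring of the planted apices).

Feature regions are anisotropic 2D Gaussians
`offset + A·exp(−½ (x−μ)ᵀ Σ⁻¹ (x−μ))` fitted by Levenberg–Marquardt over
the peak's watershed basin (grown to ≥ 12 vertices), with the precision
matrix parameterised by its Cholesky factor and moment-based
initialisation (no random seed). The support set is all vertices within
Mahalanobis distance 1. For correspondence the FH/GT/LT regions are
(re)fitted in the strip frame, where the processes are magnified rather
than compressed.

## Correspondence

The canonical template is the strip mesh of a designated reference
subject (first subject by default), cropped to faces whose vertices
satisfy `Re ≥ distal_limit` (default 95% of the shallowest distal extent
across the cohort, so every subject covers the template).

Region matching maps the template feature ellipse onto the target's by
translation plus symmetric positive-definite scaling along the
template's principal axes — no rotation, since the strip frame already
fixes orientation (a documented limitation: a genuinely rotated feature
process would be matched only up to its axis-aligned spread). Controls
are the centre plus eight 1σ-ellipse points per region; displacements
are interpolated by Wendland C2 RBFs `(1 − r/ρ)⁴(4r/ρ + 1)` with no
polynomial term, so the deformation is exactly zero beyond `ρ` from all
controls and exactly interpolates them (kernel solve; conditioning above
1e12 raises with the advice to increase `ρ`). Default
`ρ = 2 ×` the largest fitted 1σ radius.

Point location uses a trapezoid-map locator on the target triangulation;
nodes on shared edges/vertices take the lowest-index containing face;
nodes outside the domain are clamped to the nearest boundary point of
the nearest face and flagged (flags are cleared when the "outside"
distance is below 1e−9 of the domain diagonal — hull roundoff, not
geometry). Clamped nodes are excluded from statistics by default.
Barycentric resampling has linear precision, so constant and affine
fields are reproduced to ~1e−15, and registering a subject to itself
reproduces it exactly.

## Morphometry

Cortical thickness at an outer vertex is its exact distance to the inner
surface. Generalised Procrustes analysis iterates translation + proper
rotation (+ optional scale) alignment about the evolving mean to an RMS
mean change below 1e−10; reflections are never used (anatomy is chiral).
Scale factors are the Procrustes scales of the mean-to-subject
transforms, normalised to geometric mean 1 across the cohort. Shape
modes are the SVD principal components of the mean-centred aligned
coordinate vectors (orthonormal loadings, centred scores, non-increasing
variance fractions; default 5 modes). With scale normalised, isotropic
size lives in the scale factors and mode-1 scores are uncorrelated with
planted size multipliers.

## Statistics

Node-wise OLS with contrast t-statistics (`df = n − rank(X)`); the
standard design for thickness is intercept + group indicator + body
weight + scale factor + shape-mode scores (covariates centred), and for
strain fields the impact force replaces weight/scale. Clusters are
connected components (template 1-ring adjacency) of one-sided
suprathreshold nodes at `p < 0.005` per direction, intersected with the
analysis mask (control-mean thickness ≥ 1 mm and never-clamped nodes).
Both one-sided directions are analysed and reported with sign.

The primary correction is **permutation cluster-extent FWER**
(Freedman–Lane): residuals of the reduced model are permuted, the
reduced fit added back, the full model refitted, and each observed
cluster's p-value is the add-one proportion of permutations whose
maximum cluster extent reaches it. A seed is mandatory; identical seeds
give bit-identical p-values. Calibration: 200 null cohorts × 500
permutations at n = 20 vs 20 on a ~1000-node template give a family-wise
error inside the 95% binomial interval of the nominal 0.05 (measured
0.05 on a 60-cohort pre-run; the full run is in the acceptance suite).

The `rft` route is an explicit approximation: residual smoothness (FWHM)
from normalised residual gradients along template edges (graph steps as
unit distance), resels = masked nodes / FWHM², expected cluster count
from the 2D expected-Euler-characteristic density of a t-field, and
cluster extents via the exponential-tail approximation with mean matched
to the expected suprathreshold volume per cluster. It warns below ~1000
nodes and is never used by the acceptance checks.

Percent differences are `100·(mean_group − mean_control)/mean_control`
per node (zero-control nodes dropped with a warning), summarised per
cluster with the per-node values retained for histograms. Composite maps
label each node with the set of groups whose significant clusters
contain it (empty set = not significant for any group).

## Synthetic generator

The outer surface is a surface of revolution — an open shaft (default
55 mm, radius 15 mm) blending through a narrowed neck (12 mm long,
radius 10 mm) into a spherical head (radius 18 mm) capped at the apex —
plus Gaussian normal-displacement bumps for GT (14 mm tall, σ 6 mm,
lateral) and LT (4.5 mm, σ 6 mm, medial). Longitudinal bump positions
are anchored to the proximal apex, so varying the distal shaft extent
(the "field of view") does not move the anatomy. Ring spacing is chosen
for near-isotropic triangles; rings stop before the apex once they would
violate the aspect bound and the cap closes with a fan (max aspect ≈ 6.5,
well under 20). The default shape is exactly mirror-symmetric about the
plane through the apex and the GT/LT meridians — including the
triangulation, whose quad diagonals flip direction across the plane —
which is what pins FH to the slit midpoint `π`. The inner surface
offsets inward along vertex normals by the thickness field (default
3 mm, curvature-limited to 45% of the neck radius).

Cohorts perturb shaft length (SD 4 mm), neck length (SD 1.5 mm), global
size (log-normal, SD 5%) and add smooth random surface jitter (0.8 mm);
covariates draw body weight from N(65, 8) kg and sideways-fall impact
force from N(2600, 350) N, loosely matching an adult female athlete
cohort. Group effects multiply thickness (realised geometrically through
the inner shell) or the synthetic strain fields inside
(depth, azimuth) windows; thickness noise is smooth multiplicative with
SD 10%. Strain fields are plausible spatial patterns (tensile superior
neck, compressive inferior), standing in for externally computed
finite-element results; they carry no mechanical fidelity.

`make_field_cohort` draws per-node feature matrices directly on a fixed
template (smooth noise + planted multiplicative patch). It exists so the
statistics can be exercised at 200-cohort scale without re-running the
geometric pipeline; the end-to-end chain is tested separately at
5–20-subject scale.

Problem sizes used throughout the suite — 900–2000-vertex meshes,
~1000-node statistics template, cohorts of 6–40 — were chosen so each
subsystem is exercised at full fidelity while a complete run stays in
the minutes range; mesh resolution is a single parameter should larger
runs be wanted.

## What passing tests do and do not show

The generator produces smooth, noise-free, exactly manifold surfaces
whose features are ideal Gaussian protrusions in known positions. Passing
tests therefore demonstrate the *mathematical* contracts — topology of
the surgical chain, flow convergence, conformal invariance, exact
interpolation, statistical calibration — and the pipeline's robustness
to shaft-length/neck-length/size/jitter variation of the kind the method
is designed to absorb. They do not demonstrate robustness to
segmentation noise, holes, self-intersections, non-manifold artefacts,
or anatomies whose trochanters are not conformally separable from the
head; real data needs the quality checks in `mesh_core` and may need
manual feature override (the detection entry points accept explicit
exclusions and prominence thresholds for that reason).

## Known limitations

* Only the 0-curvature (disk/annulus) uniformisations are implemented;
  closed or higher-genus surfaces are out of scope.
* Feature-region matching is rotation-free in the strip frame.
* The RFT route's smoothness estimator uses graph steps, not metric
  distances; treat its p-values as indicative.
* FH-at-π is exact only under mirror symmetry; for real anatomies it is
  a reported diagnostic, not a constraint.
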