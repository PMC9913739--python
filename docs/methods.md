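# Methods

This document records the mathematical models, the parameter choices,
the design of the synthetic data generator, and the numerical decisions
behind `morphosurf`. The README covers usage; this covers *why*.

## 1. Background and scope

Dense-correspondence ("semilandmark") methods extend landmark-based
geometric morphometrics to whole surfaces: a template surface carrying a
few anatomically identifiable *fixed landmarks* plus many evenly spread
*semilandmarks* is mapped onto every specimen, producing homologous
point configurations that standard shape statistics (generalized
Procrustes analysis, PCA, allometric regression) can consume. The
library implements three widely used transfer approaches and the
apparatus to compare them:

* **sliding TPS** (`sliding_tps`) — thin-plate-spline warp of the
  template configuration to the specimen landmarks, projection of the
  warped semilandmarks onto the specimen surface, then iterative
  *sliding* along the surface to minimise TPS bending energy relative to
  the template configuration;
* **LS&ICP** (`ls_icp`) — landmark-guided similarity fit followed by
  rigid iterative-closest-point refinement (scale frozen after the
  initial fit) and nearest-point projection of the template
  semilandmarks;
* **TPS&NICP** (`tps_nicp`) — landmark TPS warp followed by optimal-step
  non-rigid ICP with per-vertex affines and a decreasing stiffness
  schedule; semilandmarks transfer through their barycentric coordinates
  on the deformed template, then project onto the specimen.

Estimated surfaces are produced by warping the template mesh to an
estimated configuration (the Procrustes mean, or an allometric
prediction), and made *comparison-ready* by re-semilandmarking and
re-warping through a common template so that all surfaces share one
vertex-level correspondence.

## 2. Thin-plate splines (3D)

With kernel U(r) = r (the 3D biharmonic fundamental solution up to a
constant), the interpolant through controls X → Y is

    f(x) = c + xB + Σᵢ wᵢ U(‖x − xᵢ‖),

solved from the (n+4)×(n+4) system [[K − λI, P], [Pᵀ, 0]] with
P = [1 | X]. Two numerical points:

* **Sign of the smoothing term.** U(r) = r is *conditionally negative
  definite*: restricted to the subspace Pᵀw = 0 the kernel matrix K has
  negative eigenvalues. The classical smoothing formulation therefore
  subtracts λI (moving those eigenvalues away from zero); *adding* λI
  crosses a singularity at a finite λ and makes the "smoothed" problem
  blow up. The bending energy of a fitted warp is −tr(WᵀKW) ≥ 0.
* **Bending-energy matrix.** Bₑ = −L⁻¹[:p,:p] is symmetric positive
  semidefinite with null space spanned by [1 | X], so affine images of
  the reference have exactly zero energy. Only ratios and orderings of
  the energy are ever used.

Degenerate inputs (duplicate controls, coplanar control sets, fewer
than 5 controls) are rejected with a dedicated `TPSSingularError`.

## 3. Sliding semilandmarks

Sliding minimises tr(YᵀBₑY) over semilandmark positions Y constrained
to the specimen surface, with fixed landmarks immobile. Each iteration
linearises the constraint: every slider moves in its local tangent
plane (from interpolated vertex normals), the generalised-least-squares
step is solved in closed form, and the moved points are re-projected
onto the triangulated surface. Because re-projection can raise the
energy when the surface curves, a step-halving backtrack guarantees the
recorded energy trace is non-increasing; the iteration stops when the
relative energy decrease falls below `slide_tol`.

## 4. Registration

* `similarity_fit` is the closed-form Umeyama solution (proper rotation
  only — biological surfaces are chiral, so reflections are never
  permitted anywhere in the library).
* `icp_refine` alternates nearest-point correspondence with the
  closed-form rigid update; landmark pairs can be pinned as fixed
  correspondences. The objective is monotone non-increasing.
* `nicp_register` is optimal-step non-rigid ICP: per-vertex 3×4
  affines X solve a sparse linear least-squares with an arc-based
  stiffness term α‖MG X‖² that decreases along a schedule, plus
  landmark rows expressed barycentrically. Correspondences whose
  nearest point lies on a border or too far away are down-weighted via
  a validity mask.

## 5. Shape statistics

GPA uses the *partial* Procrustes convention: configurations are
centred and fixed at unit centroid size, then iteratively rotated to
the running mean (proper rotations). Shape PCA operates on the
row-vectorised aligned coordinates; each component's sign is fixed so
its largest-magnitude loading is positive, which makes score tables
reproducible across methods and densities. Allometry is the
multivariate linear regression of superimposed coordinates on
ln(centroid size); predictions at a given lnCS warp the template
through the fitted configuration. No tangent-space projection is
applied (shape variation in all studies here is small).

## 6. Synthetic data generator

Real cranial/head datasets of this kind are generally not
redistributable, so validation uses simulated populations with known
ground truth. From a deterministic base template (an icosphere, an
"ellipsoid head" with nose/brow/chin bumps and a landmark-free scalp,
or a "crested cranium" with a sagittal ridge), each specimen i is

    xᵢ = exp(uᵢ) · (x + (uᵢ − ū)·A(x) + Rᵢ(x)),

where uᵢ is the log-size offset, A is a fixed smooth allometric
displacement field and Rᵢ an independent zero-mean smooth random field
(both TPS interpolants of a few random control displacements).
Configuration points are transported through barycentric coordinates on
the deformed faces, so *true* correspondence is exact by construction.
I.i.d. Gaussian vertex noise — with standard deviation expressed as a
fraction of the RMS vertex radius CS/√p, a point-count-free length
scale — is added only after ground truth is recorded.

### Two study regimes

The population parameters are fixed a priori from a signal-to-noise
analysis, mirroring the two kinds of sample such methods are applied to
in practice:

* **heads-like** (single species): lnCS half-width 0.15, allometry
  scale 0.05, individual deformation 0.015, noise 1%. Used for
  mean-surface recovery: with weak allometry the Procrustes mean is
  estimated to high accuracy (sampling error ∝ S/√n, where
  S = ‖V‖·sd(lnCS) is the allometric shape scatter).
* **apes-like** (interspecific): lnCS half-width 0.5, allometry scale
  0.25, deformation 0.01. Used for allometry recovery: the expected
  angle between fitted and true slope fields is ≈ atan(ρ/(S√n)) for
  residual scatter ρ, so a strong, well-spread size signal is what
  makes the slope identifiable above noise.

A single regime cannot satisfy both a tight mean-recovery bound and a
tight slope-angle bound at n = 50 — the two error terms pull the
allometry strength in opposite directions — hence the two named study
designs in `morphosurf.experiments`.

The allometry-recovery study fits the regression to the *noisy
configurations* (ground-truth correspondences plus measurement noise)
rather than to pipeline-placed semilandmarks. This isolates statistical
recovery of the field from semilandmark-placement differences, which
are themselves size-correlated; the placement effect is studied
separately by the size-prediction-spread experiment.

### Shared populations in comparison studies

The density-convergence and size-prediction studies simulate **one**
population at the maximum density and vary only the semilandmark
template (lower densities use the first *d* template semilandmarks).
Re-simulating per density would change the random stream and confound
population sampling noise with the density effect. All estimates are
re-warped through the maximum-density template before comparison, so
vertex sets are commensurable.

## 7. Pipeline and reproducibility

`run_pipeline` executes a methods × densities × targets grid from a
YAML config: per-cell semilandmarking, GPA, PCA score/variance tables,
mean and allometric-prediction surfaces, a landmark-only baseline,
re-warping, between-method and density-convergence tables, per-face
area-difference maps (relative triangle-area change after scaling to
common centroid size), and a manifest recording the config, library
versions, seeds and per-stage timings. Identical config + seed yields
byte-identical tables; every randomized stage takes an explicit seed.

## 8. Limitations

* Surface semilandmarks only; curve (ridge) semilandmarks and
  Procrustes-distance-criterion sliding are out of scope.
* Sliding over landmark-free regions (e.g. the ellipsoid head's scalp)
  is poorly controlled — an intrinsic property of the method, not
  mitigated here.
* The re-semilandmark/re-warp operation is an exact fixed point only on
  the template's own warped surface; on deformed surfaces repeated
  application contracts geometrically rather than terminating after one
  pass.
* Allometric regressions fitted to pipeline-placed semilandmarks absorb
  size-correlated placement bias; slope-field angles of tens of degrees
  against the generating field are expected there, which is precisely
  the between-method disagreement the size-prediction study measures.
* TPS warps are global and can fold for extreme deformations; no
  fold-over detection is performed.
* Meshes must be clean, oriented triangle surfaces; the loader drops
  degenerate faces and unreferenced vertices but does not repair holes
  or self-intersections.
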