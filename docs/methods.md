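# Methods

This note records the models, conventions and numerical choices behind
`lensrecon`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the open design decisions were settled.

## Coordinates and units

Right-handed instrument frame: +Z from the instrument into the eye, X
along the temporal→nasal axis, Y inferior→superior, origin at the on-axis
corneal apex before registration; millimetres throughout. Meridian angles
span [0, π) at 0.048 rad steps; a direction flag (±1) distinguishes the
two half-meridians, and an angle of exactly π is normalised to 0 with the
flag flipped. A-scan index (n_ascans − 1)/2 maps to lateral 0 mm; the
lateral pitch is 14 mm / 256 A-scans (the instrument's lateral pitch is
not part of the calibration constants, so this value is configurable).
Axial pixel positions are optical path lengths at 9.2 µm/pixel.

## Phantom forward model

The phantom is an analytic anterior segment: conicoid anterior/posterior
cornea (apex radii 7.8/6.5 mm, conic −0.25, central thickness 0.55 mm),
an iris plane 0.1 mm anterior of the lens apex (anterior chamber depth
3.0 mm), and a lens built from two conicoid caps meeting exactly at the
equator. The caps are parametrised by (diameter, thickness, anterior
thickness fraction, apex radii); each conic constant is solved from
r_eq² = 2Rh − (1+k)h², and an apex radius above r_eq²/h is rejected
because the cap would bulge wider than its own equator. The
`young_adult` preset (DIA 9.2 mm, thickness 3.9 mm, anterior fraction
0.42, radii 10.5/6.0 mm, dilated pupil radius 3.5 mm) is a plausible
dilated adult eye; `spherical` makes the lens a full sphere so every
metric has a closed form. Corneal apertures are truncated at
physiological semi-diameters (5.5 / 5.2 mm), which also bounds the
surface slopes a 15-term Zernike expansion must represent (residuals of
order 1 µm over those apertures).

Forward simulation rotates the whole phantom rigidly about the
iris-circle centre by the gaze angle (no cyclotorsion, matching the
rigid registration model), traces one telecentric ray per A-scan per
meridian, applies vector Snell refraction at each conicoid (closed-form
line–quadric intersection), and records each crossing as cumulative
optical path length (segment length × group index) in axial pixels.
Lens samples whose aqueous-segment ray meets the iris annulus are
missing; rays that miss a surface or suffer total internal reflection
drop their deeper samples. Gaussian iid pixel noise is added to axial
coordinates only (axial localisation dominates OCT segmentation error);
lateral sampling is exact. A single index per medium serves both ray
bending and OPL conversion — the group values 1.385/1.345/1.417 — since
a phase/group split is not resolvable from the data this pipeline
consumes. The simulator and the corrector draw from the same
`OpticalMedia`, so the correction is the exact inverse of the forward
model; a phase-index variant would slot in as a second `OpticalMedia`
used only for the refraction step.

DIA/VOL/LSA ground truth comes from 1-D adaptive quadrature over the cap
profiles (volume by shells, area by surface-of-revolution integrals),
fully independent of the pipeline's polar-grid computation, and
cross-checked in tests against a voxel-counting oracle.

## Cleaning

Eyelash artifact rejection follows the iterative rule: fit a low-order
polynomial (default order 4 — high enough for corneal sagitta over a
14 mm scan, low enough not to chase spikes), discard samples beyond
3 residual SDs, refit until stable (≤ 10 passes). The residual SD is
recomputed each pass. A 3·SD rule has a limited breakdown point: a
contiguous spike cluster covering ~17 % of a short trace inflates the SD
enough to be self-masking, so the test fixtures use realistic
contamination (a few A-scans of a 256-sample trace). Manual click-points
(≥ 5) are densified with a monotone shape-preserving cubic (PCHIP): it
cannot overshoot, so it never fabricates lens periphery, at the cost of
lower smooth-curve accuracy than an unconstrained spline (~tens of µm at
6 clicks over an 8 mm arc, ~5 µm at 16 clicks). No extrapolation beyond
the clicked span: uncovered regions stay missing because they could not
be distortion-corrected anyway.

## Zernike surfaces

OSA/ANSI single-index ordering with unit-variance normalisation
√(2(n+1)/(1+δ_m0)); 15 terms = radial orders ≤ 4. Terms are expanded
into exact bivariate Cartesian polynomials in normalised coordinates, so
evaluation and gradients (needed for ray–surface normals) are exact and
pole-free. The normalisation radius is the support's maximal lateral
radius × 1.001 about the data centroid, keeping the design matrix
conditioned on partial off-axis domains; the fit is plain least squares
(artifact rejection precedes fitting) via SVD. The evaluation domain is
the convex hull of the supporting data (Delaunay membership) — for the
cap- and sector-shaped domains this pipeline produces, the hull is an
adequate stand-in for a concave alpha-shape, and evaluation outside it
is refused rather than extrapolated.

Off-axis incidences tilt the whole anterior segment by up to 45°;
fitted as graphs over the instrument lateral plane such surfaces waste
the low-order basis on tilt and leave residuals of tens of µm. Each
incidence therefore carries a *fit frame*: the rotation taking the
apparent iris-plane normal to +Z, estimated by total least squares from
the raw iris points. All surfaces of that incidence are fitted as graphs
in this frame (residuals return to ~1 µm), and the ray tracer transforms
rays into the frame for intersection (Newton iteration with the analytic
gradient) and transforms normals back.

## Distortion correction

Surfaces are rebuilt front to back (CP, then LA, then LP), refitting each
corrected surface before the next refraction — the correction at each
depth then uses true, not apparent, anterior geometry. For each A-scan
ray the recorded crossing depths give the per-segment OPLs directly, so
the corrected point is placed by advancing the refracted ray by OPL/n;
the fitted surfaces supply only the refraction normals. A ray whose
anterior-surface sample is missing cannot be corrected and its deeper
samples are dropped. Iris points are corrected through cornea and
aqueous by default (`iris_mode="raw"` keeps apparent points, since which
variant was used upstream is not always known). On the noiseless
phantom the correction inverts the forward distortion to ≈ 1 µm RMS per
surface on-axis and a few µm at 45°; the residual is the Zernike
representation error, not the ray tracing. The 3-D character matters:
at oblique incidence corrected points leave their meridian plane by
well over 10 µm, which no per-meridian 2-D correction can reproduce.

## Registration

The iris anchors the initial alignment: a total-least-squares plane
(smallest principal direction) for tilt, then a circle fit for the
centre. Segmented iris points generally cover a band of the iris disc,
so the circle is fitted to the *inner margin* (innermost point per 5°
angular bin — the pupil edge); when the input's radial spread about that
margin is below 50 µm the input is already a thin pupil-margin trace and
all points are used, avoiding the inward bias of minimum-selection under
noise. Circle fitting is Taubin's algebraic fit polished by
Gauss–Newton. The minimal rotation (axis = normal × Z) maps the iris
normal to +Z and the circle centre moves to the origin; because gaze
rotations have axes perpendicular to Z, this recovers them exactly on
noiseless data (the component about the line of sight is unobservable
from the iris and is left to ICP).

ICP refinement is point-to-point with nearest-neighbour correspondences
on the lens surfaces only (the lens is the rigid structure shared across
gaze-rotated views; the cornea is not, since the views overlap on
different corneal sectors after rotation about the iris centre).
Trimming keeps a fixed count — the best 80 % of source points — which
makes the trimmed MSE provably non-increasing across iterations; the
0.5 mm gate is only a "no overlap" guard. Convergence at MSE
improvement < 1e-8 mm² or 100 iterations. Views are registered
sequentially by increasing gaze angle against the union of already
registered lens points, maximising overlap with the growing reference.
Inter-incidence overlap RMS over mutually observed regions is reported
as the registration audit.

## Eigenlens basis and projection

The merged lens cloud is centred laterally under the anterior surface's
most anterior point and axially at the midpoint of the two apex depths
(both found on smooth low-order fits of the central surfaces), then
resampled as radial elevations I(θ, φ) on the fixed polar grid
(θ ∈ [0, π] pole to pole, P = 100; φ ∈ [0, 2π), Q = 100). Node values
are barycentric-linear interpolations over a Delaunay triangulation of
the sample directions in the parameter plane with periodic azimuth
padding and pole reflection. A node is left *unobserved* when it lies
outside the data, farther than 3 grid pitches from any sample direction,
or inside a triangle spanning a data gap (any edge over 3 pitches in the
metric dθ² + (sinθ dφ)²) — interpolating across a gap would cut a chord
under the equator instead of measuring it. Near the poles, where the
chart degenerates, rejected nodes are filled by inverse-distance
weighting on the sphere with a cone adapted to the local sampling
density. A star-convexity audit (near-identical directions with
conflicting radii) is reported with the grid.

The training population is a synthetic parametric family of two-cap
lenses — diameter U(8, 10.5) mm, thickness U(3.2, 4.8) mm, anterior
fraction U(0.40, 0.44), apex radii U(0.6, 0.98) of the geometric maximum
r_eq²/h — evaluated analytically on the grid; 40 lenses by default,
fixed seed. The basis is the SVD of the centred training matrix, first
6 right singular vectors; the serialised basis format (JSON with
checksum) accepts an externally trained basis with the same grid.
Because the family is rotationally symmetric the eigenlenses are
functions of θ only; azimuthal irregularity of a measured lens is
averaged, which is part of the smoothing role of the projection.

Complete grids project orthogonally, a = Mᵀ(I − Ī). With missing nodes
the normal equations restricted to observed rows are used, stabilised by
the training eigenvalue prior (the probabilistic-PCA posterior mean,
ridge σ²Λ⁻¹): the trailing eigenlenses are concentrated exactly where
data are missing (the equator), so the bare restricted Gram matrix can
be near-singular and would amplify µm-scale model mismatch into
hundreds of µm at the equator. The noise scale σ defaults to 5 µm — the
verified accuracy of the distortion-corrected surfaces — and is
configurable (`projection_noise_sd`).

## Quantification

- **DIA**: per azimuth, the maximal lateral radius I·sinθ over elevation,
  refined below the grid pitch; the diameter is the maximum over opposite
  azimuth pairs of the two-sided sum. The refinement distinguishes a
  *corner* equator (generic for a lens: two surfaces meeting with a slope
  break; refined as the intersection of the two branch secant lines) from
  a *smooth* equator (3-point parabola), by whether the second difference
  at the peak dominates its neighbours five-fold. Errors at the default
  grid: ≲ 0.1 % for two-cap lenses, ≲ 0.04 % for smooth shapes.
- **VOL**: star-convex volume element I³sinθ/3, integrated by composite
  trapezoid in elevation and periodic rectangle rule in azimuth, split at
  the per-azimuth equator into anterior and posterior parts whose sum is
  reported (the parts are exact partial integrals, so the split is free).
- **LSA**: Delaunay triangulation in the parameter plane (seam column
  duplicated; pole rows close as degenerate fans) and the sum of 3-D
  triangle areas; an inscribed mesh, so convergence is from below.

Sphere limits at the default grid are within 0.5 % for all three metrics
(DIA ~2×10⁻⁶ %, VOL 0.008 %, LSA 0.045 %), and errors at least halve per
grid doubling.

## Statistics

Coefficient of variation uses the sample (n−1) SD: this convention
reproduces the published repeatability CVs from their measurement
triplets (five of six to the printed 2 decimals by rounding; the
volume triplet 188/190/191 mm³ computes to 0.8054 %, printed 0.80 — the
inputs are themselves rounded to 3 significant figures, and all six
match under truncation to 2 decimals). Spearman's ρ uses midranks;
the two-sided p-value is exact (full n! permutation enumeration) for
n ≤ 9 and the t-approximation otherwise. Bland–Altman reports the mean
difference and MD ± 1.96·SD (sample SD) limits of agreement.
Shapiro–Wilk gates normality at p < 0.05, routing to non-parametric
summaries (scipy's implementation, cross-checked against an independent
R oracle in the tests).

## What the phantom does and does not establish

Passing the round trip shows the pipeline inverts its own forward model
— refraction physics, OPL bookkeeping, occlusion geometry, rigid view
misalignment — to sub-percent metric accuracy at the study's sampling
(65 meridians × 256 A-scans × 8 orientations), and degrades gracefully
with axial pixel noise. It does not exercise: segmentation of intensity
images (only segmented coordinates are simulated), gradient-index lens
optics (a constant lens index is assumed; the `index-sweep` CLI
reproduces the n_lens ∈ {1.40, 1.417, 1.44} sensitivity check),
accommodation or fixation instability between acquisitions beyond rigid
motion, cyclotorsion, and real lens surface irregularity beyond the
two-conicoid family (azimuthally asymmetric lenses are smoothed toward
symmetry by the synthetic basis; dropping in a basis trained on real
full-lens data lifts this limit).

## Problem sizes

Defaults reproduce the full study geometry: 65 meridians × 256 A-scans
× 8 orientations (≈ 133 000 rays), 10 000-node grid, 40 training lenses.
The complete noise-free round trip runs in well under a minute on one
CPU; the test suite regenerates all fixtures programmatically.
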