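# Methods

## Acquisition model

The object of interest is a raised lesion on (approximately) planar
healthy skin, photographed in side view against a contrasting
background while rotated about the axis normal to the base plane. A
*radial section* at rotation angle *y* is the diametral height profile
z(x), with x the signed distance from the rotation axis (mm) and z the
height above the base plane (mm). Because x is signed, a half turn of
angles [0°, 180°) already covers the full object; section angles are
therefore normalized modulo π at ingestion, and files/manifests carry
human-facing degrees while the API works in radians. All lengths are
millimetres; mixed-unit inputs must be converted at ingestion.

The canonical acquisition is six sections at 30° steps
(`AcquisitionPlan()` default). The default profile sampling (101
samples per section) emulates digitizing a photographed profile at
sub-millimetre resolution; acquisition noise is additive Gaussian on
the heights, default 0 (a static phantom under controlled lighting),
explicitly settable for robustness studies. All randomness flows
through one seeded `numpy` generator, so identical seeds give
bit-identical datasets.

## Two-layer polynomial surface

Stage one fits every section with a degree-N polynomial by linear least
squares; stage two fits each coefficient's dependence on the section
angle with a degree-M polynomial. The result is the bivariate surface
z(x, y) = Σ_i Σ_k b_ik y^k x^i, held as the (N+1)×(M+1) matrix B.
Defaults N = 12, M = 5 (13 × 6 coefficients for six sections; N = 8
gives 9 × 6). M = 5 with six sections makes the second layer an exact
interpolation across angles; more sections turn it into a genuine
smoothing fit.

Numerical choices:

- Both stages fit on coordinates affinely mapped to [−1, 1] (one shared
  x scaling across sections, stored in the model together with the
  angle scaling, so evaluation in original units is exact). A raw
  degree-12 Vandermonde matrix has condition number far beyond double
  precision; raw fitting is kept behind `scale=False` with a warning,
  for demonstration only.
- Least squares is solved by orthogonal decomposition
  (`numpy.linalg.lstsq`), i.e. the minimizer of ‖Z − Va‖₂ with the
  minimum-norm solution on rank deficiency; a rank-deficient design is
  rejected rather than silently regularized.
- Exact recovery: any polynomial surface of degrees ≤ (N, M) sampled
  noiselessly on enough distinct points is reproduced to ≤ 1e−8 mm
  (tested; in practice ~1e−14).
- Evaluation outside the fitted (x, y) ranges is permitted but raises
  an `ExtrapolationWarning` — high-order polynomials diverge quickly
  off-domain.
- No continuity constraint ties the sections together at x = 0; the
  seam mismatch is absorbed by the second-layer fit and is quantified
  by the phantom tests rather than constrained away.

Two fixed contour polynomials (degree 3 for a concave outline segment,
degree 5 for a convex one, each with an additive correction offset G)
are packaged as evaluators for piecewise 2-D outline approximation;
their coefficients are treated as dimensionless fixture data.

## Meshing and measures

The fitted surface is triangulated structurally: rectangles get two
triangles per grid cell; discs get a centre fan plus rings with a fixed
angular count (max(8, ⌈2πR/h⌉) for element size h), so meshes are
deterministic given domain and element size. In `section-space` frame a
vertex at polar (r, θ) is evaluated as x = ±r with angle θ mod π and
embedded at (r cos θ, r sin θ, z).

- **Area**: sum of triangle areas (half cross-product magnitudes);
  effective skin area S = k·∫dS with the dimensionless elasticity
  coefficient k (default 1.0). No age→k table is built in — k is an
  input, since skin stiffening with age is patient-specific.
- **Volume**: two independent routes must agree to 0.1% — (a) vertical
  prisms (projected triangle area × mean vertex height) and (b) the
  divergence theorem on the mesh closed with side walls and a base
  polygon. Route (b) is also cross-checked against `trimesh` in the
  test suite.
- **Mass / centroid / mean density**: composite midpoint quadrature
  per vertical prism with n_z = 8 height subdivisions. For uniform
  density this is exact (m = μV, centroid of the prism stack); for
  varying μ the error is O((h_prism/n_z)²). A single midpoint per prism
  would bias the z-moment of height-dependent densities (e.g. μ ∝ z on
  a unit slab gives z̄ = 0.5 instead of 2/3), hence the subdivision.
  Mean density is m/V by construction.
- **Resection measurements**: the straight-line distance uses the two
  given points; surface path and depths use the nearest mesh vertices
  (each input must lie within one element size of a vertex). The
  along-surface path is the shortest edge path (Dijkstra on the edge
  graph) — an upper bound on the true geodesic, adequate at the 0.4 mm
  default element size; exact geodesics are out of scope.
- Exports are ASCII OBJ/PLY/STL with fixed 9-significant-digit
  formatting, so identical inputs give byte-identical files.

The base plane z = 0 (healthy skin) is configurable via `base_z`.
Area and prism volume are invariant under rotations about the z axis;
volume referenced to a base plane is *not* invariant under arbitrary
rotations, by construction.

## Silhouette imaging

Binarization normalizes polarity (object dark or light), thresholds,
and keeps the largest 4-connected component (ties broken by leftmost
bounding box). The automatic threshold is Otsu's inter-class-variance
maximizer over 256 bins, implemented in-package with one refinement:
when the histogram is bimodal with an empty gap, every cut through the
gap attains the same maximal variance, and the *middle* of that plateau
is returned. (A first-maximizer tie-break — as in common library
implementations — lands on a cluster edge, which is fragile under
small histogram perturbations.) The implementation is verified against
an exhaustive search oracle.

The profile is the column-wise upper envelope of the mask: topmost
foreground row per column, heights measured from the bottom image row,
x measured from a symmetry axis that defaults to the foreground
centroid column and is user-overridable. Objects touching the top
border are rejected as clipped. Only grayscale input is processed;
color frames collapse to Rec. 709 luminance at load.

## Phantoms

Three analytic height fields with closed-form measures serve as the
validation bed: a hemisphere (area 2πR², volume ⅔πR³, centroid height
3R/8), a sum of Gaussian bumps (the asymmetric "complex lesion" case;
default: an 8 mm dome with two satellite bumps within a ~16 mm support,
roughly the footprint of a small lesion), and a half-ellipsoid. The
virtual rig samples sections and renders binary silhouettes whose upper
envelope matches the analytic profile within one pixel, closing the
loop photograph → extraction → reconstruction in tests.

What the phantoms do *not* emulate: perspective and lens distortion,
specular highlights, shadows, soft tissue deformation between views,
and operator misalignment of the rotation axis. Passing phantom tests
therefore demonstrates correctness of the numerical pipeline, not
robustness to real acquisition artifacts.

## Error budget

Guidance error chains as: δT = √(δTx² + δTy² + δTz²) (half-resolution
representation error per axis); δV = δT + δC + δM — the image-derived
terms are treated as fully correlated, so the general combination
√(δ1² + δ2² + 2Kδ1δ2) collapses to plain addition at K = +1 (an RSS
mode exists behind a flag for sensitivity studies); per-axis mechanical
errors are linear sums of six drive components (backlash, kinematic,
shaft twist, support gap, clutch, thermal); δP is their RSS over the
three axes; δR = √(δV² + δP²) at K = 0. The boundary-determination
error δC and methodological error δM are opaque inputs. Reference
components (δTx = δTy = 0.25, δTz = 0.5, δC = 1.13, δM = 0.5,
δP = 0.41 mm) give δT = 0.6124, δV = 2.2424, δR = 2.2795 mm.
Displayed values truncate toward zero at two decimals (0.61 / 2.24 /
2.27); internal values keep full precision.

## Discriminant screening

Per-parameter means and SDs in normal (Θ0) and pathological (Θ1)
states, with the conservative spread σᵢ = max(σᵢ(0), σᵢ(1)), give the
diagonal Mahalanobis separation δ = Σ (mᵢ(0) − mᵢ(1))²/σᵢ² (default);
a signed non-squared variant is selectable as `as-printed` for
comparison with applied texts that omit the square. The decision-error
bound is P ≤ 1 − Φ(δ/2) with Φ the standard normal CDF, or optionally
the Laplace function Φ − ½ (some handbooks tabulate that convention;
under the CDF reading a bound above 0.5 is impossible for δ > 0). A
packaged five-parameter reference table (state means plus reported
distances and bounds) ships as data only: the SDs behind its reported
distances are not available, so the table is loadable but never used
as a target for the formulas.

## Validation metrics

Calculated-vs-actual pairs are summarized by OLS (via statsmodels):
intercept/slope, residual SD S = √(SSR/(n−2)), R², the regression F
test and per-coefficient t tests at a user-chosen α. The average
approximation error A̅ is the mean absolute relative deviation in
percent over pairs with nonzero calculated value (zeros excluded and
counted); it is scale-invariant. The conventional quality gate rates a
model "good" iff A̅ ≤ 10% (threshold configurable). Residual
diagnostics report the mean, lag-1 autocorrelation and a runs count of
residual signs (residuals below 1e−12 of the largest are treated as
zero so exact fits are not miscounted).

## Problem sizes and tolerances used in the checks

The automated checks run a 10 mm hemisphere at 0.2 mm elements (~31k
triangles) for closed-form geometry (area/volume within 1%, centroid
height within 2%), 0.25 mm elements for the full section→surface→mesh
pipeline (volume within 5%; the rim's vertical tangent dominates), and
the 16 mm Gaussian-bump phantom for data-scaling and noise-scaling
properties. Least-squares stages are compared against independent
normal-equation oracles at 1e−8; coordinate round trips at 1e−12; the
two volume routes at 0.1%.

## Known limitations

- A single-valued height field z(x, y) cannot represent overhangs or
  undercut lesion rims.
- Profiles with near-vertical flanks (the hemisphere rim) limit the
  achievable polynomial accuracy at fixed order; accuracy improves with
  more sections/samples only up to that approximation floor.
- The edge-path resection distance overestimates the true geodesic by
  up to the mesh anisotropy factor; refine the mesh for tighter paths.
- The discriminant uses per-parameter variances only (no covariance);
  correlated parameters will overstate the separation.
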