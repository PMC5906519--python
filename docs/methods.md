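# Methods

## Model

The ST-segment extracellular potential in a slab of ventricular tissue in
contact with a blood volume satisfies the passive bidomain equation

    div((M_i + M_e) grad phi_e) = -div(M_i grad phi_m)        (tissue)
    g_b lap phi_b = 0                                          (blood)

with potential and total normal current continuous across the endocardium,
insulated lateral walls and epicardium, and phi_b = 0 at the bottom of the
blood. The geometry is a 16 cm x 16 cm x 1 cm slab (epicardium at z = 0) over
a 25 cm blood layer; a 4 cm x 4 cm ischaemic region is centred at the origin
and reaches from the endocardium down to a fraction `depth` of the wall.

The transmembrane source is prescribed analytically,
`phi_m = dphi_p * Psi(x) Psi(y) Psi(1-z)`, where `Psi` is a smoothed
indicator with half-widths (2, 2, depth) cm and border steepness
lambda = 0.01 cm, and dphi_p = -30 mV is the plateau offset. The border is
therefore ~1 mm wide — sharp by design; no attempt is made to model wider
experimentally observed border zones.

Fibres lie in planes parallel to the epicardium, aligned with +x at z = 0
and rotating linearly through the wall by a total angle ROT (anticlockwise
viewed from outside the epicardium; this sign convention reproduces the
anticlockwise rotation of the potential pattern with increasing ROT).
Conductivity tensors are `M_p = A G_p A^T` with `G_p = diag(g_pl, g_pt,
g_pn)` and A the z-rotation by the local fibre angle; sheets never incline
relative to the epicardium, a known simplification.

### Parameters

Defaults (mS/cm; degrees for ROT), each varied uniformly over
mean +/- 50 % (ROT: 100 +/- 40):

| input | min | mean | max |
|-------|-----|------|-----|
| ROT   | 60  | 100  | 140 |
| g_b   | 3.25| 6.5  | 9.75|
| g_il  | 1.2 | 2.4  | 3.6 |
| g_el  | 1.2 | 2.4  | 3.6 |
| g_it  | 0.12| 0.24 | 0.36|
| g_et  | 0.8 | 1.6  | 2.4 |
| g_in  | 0.05| 0.1  | 0.15|
| g_en  | 0.5 | 1.0  | 1.5 |

The means give bulk conductivity ratios g_l/g_t = 2.6 and g_t/g_n = 1.7 and
conduction-velocity ratios c_l/c_t = 2.4, c_t/c_n = 1.5, inside the range
of published measurements (shipped as `data/literature_conductivities.csv`;
the summary row uses the sample standard deviation, which reproduces the
published summary to one decimal).

## Discretization and solver

The mesh is tensor-product hexahedral: lateral coordinates geometrically
graded toward the ischaemic border x, y = +/-2 cm, uniform fine z spacing
through the wall, geometric stretching through the blood. Presets: `full`
(61 x 61 x 101 nodes = 375,821, 0.2 mm wall resolution), `coarse`
(33 x 33 x 33; the default for studies) and `tiny` (25 x 25 x 21; unit
tests). The exact grading law is a package choice (configurable); only the
full preset's node/cell counts and average resolutions are fixed targets.

The spatial scheme is a vertex-centred control-volume/trilinear-element
discretization. Each term of the weak form factorizes into Kronecker
products of 1-D mass/stiffness/gradient matrices because the tensors vary
with z only; the fibre-rotation cross-derivative terms use the same
factorization and keep the matrix symmetric. Assembly is exact for
piecewise-constant-per-layer coefficients and costs milliseconds. The
bottom Dirichlet plane is eliminated, leaving an SPD system. A manufactured
smooth solution with a full anisotropic tensor converges at second order in
the mesh spacing (tested on nested uniform meshes).

The right-hand side is the weak divergence of the intracellular source
current `-A_intra phi_m`, assembled with the same flux stencil and with
M_i = 0 in the blood, so intracellular current cannot cross the endocardium
and insulated boundaries carry zero source flux. The stated boundary
conditions are the natural conditions of the weak form.

Linear solves use conjugate gradients with an exact fast-diagonalization
preconditioner for the separable (cross-term-free) part of the operator:
generalized eigenbases of the 1-D (stiffness, mass) pencils in x and y
reduce it to independent tridiagonal systems in z, factorized once per
parameter set and swept vectorized. Only the fibre-rotation coupling is
left to CG, which converges in ~10-30 iterations at relative tolerance
1e-8, independent of mesh size; a SuperLU direct path is kept for
verification. Solutions are cached per (parameter set, mesh) inside each
study, which the nested sparse-grid levels exploit.

## EPD features

cminV/cmaxV are the min/max over nodes with |x|, |y| <= 2 cm at z = 0, and
ominV the minimum over the remaining epicardial nodes. Patterns partition
as: elevation iff cmaxV > 0; else type 2 iff ominV < cminV; else type 1.

Extremum angles (angmin, angmax) locate a strict 8-neighbour local
extremum with y > 0 (outside the footprint for angmin), refine it with a
local least-squares quadratic (clipped to the surrounding cell, which
suppresses the stepped-angle artefact of finite grids), and report
atan2(y, x) reduced to [0, 180). Ties are broken toward the smaller angle;
a missing qualifying extremum yields None rather than an error.

The ellipse orientation of the depression is the principal-axis angle of
the area-weighted second moments of the connected component of
{phi <= level * cminV} containing the central minimum, with level = 0.2 by
default. The published analysis fitted an ellipse to the plotted contour
but named no level or method; second-moment fitting on the depression
contour component was chosen because it is grid-robust and equivariant
under rotation. Probes across conductivity jitter showed the 0.2-level
component is better conditioned (axis ratio further from 1, smaller
repeat-scatter) than the deep 0.5-level core; at high ROT the depression
becomes nearly circular (axis ratio ~1.1) and the orientation is
intrinsically noisy — the axis ratio is reported so degenerate fits can be
flagged. Because the contour is referenced to zero potential, the ellipse
angle — unlike the extremum angles — is not invariant under adding a
constant to the field.

## Polynomial chaos

Uniform input uncertainty is propagated by stochastic collocation on
Smolyak sparse grids built from nested Clenshaw-Curtis rules with growth
1, 3, 5, 9, ... points (the only standard growth giving 85 and 389 nodes in
six dimensions at levels 2 and 3). Mean and standard-deviation fields are
the weighted moments `sum_j w_j f_j` and `(sum_j w_j (f_j - mean)^2)^1/2`;
since Smolyak weights may be negative, the variance field is clipped at
zero before the square root. Level-2/level-3 agreement is measured by the
node-wise Pearson correlation and the relative Euclidean norm error
||a - b|| / ||a|| (the reference metric is not uniquely defined in the
literature; this definition is configurable).

## Gaussian-process emulation

Each scalar feature gets a universal-kriging emulator: linear mean
h(x) = (1, x), squared-exponential kernel with per-dimension length-scales,
and a noise nugget, all estimated by profile maximum marginal likelihood
with multi-start L-BFGS (deterministic starts covering the interpolating
and the smooth/noisy likelihood basins, plus seeded random restarts).
Inputs are normalized to [0, 1] by the parameter ranges. Training follows
the split-validate-refit pattern: hyperparameters on 90 % of the design,
Mahalanobis validation of the joint predictive on the held-out 10 %, final
refit on everything with the verdict frozen. The Mahalanobis reference
distribution is taken as m * F(m, n - q) (test size m, n training points,
q = d + 1 regressors), whose mean is approximately m; the exact scaled-F
form in the source methodology is not reprinted, so only the mean/sd-level
comparison is relied on.

Main effects E{f(x)|x_w} (remaining inputs independent N(0.5, 0.04) on the
normalized scale) and main-effect sensitivity indices
Var[E{f(x)|x_w}]/Var{f(x)} (all inputs N(0.5, 0.02)) are computed in closed
form from the Gaussian integrals of the kernel; truncation of the normals
to [0, 1] is ignored (the inputs' +-0.2 sd covers the cube). The reported
indices are posterior means of the random variances under the fitted
process: closed-form corrections involving the integrated predictive
covariance are added to the plug-in variances (verified against Monte
Carlo), and the estimated noise variance is included in the total-variance
denominator. A plug-in variant is available
(`include_emulator_uncertainty=False`).

## Partial least squares

Outputs are regressed on standardized inputs (and on seven conductivity
ratios) by NIPALS PLS, delegated to scikit-learn, with all min(p, 8)
components retained by default so that well-conditioned designs give
standardized least-squares coefficients; coefficients are comparable only
within one output. Latin-hypercube designs are plain seeded stratified
sampling (no maximin or correlation reduction), so finite designs carry
spurious input correlations of order 1/sqrt(n) that shrink standardized
coefficients slightly — one reason studies here use the full published
design sizes rather than smaller ones.

## Synthetic data

The surrogate generator produces functions on [0, 1]^8 with linear, sine
and pairwise-product terms whose main-effect indices under independent
normal inputs follow in closed form from the ANOVA decomposition; they are
the ground truth for emulator-recovery tests. Synthetic EPDs are sums of
anisotropic Gaussian wells/peaks with features computed by brute force on a
0.05 cm oracle grid. The mock simulator composes three such blobs so that
the pattern class walks type 1 -> type 2 -> elevation with depth, the flank
minima rotate at 0.5 deg per degree of ROT, and the centre deepens with
g_in and shallows with g_en; it is not calibrated to physical magnitudes
and exists for pipeline tests only. What passing mock-backed tests show is
that the analysis stages are correct, not that the physics is — the
solver-backed studies cover that separately.

## Study definitions and desk-scale sizes

* PC depth sweep: six conductivities on the level-2 grid (85 solves per
  depth), g_b = 6.5, ROT = 100 fixed.
* Scenarios: type 1 (depth 10 %), type 2 (30 %), elevation (60 %); LHC over
  the eight inputs, runs filtered to the target class in generation order
  and truncated to a multiple of ten, then GP + PLS per output.
* angmin study: ROT 60-140 and depth 30-80 % co-varied, conductivities at
  means.

This package runs these studies on the coarse mesh with the published
design sizes (250 for the scenarios with 240 used, 750 for the 30 %-depth
classification, 250 for the angmin study); the unit-test suite uses the
tiny mesh and smaller designs. The coarse-mesh polynomial-chaos extrema
carry a documented tolerance of +-0.2 mV relative to full resolution; in
practice they agree to ~0.05 mV.

## Known limitations

* Slab geometry, no torso, no sheet inclination, sharp (1 mm) ischaemic
  border, purely passive membrane: structural simplifications shared with
  the modelling tradition this follows.
* At high fibre rotation the type-1 depression contour is nearly circular,
  so its orientation — and every statistic built on it — is intrinsically
  noisy at coarse resolution.
* Sensitivity-index sums for very smooth features (e.g. cminV) come out
  near 0.99: the desk-scale responses are nearly additive over the +-0.2 sd
  input perturbations and the emulator's residual uncertainty is tiny, so
  little variance is left unexplained.
* The ellipse contour level, the relative-error metric, the LHC variant and
  the Mahalanobis reference moments are documented package choices where
  the source methodology leaves them open.
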