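# Methods

This note records the statistical model, the numerical conventions, and the
design choices behind `spmtopo`, at the level of detail a user needs to
judge what the package's results do and do not establish.

## Model and procedure

A mass-univariate GLM **y** = **X**β + **e** is fitted site-wise by ordinary
least squares. Residuals are standardized per site to squared norm
ν = N − p, so each of the N standardized residual fields is a unit-variance
field with the spatial correlation of the noise — under the model, a
realization of a Gaussian (Z) random field. The test SPM is, under the null,
a central t (or F) field.

The package estimates the Lipschitz–Killing curvatures
L = (L₀, …, L_D) of the search space in two independent ways:

1. **Smoothness (simplex-volume) estimator.** The search lattice is
   triangulated (see below) and each element is assigned the volume it
   occupies in the "statistically flattened" space, where the distance
   between two sites is the Euclidean norm of the difference of their
   *unit-norm* residual vectors (standardized residuals divided by √ν).
   With that normalization an edge length estimates √(2(1 − ρ)), whose
   small-lag limit is the gradient-variance metric of the flattened field;
   using √ν-scaled vectors instead would inflate L_d by ν^(d/2).
   L_D is the sum of top-dimensional simplex volumes
   (1/d!)·√det(ΔRᵀΔR); L₀ is the Euler characteristic of the mask.
   Intermediate curvatures use lattice inclusion–exclusion counting
   (edges − squares + cubes) with residual-metric element sizes, which
   reduces to the classical resel-counting formulas for homogeneous
   smoothness. Only L₀ and L_D enter the threshold-free pipeline; the
   intermediate dimensions serve the classical comparisons.

2. **EC-curve regression estimator.** Since
   E[φ(A_u)] = Σ_d L_d ρ_d(u) at *every* threshold, the observed EC curve
   of a single field over H thresholds, after subtraction of the known
   L₀·ρ₀(u) term, is regressed by OLS (pseudo-inverse) onto the density
   columns ρ₁..ρ_D. This yields per-realization LKC estimates for each
   residual field (with Z densities) and for the SPM (with t or F
   densities built from its degrees of freedom, which factors the
   statistic type out of the comparison). OLS is used deliberately: the
   error terms are heteroscedastic and correlated across thresholds, but
   weighted variants have been reported to buy little robustness, and the
   simplest model keeps the estimator linear and deterministic. Negative
   estimates are retained — the multivariate test needs the raw sampling
   distribution.

**The set-level test.** The SPM estimate (L₁..L_D) is stacked over the N
residual rows in a two-group multivariate GLM and the group contrast is
tested with Wilks' Λ = det(E)/det(E + H). With a single contrast degree of
freedom, Rao's F approximation is exact and algebraically identical to a
one-observation-versus-group Hotelling T²:
F = ((1 − Λ)/Λ)·(v − D + 1)/D on (D, v − D + 1) df, v = (N + 1) − 2.
L₀ is excluded from the test: it is determined by the mask, identical for
the SPM and every residual field, and would make the scatter singular.
Mardia's skewness and kurtosis tests on the residual LKC rows are computed
as an advisory normality check (the multivariate test assumes multivariate
normal errors); they warn but never gate the p-value.

**Classical comparisons.** Expected-EC peak inference
P(M ≥ u) ≈ E[φ(A_u)], cluster-count inference via the Poisson clumping
heuristic with mean λ = E[φ(A_u)], and FWE thresholds obtained by locating
the final downward crossing of α by the expected-EC curve (the curve is not
monotone at low thresholds, where odd-dimension densities change sign) and
refining by bisection to 1e−6.

## Topology and EC counting

Lattice masks are triangulated conformingly: 2D squares split into two
triangles, 3D cubes into 5 tetrahedra (a central one plus four corner
tetrahedra). The diagonal of every square face joins the two corners with
even lattice-coordinate sum; equivalently the central tetrahedron of every
cube is its four even-parity corners. This single global rule makes
adjacent cells share identical face diagonals, so the decomposition
introduces no spurious EC contributions. Excursion sets use the closed
(vertex-inclusion) rule — a simplex is supra-threshold iff all its vertices
are — so φ(u → −∞) equals the EC of the full space exactly. Cluster
connectivity is defined by the same complex's edges (including
triangulation diagonals), keeping one topology for EC counting, cluster
labelling and LKC estimation. Coordinates are 0-based lattice indices with
unit spacing; physical anisotropy is absorbed by the residual metric, never
by the complex. Surface meshes enter as 0-based triangle index arrays;
edges are derived from the triangles.

EC curves are computed by sorting each simplex's birth threshold (its
minimum vertex value) once and binary-searching the grid, so a whole
81-point curve costs one sort per simplex class.

## EC densities

Densities use the unit-roughness (LKC) parameterization, in which the GKF
carries no (4 ln 2) factors; resel-facing code applies
(4 ln 2)^(d/2) explicitly. Closed forms (d ≤ 3) for Z, t and F fields
follow the standard RFT literature. Two checks pin the conventions: the
exact identity ρ_d^{F(1,ν)}(u²) = 2ρ_d^{t(ν)}(u) for all d, and a
Monte-Carlo Rice-type oracle that recovers ρ₁(0) = 1/(2π) from the mean EC
of simulated 1D Gaussian processes whose intrinsic length is estimated
independently by the smoothness estimator.

The default threshold grid is −4 to +4 in steps of 0.1 (81 levels),
constructed by `linspace` so the endpoints are exact. The same grid serves
the Z residual curves and the t-SPM curve; published analyses of grid
choice indicate estimator variance plateaus beyond ~50 levels, so the grid
is not a sensitive tuning parameter.

## Synthetic data generator

`gen_noise_fields` draws i.i.d. Gaussian white noise per observation,
convolves with a separable Gaussian kernel (default FWHM 4 voxels,
truncated at 4σ, zero padding) and divides by the exact site-wise standard
deviation of the smoothed noise (computed from the squared kernel), so
every site — including borders — has unit variance. Default lattice sizes
follow the reference study conditions (2D 100×100, 3D 30×30×30; batches of
400 realizations), with scaled-down shapes (50×50, 40–200 realizations)
used in the routine test runs; the statements tests make are therefore
about those problem sizes.

Signals are injected as 1–25 impulses at random sites, smoothed with a
Gaussian of FWHM 2–32, scaled to a chosen peak height, and added
*identically to every observation before* the final smoothing — so
residuals are unchanged by construction and only the SPM departs from the
null. The peak amplitude is not dictated by the model; the default (0.03 in
pre-smoothing white-noise units — the post-smoothing variance
renormalization raises the effective height by roughly the reciprocal of
the smoothed-noise SD) was calibrated once by pilot simulation so the
classical FWE peak test at N = 100 on 2D 50×50 fields has intermediate
(~0.5) power, because ROC *shape comparison* rather than absolute power is
the quantity of interest.

What the generator does **not** emulate: temporal autocorrelation (inputs
are assumed pre-whitened), non-Gaussian noise, nonstationary smoothness,
anatomically realistic masks, or physiological signal structure. Passing
calibration and power tests on these fields shows the machinery is correct
under its own assumptions; it does not by itself validate behaviour on real
fMRI/MEG data.

## Numerical choices and degenerate inputs

- GLM solves use the pseudo-inverse; rank-deficient designs and N ≤ p are
  rejected explicitly.
- Sites with (numerically) zero residual variance cannot be standardized
  and are removed from the mask for *all* downstream computation — EC and
  LKC are mask-relative quantities — with a logged warning.
- Degenerate simplices (linearly dependent residual differences) get
  volume 0; Gram determinants are clipped at 0 before the square root.
- Wilks' Λ uses log-determinants; singular scatter raises an error rather
  than returning a spurious p-value.
- Residual rotation multiplies the N×sites residual matrix by the left
  singular vectors of a seeded standard-normal N×N matrix, then
  re-standardizes site-wise (mathematically a no-op for an exact rotation;
  kept as a numerical guard). The seed is a required argument.
- All simulation randomness flows from a single master seed through
  per-realization child seeds recorded in the output tables.

## Known limitations

- The chi-square/normal approximations in Mardia's tests are asymptotic;
  at small N the skewness p-values are conservative.
- The lattice inclusion–exclusion scheme for intermediate L_d is exact for
  homogeneous smoothness and an approximation otherwise; L₀ and L_D, the
  quantities the threshold-free test relies on, do not use it.
- The expected-EC approximation to P(M ≥ u) degrades when E[φ] > 1; the
  package warns and saturates at 1.
- The multivariate test needs N > D + 1 residual fields and loses power
  for small search volumes or few observations, where classical
  smoothness-based tests remain preferable.
- χ² and non-central field densities, TFCE-style competitors, permutation
  inference and persistent-homology topology estimation are out of scope.
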