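# Methods

This note records the model, the defaults, and the numerical and design
choices behind `ceidr`, in the spirit of a statistical software methods
appendix.  Notation follows the README.

## The estimand and why adjustment comes first

The target of inference is the conditional correlation
`rho(z, x, v) = tanh(b0(v) + z b1(v) + x kappa(v))` between the residuals
of two modalities, and specifically the covariate effect `kappa(v)`.
Correlation is not invariant to mean and variance structure: if a
covariate shifts the mean or scales the variance of either modality and
that structure is not removed, a coupling test will attribute it to
`kappa`.  The pipeline therefore standardizes each modality before any
coupling estimate is formed, by two complementary routes:

* **Between-subject** (observed covariates): per vertex, a Gaussian
  location-scale model across subjects.  The mean is additive with
  optional natural cubic regression spline terms for continuous covariates
  (optionally stratified by a binary covariate); `log(sigma)` is linear in
  named covariates.  Estimation is an iterated two-stage scheme — (i)
  weighted least squares for the mean, (ii) Newton maximization of the
  Gaussian likelihood in the log-SD coefficients given the mean residuals
  — iterated twice, which is sufficient for this model because the two
  blocks of the information matrix are orthogonal at the optimum.  The
  Newton step is validated against direct likelihood maximization
  (`scipy.optimize`) in the test suite.  With intercept-only models the
  residuals reduce to per-vertex z-scores with the ML (denominator `N`)
  convention.
* **Within-subject** (unobserved factors): per subject and vertex,
  centering/scaling by the sample mean and SD over the geodesic disc
  `N_r(v)`, vertex included, SD with the `n - 1` denominator, default
  `r = 5` mm.  This assumes local stationarity of mean and variance; a
  small radius keeps that assumption mild at the cost of noisier local
  estimates.  Locally constant data produce residual 0 and flag the
  vertex rather than NaN.

The recommended (and default) configuration composes both: between first,
then within on its residuals.

## Coupling estimators

* `ceidr_coupling`: the residual product `eps1 * eps2`.  Per cell it is a
  crude (unbounded) estimate, but its expectation is exactly `rho` for
  standardized bivariate normal residuals, which is all the linear score
  test needs.
* `imco_coupling`: per subject and vertex, the weighted Pearson
  correlation of the raw maps over a kernel neighborhood, with Gaussian
  weights `w = exp(-d^2 / (2 theta^2))`, `theta = FWHM / (2 sqrt(2 ln 2))`.
  Correlations (not regression slopes) keep the measure symmetric in the
  modalities.  Weights below 5% of the peak are truncated to zero; this
  bounds the neighborhood, is recorded in the result's settings, and
  determines how far the geodesic distance index must extend (about 5.2 mm
  for FWHM 5, 15.7 mm for FWHM 15).  The weighted moments use the
  sum-of-weights (population) normalization, so equal weights reduce
  exactly to the ordinary Pearson correlation.  With a box kernel, IMCo is
  an exact special case of the CEIDR statistic: on a neighborhood shared
  by its members, enhanced products of within-standardized residuals and
  the vertex-wise statistic of box-kernel correlations coincide (the
  `n` vs `n - 1` denominator conventions cancel in `T`); the test suite
  asserts this identity to 1e-10.

## Inference

The tanh link is handled by linearization: for `|t| <= 0.5`,
`|tanh(t) - t| <= 0.042`, so across the correlation magnitudes the design
produces, `E[rho_hat | x, z] ~ b0 + z b1 + x kappa` is an accurate working
model, and `kappa = 0` is tested by a score statistic from the null fit
only — no per-permutation refitting.

`Var_H0` in the enhanced statistic `T_r(v)` is the *exact* variance of the
cluster score `S = sum_i x~_{pi(i)} R_i` under a uniformly random
permutation `pi` of the residualized covariate:
`(sum_i x~_i^2) (sum_i (R_i - R_bar)^2) / (N - 1)`.  It is
permutation-invariant, so it is computed once; because any fixed positive
standardization yields an exact max-statistic permutation test, the choice
affects power (through how radii are weighted against each other), not
validity.  The test suite verifies the formula against brute-force
enumeration of all `N!` permutations at `N = 6` to 1e-10.

Permutation scheme: `x` is residualized on `[1, Z]` once and the
residualized vector is permuted, with stages I–II held fixed.  A joint
`(x, z)` permutation variant is provided for strongly correlated
covariates; its refitted-null score collapses analytically (by projection
orthogonality) to scoring the permuted `x~` against the raw coupling, so
it costs the same as the residual scheme — the identity with an explicit
refit is asserted in a test.

Conventions, all chosen for finite-B validity and determinism:

* adjusted p-values: `(1 + #{M_b >= T(v)}) / (B + 1)`, so p ranges over
  `[1/(B+1), 1]`;
* threshold: the `ceil((1 - alpha)(B + 1))`-th smallest null maximum;
  `significant(v) = T(v) > t_alpha`, which matches `p <= alpha` except at
  exact ties with the threshold (measure-zero for continuous data);
* ties in `max_r T_r(v)`: the smallest maximizing radius wins;
* `signed_T` carries the sign of the enhancing cluster sum at the
  maximizing radius — a display convention only (the test uses `T`); the
  result table also exposes `signed_sqrt_T` for users who prefer a
  z-like scale;
* zero-variance `(v, r)` combinations contribute `T_r = 0` and are
  flagged;
* one seed drives everything; simulation replicates derive per-replicate
  streams from `SeedSequence(master, spawn_key=(replicate,))`, independent
  of kappa and method, so sweeps share replicate data (common random
  numbers) and tables reproduce exactly.

Geodesic distances are graph shortest paths along mesh edges (Dijkstra on
Euclidean edge lengths), truncated at the maximum requested radius and
stored sparsely; masked-out vertices (e.g., the medial wall) are removed
from the graph before the computation, so paths cannot route through them
and they belong to no neighborhood.  At the radii used here (<= ~16 mm)
the graph approximation error is small relative to vertex spacing.  If the
masked surface is disconnected, a warning is issued and components are
analyzed independently (truncated distances make this automatic).

## The synthetic study design

The generator emulates a covariate-coupling study on a sphere standing in
for a cortical hemisphere: `x, z` iid standard normal; five disjoint
geodesic discs placed by greedy farthest-point sampling (largest regions
claim the most separated seeds):

| region | radius | mean | SD | coupling |
|---|---|---|---|---|
| A | 10 mm | modality 1: `0.5x + 0.5z` | modality 1: `log sd = 0.2x` | `tanh(0.3 + 0.1z)` |
| B | 10 mm | both: `0.5x + 0.5z` | constant | `tanh(0.3 + 0.1z)` |
| C | 15 mm | both: `0.5x + 0.5z` | both: `log sd = 0.2x` | `tanh(0.3 + 0.1z + kappa x)` |
| D | 7 mm | 0 | 1 | `tanh(0.3 + 0.1z + kappa x)` |
| E | 5 mm | 0 | 1 | `tanh(0.3 + 0.1z + kappa x)` |
| elsewhere | — | 0 | 1 | 0 |

A and B are decoys: their marginal distributions depend on the covariates
but their coupling does not, so any detection there is a false positive
caused by insufficient mean/variance adjustment.  With `kappa = 0` the
entire design is null and the any-vertex rejection rate estimates the
family-wise error rate; the default `kappa` sweep is 0, 0.01, ..., 0.09.
The A/B radii and the A–C mean/SD magnitudes (`0.5`, `0.5`, `0.2`) are
package defaults chosen to give the decoy regions clearly visible
heterogeneity at moderate amplitude; they are overridable per region
through `FieldSpec`.

Correlated residual pairs are drawn through the 2x2 Cholesky factor
(`eps2 = rho eps1 + sqrt(1 - rho^2) u`), exact and vectorized.  The draw
order (x, z, eps1, u) is part of the reproducibility contract.

**What the generator does not emulate:** smooth spatial autocorrelation of
the noise field (vertices are independent given the region structure),
non-Gaussian or heavy-tailed residuals, scanner/site effects, and the
irregular vertex density and folding geometry of a real pial surface.
Passing the study therefore demonstrates correct error control and the
power ordering of the methods under the stated generative model — not
performance guarantees on real cortical data.

## Problem sizes and defaults

The packaged desk-scale study uses a 642-vertex icosphere of radius 28 mm
(typical edge ~4 mm, so the 15/7/5 mm signal discs contain ~31/7/7
vertices), `N = 200` subjects, `B = 500` permutations, `alpha = 0.05`, 200
replicates, and enhancement radii 0–15 mm in 1 mm steps (radii whose
neighborhoods coincide on the mesh are collapsed internally before any
linear algebra).  A full-resolution surface (fsaverage5-like, ~10k
vertices per hemisphere) is reachable through configuration: the
per-permutation cost is one `(B x N) @ (N x V)` product plus one sparse
cluster-sum per distinct radius.  In the study driver the between-subject
models are linear in `(x, z)` for the mean and log-linear for the SD,
matching the generative design; analyses of real data would use the spline
mean model.  Default `B = 1000` and `alpha = 0.05` for single analyses.

## Known limitations

* The between-subject two-stage fit is not a full joint-likelihood GAMLSS;
  with two iterations its estimates agree with joint ML to well within
  sampling error for the Gaussian location-scale model, but no smoothness
  selection is performed (the spline basis is small and fixed).
* The score test is linear in the coupling products; strongly nonlinear
  covariate effects on coupling (e.g., quadratic age trajectories) are
  outside the tested alternative.
* Graph-geodesic distances slightly overestimate true surface distances on
  coarse meshes; neighborhoods inherit that bias.
* FWER control is finite-B exact under exchangeability of the residualized
  covariate; at `N = 200` with strong decoy heterogeneity, estimation
  error in the stage-I fits leaks a small amount of covariate dependence
  into the residuals, which can leave the empirical rate within a couple
  of binomial standard errors of (rather than strictly at) the nominal
  level — the acceptance study quantifies this directly.
* False discovery rate control, spatial enrichment ("spin") tests, and
  longitudinal/repeated-measures designs are out of scope.
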