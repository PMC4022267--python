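# Methods

## Model class and noise assumptions

A model is any deterministic map from a parameter vector `theta` and an
evaluation design (time points or regressor values, one grid per measured
signal) to predicted outputs.  Measurement noise is assumed additive,
independent, zero-mean Gaussian with *known* per-point standard deviations
`sigma_i(t_j)`; no variance estimation is performed.  Under this assumption
the chi-square statistic is (twice the negative) log-likelihood up to a
constant, which is what makes the chi-square difference of two models a
log-likelihood ratio and their sum a log-likelihood product.

Built-in benchmark models:

| id    | definition                                   | fitting strategy |
|-------|----------------------------------------------|------------------|
| MS1   | `theta1*x + theta2`                          | weighted normal equations (exact) |
| MS2   | `theta1*e^x + theta2`                        | weighted normal equations (exact) |
| MD1   | `dx/dt = -theta*x`, `x(0)=10`, `y = x`       | dense log-grid scan + golden-section |
| MD2   | `dx/dt = -theta*x/(0.01+x)`, `x(0)=10`       | dense log-grid scan + golden-section |
| CONST | per-signal constant                          | weighted mean (exact) |
| FLEX  | exact interpolant through all data points    | trivial; cost identically zero |

`MD1` and `MD2` are evaluated through exact solutions rather than numerical
integration: `MD1` in closed form (`10*exp(-theta*t)`), `MD2` through its
implicit integral `x + 0.01*ln x = 10 + 0.01*ln 10 - theta*t`, solved with a
monotonically convergent Newton iteration in `ln x` (the residual is convex
and increasing there, so iteration from the initial state converges from the
right; far past the substrate-exhaustion kink the solution underflows to
zero, which is the correct limit).  A numerical initial-value solver (LSODA,
rtol 1e-8, atol 1e-10 — the small Michaelis constant makes the final decay
phase stiff) remains available as `predict_ode` and is used as an
independent cross-check in the tests, to 1e-6 relative (MD1) and 1e-5
absolute (MD2) agreement.

### Parameter estimation

All fitting minimizes the chi-square objective.  Linear-basis models are
solved exactly, so their fits are deterministic and start-point free.  For
the one-parameter decay models the objective is *not* globally well-behaved:
as `theta` varies, the trajectory's fast-decay kink slides across data
points and can leave shallow secondary minima.  Local search from a handful
of starts is therefore unreliable, and the package instead scans a dense
log-spaced grid over the parameter bounds (300 points; each grid point is a
bounded start), brackets the best point, and refines by golden-section plus
a final Brent polish.  The same scan is vectorized across bootstrap samples
(all samples advance through the golden-section steps together), which is
what makes refitting ~1e5 samples per benchmark affordable.  Noise-free data
are recovered to machine precision (linear models) and better than 1e-6
(decay models).

## The bootstrap null

Under the null hypothesis that the tested model is true, its fit to the
observed data is the data-generating process.  Each bootstrap sample is the
noise-free simulation at the fitted parameters plus a fresh Gaussian noise
draw on the same design; refitting to every sample and evaluating the
statistics yields the cloud — the empirical joint null distribution.  The
fitted parameters (not the unknown truth) generate the samples; bootstrap
refits start from scratch, with the observed-data fit reachable through the
dense grid scan.  Each sample owns an RNG stream spawned from the base seed
and keyed by sample index, so clouds are bit-identical for a given seed
independent of execution order.  Failed refits are retried with a denser
scan and then dropped; more than 1% drops aborts the cloud as
unrepresentative.

## p-values

**1D tests.**  The empirical CDF of a cloud column is interpolated linearly
between order statistics at plotting positions `i/(B+1)`; observed values
beyond the cloud range are clamped so p-values stay inside
`[1/(B+1), 1-1/(B+1)]` (keeps log-p finite; the floor is also an honest
statement of the resolution a size-B cloud can support).  Tails: right for
chi-square (only large residuals are evidence against the model), left for
Durbin-Watson (the package tests for positive autocorrelation only),
two-sided for the LHR.  A "density" tail — the mass of cloud points whose 1D
kernel density falls below the density at the observed value — is available
for diagnostic use.

**2D joint test.**  The cloud density is estimated with a Gaussian kernel
and evaluated on a 128x128 grid (64 in the large benchmark loops); the
p-value is the summed mass of all bins whose density lies strictly below the
density at the observed statistic pair, i.e. the mass outside the
equidensity contour through the observation.  The density at the observed
point is computed with the continuous kernel sum, not grid interpolation,
avoiding discretization bias exactly where it matters.  Like a two-sided
test, the region includes low-density areas where the model is surprisingly
*good*.

**Kernel choice.**  The kernel is covariance-adaptive: the cloud is whitened
by the eigendecomposition of its sample covariance and smoothed
isotropically with bandwidth `B^(-1/6)` in whitened coordinates (the 2D
Silverman rule with a full covariance matrix, as in
`scipy.stats.gaussian_kde`).  An axis-aligned product kernel was considered
and rejected: it is not rotation-covariant, and the package's own invariant
— that the test must give the same answer in the `(chi2_1, chi2_2)` plane
and in its 45-degree-tilted `(LHR, LHP)` image — failed by ~0.03 with
per-axis bandwidths at B = 1e4.  With the whitened kernel the estimate is
affine-equivariant and the two planes agree to grid accuracy (< 0.005 at
grid 128, measured).  An explicit `(hx, hy)` bandwidth pair can still be
passed for an axis-aligned kernel.

Accuracy of the resulting p-values is anchored by a closed-form oracle: for
an isotropic bivariate normal cloud the mass outside the contour through
radius `r` is `exp(-r^2/2)`; at B = 1e4 the estimate agrees to within 0.02
(averaged around the circle — the density evaluated at a single point
carries Monte-Carlo noise of ~0.03 in p at small radii, which is a property
of any kernel estimate, not of the integration).  Kernel smoothing biases
the p upward by O(bandwidth^2); at B = 200, the benchmark cloud size, this
makes the 2D tests mildly conservative — visible in the calibration results
below — and the bias shrinks with B.

**Degenerate clouds.**  If one statistic has no spread across the cloud
(e.g. the chi-square of the FLEX interpolant, which is identically zero), or
the two columns are perfectly collinear, the 2D estimate degrades to a 1D
density test along the informative direction and the result carries a
collapse warning: there is no joint information to exploit, and the
two-model tests degenerate to the (mirrored) chi-square test of the tested
model.  `cloud_geometry_diagnostic` reports correlation, principal-axis
angle and the collapse flag, to advise whether a chosen help model can help
at all — a useful help model must be neither flexible enough to fit
everything nor too simple to track the tested model.

**Simplistic combinations.**  `min`, `max`, `mean` and `prod` of the two 1D
p-values are computed exactly as stated and flagged demonstration-only in
output metadata: none of them is calibrated (min and prod are liberal, max
and mean conservative at practical levels), which the evaluation harness
demonstrates.

## Evaluation harness

A scenario fixes the truths, the hypothesis models, the test battery, sizes
and seeds.  For every truth, `n_datasets` replicate datasets are simulated;
for every dataset, each hypothesis model serves as H0 in turn.  One
bootstrap sample set is generated per (dataset, H0) pair and shared by all
tests — the joint columns (chi2 and DW of the H0 model, chi2 of the
competing model) are computed once per refit, and all p-values derive from
the same cloud; this sharing is statistically equivalent to independent runs
and an order of magnitude cheaper.  With both models as truth and H0,
`n_datasets` per truth yields `2*n_datasets` true-H0 and `2*n_datasets`
false-H0 p-values per test.  Runs are checkpointable to CSV and resumable.

ROC curves evaluate TPR (rejections of false models) against FPR
(rejections of true models) at all observed p-values plus a fixed level
grid; partial AUC integrates over FPR in [0, 0.1] — biology rarely uses
alpha above 0.05 — normalized by the maximal area 0.1, so an uninformative
test scores 0.05 and a perfect one 1.0.  Calibration compares observed FPR
with the nominal level against the exact central 99% binomial band,
yielding the verdict sound / liberal / conservative.

### Study conditions and scale

Defaults mirror the benchmark design: noise sigma 0.5 (static) and 0.75
(dynamic), roughly 5-10% of mean model output for the default truths
(MS1 theta = (4, 5), MS2 theta = (2, 3), MD1 theta = 0.7, MD2 theta = 5);
11-point designs on x in [0, 2] (static) and t in [0, 3] (dynamic); cloud
size B = 1000 and 500 datasets per truth as production defaults.  The test
suite and the acceptance script run the benchmarks at reduced scale —
static: 100 datasets per truth with B = 200, five seed replicates; dynamic:
50 datasets with B = 100, three replicates — which keeps the suite at a few
minutes while leaving the qualitative claims (orderings and calibration
verdicts, with ties allowed inside the replicate noise band) intact.

Two scale effects are worth knowing about.  First, the B = 200 kernel
bandwidth makes the 2D tests conservative at alpha ≥ 0.05 (never liberal);
at production B they tighten toward the band.  Second, a two-tailed
empirical p-value has a floor of `2/(B+1)`, so at B = 100 the LHR cannot
reject below p ≈ 0.02 and its ROC is truncated in exactly the region the
partial AUC measures; the LHR's advantage over the 2D chi-square-vs-chi-square
test is therefore only asserted at the static scale (B = 200), where the
measured ranking is LHR ≳ 2D chi2-vs-chi2 > 2D chi2-vs-DW > both 1D tests,
with the LHP uninformative (ROC on the identity line).

## What the synthetic generator does and does not emulate

The generator produces exactly the assumed data model: known design, known
Gaussian noise with known sigma, a true model inside the candidate set.
Passing tests therefore certify the machinery under its own assumptions.
Real data violate them in ways the benchmarks do not probe: misspecified or
non-Gaussian noise, correlated errors, unknown sigma (here taken as given),
parameter non-identifiability, and uncertainty in the fitted parameters
propagating into the bootstrap null (not modeled — samples are generated at
the point estimate).

## Numerical choices

* Strict inequality (`density < density(Z)`) defines the rejection region;
  exact ties are excluded.
* Grid: bin centers over the cloud extent padded by 3 bandwidths; doubling
  the grid changes p by < 0.005 at B = 1e4 (tested).
* The Durbin-Watson ratio rescales residuals by their maximum magnitude
  before squaring (the statistic is scale-invariant; this avoids underflow
  for near-zero residual vectors) and raises a dedicated degenerate-fit
  error when all residuals are exactly zero.
* LHR sign convention: tested-model chi2 minus second-model chi2, so large
  positive values mean the tested model fits worse; two-tailed testing makes
  the convention immaterial.
* The DW denominator includes all residuals (first point of each signal
  included); adjacent differences never cross a signal boundary.
* Optimizer determinism is preferred over stochastic global search: the
  dense-grid multi-start is reproducible bit-for-bit and, for these
  one-parameter problems, at least as reliable.

## Known limitations

* Only k = 2 joint statistics; higher dimensions pay a steep density-
  estimation price for little demonstrated benefit.
* The 2D test cannot distinguish one-sided from two-sided alternatives; its
  rejection region always includes the "surprisingly good" low-density side.
* Multi-signal observation functions beyond direct readout, non-parametric
  bootstrap variants, and parameter-uncertainty-aware sampling are out of
  scope.
* Empirical p-values are bounded away from 0 by `1/(B+1)` (one-tailed) or
  `2/(B+1)` (two-tailed); choose B accordingly for small target levels.
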