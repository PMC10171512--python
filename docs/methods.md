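# Methods

## Statistical model

The analysis treats each subject as one observation of two variable
blocks: X (n × p connectome edges) and Y (n × q phenotypes).  A *mode of
covariation* is a pair of weight vectors (a, b) maximising
corr(Xa, Yb); successive modes maximise the same quantity subject to
within-block decorrelation.  With Σ̂ the sample covariances, the canonical
correlations are the singular values of Q_x'Q_y where Q_x, Q_y are
orthonormal bases (economy QR) of the centred blocks — the numerically
stable equivalent of the generalised eigenproblem
Σ_xx⁻¹Σ_xy Σ_yy⁻¹Σ_yx a = ρ²a, which the test suite uses as an
independent oracle.

Sample CCA overfits badly when p + q approaches n (the first sample
correlation of independent blocks tends to 1; demonstrated in
`test_overfitting_inflates_at_small_n`).  The pipeline therefore reduces
each block first to the smallest number of principal components whose
cumulative explained variance reaches `variance_target` (default 0.80),
computed by SVD of the centred data.

## Inference

Significance is assessed by a max-statistic permutation test: the subject
rows of one block are permuted (uniformly, B fresh draws; default
B = 100,000, α = 0.05), CCA is refit, and only the *largest* canonical
correlation of each permutation enters the null.  Comparing every
observed mode to this one null distribution controls the family-wise
error rate across modes; because observed correlations are
non-increasing, the resulting p-values are monotone and significant modes
form a leading prefix.  P-values use the plus-one estimator
p = (1 + #{null ≥ r}) / (1 + B), which is valid at finite B and never
zero (floor 1/(B+1)).  Since centring commutes with row permutation, the
orthonormal bases are computed once and each permutation costs only one
small SVD; an exhaustive mode enumerates all n! row orders for n ≤ 8 and
is verified against brute force.  Either block may be permuted —
exchangeability makes the choice immaterial (verified exactly in the
exhaustive test); the implementation permutes the narrower block.

## Preprocessing conventions

Stage order is fixed and logged: phenotypes are filtered (variables with
missing fraction > 0.5 excluded), winsorised, imputed, standardised, then
deconfounded; imaging edges (complete by construction) skip filtering and
imputation.  Specific conventions, all recorded in the run manifest:

* **Percentiles** (winsorisation bounds, default 1st/99th): linear
  interpolation between order statistics, computed per variable over
  observed values only.
* **Imputation** (k = 1 nearest neighbour): distance is the mean squared
  difference over variables observed in both subjects — normalising by
  the shared-column count avoids biasing donor choice toward
  high-overlap pairs.  Donors contribute pre-imputation observed values
  only (no chaining), ties go to the lowest donor index, and a subject
  sharing no observed variable with any donor falls back to the column
  median (logged).
* **Standardisation**: sample SD (n − 1 denominator).  Zero-variance
  columns become all-zero and are flagged rather than dropped.
* **Deconfounding**: least-squares residuals on [1, confounds];
  categorical confounds (e.g. site) are one-hot encoded with the first
  level dropped; rank-deficient designs lose their dependent columns via
  pivoted QR, logged.  Residualisation is a projection (idempotent) and
  leaves correlations with every confound below 1e-8.
* **Edge means for sign adjustment** are taken on the winsorised,
  pre-standardisation edge values (after standardisation they would be
  identically zero).

## Mode interpretation

For each significant mode the two canonical variates are averaged and
re-standardised — a conservative summary that cannot be dominated by
either block; a zero-variance average (u = −v) is an error surfaced to
the user, since it indicates a sign-convention failure rather than a
statistical finding.  Loadings are Pearson correlations of this average
with the processed (deconfounded, non-PCA-reduced) original variables:
the variates live in deconfounded space, so correlating them with raw
values would reintroduce confound variance.  Only |r| ≥ 0.2 (inclusive)
is reported.  Edge loadings are multiplied by the sign of the population
mean of that edge's connectivity; mean-zero edges pass through unadjusted
and flagged.  Variance explained per mode is 100·ρ², kept at full
precision internally and rounded to 2 dp only at presentation (4 dp for
correlations).

Both PCA and CCA are sign-indeterminate, so deterministic conventions
make loadings reproducible across runs and platforms: each principal
component's largest-magnitude loading is positive, and each variate pair
is flipped so the x-variate correlates non-negatively with the first
reference variable having non-negligible correlation (the processed
original X block in the pipeline).

## Synthetic populations

`generate_two_block` plants mode k as x_k = √ρ_k·z_k + √(1−ρ_k)·e_xk,
y_k = √ρ_k·z_k + √(1−ρ_k)·e_yk with iid standard-normal z and e, giving
population corr(x_k, y_k) = ρ_k exactly; the remaining channels are iid
noise, and each block is rotated by a Haar-uniform orthogonal map (QR of
a Gaussian matrix with sign-fixed diagonal), which leaves canonical
correlations invariant.  Contamination defaults mirror the conditions
the pipeline is designed for: 2% missing cells punched into Y completely
at random (matching the ~2% median missingness of the phenotype tables
this emulates), 1% of cells in each block replaced by ±8 SD point
outliers (enough to exercise 1%-per-tail winsorisation visibly without
destroying rank structure), and additive effects of an age-like
continuous, a binary sex-like and a 3-level site-like confound with
coefficients drawn N(0, 0.3).  One global seed fans out to fixed
per-stage child streams, so e.g. the missingness mask is reproducible
independently of the outlier draws.

`generate_roi_timeseries` draws each subject's T × R series (default
T = 490, one resting-state run) from a zero-mean multivariate normal
with covariance inv(P) for a user-specified positive-definite precision
P, making every population partial correlation available in closed form.

What the generator does **not** emulate: ordinal or binary phenotypes
(all channels are Gaussian; an ordinal-discretisation option is left as
future work), temporally autocorrelated or drifting time series, motion
artefacts, and missingness that depends on the data.  Passing recovery
tests therefore show correctness of the estimator under the stated
model, not robustness to every feature of real cohort data.

## Problem sizes and numerical choices

* Recovery experiments (planted ρ = (0.5, 0.3), n = 2000, 10 × 20
  variables, B = 999, 20 seeds) run the full pipeline with
  `variance_target = 1.0`: the planted blocks have a flat variance
  spectrum (signal and noise channels all have unit variance), so an 80%
  cut would discard a fifth of the signal subspace by construction —
  a property of the isotropic synthetic design, not of the method.  The
  80% default targets real data, whose spectra are strongly structured.
  Under the default contaminated conditions the mean absolute error of
  the top-2 estimated correlations is ≈ 0.026 and exactly two modes are
  declared significant in 20/20 seeds.
* The family-wise error simulation uses 1000 replicates of n = 200 with
  5- and 10-column independent blocks and B = 199 — large enough that
  the binomial standard error of the rate is ≈ 0.7 percentage points,
  small enough to run in seconds.
* Covariance inversion for partial correlations supports an optional
  ridge (cov + ridge·I, default 0); a singular covariance at ridge = 0
  raises with the suggestion to enable it.  No Fisher r-to-z transform
  is applied.  Connectome matrices are clipped to [−1, 1] against
  floating-point overshoot; diagonals are zero by convention.
* CCA raises on rank-deficient score blocks with the instruction to
  reduce by PCA first; the retention rule is "smallest m with cumulative
  ratio ≥ target" (first crossing).
* Degenerate inputs handled explicitly: constant columns (zero loading /
  zero standardised value, flagged), all-missing columns (filtered or
  passed through winsorisation with a warning), mean-zero edges
  (unadjusted, flagged), duplicate subject IDs (hard error), subject-ID
  mismatch across tables (realigned by sorted ID intersection).

## Known limitations

Permutations assume full exchangeability of subjects; family or site
structure would require exchangeability blocks, which are not
implemented.  Successive modes are tested against the first-correlation
null (no step-down refit), which is conservative for later modes.
Confound models are linear; quadratic confound terms are out of scope.
The loading threshold (0.2) is a reporting convention, not an inference:
thresholded loadings carry no error control.
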