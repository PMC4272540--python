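# Methods

This note records the statistical models the package implements, the
conventions and defaults it commits to, and what its synthetic-data
tests do and do not demonstrate.

## Superimposition

Configurations of k 2D landmarks are superimposed by partial Procrustes
alignment: each configuration is centred, scaled to unit centroid size,
and iteratively rotated to the running consensus (initialised from the
first specimen); the consensus is the mean of the aligned shapes,
rescaled to unit centroid size each round. Iteration stops when the
summed squared change in the consensus falls below 1e-8 (cap 100
iterations; typical morphometric samples converge in 3–5). There is no
per-iteration optimal-scaling step beyond the unit-CS normalisation, so
shape coordinates live on the unit hypersphere — the convention of the
mainstream morphometrics software lineage. Reflections are never
admitted in the per-specimen rotation (determinant +1 enforced): all
specimens are assumed digitised in the same lateral view.

Orientation is made reproducible by rotating the final consensus to its
principal axes, with the sign fixed so the largest-magnitude coordinate
entry is positive; all specimens are co-rotated. Runs on the same input
are therefore bit-comparable.

Aligned shapes are projected orthogonally onto the tangent space at the
consensus c (unit norm): `x ↦ x + (1 − x·c) c`. The displacement is
second order in the Procrustes distance, so for realistic digitisation
noise (sd ~1% of CS) total variance changes by well under 1%. Centroid
sizes are measured on the raw configurations before any scaling; the
size variable is `ln(CS)`.

Degenerate configurations (all landmarks coincident) and non-finite
coordinates are hard errors; missing-landmark estimation is out of
scope. A `flip_y` option negates all y coordinates uniformly, for files
digitised against a top-left image origin; applied uniformly it changes
no downstream result.

## Ordination

PCA is the spectral decomposition of the sample covariance of the shape
coordinates (computed via SVD of the centred data); components below
1e-12 of the leading eigenvalue are dropped, because Procrustes data
have rank at most 2k − 4. "Leading PCs above a variance threshold"
means the smallest leading set whose cumulative share strictly exceeds
the threshold (default 0.90).

CVA first projects onto the non-null PCs (rank guard), then solves the
generalized eigenproblem `H v = λ E v` with H and B the among-group and
E the pooled within-group cross-product matrices. Scores are scaled so
the pooled within-group covariance is the identity (Mahalanobis
convention), making group ellipses comparable; eigenvalues are reported
as among/within variance ratios per axis and "percent among" as each
axis' share of their sum. Confidence ellipses for bivariate group means
scale the covariance of the mean by the χ²₂ quantile at the requested
level.

## Allometric regression

The allometric shape vector is the multivariate OLS slope of shape on
`ln(CS)` — one shared scalar predictor, one simple regression per
coordinate. The degree of allometry is predicted SS over total centred
SS, summed across coordinates (units of squared Procrustes distance).

Three levels:

* **per-population** — each group fitted alone;
* **pooled within-population** — shapes and sizes mean-centred within
  each group before a single pooled fit; group mean differences cannot
  influence the estimate. Percent explained uses the pooled-centred
  total SS as denominator (the raw-data alternative would mix
  among-group shape variance into the denominator and is not used);
* **evolutionary** — one observation per population (consensus shape,
  mean `ln(CS)`), unweighted regardless of group n, since the
  population is the evolutionary unit. Requires ≥ 3 populations.

The non-allometric shape component subtracts the pooled-within
prediction with per-group centring respected
(`residual = shape − β₁ (lnCS − group mean lnCS)`), so group mean
differences survive and can be ordinated by CVA. Regression scores are
projections of mean-centred shapes onto the unit slope vector, the
y-axis of allometric trajectory plots.

Sexes are modelled separately throughout (separate GPA by default): in
sexually dimorphic species pooling sexes would mix two allometries. A
`joint_alignment` flag exists for sensitivity analysis.

## Angle tests

The angle between allometric vectors is the arc-cosine of the inner
product of the unit-normalised vectors. Under the null that both are
uniform random directions in p dimensions, `(1 + cos Θ)/2` follows
Beta((p−1)/2, (p−1)/2), so the CDF is the regularized incomplete beta
function `I_{(1−cos θ)/2}((p−1)/2, (p−1)/2)` — exact, no quadrature.
Checks: CDF(90°, p) = 0.5 for all p; uniform-angle and uniform-cosine
special cases at p = 2 and 3; Monte-Carlo agreement at p = 16.

p defaults to 2k − 4 (= 16 for 10 landmarks), the dimension in which
regression vectors live after translation, scale and rotation are
removed; it is exposed as a parameter. p-values are one-sided: small
angles are the evidence of shared allometry.

For the mean of all g(g−1)/2 pairwise angles among g vectors the
pairwise angles are dependent and no closed form is available, so the
null is simulated: g uniform directions in p dimensions, n_reps times
(default 10,000, minimum 1,000), with the seed recorded in the result;
p-values carry the plus-one correction (count+1)/(n_reps+1), so the
smallest attainable value is 1/(n_reps+1).

PROTEST centres both matrices, scales each to unit total sum of
squares, and takes the trace norm of XᵀY as the Procrustes correlation
(equivalently `sqrt(1 − m²)` under the optimal orthogonal rotation plus
scaling, reflections admitted as in vegan); significance comes from row
permutations of Y with the plus-one correction. It is applied to the
GPA-aligned coordinates of two digitisation series, each series aligned
jointly and specimen-matched.

## Group tests

ANOVA on `ln(CS)` is the standard one-way F. MANOVA uses
Wilks' Λ = det(E)/det(E+H) on the selected PC scores, converted to F by
Rao's approximation (exact for q ≤ 2 variables or g ≤ 3 groups); the
implementation is cross-checked against statsmodels' MANOVA in the test
suite. Guards: every group larger than q, n − g ≥ q, E nonsingular.

## Synthetic data generator

The generator emulates a six-population field design: unequal sample
sizes (default 76, 46, 53, 28, 68, 72 — counts taken from the kind of
per-population survey table the design mirrors), population mean
`ln(CS)` spanning 0.9–1.5 with within-population sd 0.1, a common
within-population allometric direction w, an evolutionary direction e
at a configurable angle to w (default 40°), optional per-population
non-allometric shape offsets, and isotropic per-coordinate digitisation
noise (default sd 0.005, about 0.5% of centroid size).

w and e are constructed inside the tangent space at a fixed fish-like
10-landmark template — orthogonal to the translation, scale and
rotation directions — so they are genuine shape directions; e is built
in span{w, w⊥} so the requested angle is achieved exactly. The
tangent-space displacement d of each specimen is lifted onto the unit
shape sphere as `sqrt(1 − |d|²)·base + d` (the inverse of the
orthogonal tangent projection) before noise, scaling to `exp(lnCS)` and
a random rotation/translation are applied. Without the lift, the
sphere's curvature biases recovered angles by ~1° at this effect size.
`map_to_sample_frame` transports a template-frame truth vector into an
aligned sample's frame (optimal rotation plus projection into the
tangent space at the sample consensus) for recovery comparisons.

Ground truth records the drawn sizes and the *realised* within- and
evolutionary percents, computed from the generated tangent-space sample
with the same regression formulas the pipeline uses — recovery is
checked against the truth of the particular sample, not a population
expectation.

What passing tests show: the pipeline recovers directions, angles and
percents from data whose generating model is exactly the fitted model
(linear in `ln(CS)`, Gaussian isotropic noise, shared w). What they do
not show: robustness to allometric curvature, non-Gaussian or
landmark-correlated digitisation error, or unmodelled within-population
heterogeneity — on real data, estimated angles should be read as upper
bounds, since independent estimation noise pushes vectors apart.

## Numerical choices and problem sizes

* GPA convergence 1e-8 (squared-distance norm), cap 100 iterations.
* PCA/CVA rank guard 1e-12 relative; CVA refuses within-group matrices
  with condition number above 1e12.
* Angle CDF arguments clamped to [−1, 1] before arccos.
* Axis sign conventions (largest-magnitude loading positive) applied in
  GPA, PCA and CVA so repeated runs agree exactly.
* Test-suite simulations use 6 populations × 20–100 specimens and
  Monte-Carlo sizes of 10³–10⁶ chosen so the full suite runs in a few
  seconds while keeping binomial/KS error comfortably inside the
  asserted tolerances; the acceptance script uses 6 × 100 and 10⁴
  angle-null replicates.

## Known limitations

3D landmarks, semilandmarks, missing-landmark estimation and Procrustes
ANOVA of measurement error are out of scope. The evolutionary
regression is unweighted and non-phylogenetic. Wilks' Λ assumes
multivariate normal within-group scores; the CVA percent-among
convention (eigenvalue share of among-group variation) differs from
"percent of total shape variance" reported by some packages.
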