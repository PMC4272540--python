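# allomorph

Geometric-morphometric allometry analysis for 2D landmark data, built
for multi-population studies of body shape in small fishes (and any
other organism digitised as fixed 2D landmarks).

## The problem

Populations of a species often differ in both body size and body shape.
When shape changes proportionally with size — allometry — apparent shape
divergence among populations may be an indirect consequence of size
divergence rather than direct selection on shape. Separating the two
requires comparing the *within-population* (static) allometric
trajectory with the *evolutionary* allometry of population means, and
asking whether the two directions in shape space are more aligned than
chance.

`allomorph` implements that workflow end to end:

* **Superimposition** — Generalized Procrustes Analysis (GPA) of k
  landmarks per specimen: configurations are translated, scaled to unit
  centroid size `CS = sqrt(Σᵢ ‖pᵢ − p̄‖²)` and iteratively rotated to a
  consensus; shapes are then projected into the tangent space at the
  consensus. `ln(CS)` is the size variable.
* **Ordination** — PCA of the shape coordinates; CVA maximising
  among-population relative to pooled within-population variation, with
  scores scaled to unit within-group covariance; 95% confidence
  ellipses for group means.
* **Allometric regression** — multivariate OLS of shape on `ln(CS)`,
  `y = β₀ + β₁ ln CS + ε`, with the slope vector `β₁` as the allometric
  shape vector and percent explained measured in squared-Procrustes-
  distance units. Fitted per population, pooled within populations
  (mean-centred per group), and across population means (evolutionary).
* **Vector tests** — the angle between two allometric vectors is
  `arccos(a·b / |a||b|)`; under the null of uniformly random directions
  in p dimensions the angle has density ∝ sin^(p−2)θ, giving a closed-
  form CDF via the regularized incomplete beta function. The mean
  pairwise angle among g population vectors is tested against a
  Monte-Carlo null. p defaults to the shape-space dimension 2k − 4.
* **Group tests** — ANOVA on `ln(CS)`; MANOVA (Wilks' Λ with Rao's F)
  on the leading PCs that carry >90% of shape variation.
* **PROTEST** — Procrustes concordance of two digitisation series with
  a row-permutation test, for assessing measurement repeatability.
* **Synthetic data** — a generator that emulates the study design (six
  populations of unequal size along a `ln(CS)` gradient, a common
  within-population vector w and an evolutionary vector e at a
  controlled angle to w, digitisation noise) with exact ground truth,
  so every stage is testable without real data.

## Worked example

```python
from allomorph import (build_spec, simulate_dataset, gpa_align,
                       evolutionary_allometry, pooled_within_allometry,
                       pairwise_angle_test, shape_space_dim)

dataset, truth = simulate_dataset(build_spec(angle_e_w=40.0, seed=11))
aligned = gpa_align(dataset)
evo = evolutionary_allometry(aligned)
within = pooled_within_allometry(aligned)
test = pairwise_angle_test(evo.slope, within.slope,
                           p=shape_space_dim(aligned.k))
print(f"{test.angle_deg:.1f} degrees, p = {test.p_value:.2e}")
```

Running `python examples/03_angle_tests.py` (which does the above)
prints:

```
evolutionary vs within angle: 38.2 degrees (generating angle 40), p = 9.34e-05
mean pairwise angle among 6 population vectors: 2.7 degrees, p = 0.0001 (10000 Monte-Carlo replicates)
```

The 38.2° estimate recovers the generating 40° angle between the
evolutionary and within-population allometric vectors; its p-value says
an angle that small would essentially never arise between random
directions in 16-dimensional shape space, i.e. the two allometries
share a direction. The 2.7° mean pairwise angle shows the six
populations share a common within-population trajectory, justifying the
pooled fit. The other scripts in `examples/` walk through
superimposition, the three regression levels and the full pipeline; the
`allomorph` command-line tool (`simulate`, `align`, `allometry`,
`angles`, `run`) exposes the same steps from the shell.

## Layout

```
src/allomorph/   io, gpa, ordination, allometry, vector_stats,
                 group_tests, synthetic, pipeline, cli
tests/           unit + property + acceptance suites
examples/        narrative scripts, one per capability
docs/methods.md  models, conventions, parameter choices, limitations
```
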