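"""Compare allometric directions against a random-directions null.

Two unit vectors drawn uniformly at random in p dimensions are almost
orthogonal when p is large; observing a much smaller angle between two
estimated allometric vectors is evidence they share a direction.
"""

from allomorph import (
    build_spec,
    evolutionary_allometry,
    gpa_align,
    mean_pairwise_angle_test,
    pairwise_angle_test,
    per_group_allometries,
    pooled_within_allometry,
    shape_space_dim,
    simulate_dataset,
)

dataset, truth = simulate_dataset(build_spec(angle_e_w=40.0, seed=11))
aligned = gpa_align(dataset)
p = shape_space_dim(aligned.k)  # 2k - 4 = 16 for 10 landmarks

evo = evolutionary_allometry(aligned)
within = pooled_within_allometry(aligned)
pair = pairwise_angle_test(evo.slope, within.slope, p=p)
print(f"evolutionary vs within angle: {pair.angle_deg:.1f} degrees "
      f"(generating angle {truth.angle_e_w:.0f}), p = {pair.p_value:.2e}")

vectors = [m.slope for m in per_group_allometries(aligned).values()]
mean = mean_pairwise_angle_test(vectors, p=p, n_reps=10_000, seed=1)
print(f"mean pairwise angle among {len(vectors)} population vectors: "
      f"{mean.angle_deg:.1f} degrees, p = {mean.p_value:.4f} "
      f"({mean.n_reps} Monte-Carlo replicates)")
# Small p-values reject the null that the vectors point in random
# directions of the 16-dimensional shape space: the populations share a
# common allometric trajectory.
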