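"""Multivariate regression of shape on ln(CS) at the three levels."""

import numpy as np
import pytest

from allomorph.allometry import (
    AllometryError,
    evolutionary_allometry,
    multivariate_regression,
    nonallometric_component,
    per_group_allometries,
    pooled_within_allometry,
    predict_shape,
    regression_scores,
)
from allomorph.gpa import AlignedSample
from allomorph.vector_stats import vector_angle


def make_sample(shapes, ln_cs, groups):
    """Wrap raw matrices as an AlignedSample for the group-level fits."""
    from allomorph.io import SpecimenMeta

    shapes = np.asarray(shapes, float)
    ln_cs = np.asarray(ln_cs, float)
    meta = tuple(
        SpecimenMeta(str(i), population=str(g)) for i, g in enumerate(groups)
    )
    mean = shapes.mean(axis=0)
    return AlignedSample(
        shapes=shapes,
        centroid_sizes=np.exp(ln_cs),
        ln_cs=ln_cs,
        consensus=mean / np.linalg.norm(mean),
        meta=meta,
    )


def linear_shapes(rng, n=40, m=12, noise=0.0):
    sizes = rng.uniform(0.5, 2.0, n)
    intercept = rng.normal(size=m)
    slope = rng.normal(size=m)
    shapes = intercept + np.outer(sizes, slope) + rng.normal(0, noise, (n, m))
    return shapes, sizes, intercept, slope


class TestMultivariateRegression:
    def test_noiseless_linear_recovered_exactly(self):
        rng = np.random.default_rng(0)
        shapes, sizes, intercept, slope = linear_shapes(rng)
        model = multivariate_regression(shapes, sizes)
        np.testing.assert_allclose(model.slope, slope, rtol=1e-9)
        np.testing.assert_allclose(model.intercept, intercept, rtol=1e-9, atol=1e-9)
        assert model.percent_explained == pytest.approx(1.0, abs=1e-12)

    def test_size_independent_shapes_have_vanishing_allometry(self):
        """Pure noise: percent explained sits at the 1/(n-1) chance level
        and the slope shrinks toward zero."""
        rng = np.random.default_rng(1)
        n = 1000
        sizes = rng.uniform(0.5, 2.0, n)
        shapes = rng.normal(size=(n, 10))
        model = multivariate_regression(shapes, sizes)
        assert model.percent_explained < 5.0 / (n - 1)
        # E||slope|| ~ sigma * sqrt(m / SSx); allow twice that
        ssx = ((sizes - sizes.mean()) ** 2).sum()
        assert np.linalg.norm(model.slope) < 2 * np.sqrt(shapes.shape[1] / ssx)

    def test_percent_matches_longhand_residual_loop(self):
        """1 - RSS/TSS computed coordinate by coordinate with an explicit
        loop must equal the reported percent."""
        rng = np.random.default_rng(2)
        shapes, sizes, *_ = linear_shapes(rng, noise=0.3)
        model = multivariate_regression(shapes, sizes)
        rss = tss = 0.0
        for j in range(shapes.shape[1]):
            y = shapes[:, j]
            b1 = np.cov(sizes, y, ddof=1)[0, 1] / np.var(sizes, ddof=1)
            b0 = y.mean() - b1 * sizes.mean()
            rss += ((y - b0 - b1 * sizes) ** 2).sum()
            tss += ((y - y.mean()) ** 2).sum()
        assert model.percent_explained == pytest.approx(1 - rss / tss, rel=1e-9)

    def test_degenerate_predictor(self):
        with pytest.raises(AllometryError, match="zero size variance"):
            multivariate_regression(np.zeros((5, 4)), np.ones(5))


def grouped_sample(rng, n_per=30, m=12, noise=0.05, n_groups=4, common_slope=None):
    slope = common_slope if common_slope is not None else rng.normal(size=m)
    shapes, sizes, groups = [], [], []
    for gi in range(n_groups):
        mu = 0.8 + 0.25 * gi
        s = rng.normal(mu, 0.2, n_per)
        offset = rng.normal(size=m) * 0.5
        shapes.append(offset + np.outer(s, slope) + rng.normal(0, noise, (n_per, m)))
        sizes.append(s)
        groups += [f"g{gi}"] * n_per
    return (
        make_sample(np.vstack(shapes), np.concatenate(sizes), groups),
        np.array(groups),
        slope,
    )


class TestPooledWithin:
    def test_recovers_common_vector(self):
        rng = np.random.default_rng(3)
        sample, groups, slope = grouped_sample(rng, n_per=50)
        model = pooled_within_allometry(sample, groups)
        assert vector_angle(model.slope, slope) < 5.0

    def test_group_mean_offsets_do_not_matter(self):
        rng = np.random.default_rng(4)
        sample, groups, _ = grouped_sample(rng)
        model = pooled_within_allometry(sample, groups)
        shifted = sample.shapes.copy()
        for gi, g in enumerate(np.unique(groups)):
            shifted[groups == g] += rng.normal(size=shifted.shape[1]) * (gi + 1)
        model2 = pooled_within_allometry(
            make_sample(shifted, sample.ln_cs, groups), groups
        )
        np.testing.assert_allclose(model2.slope, model.slope, atol=1e-10)
        assert model2.percent_explained == pytest.approx(
            model.percent_explained, abs=1e-10
        )

    def test_small_group_named_in_error(self):
        rng = np.random.default_rng(5)
        sample, groups, _ = grouped_sample(rng, n_per=5)
        groups = groups.copy()
        groups[:3] = "tiny"
        groups[3:5] = "g0"
        with pytest.raises(AllometryError, match="'g0'|'tiny'"):
            pooled_within_allometry(
                make_sample(sample.shapes, sample.ln_cs, groups), groups
            )

    def test_equals_precision_weighted_per_group_combination(self):
        """With equal group size-variances the pooled slope is the
        SSx-weighted (here: equal-weight) mean of per-group slopes."""
        rng = np.random.default_rng(6)
        m, n_per = 8, 25
        slope = rng.normal(size=m)
        shapes, sizes, groups = [], [], []
        s_template = np.linspace(-0.3, 0.3, n_per)  # identical size design
        for gi in range(3):
            s = 1.0 + 0.3 * gi + s_template
            shapes.append(np.outer(s, slope) + rng.normal(0, 0.1, (n_per, m)))
            sizes.append(s)
            groups += [f"g{gi}"] * n_per
        sample = make_sample(np.vstack(shapes), np.concatenate(sizes), groups)
        groups = np.array(groups)
        pooled = pooled_within_allometry(sample, groups)
        per = per_group_allometries(sample, groups)
        weighted = np.mean([mdl.slope for mdl in per.values()], axis=0)
        np.testing.assert_allclose(pooled.slope, weighted, rtol=1e-9)


class TestEvolutionary:
    def test_exactly_linear_consensus_means(self):
        rng = np.random.default_rng(7)
        m = 10
        slope = rng.normal(size=m)
        base = rng.normal(size=m)
        shapes, sizes, groups = [], [], []
        for gi, mu in enumerate([0.8, 1.1, 1.4, 1.7]):
            # symmetric within-group scatter: group means stay exact
            dev = np.vstack([np.eye(1, m, gi), -np.eye(1, m, gi), np.zeros((1, m))])
            shapes.append(base + mu * slope + 0.01 * dev)
            sizes.append([mu - 0.05, mu + 0.05, mu])
            groups += [f"g{gi}"] * 3
        sample = make_sample(np.vstack(shapes), np.concatenate(sizes), groups)
        model = evolutionary_allometry(sample, np.array(groups))
        assert model.level == "evolutionary" and model.n_units == 4
        np.testing.assert_allclose(model.slope, slope, rtol=1e-9)
        assert model.percent_explained == pytest.approx(1.0, abs=1e-9)

    def test_needs_three_groups(self):
        rng = np.random.default_rng(8)
        sample, groups, _ = grouped_sample(rng, n_groups=2)
        with pytest.raises(AllometryError, match="at least 3 groups"):
            evolutionary_allometry(sample, groups)

    def test_unweighted_across_populations(self):
        """Replicating every specimen of one population must not change the
        fit: each population counts once."""
        rng = np.random.default_rng(9)
        sample, groups, _ = grouped_sample(rng, n_per=20, noise=0.05)
        model = evolutionary_allometry(sample, groups)
        mask = groups == "g0"
        shapes2 = np.vstack([sample.shapes, sample.shapes[mask]])
        sizes2 = np.concatenate([sample.ln_cs, sample.ln_cs[mask]])
        groups2 = np.concatenate([groups, groups[mask]])
        model2 = evolutionary_allometry(
            make_sample(shapes2, sizes2, groups2), groups2
        )
        np.testing.assert_allclose(model2.slope, model.slope, rtol=1e-9)


class TestPerGroup:
    def test_single_group_matches_direct_regression(self):
        rng = np.random.default_rng(10)
        sample, groups, _ = grouped_sample(rng)
        per = per_group_allometries(sample, groups)
        mask = groups == "g1"
        direct = multivariate_regression(sample.shapes[mask], sample.ln_cs[mask])
        np.testing.assert_allclose(per["g1"].slope, direct.slope, rtol=1e-12)
        assert per["g1"].group == "g1"

    def test_identical_groups_have_small_pairwise_angles(self):
        rng = np.random.default_rng(11)
        sample, groups, _ = grouped_sample(rng, n_per=200, noise=0.02)
        per = per_group_allometries(sample, groups)
        slopes = [m.slope for m in per.values()]
        for i in range(len(slopes)):
            for j in range(i + 1, len(slopes)):
                assert vector_angle(slopes[i], slopes[j]) < 5.0

    def test_mean_angle_shrinks_with_sample_size(self):
        """Shared true vector: the median pairwise angle falls as per-group
        n grows (consistency of the per-group estimates)."""
        medians = []
        for n_per in (10, 50, 250):
            angles = []
            for rep in range(25):
                rng = np.random.default_rng(1000 + rep)
                sample, groups, _ = grouped_sample(
                    rng, n_per=n_per, noise=0.3, n_groups=3
                )
                per = per_group_allometries(sample, groups)
                s = [m.slope for m in per.values()]
                angles += [
                    vector_angle(s[i], s[j])
                    for i in range(3)
                    for j in range(i + 1, 3)
                ]
            medians.append(np.median(angles))
        assert medians[0] > medians[1] > medians[2]


class TestScoresAndPrediction:
    def test_scores_track_size_in_linear_data(self):
        rng = np.random.default_rng(12)
        shapes, sizes, *_ = linear_shapes(rng)
        model = multivariate_regression(shapes, sizes)
        scores = regression_scores(model, shapes)
        assert abs(np.corrcoef(scores, sizes)[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_scores_invariant_to_orthogonal_offsets(self):
        rng = np.random.default_rng(13)
        shapes, sizes, *_ = linear_shapes(rng, noise=0.1)
        model = multivariate_regression(shapes, sizes)
        direction = model.slope / np.linalg.norm(model.slope)
        v = rng.normal(size=shapes.shape[1])
        v -= (v @ direction) * direction
        scores = regression_scores(model, shapes)
        shifted = regression_scores(model, shapes + np.outer(rng.normal(size=len(shapes)), v))
        np.testing.assert_allclose(shifted, scores, atol=1e-9)

    def test_zero_slope_is_undefined_direction(self):
        model = multivariate_regression(
            np.zeros((5, 4)) + 1.0, np.arange(5.0)
        )  # constant shapes: slope 0
        with pytest.raises(AllometryError, match="undefined"):
            regression_scores(model, np.zeros((3, 4)))

    def test_prediction_at_mean_size_is_mean_shape(self):
        rng = np.random.default_rng(14)
        shapes, sizes, *_ = linear_shapes(rng, noise=0.2)
        model = multivariate_regression(shapes, sizes)
        np.testing.assert_allclose(
            predict_shape(model, sizes.mean()), shapes.mean(axis=0), atol=1e-12
        )

    def test_prediction_is_affine(self):
        rng = np.random.default_rng(15)
        shapes, sizes, *_ = linear_shapes(rng, noise=0.2)
        model = multivariate_regression(shapes, sizes)
        mid = predict_shape(model, 1.0)
        np.testing.assert_allclose(
            (predict_shape(model, 0.5) + predict_shape(model, 1.5)) / 2, mid, atol=1e-12
        )


class TestNonAllometric:
    def test_residuals_uncorrelated_with_centred_size(self):
        rng = np.random.default_rng(16)
        sample, groups, _ = grouped_sample(rng, noise=0.1)
        model = pooled_within_allometry(sample, groups)
        residuals = nonallometric_component(sample, model, groups)
        sizes_c = sample.ln_cs.copy()
        for g in np.unique(groups):
            sizes_c[groups == g] -= sizes_c[groups == g].mean()
        res_c = residuals.copy()
        for g in np.unique(groups):
            res_c[groups == g] -= res_c[groups == g].mean(axis=0)
        corr = sizes_c @ res_c / len(sizes_c)
        np.testing.assert_allclose(corr, 0, atol=1e-10)

    def test_noiseless_data_leaves_only_group_differences(self):
        rng = np.random.default_rng(17)
        sample, groups, _ = grouped_sample(rng, noise=0.0)
        model = pooled_within_allometry(sample, groups)
        residuals = nonallometric_component(sample, model, groups)
        for g in np.unique(groups):
            block = residuals[groups == g]
            np.testing.assert_allclose(
                block, np.broadcast_to(block.mean(axis=0), block.shape), atol=1e-9
            )

    def test_variance_decomposition(self):
        """Within-group variance splits exactly into allometric and residual
        parts (OLS orthogonality)."""
        rng = np.random.default_rng(18)
        sample, groups, _ = grouped_sample(rng, noise=0.1)
        model = pooled_within_allometry(sample, groups)
        residuals = nonallometric_component(sample, model, groups)
        ss = {"total": 0.0, "resid": 0.0}
        sizes_c = sample.ln_cs.copy()
        for g in np.unique(groups):
            m = groups == g
            sizes_c[m] -= sizes_c[m].mean()
            ss["total"] += ((sample.shapes[m] - sample.shapes[m].mean(0)) ** 2).sum()
            ss["resid"] += ((residuals[m] - residuals[m].mean(0)) ** 2).sum()
        explained = (np.outer(sizes_c, model.slope) ** 2).sum()
        assert ss["resid"] + explained == pytest.approx(ss["total"], rel=1e-9)
        assert explained / ss["total"] == pytest.approx(
            model.percent_explained, rel=1e-9
        )

    def test_requires_pooled_within_model(self):
        rng = np.random.default_rng(19)
        sample, groups, _ = grouped_sample(rng)
        evo = evolutionary_allometry(sample, groups)
        with pytest.raises(AllometryError, match="pooled_within"):
            nonallometric_component(sample, evo, groups)
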