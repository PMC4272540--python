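"""Multivariate allometric regression of shape on log centroid size.

The allometric shape vector is the multivariate slope of an ordinary
least-squares regression of the Procrustes shape coordinates on ln(CS):
one shared scalar predictor, one simple regression per coordinate.  The
degree of allometry is the proportion of total shape variation — in
units of squared Procrustes distance, i.e. summed squared deviations
over all coordinates — explained by the regression.

Three levels are supported:

* per-population (static) — each group regressed alone;
* pooled within-population — shapes and ln(CS) mean-centred within each
  group, then pooled, estimating the common within-group allometry;
* evolutionary — one observation per population (consensus shape, mean
  ln(CS)), estimating the allometry of population means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gpa import AlignedSample

__all__ = [
    "AllometricModel",
    "AllometryError",
    "multivariate_regression",
    "pooled_within_allometry",
    "evolutionary_allometry",
    "per_group_allometries",
    "regression_scores",
    "predict_shape",
    "nonallometric_component",
]


class AllometryError(ValueError):
    pass


@dataclass(frozen=True)
class AllometricModel:
    """A fitted shape-on-size regression.

    intercept + slope * ln_cs predicts the shape vector; slope is the
    allometric shape vector (shape change per unit ln CS);
    percent_explained is predicted SS / total centred SS, both summed
    over all shape coordinates; level is one of
    {"per_population", "pooled_within", "evolutionary"}.
    """

    intercept: np.ndarray
    slope: np.ndarray
    percent_explained: float
    n_units: int
    level: str
    mean_size: float = float("nan")
    group: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_explained <= 1.0 + 1e-12:
            raise AllometryError(
                f"percent_explained out of [0, 1]: {self.percent_explained}"
            )


def multivariate_regression(
    shapes: np.ndarray,
    sizes: np.ndarray,
    level: str = "per_population",
    group: str | None = None,
) -> AllometricModel:
    """OLS regression of an (n, 2k) shape matrix on n ln(CS) values.

    Each coordinate is regressed on the shared predictor; the slope
    vector collects the per-coordinate slopes.
    """
    shapes = np.atleast_2d(np.asarray(shapes, float))
    sizes = np.asarray(sizes, float).ravel()
    n = shapes.shape[0]
    if n < 3:
        raise AllometryError(f"need at least 3 observations, got {n}")
    if sizes.shape[0] != n:
        raise AllometryError(f"{n} shapes but {sizes.shape[0]} sizes")
    s_centred = sizes - sizes.mean()
    ss_x = float(s_centred @ s_centred)
    if ss_x == 0.0:
        raise AllometryError("zero size variance: predictor is degenerate")
    y_mean = shapes.mean(axis=0)
    y_centred = shapes - y_mean
    slope = (s_centred @ y_centred) / ss_x
    intercept = y_mean - slope * sizes.mean()
    predicted = np.outer(s_centred, slope)
    ss_pred = float((predicted**2).sum())
    ss_tot = float((y_centred**2).sum())
    percent = ss_pred / ss_tot if ss_tot > 0 else 0.0
    return AllometricModel(
        intercept=intercept,
        slope=slope,
        percent_explained=min(percent, 1.0),
        n_units=n,
        level=level,
        mean_size=float(sizes.mean()),
        group=group,
    )


def _group_indices(groups) -> tuple[np.ndarray, np.ndarray]:
    labels, inverse = np.unique(np.asarray(groups), return_inverse=True)
    return labels, inverse


def _check_groups(shapes, sizes, labels, inverse) -> None:
    for gi, label in enumerate(labels):
        mask = inverse == gi
        if mask.sum() < 3:
            raise AllometryError(
                f"group {label!r} has {int(mask.sum())} members (need >= 3)"
            )
        if np.var(sizes[mask]) == 0:
            raise AllometryError(f"group {label!r} has zero size variance")


def pooled_within_allometry(aligned: AlignedSample, groups=None) -> AllometricModel:
    """Common within-group allometry from pooled mean-centred data.

    Shapes and ln(CS) are mean-centred within each group before fitting,
    so among-group differences do not enter; percent_explained is
    measured on the pooled centred variation.
    """
    groups = aligned.populations() if groups is None else np.asarray(groups)
    shapes, sizes = aligned.shapes, aligned.ln_cs
    labels, inverse = _group_indices(groups)
    _check_groups(shapes, sizes, labels, inverse)
    shapes_c = shapes.astype(float).copy()
    sizes_c = sizes.astype(float).copy()
    for gi in range(len(labels)):
        mask = inverse == gi
        shapes_c[mask] -= shapes_c[mask].mean(axis=0)
        sizes_c[mask] -= sizes_c[mask].mean()
    model = multivariate_regression(shapes_c, sizes_c, level="pooled_within")
    # centred data: intercept is the origin; report the grand mean shape
    return AllometricModel(
        intercept=shapes.mean(axis=0) - model.slope * sizes.mean(),
        slope=model.slope,
        percent_explained=model.percent_explained,
        n_units=model.n_units,
        level="pooled_within",
        mean_size=float(sizes.mean()),
    )


def evolutionary_allometry(aligned: AlignedSample, groups=None) -> AllometricModel:
    """Allometry of population means: consensus shape on mean ln(CS).

    Each population contributes one unweighted observation regardless of
    its sample size; percent_explained is measured on the among-consensus
    variation.
    """
    groups = aligned.populations() if groups is None else np.asarray(groups)
    labels, inverse = _group_indices(groups)
    g = len(labels)
    if g < 3:
        raise AllometryError(f"need at least 3 groups, got {g}")
    mean_shapes = np.stack(
        [aligned.shapes[inverse == gi].mean(axis=0) for gi in range(g)]
    )
    mean_sizes = np.array([aligned.ln_cs[inverse == gi].mean() for gi in range(g)])
    if np.var(mean_sizes) == 0:
        raise AllometryError("group mean sizes are all equal")
    model = multivariate_regression(mean_shapes, mean_sizes, level="evolutionary")
    return AllometricModel(
        intercept=model.intercept,
        slope=model.slope,
        percent_explained=model.percent_explained,
        n_units=g,
        level="evolutionary",
        mean_size=model.mean_size,
    )


def per_group_allometries(aligned: AlignedSample, groups=None) -> dict[str, AllometricModel]:
    """Independent shape-on-size regression within each group."""
    groups = aligned.populations() if groups is None else np.asarray(groups)
    labels, inverse = _group_indices(groups)
    _check_groups(aligned.shapes, aligned.ln_cs, labels, inverse)
    return {
        str(label): multivariate_regression(
            aligned.shapes[inverse == gi],
            aligned.ln_cs[inverse == gi],
            level="per_population",
            group=str(label),
        )
        for gi, label in enumerate(labels)
    }


def regression_scores(model: AllometricModel, shapes: np.ndarray) -> np.ndarray:
    """Projection of mean-centred shapes onto the unit allometric vector.

    These are the values plotted against size in allometric trajectory
    plots; the sample mean shape scores 0.
    """
    shapes = np.atleast_2d(np.asarray(shapes, float))
    norm = np.linalg.norm(model.slope)
    if norm == 0:
        raise AllometryError("zero slope vector: regression direction undefined")
    direction = model.slope / norm
    centred = shapes - shapes.mean(axis=0)
    return centred @ direction


def predict_shape(model: AllometricModel, ln_cs: float) -> np.ndarray:
    """Predicted shape vector at a given ln(CS): intercept + slope * ln_cs."""
    return model.intercept + model.slope * float(ln_cs)


def nonallometric_component(
    aligned: AlignedSample, model: AllometricModel, groups=None
) -> np.ndarray:
    """Shape residuals after removing the pooled within-group allometric part.

    Per-group centring is respected: for each specimen the removed part
    is slope x (ln CS - its group's mean ln CS), so group mean shape
    differences remain in the residuals and can be ordinated (CVA of the
    non-allometric shape component).
    """
    if model.level != "pooled_within":
        raise AllometryError(
            f"non-allometric component requires a pooled_within model, got {model.level!r}"
        )
    groups = aligned.populations() if groups is None else np.asarray(groups)
    if model.slope.shape[0] != aligned.shapes.shape[1]:
        raise AllometryError("model and sample dimension mismatch")
    labels, inverse = _group_indices(groups)
    sizes_c = aligned.ln_cs.astype(float).copy()
    for gi in range(len(labels)):
        mask = inverse == gi
        sizes_c[mask] -= sizes_c[mask].mean()
    return aligned.shapes - np.outer(sizes_c, model.slope)
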