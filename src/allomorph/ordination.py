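"""Ordination of Procrustes shape coordinates: PCA, CVA, confidence ellipses.

PCA is a rigid rotation of the shape coordinates (spectral decomposition
of the sample covariance matrix).  CVA maximises the ratio of
among-group to pooled within-group variation; because Procrustes
coordinates are rank-deficient (at most 2k - 4 dimensions of variation),
the data are first projected onto principal components with non-zero
variance before the within-group matrix is inverted.  CVA scores are
scaled so the pooled within-group covariance is the identity (the
Mahalanobis convention used by MorphoJ), which makes confidence ellipses
comparable across groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy import stats

from .gpa import AlignedSample

__all__ = [
    "PcaResult",
    "CvaResult",
    "ConfidenceEllipse",
    "OrdinationError",
    "shape_pca",
    "pca",
    "select_pcs_by_variance",
    "cva",
    "confidence_ellipse",
]

RANK_GUARD_RTOL = 1e-12


class OrdinationError(ValueError):
    pass


@dataclass(frozen=True)
class PcaResult:
    """Principal components of a shape sample.

    eigenvalues are variances (descending); axes are orthonormal columns
    in the original variable space; scores are centred projections;
    cum_variance gives cumulative proportions of total variance.
    """

    eigenvalues: np.ndarray
    axes: np.ndarray  # (n_vars, r), orthonormal columns
    scores: np.ndarray  # (n, r)
    cum_variance: np.ndarray
    mean: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass(frozen=True)
class CvaResult:
    """Canonical variates of grouped shape data.

    cv_axes are vectors in the input variable space (columns, one per
    canonical axis, not orthonormal); scores have pooled within-group
    covariance equal to the identity; percent_among is each axis' share
    of the among-group variation; group_means holds per-group score means.
    """

    cv_axes: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    percent_among: np.ndarray
    group_means: np.ndarray
    group_labels: tuple[str, ...]


@dataclass(frozen=True)
class ConfidenceEllipse:
    """Confidence ellipse for a bivariate group mean."""

    center: np.ndarray
    semi_axes: np.ndarray  # descending
    orientation: float  # radians, major axis vs. first score axis
    level: float
    degenerate: bool = False


def pca(data: np.ndarray) -> PcaResult:
    """PCA of an (n, m) data matrix via SVD of the centred data.

    Components with eigenvalue below 1e-12 of the largest are dropped
    (Procrustes data are rank-deficient by construction).
    """
    data = np.asarray(data, float)
    n = data.shape[0]
    if n < 3:
        raise OrdinationError(f"PCA needs at least 3 observations, got {n}")
    mean = data.mean(axis=0)
    centred = data - mean
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    if eigenvalues[0] > 0:
        keep = eigenvalues > RANK_GUARD_RTOL * eigenvalues[0]
    else:
        keep = np.zeros(len(eigenvalues), bool)
        keep[0] = True
    eigenvalues = eigenvalues[keep]
    axes = vt[keep].T
    # fix sign: largest-magnitude loading of each axis positive
    for j in range(axes.shape[1]):
        col = axes[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            axes[:, j] = -col
    scores = centred @ axes
    total = eigenvalues.sum()
    cum = np.cumsum(eigenvalues) / total if total > 0 else np.ones_like(eigenvalues)
    return PcaResult(eigenvalues, axes, scores, cum, mean)


def shape_pca(aligned: AlignedSample) -> PcaResult:
    """PCA of tangent-space Procrustes shape coordinates."""
    return pca(aligned.shapes)


def select_pcs_by_variance(pca_result: PcaResult, threshold: float) -> np.ndarray:
    """Indices of the smallest leading PC set whose cumulative variance
    strictly exceeds ``threshold`` (all components at threshold 1.0)."""
    if not 0 < threshold <= 1:
        raise OrdinationError(f"threshold must be in (0, 1], got {threshold}")
    cum = pca_result.cum_variance
    over = np.nonzero(cum > threshold)[0]
    last = over[0] if len(over) else len(cum) - 1
    return np.arange(last + 1)


def cva(shapes: np.ndarray, groups) -> CvaResult:
    """Canonical variates analysis of grouped multivariate data.

    The data are projected onto non-null principal components, then the
    generalized eigenproblem H v = lambda E v is solved, where H and E
    are the among-group and pooled within-group cross-product matrices.
    Eigenvalues are reported on the conventional scale
    lambda_H / lambda_E * (n - g) / (g - 1) (ratio of among- to
    within-group variance per axis); scores are scaled to unit pooled
    within-group covariance.
    """
    shapes = np.asarray(shapes, float)
    groups = np.asarray(groups)
    n = shapes.shape[0]
    labels, inverse = np.unique(groups, return_inverse=True)
    g = len(labels)
    if g < 2:
        raise OrdinationError(f"CVA needs at least 2 groups, got {g}")
    counts = np.bincount(inverse)
    small = labels[counts < 3]
    if len(small):
        raise OrdinationError(f"groups with fewer than 3 members: {list(small)}")

    pca_result = pca(shapes)
    rank = pca_result.n_components
    if n - g <= rank:
        raise OrdinationError(
            f"too few residual degrees of freedom (n - g = {n - g}) for "
            f"rank {rank} data"
        )
    x = pca_result.scores  # centred, full-rank coordinates

    grand = x.mean(axis=0)
    h = np.zeros((rank, rank))
    e = np.zeros((rank, rank))
    for gi in range(g):
        xi = x[inverse == gi]
        mi = xi.mean(axis=0)
        d = (mi - grand)[:, None]
        h += len(xi) * (d @ d.T)
        r = xi - mi
        e += r.T @ r
    # guard: E must be invertible on the rank-reduced space
    cond = np.linalg.cond(e)
    if not np.isfinite(cond) or cond > 1e12:
        raise OrdinationError(
            f"pooled within-group covariance ill-conditioned (cond={cond:.2e})"
        )
    evals, evecs = scipy.linalg.eigh(h, e)  # v' E v = I
    order = np.argsort(evals)[::-1][: g - 1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    # unit pooled within-group covariance: v' (E/(n-g)) v = I
    evecs = evecs * np.sqrt(n - g)
    eigenvalues = evals * (n - g) / (g - 1)

    for j in range(evecs.shape[1]):
        col = evecs[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            evecs[:, j] = -col

    scores = x @ evecs
    cv_axes = pca_result.axes @ evecs
    total = eigenvalues.sum()
    percent = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    group_means = np.stack([scores[inverse == gi].mean(axis=0) for gi in range(g)])
    return CvaResult(
        cv_axes=cv_axes,
        scores=scores,
        eigenvalues=eigenvalues,
        percent_among=percent,
        group_means=group_means,
        group_labels=tuple(str(lb) for lb in labels),
    )


def confidence_ellipse(scores: np.ndarray, level: float = 0.95) -> ConfidenceEllipse:
    """Confidence ellipse for a bivariate mean.

    The covariance of the mean (sample covariance / n) is scaled by the
    chi-square quantile with 2 degrees of freedom at ``level``; ellipse
    semi-axes are the square roots of the scaled eigenvalues.
    """
    scores = np.asarray(scores, float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise OrdinationError(f"scores must be n x 2, got {scores.shape}")
    n = scores.shape[0]
    if n < 3:
        raise OrdinationError(f"need at least 3 observations, got {n}")
    if not 0 < level < 1:
        raise OrdinationError(f"level must be in (0, 1), got {level}")
    center = scores.mean(axis=0)
    cov_mean = np.cov(scores, rowvar=False) / n
    evals, evecs = np.linalg.eigh(cov_mean)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    degenerate = bool(evals[-1] <= 1e-15 * max(evals[0], 1e-300))
    q = stats.chi2.ppf(level, df=2)
    semi = np.sqrt(np.clip(evals, 0, None) * q)
    orientation = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return ConfidenceEllipse(center, semi, orientation, level, degenerate)
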