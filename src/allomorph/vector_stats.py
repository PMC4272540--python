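"""Angles between allometric vectors and their random-direction nulls.

The angle between two allometric shape vectors is the arc-cosine of the
inner product of the unit-normalised vectors.  Under the null that both
directions are uniform on the unit sphere in p dimensions, the angle has
density proportional to sin^(p-2)(theta); equivalently
(1 + cos Theta)/2 ~ Beta((p-1)/2, (p-1)/2), which gives a closed-form
CDF through the regularized incomplete beta function.  Small observed
angles are evidence that two allometries share a direction, so p-values
are one-sided lower tails.

For the *mean* of all pairwise angles among g vectors no closed form is
available (the pairwise angles are dependent), so the null distribution
is simulated by Monte Carlo with a recorded seed.

PROTEST measures concordance of two matched multivariate configurations
(here: two digitisation series of the same specimens): both matrices are
centred and scaled to unit total sum of squares, one is rotated onto the
other by the optimal orthogonal transformation, and the residual m^2 is
compared against row permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "AngleTestResult",
    "ProtestResult",
    "VectorStatsError",
    "vector_angle",
    "random_angle_cdf",
    "pairwise_angle_test",
    "mean_pairwise_angle_test",
    "protest",
]


class VectorStatsError(ValueError):
    pass


@dataclass(frozen=True)
class AngleTestResult:
    """An observed angle with its random-directions null assessment."""

    angle_deg: float
    dim: int
    p_value: float
    null_kind: str  # "analytic_pairwise" | "monte_carlo_mean"
    n_reps: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_deg <= 180.0:
            raise VectorStatsError(f"angle out of [0, 180]: {self.angle_deg}")
        if not 0.0 <= self.p_value <= 1.0:
            raise VectorStatsError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class ProtestResult:
    """Procrustes concordance of two matched configurations."""

    correlation: float
    m2: float
    p_value: float
    n_perm: int
    seed: int


def vector_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two vectors, scale-invariant, in [0, 180]."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise VectorStatsError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise VectorStatsError("zero vector has no direction")
    cos = np.clip((a @ b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def random_angle_cdf(angle_deg: float, p: int) -> float:
    """P(Theta <= angle) for the angle between two uniform random directions
    in p dimensions.

    Uses the closed form I_x((p-1)/2, (p-1)/2) with x = (1 - cos angle)/2,
    where I is the regularized incomplete beta function.
    """
    if p < 2:
        raise VectorStatsError(f"dimension must be >= 2, got {p}")
    if not 0.0 <= angle_deg <= 180.0:
        raise VectorStatsError(f"angle out of [0, 180]: {angle_deg}")
    a = (p - 1) / 2.0
    x = (1.0 - np.cos(np.radians(angle_deg))) / 2.0
    return float(special.betainc(a, a, np.clip(x, 0.0, 1.0)))


def pairwise_angle_test(a: np.ndarray, b: np.ndarray, p: int) -> AngleTestResult:
    """Test whether two vectors are more aligned than random directions.

    One-sided: the p-value is the null probability of an angle at least
    as small as observed.
    """
    angle = vector_angle(a, b)
    return AngleTestResult(
        angle_deg=angle,
        dim=p,
        p_value=random_angle_cdf(angle, p),
        null_kind="analytic_pairwise",
    )


def _mean_pairwise_angles(vectors: np.ndarray) -> float:
    """Mean of all pairwise angles among unit rows of ``vectors``."""
    gram = np.clip(vectors @ vectors.T, -1.0, 1.0)
    iu = np.triu_indices(vectors.shape[0], k=1)
    return float(np.degrees(np.arccos(gram[iu])).mean())


def mean_pairwise_angle_test(
    vectors, p: int, n_reps: int = 10_000, seed: int = 0
) -> AngleTestResult:
    """Test whether a set of vectors is mutually more aligned than random.

    The statistic is the mean of the g(g-1)/2 pairwise angles; its null
    distribution (g independent uniform directions in p dimensions) is
    simulated ``n_reps`` times.  p-value uses the plus-one correction
    (count + 1) / (n_reps + 1).
    """
    vs = np.stack([np.asarray(v, float).ravel() for v in vectors])
    g = vs.shape[0]
    if g < 2:
        raise VectorStatsError(f"need at least 2 vectors, got {g}")
    if n_reps < 1000:
        raise VectorStatsError(f"n_reps must be >= 1000, got {n_reps}")
    if p < 2:
        raise VectorStatsError(f"dimension must be >= 2, got {p}")
    norms = np.linalg.norm(vs, axis=1)
    if np.any(norms == 0):
        raise VectorStatsError("zero vector has no direction")
    observed = _mean_pairwise_angles(vs / norms[:, None])

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(g, k=1)
    count = 0
    # chunked so memory stays flat at large n_reps
    chunk = max(1, min(n_reps, 200_000 // max(g * p, 1)))
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        z = rng.standard_normal((m, g, p))
        z /= np.linalg.norm(z, axis=2, keepdims=True)
        gram = np.clip(np.einsum("rgp,rhp->rgh", z, z), -1.0, 1.0)
        means = np.degrees(np.arccos(gram[:, iu[0], iu[1]])).mean(axis=1)
        count += int((means <= observed).sum())
        done += m
    return AngleTestResult(
        angle_deg=observed,
        dim=p,
        p_value=(count + 1) / (n_reps + 1),
        null_kind="monte_carlo_mean",
        n_reps=n_reps,
        seed=seed,
    )


def _procrustes_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Procrustes correlation of centred, unit-SS matrices: the trace norm
    of X'Y, i.e. sqrt(1 - min residual SS) under optimal orthogonal
    rotation plus scaling."""
    s = np.linalg.svd(x.T @ y, compute_uv=False)
    return float(min(s.sum(), 1.0))


def protest(
    x: np.ndarray, y: np.ndarray, n_perm: int = 999, seed: int = 0
) -> ProtestResult:
    """Permutation test of concordance between two matched configurations.

    Both matrices are column-centred and scaled to unit total sum of
    squares; y is fitted to x by the optimal orthogonal transformation
    (reflections allowed, as in vegan's protest).  The observed
    correlation sqrt(1 - m^2) is compared with values obtained after
    random row permutations of y.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise VectorStatsError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 2 or x.shape[0] < 2:
        raise VectorStatsError("need an n x m matrix with n >= 2")
    if n_perm < 1:
        raise VectorStatsError(f"n_perm must be >= 1, got {n_perm}")

    def _norm(m: np.ndarray) -> np.ndarray:
        c = m - m.mean(axis=0)
        ss = np.sqrt((c**2).sum())
        if ss == 0:
            raise VectorStatsError("degenerate matrix: zero total sum of squares")
        return c / ss

    xs, ys = _norm(x), _norm(y)
    corr = _procrustes_correlation(xs, ys)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _procrustes_correlation(xs, _norm(y[perm])) >= corr:
            count += 1
    return ProtestResult(
        correlation=corr,
        m2=1.0 - corr**2,
        p_value=(count + 1) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
    )
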