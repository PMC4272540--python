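"""Group-difference tests: one-way ANOVA on size, MANOVA on shape PCs.

ANOVA tests for body-size differences among populations using ln(CS).
MANOVA tests for shape differences using the leading principal
components of the Procrustes shape coordinates as dependent variables;
the statistic is Wilks' Lambda = det(E) / det(E + H) with E and H the
within- and among-group cross-product matrices, converted to an F
statistic by Rao's approximation (exact when the number of variables is
at most 2 or the number of groups at most 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AnovaResult",
    "ManovaResult",
    "GroupTestError",
    "one_way_anova",
    "manova_wilks",
]


class GroupTestError(ValueError):
    pass


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    F: float
    df1: float
    df2: float
    p_value: float


def _split(values: np.ndarray, groups) -> list[np.ndarray]:
    groups = np.asarray(groups)
    labels, inverse = np.unique(groups, return_inverse=True)
    parts = [values[inverse == gi] for gi in range(len(labels))]
    for label, part in zip(labels, parts):
        if len(part) == 0:
            raise GroupTestError(f"empty group {label!r}")
    return parts


def one_way_anova(values: np.ndarray, groups) -> AnovaResult:
    """One-way fixed-effects ANOVA: F = (SSB/(g-1)) / (SSW/(n-g))."""
    values = np.asarray(values, float).ravel()
    parts = _split(values, groups)
    g, n = len(parts), len(values)
    if g < 2:
        raise GroupTestError(f"need at least 2 groups, got {g}")
    if n <= g:
        raise GroupTestError(f"need n > g, got n={n}, g={g}")
    f, p = stats.f_oneway(*parts)
    return AnovaResult(F=float(f), df_between=g - 1, df_within=n - g, p_value=float(p))


def manova_wilks(scores: np.ndarray, groups) -> ManovaResult:
    """One-way MANOVA via Wilks' Lambda with Rao's F approximation.

    Raises
    ------
    GroupTestError
        If any group has fewer than q + 1 members, n - g < q, or the
        within-group cross-product matrix is singular.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    if scores.ndim != 2:
        raise GroupTestError("scores must be an n x q matrix")
    n, q = scores.shape
    groups = np.asarray(groups)
    labels, inverse = np.unique(groups, return_inverse=True)
    g = len(labels)
    if g < 2:
        raise GroupTestError(f"need at least 2 groups, got {g}")
    counts = np.bincount(inverse, minlength=g)
    small = labels[counts < q + 1]
    if len(small):
        raise GroupTestError(f"groups smaller than q + 1 = {q + 1}: {list(small)}")
    if n - g < q:
        raise GroupTestError(f"need n - g >= q, got n-g={n - g}, q={q}")

    grand = scores.mean(axis=0)
    e = np.zeros((q, q))
    h = np.zeros((q, q))
    for gi in range(g):
        xi = scores[inverse == gi]
        mi = xi.mean(axis=0)
        r = xi - mi
        e += r.T @ r
        d = (mi - grand)[:, None]
        h += len(xi) * (d @ d.T)
    sign_e, logdet_e = np.linalg.slogdet(e)
    sign_t, logdet_t = np.linalg.slogdet(e + h)
    if sign_e <= 0 or sign_t <= 0:
        raise GroupTestError("singular within-group cross-product matrix")
    wilks = float(np.exp(logdet_e - logdet_t))

    # Rao's F approximation
    df_h = g - 1
    if q**2 + df_h**2 - 5 > 0:
        t = np.sqrt((q**2 * df_h**2 - 4) / (q**2 + df_h**2 - 5))
    else:
        t = 1.0
    df1 = q * df_h
    m = (n - 1) - (q + df_h + 1) / 2.0
    df2 = m * t - (q * df_h - 2) / 2.0
    lam_t = wilks ** (1.0 / t)
    f = (1.0 - lam_t) / lam_t * df2 / df1
    p = float(stats.f.sf(f, df1, df2))
    return ManovaResult(wilks_lambda=wilks, F=float(f), df1=float(df1), df2=float(df2), p_value=p)
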