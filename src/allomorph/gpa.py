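"""Generalized Procrustes Analysis of 2D landmark configurations.

Superimposition follows the partial-Procrustes convention used by the
main geometric-morphometrics packages (MorphoJ, geomorph): every
configuration is translated to the origin and scaled to unit centroid
size, then iteratively rotated to the running consensus until the
consensus stabilises.  The consensus is finally rotated to its principal
axes (with a fixed sign convention) so repeated runs are bit-comparable,
and all configurations are projected orthogonally onto the tangent space
at the consensus.  Centroid sizes are measured on the raw configurations
before any scaling and carried through as the size variable ln(CS).

The shape space of k 2D landmarks has dimension 2k - 4 after removing
translation (2), scale (1) and rotation (1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import LandmarkConfiguration, ShapeDataset, SpecimenMeta

__all__ = [
    "AlignedSample",
    "GpaError",
    "centroid_size",
    "optimal_rotation",
    "gpa_align",
    "tangent_project",
    "procrustes_distance",
    "shape_space_dim",
]

CONVERGENCE_TOL = 1e-8
MAX_ITERATIONS = 100


class GpaError(ValueError):
    """Degenerate configurations, dimension mismatches, non-convergence."""


def shape_space_dim(k: int) -> int:
    """Dimension of the shape (tangent) space for k 2D landmarks: 2k - 4."""
    return 2 * k - 4


@dataclass(frozen=True)
class AlignedSample:
    """Procrustes shape coordinates for a sample of specimens.

    Attributes
    ----------
    shapes : ndarray (n, 2k)
        Tangent-space Procrustes shape coordinates, row-flattened
        (x1, y1, ..., xk, yk).
    centroid_sizes : ndarray (n,)
        Centroid sizes of the raw configurations, original units.
    ln_cs : ndarray (n,)
        Natural log of centroid size; the size variable.
    consensus : ndarray (2k,)
        Mean shape, centred, unit centroid size, principal-axes oriented.
    meta : tuple of SpecimenMeta
        Per-specimen metadata carried through from the input dataset.
    n_iterations : int
        Iterations used by the superimposition.
    """

    shapes: np.ndarray
    centroid_sizes: np.ndarray
    ln_cs: np.ndarray
    consensus: np.ndarray
    meta: tuple[SpecimenMeta, ...]
    n_iterations: int = 0

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def k(self) -> int:
        return self.shapes.shape[1] // 2

    def populations(self) -> np.ndarray:
        return np.array([m.population for m in self.meta])

    def to_dataset(self) -> ShapeDataset:
        """Repackage aligned shapes as a ShapeDataset (for export/re-analysis)."""
        from .io import dataset_from_arrays

        coords = self.shapes.reshape(self.n, self.k, 2)
        return dataset_from_arrays(
            coords,
            specimen_ids=[m.specimen_id for m in self.meta],
            populations=[m.population for m in self.meta],
            sexes=[m.sex for m in self.meta],
            age_classes=[m.age_class for m in self.meta],
        )


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    Raises
    ------
    GpaError
        If all landmarks coincide (size 0 cannot be log-transformed).
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs == 0.0:
        raise GpaError("degenerate configuration: all landmarks coincide")
    return cs


def optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper 2x2 rotation R minimising ||a @ R - b||^2 for centred k x 2 matrices.

    Reflections are never returned (determinant forced to +1): all
    specimens are digitised in the same lateral view, so an improper fit
    would be an artefact.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise GpaError(f"shape mismatch: {a.shape} vs {b.shape}")
    m = a.T @ b
    if not np.any(m):
        raise GpaError("rank-0 input: cannot determine a rotation")
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    # flip the weakest singular direction to force a proper rotation
    return u @ np.diag([1.0, d]) @ vt


def _centre_and_scale(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre each configuration and scale to unit centroid size."""
    centred = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centred**2).sum(axis=(1, 2)))
    if np.any(sizes == 0):
        bad = int(np.argmax(sizes == 0))
        raise GpaError(f"degenerate configuration at index {bad}: zero centroid size")
    return centred / sizes[:, None, None], sizes


def _principal_axes_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation taking the consensus to its principal axes.

    Sign convention: the coordinate entry of largest magnitude in the
    rotated consensus is made positive, fixing the 180-degree ambiguity.
    """
    _, _, vt = np.linalg.svd(consensus, full_matrices=False)
    rot = vt.T
    if np.linalg.det(rot) < 0:
        rot = rot @ np.diag([1.0, -1.0])
    rotated = consensus @ rot
    flat = rotated.ravel()
    if flat[np.argmax(np.abs(flat))] < 0:
        rot = rot @ np.diag([-1.0, -1.0])  # 180-degree turn, still proper
    return rot


def gpa_align(
    dataset: ShapeDataset,
    tol: float = CONVERGENCE_TOL,
    max_iter: int = MAX_ITERATIONS,
    project_to_tangent: bool = True,
) -> AlignedSample:
    """Generalized Procrustes superimposition of a landmark dataset.

    Iteratively rotates unit-size, centred configurations to the running
    consensus (initialised from the first specimen), recomputing the
    consensus (rescaled to unit centroid size) until its change, measured
    as summed squared coordinate difference, falls below ``tol``.

    Raises
    ------
    GpaError
        Fewer than 2 specimens, degenerate configurations, or failure to
        converge within ``max_iter`` iterations.
    """
    if len(dataset) < 2:
        raise GpaError(f"need at least 2 specimens, got {len(dataset)}")
    coords = dataset.coords_array()  # (n, k, 2)
    scaled, sizes = _centre_and_scale(coords)

    consensus = scaled[0].copy()
    n_iter = 0
    change = np.inf
    aligned = scaled
    for n_iter in range(1, max_iter + 1):
        aligned = np.stack([x @ optimal_rotation(x, consensus) for x in scaled])
        new_consensus = aligned.mean(axis=0)
        new_consensus /= np.sqrt((new_consensus**2).sum())
        change = float(((new_consensus - consensus) ** 2).sum())
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise GpaError(
            f"GPA did not converge in {max_iter} iterations (last change {change:.3e})"
        )
    # re-rotate to the final consensus so shapes and consensus agree exactly
    aligned = np.stack([x @ optimal_rotation(x, consensus) for x in scaled])

    rot = _principal_axes_rotation(consensus)
    consensus = consensus @ rot
    aligned = aligned @ rot

    flat = aligned.reshape(len(dataset), -1)
    cons_flat = consensus.ravel()
    if project_to_tangent:
        flat = tangent_project(flat, cons_flat)
    return AlignedSample(
        shapes=flat,
        centroid_sizes=sizes,
        ln_cs=np.log(sizes),
        consensus=cons_flat,
        meta=dataset.meta,
        n_iterations=n_iter,
    )


def tangent_project(shapes: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Orthogonal projection of aligned shapes onto the tangent space.

    The tangent space at the (unit-norm) consensus c is the hyperplane
    {y : y . c = 1}; each shape x maps to x + (1 - x.c) c.  For shapes
    near the consensus the displacement is second order in the
    Procrustes distance.
    """
    shapes = np.atleast_2d(np.asarray(shapes, float))
    c = np.asarray(consensus, float)
    c = c / np.linalg.norm(c)
    dots = shapes @ c
    return shapes + (1.0 - dots)[:, None] * c


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root summed squared coordinate difference of two shape vectors."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise GpaError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))
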