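"""Three-dimensional thin-plate-spline interpolation and bending energy.

Uses the 3D biharmonic kernel U(r) = r.  The interpolant through control
points ``p_i`` is

    f(x) = A^T [1, x] + sum_i W_i U(|x - p_i|)

with side conditions sum_i W_i = 0 and P^T W = 0 that remove the affine
component from the radial part.  The bending-energy matrix is the k x k
upper-left block of the inverse of the bordered system matrix; its quadratic
form on target coordinates measures non-affine deformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "TPSModel",
    "BendingEnergyMatrix",
    "TPSSingularityError",
    "fit_tps",
    "evaluate_tps",
    "bending_energy_matrix",
    "bending_energy",
]

COINCIDENCE_TOL = 1e-9
CONDITION_WARN = 1e12


class TPSSingularityError(ValueError):
    """Raised when control points are coincident or coplanar."""


@dataclass
class TPSModel:
    control_points: np.ndarray  # (k, 3)
    warp_weights: np.ndarray  # (k, 3)
    affine: np.ndarray  # (4, 3): row 0 translation, rows 1..3 linear part

    def __call__(self, query: np.ndarray) -> np.ndarray:
        return evaluate_tps(self, query)


@dataclass
class BendingEnergyMatrix:
    matrix: np.ndarray  # (k, k), symmetric PSD, rank <= k - 4
    source_points: np.ndarray  # (k, 3)


def _validate_controls(points: np.ndarray) -> None:
    k = len(points)
    if k < 4:
        raise TPSSingularityError(f"need at least 4 control points, got {k}")
    d = pdist(points)
    if d.size and d.min() < COINCIDENCE_TOL:
        dm = squareform(d)
        np.fill_diagonal(dm, np.inf)
        i, j = np.unravel_index(np.argmin(dm), dm.shape)
        raise TPSSingularityError(
            f"coincident control points {int(i)} and {int(j)} "
            f"(distance {dm[i, j]:.3e} mm)"
        )
    centered = points - points.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    scale = svals[0] if svals[0] > 0 else 1.0
    if svals[2] / scale < 1e-10:
        raise TPSSingularityError("control points are coplanar")


def _bordered_matrix(points: np.ndarray) -> np.ndarray:
    k = len(points)
    K = cdist(points, points)  # U(r) = r
    P = np.hstack([np.ones((k, 1)), points])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    return L


def fit_tps(source: np.ndarray, target: np.ndarray) -> TPSModel:
    """Fit the interpolating TPS mapping ``source`` points onto ``target``.

    Solves the bordered linear system K W + P A = target, P^T W = 0.
    """
    source = np.asarray(source, float).reshape(-1, 3)
    target = np.asarray(target, float).reshape(-1, 3)
    if source.shape != target.shape:
        raise ValueError("source and target must have the same shape")
    _validate_controls(source)
    k = len(source)
    L = _bordered_matrix(source)
    cond = np.linalg.cond(L)
    if cond > CONDITION_WARN:
        warnings.warn(
            f"TPS system condition number {cond:.3e} exceeds {CONDITION_WARN:.0e}",
            RuntimeWarning,
            stacklevel=2,
        )
    rhs = np.vstack([target, np.zeros((4, 3))])
    try:
        sol = scipy.linalg.solve(L, rhs, assume_a="sym")
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise TPSSingularityError(f"singular TPS system: {exc}") from exc
    return TPSModel(source.copy(), sol[:k], sol[k:])


def evaluate_tps(model: TPSModel, query: np.ndarray) -> np.ndarray:
    """Evaluate f(x) = affine(x) + sum_i W_i |x - p_i| at the query points."""
    query = np.asarray(query, float)
    single = query.ndim == 1
    q = query.reshape(-1, 3)
    U = cdist(q, model.control_points)
    out = (
        np.hstack([np.ones((len(q), 1)), q]) @ model.affine
        + U @ model.warp_weights
    )
    return out[0] if single else out


def bending_energy_matrix(points: np.ndarray) -> BendingEnergyMatrix:
    """Bending-energy matrix of a control-point set.

    The k x k upper-left block of the inverse bordered matrix; symmetric,
    positive semidefinite, and annihilating affine coordinate vectors.

    With the 3D kernel U(r) = r the raw block is negative semidefinite on
    the constraint subspace (r is conditionally negative definite), so the
    block is negated — equivalent to building the system with kernel -r,
    the usual 3D convention.
    """
    points = np.asarray(points, float).reshape(-1, 3)
    _validate_controls(points)
    k = len(points)
    L = _bordered_matrix(points)
    try:
        Linv = scipy.linalg.inv(L)
    except scipy.linalg.LinAlgError as exc:
        raise TPSSingularityError(f"singular bending-energy system: {exc}") from exc
    B = -Linv[:k, :k]
    B = 0.5 * (B + B.T)
    return BendingEnergyMatrix(B, points.copy())


def bending_energy(B: BendingEnergyMatrix | np.ndarray, target: np.ndarray) -> float:
    """trace(target^T B target): zero iff target is an affine image of the source."""
    mat = B.matrix if isinstance(B, BendingEnergyMatrix) else np.asarray(B, float)
    target = np.asarray(target, float).reshape(len(mat), -1)
    e = float(np.einsum("ij,ik,kj->", target, mat, target))
    # quadratic form can go epsilon-negative through rounding
    return e if e > 0 else 0.0
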