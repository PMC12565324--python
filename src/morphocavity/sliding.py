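"""Template-to-specimen semi-landmark transfer and bending-energy sliding.

Semi-landmarks are warped from the template onto a specimen surface with a
TPS fitted on the fixed-landmark pairs, projected onto the mesh, and then
slid within their local tangent planes to minimize the bending energy of
the full configuration relative to the template, re-projecting after every
step.  Fixed landmarks never move.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry_io import (
    LandmarkConfiguration,
    TemplateDefinition,
    TriangleMesh,
    closest_points,
)
from .tps import BendingEnergyMatrix, bending_energy, bending_energy_matrix, fit_tps

__all__ = [
    "SlidingResult",
    "SlidingOptions",
    "transfer_semilandmarks",
    "tangent_basis",
    "slide_semilandmarks",
]

#: fixed landmarks digitized more than this far from the surface are rejected (mm)
FIXED_SURFACE_TOL = 0.5


@dataclass
class SlidingOptions:
    tol: float = 1e-6  # relative energy-drop convergence threshold
    max_iter: int = 10
    max_halvings: int = 5
    ridge: float = 1e-10  # scaled by trace of the step system


@dataclass
class SlidingResult:
    configuration: LandmarkConfiguration
    energy_trace: np.ndarray  # energy after each accepted state, starting at iter 0
    iterations: int
    converged: bool


def transfer_semilandmarks(
    template: TemplateDefinition,
    target_mesh: TriangleMesh,
    target_fixed: np.ndarray,
    specimen_id: str = "specimen",
    surface_tol: float = FIXED_SURFACE_TOL,
) -> LandmarkConfiguration:
    """Warp the template's 200 semi-landmarks onto ``target_mesh``.

    A TPS is fitted on the 10 fixed-landmark pairs (template -> specimen),
    the template semi-landmarks are pushed through it and each warped point
    is replaced by its closest point on the target surface.  Patch ids are
    preserved.
    """
    target_fixed = np.asarray(target_fixed, float).reshape(-1, 3)
    if target_fixed.shape != template.fixed_landmarks.shape:
        raise ValueError("target_fixed must match the template's fixed landmark count")
    _, _, dist = closest_points(target_fixed, target_mesh)
    off = np.flatnonzero(dist > surface_tol)
    if off.size:
        raise ValueError(
            f"fixed landmarks {off.tolist()} are more than {surface_tol} mm "
            f"off the target surface (max {dist.max():.3f} mm)"
        )
    model = fit_tps(template.fixed_landmarks, target_fixed)
    warped = model(template.semilandmarks)
    projected, _, _ = closest_points(warped, target_mesh)
    coords = np.vstack([target_fixed, projected])
    patch = np.concatenate(
        [np.zeros(len(target_fixed), np.int64), template.semilandmark_patches]
    )
    return LandmarkConfiguration(specimen_id, coords, patch)


def _vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted vertex normals (unnormalized face cross products summed)."""
    a, b, c = mesh.triangle_corners()
    face_n = np.cross(b - a, c - a)  # magnitude = 2 * area
    vn = np.zeros_like(mesh.vertices)
    for col in range(3):
        np.add.at(vn, mesh.triangles[:, col], face_n)
    return vn


def _surface_normals(
    points: np.ndarray,
    tri_idx: np.ndarray,
    mesh: TriangleMesh,
    vertex_normals: np.ndarray,
    tol: float = 1e-8,
) -> np.ndarray:
    """Unit normals at on-surface points with known host triangles.

    Face-interior points take the face normal; points on a vertex or edge
    (barycentric coordinate within ``tol`` of the boundary) take the
    area-weighted averaged normals of the touching vertices.
    """
    tris = mesh.triangles[tri_idx]
    a = mesh.vertices[tris[:, 0]]
    b = mesh.vertices[tris[:, 1]]
    c = mesh.vertices[tris[:, 2]]
    face_n = np.cross(b - a, c - a)
    # barycentric coordinates of each point in its host triangle
    v0 = b - a
    v1 = c - a
    v2 = points - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    den = d00 * d11 - d01 * d01
    den[den == 0] = 1.0
    w1 = (d11 * d20 - d01 * d21) / den
    w2 = (d00 * d21 - d01 * d20) / den
    bary = np.stack([1.0 - w1 - w2, w1, w2], axis=1)

    scale = np.sqrt(np.maximum(d00, d11))
    near = bary * scale[:, None] < tol * np.maximum(scale, 1.0)[:, None]
    n = face_n.copy()
    boundary = near.any(axis=1)
    for i in np.flatnonzero(boundary):
        touching = tris[i][~near[i]]  # vertices with non-zero barycentric weight
        n[i] = vertex_normals[touching].sum(axis=0)
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate surface normal at sliding point")
    return n / norms


def _orthonormal_tangents(normals: np.ndarray) -> np.ndarray:
    """(n, 2, 3) orthonormal tangent pairs perpendicular to each unit normal."""
    seeds = np.zeros_like(normals)
    seeds[np.arange(len(normals)), np.argmin(np.abs(normals), axis=1)] = 1.0
    u = seeds - np.einsum("ij,ij->i", seeds, normals)[:, None] * normals
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(normals, u)
    return np.stack([u, v], axis=1)


def tangent_basis(point: np.ndarray, mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal vectors spanning the surface tangent plane at ``point``.

    The point is first snapped to its closest surface point; vertex and edge
    locations use area-weighted averaged normals.
    """
    point = np.asarray(point, float).reshape(3)
    projected, tri_idx, _ = closest_points(point[None], mesh)
    n = _surface_normals(projected, tri_idx, mesh, _vertex_normals(mesh))
    t = _orthonormal_tangents(n)
    return t[0, 0], t[0, 1]


def _step_system(
    B_ss: np.ndarray,
    B_full: np.ndarray,
    coords: np.ndarray,
    semi_rows: np.ndarray,
    tangents: np.ndarray,
    ridge: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble T^T (I3 (x) B) T and T^T (I3 (x) B) y for tangent sliding.

    ``tangents`` is (n_semi, 2, 3); the tangent matrix T has two columns per
    semi-landmark and none for fixed landmarks, acting on the 3k stacked
    coordinate vector.
    """
    grad = B_full @ coords  # (k, 3) = per-axis B y blocks
    g = np.einsum("sac,sc->sa", tangents, grad[semi_rows])  # (n_semi, 2)
    tt = np.einsum("iac,jbc->iajb", tangents, tangents)  # tangent dot products
    A = (B_ss[:, None, :, None] * tt).reshape(2 * len(semi_rows), 2 * len(semi_rows))
    A = A + ridge * np.trace(A) / len(A) * np.eye(len(A))
    return A, g.reshape(-1)


def slide_semilandmarks(
    template: TemplateDefinition | np.ndarray,
    initial: LandmarkConfiguration,
    mesh: TriangleMesh,
    opts: SlidingOptions | None = None,
    bending: BendingEnergyMatrix | None = None,
) -> SlidingResult:
    """Slide semi-landmarks tangentially to minimize template bending energy.

    Each iteration solves the tangent-restricted least-squares step of the
    bending-energy quadratic form (built from all 210 template points),
    displaces the semi-landmarks, re-projects them onto the mesh, and keeps
    the move only if the energy decreased (otherwise the step is halved, up
    to ``max_halvings`` times).  The energy trace is therefore
    non-increasing.  Fixed landmarks are never displaced.
    """
    opts = opts or SlidingOptions()
    if bending is None:
        reference = (
            template.all_points()
            if isinstance(template, TemplateDefinition)
            else np.asarray(template, float)
        )
        bending = bending_energy_matrix(reference)
    B = bending.matrix
    k = len(B)
    coords = initial.coordinates.copy()
    if coords.shape[0] != k:
        raise ValueError("initial configuration size must match the template")
    semi_rows = np.flatnonzero(initial.patch_ids != 0)
    vnormals = _vertex_normals(mesh)

    energy = bending_energy(bending, coords)
    trace = [energy]
    converged = False
    iterations = 0
    for _ in range(opts.max_iter):
        iterations += 1
        projected, tri_idx, _ = closest_points(coords[semi_rows], mesh)
        normals = _surface_normals(projected, tri_idx, mesh, vnormals)
        tangents = _orthonormal_tangents(normals)
        A, g = _step_system(B[np.ix_(semi_rows, semi_rows)], B, coords, semi_rows, tangents, opts.ridge)
        step, *_ = np.linalg.lstsq(A, -g, rcond=None)
        disp = np.einsum("sa,sac->sc", step.reshape(-1, 2), tangents)

        accepted = False
        scale = 1.0
        for _ in range(opts.max_halvings + 1):
            trial = coords.copy()
            trial[semi_rows] += scale * disp
            trial[semi_rows], _, _ = closest_points(trial[semi_rows], mesh)
            e_new = bending_energy(bending, trial)
            if not np.isfinite(e_new):
                raise FloatingPointError(
                    f"non-finite bending energy at iteration {iterations} "
                    f"(scale {scale}, energy trace {trace})"
                )
            if e_new < energy:
                coords, energy, accepted = trial, e_new, True
                break
            scale *= 0.5
        if not accepted:
            converged = True
            break
        trace.append(energy)
        prev = trace[-2]
        if prev == 0 or (prev - energy) / max(prev, 1e-300) < opts.tol:
            converged = True
            break

    out = LandmarkConfiguration(initial.specimen_id, coords, initial.patch_ids.copy())
    return SlidingResult(out, np.asarray(trace), iterations, converged)
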