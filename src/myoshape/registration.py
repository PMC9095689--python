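"""Dense correspondence and rigid alignment of surface meshes.

Correspondence across specimens is established by non-rigidly warping one
reference mesh onto every target with a radial-basis-function (RBF)
interpolant: displacements are estimated at a deterministic farthest-point
sample of control vertices by closest-point search on the target surface,
and interpolated to all reference vertices by a thin-plate-spline (or
Gaussian) RBF with an affine term. An outer ICP-style loop re-estimates the
correspondences from the current warp; the inner solves use an annealed
smoothing schedule (coarse-to-fine), while the final solve uses the
caller's regularization, so with ``regularization=0`` the returned warp
interpolates the control displacements exactly.

Fitted meshes all share the reference topology and are brought to a
canonical pose by rigid alignment: centre of mass at the origin, principal
inertia axes (uniform vertex weights) mapped to (z, x, y) in descending
variance order, axis signs fixed by coordinate skewness, and handedness by
a cross product.

Iterating "fit everyone, average, use the mean as the next reference"
(``iterative_refit``) removes the bias of an arbitrary initial reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, DimensionError, ParameterError
from .mesh import ShapeVector, SurfaceMesh, mesh_to_shape_vector

__all__ = [
    "RegistrationSettings",
    "RegistrationResult",
    "AlignmentTransform",
    "SurfaceDistance",
    "farthest_point_sample",
    "rbf_fit",
    "rigid_align",
    "correspond_cohort",
    "iterative_refit",
]


@dataclass
class RegistrationSettings:
    """Knobs of the non-rigid fitting stage.

    ``n_control`` farthest-point control vertices (deterministic, uniform
    coverage); thin-plate kernel by default (the minimal-bending choice);
    ``regularization`` is the smoothing weight of the final RBF solve
    (0 = exact interpolation at control points); ``icp_iters`` outer
    correspondence updates; ``tol_mm``/``max_iter`` drive the iterative
    mean-reference refit.
    """

    kernel: str = "thin_plate"
    n_control: int = 200
    regularization: float = 0.0
    icp_iters: int = 10
    tol_mm: float = 0.01
    max_iter: int = 5
    epsilon: float | None = None  # Gaussian kernel shape parameter, 1/mm
    inertia_weighting: str = "vertex"


@dataclass
class RegistrationResult:
    fitted: ShapeVector
    rms_mm: float
    n_control: int
    kernel: str
    regularization: float
    converged: bool = True
    warning: str | None = None


@dataclass
class AlignmentTransform:
    """Proper rigid motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# Point-to-surface distance
# ---------------------------------------------------------------------------


class SurfaceDistance:
    """Closest-point queries against a triangulated surface.

    Candidate triangles are pre-filtered with a k-d tree over triangle
    centroids (all triangles are candidates for small meshes, making the
    query exact there); the exact closest point on each candidate triangle
    is then computed in a vectorized pass.
    """

    def __init__(self, mesh: SurfaceMesh, n_candidates: int = 32):
        self.triangles = mesh.vertices[mesh.faces]  # (f, 3, 3)
        self.k = min(n_candidates, len(self.triangles))
        self._tree = cKDTree(self.triangles.mean(axis=1))

    def query(self, points: np.ndarray, return_faces: bool = False):
        """Return (closest points on surface, distances) for (q, 3) points.

        With ``return_faces`` also return the triangle index of each closest
        point and its barycentric coordinates on that triangle.
        """
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        _, idx = self._tree.query(points, k=self.k)
        idx = np.atleast_2d(idx)
        cand = self.triangles[idx]  # (q, k, 3, 3)
        closest = _closest_point_on_triangles(points[:, None, :], cand)
        d2 = ((closest - points[:, None, :]) ** 2).sum(axis=-1)
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(points))
        cp, dist = closest[rows, best], np.sqrt(d2[rows, best])
        if not return_faces:
            return cp, dist
        faces = idx[rows, best]
        bary = _barycentric(cp, self.triangles[faces])
        return cp, dist, faces, bary


def _closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact closest point on each triangle (Ericson's method, vectorized).

    ``p`` broadcasts against ``tri[..., 3, 3]``; returns points with the
    shape of ``tri[..., 0, :]``.
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    denom_v = vc + np.where(vc == 0, 1e-300, 0.0)  # placeholders, masked below
    with np.errstate(divide="ignore", invalid="ignore"):
        v_edge_ab = d1 / (d1 - d3)
        w_edge_ac = d2 / (d2 - d6)
        w_edge_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        denom = va + vb + vc
        v_face = vb / denom
        w_face = vc / denom

    out = a + v_face[..., None] * ab + w_face[..., None] * ac  # interior default
    # Region tests, applied from lowest to highest priority so vertex regions win.
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out = np.where(
        on_bc[..., None], b + np.clip(w_edge_bc, 0, 1)[..., None] * (c - b), out
    )
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(
        on_ac[..., None], a + np.clip(w_edge_ac, 0, 1)[..., None] * ac, out
    )
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(
        on_ab[..., None], a + np.clip(v_edge_ab, 0, 1)[..., None] * ab, out
    )
    out = np.where(((d6 >= 0) & (d5 <= d6))[..., None], c, out)
    out = np.where(((d3 >= 0) & (d4 <= d3))[..., None], b, out)
    out = np.where(((d1 <= 0) & (d2 <= 0))[..., None], a, out)
    del denom_v
    return out


def _barycentric(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of points known to lie on their triangles."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    v0, v1, v2 = b - a, c - a, points - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) < 1e-300, 1e-300, denom)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    return np.clip(np.column_stack([1.0 - v - w, v, w]), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Control points and RBF fitting
# ---------------------------------------------------------------------------


def farthest_point_sample(points: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-point subsample; seeded at the point farthest
    from the centroid, ties broken by lowest index."""
    points = np.asarray(points)
    if k > len(points):
        raise ParameterError(f"cannot sample {k} control points from {len(points)}")
    sel = np.empty(k, dtype=np.int64)
    d = np.linalg.norm(points - points.mean(axis=0), axis=1)
    sel[0] = int(np.argmax(d))
    dist = np.linalg.norm(points - points[sel[0]], axis=1)
    for i in range(1, k):
        sel[i] = int(np.argmax(dist))
        dist = np.minimum(dist, np.linalg.norm(points - points[sel[i]], axis=1))
    return sel


_KERNELS = {"thin_plate": "thin_plate_spline", "gaussian": "gaussian"}


def _rbf_warp(control, targets, kernel, smoothing, epsilon):
    kwargs = dict(kernel=_KERNELS[kernel], smoothing=smoothing, degree=1)
    if kernel == "gaussian":
        kwargs["epsilon"] = epsilon
    return RBFInterpolator(control, targets, **kwargs)


def rbf_fit(
    reference: SurfaceMesh,
    target: SurfaceMesh,
    n_control: int = 200,
    kernel: str = "thin_plate",
    regularization: float = 0.0,
    icp_iters: int = 10,
    epsilon: float | None = None,
) -> RegistrationResult:
    """Non-rigidly fit the reference mesh onto the target surface.

    Returns the warped reference (on the reference topology) and the RMS of
    point-to-surface distances from all warped vertices to the target.
    Non-convergence of the outer loop is recorded as a warning on the
    result, never raised.
    """
    if kernel not in _KERNELS:
        raise ParameterError(f"unknown kernel {kernel!r}; choose from {list(_KERNELS)}")
    if n_control < 4:
        raise ParameterError("n_control must be >= 4 (affine term underdetermined)")
    if n_control > reference.n_vertices:
        raise ParameterError("n_control exceeds reference vertex count")
    if regularization < 0:
        raise ParameterError("regularization must be non-negative")
    if epsilon is None:
        # shape parameter for the Gaussian kernel: ~1/(tenth of the bbox diagonal)
        diag = np.linalg.norm(np.ptp(reference.vertices, axis=0))
        epsilon = 10.0 / max(diag, 1e-9)

    ctrl_idx = farthest_point_sample(reference.vertices, n_control)
    ctrl = reference.vertices[ctrl_idx]
    surface = SurfaceDistance(target)

    # Stage 1: symmetric affine ICP. Closest-point correspondences slide
    # tangentially on elongated shapes, which makes one-directional affine
    # ICP collapse to an under-scaled fixed point. Pairing reference control
    # points with the target surface AND target samples with (barycentric
    # preimages on) the warped reference surface makes the true affine map
    # the only fixed point, so bulk size/pose/aspect changes are recovered
    # essentially exactly before any RBF bending is spent on them.
    ctrl_h = np.column_stack([ctrl, np.ones(len(ctrl))])
    tgt_sample = target.vertices[
        farthest_point_sample(target.vertices, min(n_control, target.n_vertices))
    ]
    # Initialize from the canonical poses of both meshes so a large rigid
    # offset between reference and target (e.g. a mean shape in the aligned
    # frame vs raw specimens) never has to be discovered by closest points.
    try:
        _, t_ref = rigid_align(reference)
        _, t_tgt = rigid_align(target)
        rot = t_tgt.rotation.T @ t_ref.rotation
        shift = t_tgt.rotation.T @ (t_ref.translation - t_tgt.translation)
        M = np.vstack([rot.T, shift])
    except DegenerateGeometryError:
        M = np.vstack([np.eye(3), np.zeros(3)])
    omega = 1.5  # over-relaxation; plain iteration converges geometrically but slowly
    for _ in range(max(30, icp_iters)):
        corr_fwd, _ = surface.query(ctrl_h @ M)
        warped_ref = SurfaceMesh(
            reference.vertices @ M[:3] + M[3], reference.faces, reference.frame_note
        )
        _, _, f_idx, bary = SurfaceDistance(warped_ref).query(
            tgt_sample, return_faces=True
        )
        preimage = np.einsum(
            "ij,ijk->ik", bary, reference.vertices[reference.faces[f_idx]]
        )
        rows = np.vstack(
            [ctrl_h, np.column_stack([preimage, np.ones(len(preimage))])]
        )
        M_ls, *_ = np.linalg.lstsq(
            rows, np.vstack([corr_fwd, tgt_sample]), rcond=None
        )
        step = M_ls - M
        M = M + omega * step
        if np.abs(step).max() < 1e-10:
            break
    warped_ctrl = ctrl_h @ M

    # Stage 2: annealed RBF ICP. With exact interpolation the closest-point
    # correspondences are a fixed point after one pass, so the early
    # iterations use a stiffer (smoother) warp that is progressively
    # released. The *final* solve honours the caller's regularization.
    scale = float(np.abs(reference.vertices).max()) ** 2
    schedule = [
        max(regularization, scale * 10.0 ** (-i)) for i in range(max(icp_iters - 1, 0))
    ] + [regularization]

    rms_prev = np.inf
    rms_ctrl = np.inf
    for smoothing in schedule:
        corr, _ = surface.query(warped_ctrl)
        interp = _rbf_warp(ctrl, corr, kernel, smoothing, epsilon)
        warped_ctrl = interp(ctrl)
        rms_prev = rms_ctrl
        rms_ctrl = float(np.sqrt(((warped_ctrl - corr) ** 2).sum(axis=1).mean()))
    # Final solve at the requested regularization with the latest correspondences.
    corr, _ = surface.query(warped_ctrl)
    interp = _rbf_warp(ctrl, corr, kernel, regularization, epsilon)
    fitted_vertices = interp(reference.vertices)
    converged = abs(rms_prev - rms_ctrl) < 1e-6

    _, dist = surface.query(fitted_vertices)
    rms = float(np.sqrt((dist**2).mean()))
    warning = None
    if not converged:
        warning = (
            f"ICP correspondence loop did not reach a fixed point in "
            f"{icp_iters} iterations (last control RMS change at {rms_ctrl:.3g} mm)"
        )
    return RegistrationResult(
        fitted=ShapeVector(fitted_vertices.reshape(-1), reference.n_vertices),
        rms_mm=rms,
        n_control=n_control,
        kernel=kernel,
        regularization=regularization,
        converged=converged,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# Rigid alignment
# ---------------------------------------------------------------------------


def rigid_align(mesh_or_vector):
    """Align to the canonical inertial pose.

    The centre of mass (uniform vertex weights) is moved to the origin and
    the principal axes of the vertex covariance are mapped to (z, x, y) in
    descending-eigenvalue order. The signs of the first two axes are chosen
    so vertex-coordinate skewness along each is non-negative; the third axis
    is their cross product, which fixes handedness. Returns the aligned
    object (same type as the input) and the transform that reproduces it.
    """
    if isinstance(mesh_or_vector, SurfaceMesh):
        points = mesh_or_vector.vertices
    elif isinstance(mesh_or_vector, ShapeVector):
        points = mesh_or_vector.points()
    else:
        raise ParameterError("rigid_align expects a SurfaceMesh or ShapeVector")
    com = points.mean(axis=0)
    centered = points - com
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    top = max(evals[0], 1e-300)
    rel_gap = (evals[:-1] - evals[1:]) / top
    if evals[2] / top < 1e-12 or np.any(rel_gap < 1e-9):
        raise DegenerateGeometryError(
            "inertia axes are not well-defined (degenerate or collinear geometry)"
        )
    u1, u2 = evecs[:, 0], evecs[:, 1]
    if ((centered @ u1) ** 3).mean() < 0:
        u1 = -u1
    if ((centered @ u2) ** 3).mean() < 0:
        u2 = -u2
    u3 = np.cross(u1, u2)
    rotation = np.vstack([u2, u3, u1])  # rows: new x, y, z in old coordinates
    translation = -rotation @ com
    aligned_pts = centered @ rotation.T
    transform = AlignmentTransform(rotation, translation)
    if isinstance(mesh_or_vector, SurfaceMesh):
        aligned = SurfaceMesh(
            aligned_pts, mesh_or_vector.faces.copy(), mesh_or_vector.frame_note
        )
    else:
        aligned = ShapeVector(aligned_pts.reshape(-1), mesh_or_vector.n_vertices)
    return aligned, transform


# ---------------------------------------------------------------------------
# Cohort-level drivers
# ---------------------------------------------------------------------------


def correspond_cohort(
    reference: SurfaceMesh,
    targets: list,
    settings: RegistrationSettings | None = None,
):
    """Fit the reference to every target and align the fits.

    Returns (list of ShapeVector on the reference topology, per-target
    fitting RMS in mm). Errors from individual fits are re-raised tagged
    with the target index.
    """
    settings = settings or RegistrationSettings()
    if len(targets) == 0:
        raise ParameterError("correspond_cohort needs at least one target")
    vectors, rms_list = [], []
    for i, tgt in enumerate(targets):
        try:
            res = rbf_fit(
                reference,
                tgt,
                n_control=settings.n_control,
                kernel=settings.kernel,
                regularization=settings.regularization,
                icp_iters=settings.icp_iters,
                epsilon=settings.epsilon,
            )
        except Exception as exc:
            raise type(exc)(f"target {i}: {exc}") from exc
        if res.warning:
            warnings.warn(f"target {i}: {res.warning}", stacklevel=2)
        aligned, _ = rigid_align(res.fitted)
        vectors.append(aligned)
        rms_list.append(res.rms_mm)
    return vectors, rms_list


def iterative_refit(
    reference: SurfaceMesh,
    targets: list,
    settings: RegistrationSettings | None = None,
    tol_mm: float | None = None,
    max_iter: int | None = None,
):
    """Refit the cohort against its own evolving mean shape.

    Each round fits all targets, averages the corresponded vectors, and uses
    the mean (on the reference topology) as the next reference, until the
    mean fitting RMS improves by less than ``tol_mm`` or ``max_iter`` rounds
    are done. Returns (vectors, per-round mean RMS history, stop reason,
    per-target RMS of the final round).
    """
    settings = settings or RegistrationSettings()
    tol_mm = settings.tol_mm if tol_mm is None else tol_mm
    max_iter = settings.max_iter if max_iter is None else max_iter
    if max_iter < 1:
        raise ParameterError("max_iter must be >= 1")
    ref = reference
    history: list[float] = []
    vectors = None
    rms_list: list[float] = []
    stop = "max_iter reached"
    for _ in range(max_iter):
        vectors, rms_list = correspond_cohort(ref, targets, settings)
        history.append(float(np.mean(rms_list)))
        if len(history) >= 2 and history[-2] - history[-1] < tol_mm:
            stop = f"mean RMS improvement below {tol_mm} mm"
            break
        if history[-1] < tol_mm:
            stop = f"mean RMS below {tol_mm} mm"
            break
        mean_pts = np.mean([v.points() for v in vectors], axis=0)
        ref = SurfaceMesh(mean_pts, reference.faces.copy(), reference.frame_note)
    return vectors, history, stop, rms_list
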