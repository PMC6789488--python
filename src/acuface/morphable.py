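"""PCA morphable model of 3D face shape: construction, fitting, projection.

A face mesh with n vertices is flattened to a vector
``S = [x1, y1, z1, ..., xn, yn, zn]``; the model expresses new faces as a
linear combination around the mean, ``S = v_bar + sum_i alpha_i v_i`` with
an orthonormal basis ``v_i`` obtained by PCA over a training set in dense
correspondence.  Fitting to 2D landmarks alternates perspective-n-point
pose estimation with a regularized linear solve for the shape
coefficients, minimizing landmark reprojection error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from acuface.geometry import Camera, Pose, project_points

__all__ = [
    "Mesh3D",
    "MorphableModel",
    "FittedFace",
    "AcupunctureModel3D",
    "build_model",
    "reconstruct",
    "estimate_pose",
    "fit_landmarks",
    "project_model_points",
]


@dataclass
class Mesh3D:
    """Triangle mesh: ``vertices`` (n, 3) in mm, ``faces`` (m, 3) int indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index exceeds vertex count")

    @property
    def flat(self) -> np.ndarray:
        return self.vertices.reshape(-1)


@dataclass
class MorphableModel:
    """Linear shape model around a mean mesh.

    Attributes
    ----------
    mean : ndarray, shape (3n,)
        Flattened mean mesh vector.
    basis : ndarray, shape (m, 3n)
        Orthonormal principal directions (rows).
    mode_scales : ndarray, shape (m,)
        Per-mode standard deviations (singular values / sqrt(n_samples - 1)).
    faces : ndarray, shape (k, 3)
        Shared triangulation of every mesh drawn from the model.
    """

    mean: np.ndarray
    basis: np.ndarray
    mode_scales: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(-1)
        self.basis = np.atleast_2d(np.asarray(self.basis, dtype=float))
        self.mode_scales = np.asarray(self.mode_scales, dtype=float).reshape(-1)
        if self.mean.size % 3:
            raise ValueError("mean length must be divisible by 3")
        if self.basis.shape[1] != self.mean.size:
            raise ValueError("basis/mean dimension mismatch")

    @property
    def m(self) -> int:
        return self.basis.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.mean.size // 3

    @property
    def mean_mesh(self) -> Mesh3D:
        return Mesh3D(self.mean.reshape(-1, 3), self.faces)


@dataclass
class FittedFace:
    """Result of fitting the model to 2D landmarks."""

    alpha: np.ndarray
    mesh: Mesh3D
    pose: Pose
    rmse_px: float = 0.0
    converged: bool = True
    rmse_history: list[float] = field(default_factory=list)


@dataclass
class AcupunctureModel3D:
    """Acupoint metadata annotated on the mean mesh.

    ``landmark_indices`` are the vertex indices of the facial landmarks,
    ``acupoints_3d`` the acupoint coordinates in model space (mm), and
    ``neighbor_indices`` the three nearest mesh vertices per acupoint, used
    as local control points when transferring acupoints to a fitted mesh.
    """

    landmark_indices: np.ndarray
    acupoints_3d: np.ndarray
    neighbor_indices: np.ndarray

    def __post_init__(self) -> None:
        self.landmark_indices = np.asarray(self.landmark_indices, dtype=int)
        self.acupoints_3d = np.asarray(self.acupoints_3d, dtype=float).reshape(-1, 3)
        self.neighbor_indices = np.asarray(self.neighbor_indices, dtype=int)
        if self.neighbor_indices.shape != (len(self.acupoints_3d), 3):
            raise ValueError("each acupoint needs exactly 3 neighbor indices")


def build_model(meshes: list[Mesh3D], m: int) -> MorphableModel:
    """PCA over a set of meshes in dense correspondence.

    The mean is the arithmetic mean of the flattened meshes; the basis holds
    the top-``m`` principal directions of the centered data, and
    ``mode_scales`` the corresponding standard deviations.
    """
    if len(meshes) < 2:
        raise ValueError("need at least 2 meshes")
    counts = {len(mesh.vertices) for mesh in meshes}
    if len(counts) != 1:
        raise ValueError("meshes must share a vertex count (dense correspondence)")
    if m > len(meshes) - 1:
        raise ValueError(f"m={m} exceeds n_meshes-1={len(meshes) - 1}")
    data = np.stack([mesh.flat for mesh in meshes])
    mean = data.mean(axis=0)
    centered = data - mean
    # SVD of the (n_samples, 3n) matrix; right singular vectors are the modes.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    basis = vt[:m]
    # Deterministic sign: largest-magnitude entry of each mode is positive.
    for row in basis:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    scales = s[:m] / np.sqrt(len(meshes) - 1)
    return MorphableModel(mean, basis, scales, meshes[0].faces.copy())


def reconstruct(model: MorphableModel, alpha: np.ndarray) -> Mesh3D:
    """Mesh for coefficients ``alpha``: ``v_bar + sum_i alpha_i v_i``."""
    alpha = np.asarray(alpha, dtype=float).reshape(-1)
    if alpha.size != model.m:
        raise ValueError(f"alpha has {alpha.size} entries, model has m={model.m}")
    flat = model.mean + alpha @ model.basis
    return Mesh3D(flat.reshape(-1, 3), model.faces)


def _check_not_collinear(points3d: np.ndarray) -> None:
    centered = points3d - points3d.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate configuration: 3D points are collinear")


def estimate_pose(
    points2d: np.ndarray,
    points3d: np.ndarray,
    camera: Camera,
    refine: bool = True,
) -> Pose:
    """Perspective-n-point pose from 2D-3D correspondences.

    A DLT estimate of the projection (on intrinsics-normalized image
    coordinates) is projected onto the rotation manifold and then refined by
    Levenberg-Marquardt on the reprojection error.  The returned pose
    carries the RMS reprojection residual in ``residual_px``.
    """
    pts2 = np.asarray(points2d, dtype=float).reshape(-1, 2)
    pts3 = np.asarray(points3d, dtype=float).reshape(-1, 3)
    if len(pts2) != len(pts3):
        raise ValueError("point count mismatch")
    if len(pts2) < 4:
        raise ValueError("need at least 4 correspondences")
    _check_not_collinear(pts3)

    # Normalized image coordinates: x = (u - cx)/f.
    cx, cy = camera.principal_point
    xn = (pts2 - [cx, cy]) / camera.focal

    # DLT for P = [R | t] (3x4), 2 equations per point.
    n = len(pts3)
    A = np.zeros((2 * n, 12))
    X = np.column_stack([pts3, np.ones(n)])
    A[0::2, 0:4] = X
    A[0::2, 8:12] = -xn[:, 0:1] * X
    A[1::2, 4:8] = X
    A[1::2, 8:12] = -xn[:, 1:2] * X
    _, _, vt = np.linalg.svd(A)
    P = vt[-1].reshape(3, 4)
    # Fix scale/sign so that points have positive depth.
    scale = np.linalg.norm(P[2, :3])
    if scale < 1e-12:
        raise ValueError("degenerate DLT solution")
    P /= scale
    if np.median(pts3 @ P[2, :3] + P[2, 3]) < 0:
        P = -P
    # Nearest rotation to the 3x3 part.
    U, _, Vt = np.linalg.svd(P[:, :3])
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    t = P[:, 3]

    if refine:
        rvec0 = Rotation.from_matrix(R).as_rotvec()

        def resid(params: np.ndarray) -> np.ndarray:
            Rl = Rotation.from_rotvec(params[:3]).as_matrix()
            cam_pts = pts3 @ Rl.T + params[3:]
            z = np.maximum(cam_pts[:, 2], 1e-6)
            proj = camera.focal * cam_pts[:, :2] / z[:, None] + [cx, cy]
            return (proj - pts2).ravel()

        sol = least_squares(resid, np.concatenate([rvec0, t]), method="lm")
        R = Rotation.from_rotvec(sol.x[:3]).as_matrix()
        t = sol.x[3:]

    pose = Pose(R, t, camera)
    rmse = float(np.sqrt(np.mean(np.sum((pose.project(pts3) - pts2) ** 2, axis=1))))
    return Pose(R, t, camera, residual_px=rmse)


def _solve_alpha(
    model: MorphableModel,
    landmarks2d: np.ndarray,
    lindex: np.ndarray,
    pose: Pose,
    alpha0: np.ndarray,
    lam: float,
) -> np.ndarray:
    """Linearized ridge solve for alpha at fixed pose.

    The perspective division is linearized by freezing each landmark's depth
    at its current estimate, making the projection affine in alpha; the
    ridge penalty is ``lam * sum((alpha_i / scale_i)^2)`` (a Mahalanobis
    prior under the model's mode variances).
    """
    n_lm = len(lindex)
    mean_lm = model.mean.reshape(-1, 3)[lindex]
    # (m, n_lm, 3) basis restricted to the landmark vertices
    basis_lm = model.basis.reshape(model.m, -1, 3)[:, lindex, :]

    cur = mean_lm + np.tensordot(alpha0, basis_lm, axes=1)
    cam = pose.transform(cur)
    z = np.maximum(cam[:, 2], 1e-6)

    R = pose.rotation
    f = pose.camera.focal
    cx, cy = pose.camera.principal_point
    # d(u,v)/d(model point), with depth frozen: rows of R scaled by f/z
    # u = f * (R0.P + tx)/z + cx  ->  du/dP = f * R0 / z
    J_rows = []
    b_rows = []
    for k in range(n_lm):
        Jp = (f / z[k]) * R[:2, :]  # (2, 3)
        # Stack over modes: projection shift per unit alpha_i
        Jk = np.einsum("ij,mj->im", Jp, basis_lm[:, k, :])  # (2, m)
        base = np.array(
            [f * cam[k, 0] / z[k] + cx, f * cam[k, 1] / z[k] + cy]
        )
        base -= Jk @ alpha0  # projection of the mean-part at frozen depth
        J_rows.append(Jk)
        b_rows.append(landmarks2d[k] - base)
    J = np.vstack(J_rows)
    b = np.concatenate(b_rows)

    scales = np.maximum(model.mode_scales, 1e-8)
    reg = np.sqrt(lam) / scales
    A_aug = np.vstack([J, np.diag(reg)])
    b_aug = np.concatenate([b, np.zeros(model.m)])
    alpha, *_ = np.linalg.lstsq(A_aug, b_aug, rcond=None)
    return alpha


def fit_landmarks(
    model: MorphableModel,
    landmarks2d: np.ndarray,
    lindex: np.ndarray,
    camera: Camera,
    lam: float = 1e-3,
    max_iters: int = 20,
    tol: float = 1e-6,
    joint_refine: bool = True,
) -> FittedFace:
    """Fit shape coefficients and pose to 2D landmarks.

    Alternates pose estimation (PnP on the current mesh's landmark
    vertices) with the linearized ridge solve for alpha until the landmark
    reprojection RMSE improves by less than ``tol`` px or ``max_iters``
    outer iterations, then (by default) polishes pose and shape jointly
    with Levenberg-Marquardt on the same objective.  A step that would
    increase the RMSE is rejected, so the reported history is
    non-increasing.
    """
    landmarks2d = np.asarray(landmarks2d, dtype=float).reshape(-1, 2)
    lindex = np.asarray(lindex, dtype=int)
    if len(landmarks2d) != len(lindex):
        raise ValueError("landmarks2d and lindex length mismatch")
    if len(lindex) < 4:
        raise ValueError("need at least 4 landmarks")

    alpha = np.zeros(model.m)
    mesh = reconstruct(model, alpha)
    pose = estimate_pose(landmarks2d, mesh.vertices[lindex], camera)
    best_rmse = float(
        np.sqrt(
            np.mean(
                np.sum((pose.project(mesh.vertices[lindex]) - landmarks2d) ** 2, axis=1)
            )
        )
    )
    history = [best_rmse]
    converged = False
    for _ in range(max_iters):
        alpha_new = _solve_alpha(model, landmarks2d, lindex, pose, alpha, lam)
        mesh_new = reconstruct(model, alpha_new)
        pose_new = estimate_pose(landmarks2d, mesh_new.vertices[lindex], camera)
        rmse = float(
            np.sqrt(
                np.mean(
                    np.sum(
                        (pose_new.project(mesh_new.vertices[lindex]) - landmarks2d) ** 2,
                        axis=1,
                    )
                )
            )
        )
        if rmse > best_rmse:  # reject uphill step, keep best iterate
            break
        improvement = best_rmse - rmse
        alpha, mesh, pose, best_rmse = alpha_new, mesh_new, pose_new, rmse
        history.append(best_rmse)
        if improvement < tol:
            converged = True
            break

    if joint_refine:
        mean_lm = model.mean.reshape(-1, 3)[lindex]
        basis_lm = model.basis.reshape(model.m, -1, 3)[:, lindex, :]
        scales = np.maximum(model.mode_scales, 1e-8)
        reg = np.sqrt(lam) / scales
        cx, cy = camera.principal_point

        def resid(params: np.ndarray) -> np.ndarray:
            Rl = Rotation.from_rotvec(params[:3]).as_matrix()
            tl = params[3:6]
            al = params[6:]
            pts = mean_lm + np.tensordot(al, basis_lm, axes=1)
            cam_pts = pts @ Rl.T + tl
            z = np.maximum(cam_pts[:, 2], 1e-6)
            proj = camera.focal * cam_pts[:, :2] / z[:, None] + [cx, cy]
            return np.concatenate([(proj - landmarks2d).ravel(), reg * al])

        x0 = np.concatenate(
            [Rotation.from_matrix(pose.rotation).as_rotvec(), pose.translation, alpha]
        )
        sol = least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12)
        alpha_j = sol.x[6:]
        mesh_j = reconstruct(model, alpha_j)
        pose_j = Pose(
            Rotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:6], camera
        )
        rmse_j = float(
            np.sqrt(
                np.mean(
                    np.sum(
                        (pose_j.project(mesh_j.vertices[lindex]) - landmarks2d) ** 2,
                        axis=1,
                    )
                )
            )
        )
        if rmse_j <= best_rmse:
            alpha, mesh, pose, best_rmse = alpha_j, mesh_j, pose_j, rmse_j
            history.append(best_rmse)
            converged = True

    if not converged:
        warnings.warn("fit_landmarks: no convergence within max_iters", stacklevel=2)
    return FittedFace(alpha, mesh, pose, best_rmse, converged, history)


def project_model_points(
    fitted: FittedFace, indices_or_points: np.ndarray
) -> np.ndarray:
    """Project mesh vertices (by index) or arbitrary 3D points with the fitted pose."""
    arr = np.asarray(indices_or_points)
    if arr.ndim <= 1 and np.issubdtype(arr.dtype, np.integer):
        pts3 = fitted.mesh.vertices[arr]
    else:
        pts3 = arr.reshape(-1, 3).astype(float)
    return project_points(fitted.pose.transform(pts3), fitted.pose.camera)
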