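"""Shared camera and pose primitives.

Image coordinate convention used throughout the package: origin at the
top-left pixel, x to the right, y down, 0-based, with pixel centers at
integer coordinates.  Model and arm coordinates are in millimetres, image
coordinates in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Camera", "Pose", "project_points"]


@dataclass(frozen=True)
class Camera:
    """Pinhole camera intrinsics.

    Parameters
    ----------
    focal : float
        Focal length in pixels (square pixels assumed).
    principal_point : (float, float)
        Principal point ``(cx, cy)`` in pixels.
    """

    focal: float
    principal_point: tuple[float, float]

    @property
    def matrix(self) -> np.ndarray:
        cx, cy = self.principal_point
        return np.array(
            [[self.focal, 0.0, cx], [0.0, self.focal, cy], [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class Pose:
    """Rigid model-to-camera transform plus the intrinsics it projects with.

    ``rotation`` must be orthonormal with determinant +1 (checked to 1e-8);
    ``translation`` is in mm.  A point ``P`` in model space maps to camera
    space as ``R @ P + t`` and then through the pinhole projection.
    """

    rotation: np.ndarray
    translation: np.ndarray
    camera: Camera
    residual_px: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def transform(self, points3d: np.ndarray) -> np.ndarray:
        """Map model-space points (N, 3) into camera space."""
        pts = np.atleast_2d(np.asarray(points3d, dtype=float))
        return pts @ self.rotation.T + self.translation

    def project(self, points3d: np.ndarray) -> np.ndarray:
        """Pinhole-project model-space points (N, 3) to pixels (N, 2)."""
        return project_points(self.transform(points3d), self.camera)


def project_points(points_cam: np.ndarray, camera: Camera) -> np.ndarray:
    """Project camera-space points to the image plane.

    Raises
    ------
    ValueError
        If any point lies at or behind the camera plane (z <= 0).
    """
    pts = np.atleast_2d(np.asarray(points_cam, dtype=float))
    z = pts[:, 2]
    if np.any(z <= 0):
        raise ValueError("point behind camera (z <= 0) cannot be projected")
    cx, cy = camera.principal_point
    u = camera.focal * pts[:, 0] / z + cx
    v = camera.focal * pts[:, 1] / z + cy
    return np.column_stack([u, v])
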