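"""Perspective hand-eye calibration between image plane and robot-arm plane.

The mapping from image coordinates (x, y) in px to arm coordinates (X, Y)
in mm is the 8-parameter perspective transform

    X = (a x + b y + c) / (g x + h y + 1)
    Y = (d x + e y + f) / (g x + h y + 1)

estimated by linearizing (multiply through by the denominator) and solving
the stacked 2n-by-8 least-squares system; four point pairs are the minimum
for full column rank.  Because different acupoints sit at different heights
above the calibration plane, a second perspective matrix F between the
image planes at two known heights provides a first-order parallax
correction before the image-to-arm map T is applied:

    p_arm = T( p + s (F(p) - p) ),   s = (k - a) / (b - a)

where a is the calibration plane height, b the second plane height, and k
the height of the point being mapped.  s = 0 recovers T alone; s = 1
recovers T∘F.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PerspectiveTransform",
    "CorrespondenceSet",
    "CalibrationResult",
    "apply_transform",
    "build_design_system",
    "solve_least_squares",
    "estimate_transform",
    "estimate_height_matrix",
    "map_to_arm",
    "RankDeficiencyError",
]

_RANK_TOL = 1e-10  # smallest/largest singular value ratio for deficiency


class RankDeficiencyError(ValueError):
    """Raised when the calibration design matrix is rank deficient."""


@dataclass
class PerspectiveTransform:
    """8-parameter plane-to-plane perspective transform."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    g: float
    h: float

    @classmethod
    def identity(cls) -> "PerspectiveTransform":
        return cls(1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_params(cls, params: np.ndarray) -> "PerspectiveTransform":
        return cls(*(float(v) for v in np.asarray(params).reshape(8)))

    @classmethod
    def from_matrix(cls, H: np.ndarray) -> "PerspectiveTransform":
        H = np.asarray(H, dtype=float)
        if abs(H[2, 2]) < 1e-15:
            raise ValueError("homography with zero normalizer")
        H = H / H[2, 2]
        return cls(
            H[0, 0], H[0, 1], H[0, 2], H[1, 0], H[1, 1], H[1, 2], H[2, 0], H[2, 1]
        )

    @property
    def params(self) -> np.ndarray:
        return np.array(
            [self.a, self.b, self.c, self.d, self.e, self.f, self.g, self.h]
        )

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.a, self.b, self.c],
                [self.d, self.e, self.f],
                [self.g, self.h, 1.0],
            ]
        )

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_transform(self, points)

    def inverse(self) -> "PerspectiveTransform":
        M = self.matrix
        if abs(np.linalg.det(M)) < 1e-15:
            raise ValueError("transform is not invertible")
        return PerspectiveTransform.from_matrix(np.linalg.inv(M))

    def compose(self, other: "PerspectiveTransform") -> "PerspectiveTransform":
        """self ∘ other: apply ``other`` first."""
        return PerspectiveTransform.from_matrix(self.matrix @ other.matrix)

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in zip("abcdefgh", self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "PerspectiveTransform":
        return cls(*(float(d[k]) for k in "abcdefgh"))


@dataclass
class CorrespondenceSet:
    """Matched source/destination 2D points, optionally at a known height."""

    src: np.ndarray
    dst: np.ndarray
    height: float | None = None

    def __post_init__(self) -> None:
        self.src = np.asarray(self.src, dtype=float).reshape(-1, 2)
        self.dst = np.asarray(self.dst, dtype=float).reshape(-1, 2)
        if len(self.src) != len(self.dst):
            raise ValueError("src/dst length mismatch")
        if len(self.src):
            d = np.linalg.norm(self.src[:, None] - self.src[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < 1e-12:
                raise ValueError("duplicate source points")

    def __len__(self) -> int:
        return len(self.src)


@dataclass
class CalibrationResult:
    """Full hand-eye calibration: image->arm T, height matrix F, plane heights."""

    T: PerspectiveTransform
    F: PerspectiveTransform
    height_a: float
    height_b: float
    rms_residual_T: float = 0.0
    rms_residual_F: float = 0.0

    def __post_init__(self) -> None:
        if self.height_a == self.height_b:
            raise ValueError("plane heights must differ")

    def to_json(self) -> str:
        return json.dumps(
            {
                "T": self.T.to_dict(),
                "F": self.F.to_dict(),
                "height_a": self.height_a,
                "height_b": self.height_b,
                "rms_residual_T": self.rms_residual_T,
                "rms_residual_F": self.rms_residual_F,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationResult":
        d = json.loads(text)
        return cls(
            T=PerspectiveTransform.from_dict(d["T"]),
            F=PerspectiveTransform.from_dict(d["F"]),
            height_a=float(d["height_a"]),
            height_b=float(d["height_b"]),
            rms_residual_T=float(d.get("rms_residual_T", 0.0)),
            rms_residual_F=float(d.get("rms_residual_F", 0.0)),
        )


def apply_transform(t: PerspectiveTransform, points: np.ndarray) -> np.ndarray:
    """Evaluate the perspective transform at one point or an (N, 2) array."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    denom = t.g * pts[:, 0] + t.h * pts[:, 1] + 1.0
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("point maps to the horizon (denominator ~ 0)")
    X = (t.a * pts[:, 0] + t.b * pts[:, 1] + t.c) / denom
    Y = (t.d * pts[:, 0] + t.e * pts[:, 1] + t.f) / denom
    out = np.column_stack([X, Y])
    return out[0] if single else out


def build_design_system(corr: CorrespondenceSet) -> tuple[np.ndarray, np.ndarray]:
    """Stacked linear system for the 8 parameters.

    Rows follow the linearized equations
    ``X = a x + b y + c - g x X - h y X`` (all X-rows first) and
    ``Y = d x + e y + f - g x Y - h y Y`` (Y-rows after), giving a 2n-by-8
    matrix with columns ordered (a, b, c, d, e, f, g, h).
    """
    if len(corr) < 1:
        raise ValueError("need at least one correspondence")
    x, y = corr.src[:, 0], corr.src[:, 1]
    X, Y = corr.dst[:, 0], corr.dst[:, 1]
    n = len(corr)
    A = np.zeros((2 * n, 8))
    A[:n, 0] = x
    A[:n, 1] = y
    A[:n, 2] = 1.0
    A[:n, 6] = -x * X
    A[:n, 7] = -y * X
    A[n:, 3] = x
    A[n:, 4] = y
    A[n:, 5] = 1.0
    A[n:, 6] = -x * Y
    A[n:, 7] = -y * Y
    rhs = np.concatenate([X, Y])
    return A, rhs


def solve_least_squares(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Least-squares solve of ``A x = b`` by orthogonal decomposition.

    Equivalent (on well-conditioned inputs) to the normal-equations formula
    ``x = (A^T A)^{-1} A^T b``; raises :class:`RankDeficiencyError` when the
    design matrix loses column rank.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float).reshape(-1)
    s = np.linalg.svd(A, compute_uv=False)
    rank = int(np.sum(s > _RANK_TOL * s[0])) if s.size else 0
    if rank < A.shape[1]:
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {A.shape[1]} unknowns "
            f"({A.shape[0] // 2} point pairs; at least 4 in general position "
            "are required)"
        )
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    return x


def _norm_similarity(pts: np.ndarray) -> np.ndarray:
    """Similarity moving the centroid to 0 with mean distance sqrt(2)."""
    c = pts.mean(axis=0)
    d = np.mean(np.linalg.norm(pts - c, axis=1))
    s = np.sqrt(2.0) / max(d, 1e-12)
    return np.array([[s, 0.0, -s * c[0]], [0.0, s, -s * c[1]], [0.0, 0.0, 1.0]])


def estimate_transform(
    corr: CorrespondenceSet,
) -> tuple[PerspectiveTransform, float]:
    """Fit the 8-parameter transform to point pairs; returns (T, RMS residual).

    The linear system is assembled and solved on similarity-normalized
    coordinates for conditioning, then denormalized; the result is the
    least-squares solution of the stacked linearized equations.
    """
    if len(corr) < 4:
        raise RankDeficiencyError(
            f"{len(corr)} point pairs given; at least 4 are required"
        )
    Ns = _norm_similarity(corr.src)
    Nd = _norm_similarity(corr.dst)
    src_n = corr.src * Ns[0, 0] + Ns[:2, 2]
    dst_n = corr.dst * Nd[0, 0] + Nd[:2, 2]
    A, b = build_design_system(CorrespondenceSet(src_n, dst_n))
    params = solve_least_squares(A, b)
    H = np.linalg.inv(Nd) @ PerspectiveTransform.from_params(params).matrix @ Ns
    t = PerspectiveTransform.from_matrix(H)
    resid = apply_transform(t, corr.src) - corr.dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return t, rms


def estimate_height_matrix(
    corr_b_to_a: CorrespondenceSet,
) -> tuple[PerspectiveTransform, float]:
    """Fit F mapping image points observed at plane b to their plane-a images."""
    return estimate_transform(corr_b_to_a)


def map_to_arm(
    calib: CalibrationResult,
    p_img: np.ndarray,
    k: float | np.ndarray,
    extrapolation_margin: float = 10.0,
) -> np.ndarray:
    """Map image points to arm coordinates, correcting for point height ``k``.

    The height correction interpolates each image point toward its
    plane-height-corrected position with coefficient
    ``s = (k - height_a)/(height_b - height_a)`` before applying T.  Heights
    outside ``[a, b]`` extended by ``extrapolation_margin`` mm trigger a
    warning (the parallax model is first-order only).
    """
    pts = np.atleast_2d(np.asarray(p_img, dtype=float))
    single = np.asarray(p_img).ndim == 1
    k_arr = np.broadcast_to(np.asarray(k, dtype=float), (len(pts),))
    lo = min(calib.height_a, calib.height_b) - extrapolation_margin
    hi = max(calib.height_a, calib.height_b) + extrapolation_margin
    if np.any((k_arr < lo) | (k_arr > hi)):
        warnings.warn(
            "acupoint height outside the calibrated plane range; "
            "height correction is extrapolating",
            stacklevel=2,
        )
    s = (k_arr - calib.height_a) / (calib.height_b - calib.height_a)
    corrected = pts + s[:, None] * (apply_transform(calib.F, pts) - pts)
    out = apply_transform(calib.T, corrected)
    return out[0] if single else out
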