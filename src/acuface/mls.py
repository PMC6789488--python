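"""Moving-least-squares acupoint transfer.

Acupoints are annotated once on the mean face model; carrying them into an
input image is treated as a 2D point deformation driven by control points.
For each query point v an affine map ``l_v(x) = M x + T`` is fitted by
weighted least squares over the control-point displacements p -> q, with
weights ``w_i = 1 / |p_i - v|^(2 alpha)``; evaluating ``l_v(v)`` gives the
deformed point.  The transfer runs in two stages: first the acupoint is
moved from the mean model to the fitted model using its three projected
neighbor vertices as control points (an exact barycentric transfer), then
from the fitted model into the input image using the projected model
landmarks and the detected image landmarks as control points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ControlPointSet",
    "AcupointEstimate",
    "mls_affine_deform",
    "estimate_ref_fitted",
    "estimate_input_acupoints",
]

_COINCIDENCE_TOL = 1e-9  # px; query this close to a control point returns q_i


@dataclass
class ControlPointSet:
    """Paired source (p) and destination (q) control points."""

    p: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float).reshape(-1, 2)
        self.q = np.asarray(self.q, dtype=float).reshape(-1, 2)
        if len(self.p) != len(self.q):
            raise ValueError("p/q length mismatch")
        if len(self.p) < 3:
            raise ValueError("need at least 3 control points")
        d = np.linalg.norm(self.p[:, None] - self.p[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < _COINCIDENCE_TOL:
            raise ValueError("duplicate control points")


@dataclass
class AcupointEstimate:
    """Estimated acupoints in the input image with their provenance."""

    A_in: np.ndarray
    A_refFitted: np.ndarray
    degenerate_flags: np.ndarray = field(default_factory=lambda: np.empty(0, bool))


def _check_not_collinear(p: np.ndarray) -> None:
    centered = p - p.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("control points are collinear; affine is underdetermined")


def mls_affine_deform(
    p: np.ndarray,
    q: np.ndarray,
    v: np.ndarray,
    alpha_w: float = 1.0,
) -> np.ndarray:
    """Affine moving-least-squares deformation of query points.

    For each query v the weighted affine fit has the closed form
    ``l_v(x) = (x - p*) M + q*`` where p*, q* are the weighted centroids and
    M solves the weighted normal equations over the centered control
    points.  A query within 1e-9 px of a control point returns the
    corresponding q exactly (MLS interpolates its controls).
    """
    cps = ControlPointSet(p, q)
    if alpha_w <= 0:
        raise ValueError("alpha_w must be positive")
    _check_not_collinear(cps.p)
    queries = np.atleast_2d(np.asarray(v, dtype=float))
    single = np.asarray(v).ndim == 1

    out = np.zeros_like(queries)
    for i, vq in enumerate(queries):
        d = np.linalg.norm(cps.p - vq, axis=1)
        hit = np.argmin(d)
        if d[hit] < _COINCIDENCE_TOL:
            out[i] = cps.q[hit]
            continue
        w = 1.0 / d ** (2.0 * alpha_w)
        wsum = w.sum()
        p_star = (w[:, None] * cps.p).sum(axis=0) / wsum
        q_star = (w[:, None] * cps.q).sum(axis=0) / wsum
        ph = cps.p - p_star
        qh = cps.q - q_star
        # M minimizing sum_i w_i |ph_i M - qh_i|^2  (row-vector convention)
        G = (w[:, None] * ph).T @ ph
        B = (w[:, None] * ph).T @ qh
        M = np.linalg.solve(G, B)
        out[i] = (vq - p_star) @ M + q_star
    return out[0] if single else out


def _barycentric_2d(point: np.ndarray, tri: np.ndarray) -> np.ndarray | None:
    """Barycentric coordinates of a 2D point in a triangle; None if degenerate."""
    T = np.column_stack([tri[0] - tri[2], tri[1] - tri[2]])
    det = np.linalg.det(T)
    area2 = abs(det)
    scale = max(np.abs(tri).max(), 1.0)
    if area2 < 1e-9 * scale**2:
        return None
    uv = np.linalg.solve(T, point - tri[2])
    return np.array([uv[0], uv[1], 1.0 - uv[0] - uv[1]])


def estimate_ref_fitted(
    A_neiMean: np.ndarray,
    A_neiFitted: np.ndarray,
    A_ref: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Move each reference acupoint from the mean to the fitted model.

    With exactly three control points per acupoint the affine MLS fit is an
    exact interpolant, so the transfer is computed as a barycentric
    remapping from the mean-model neighbor triangle to the fitted-model
    one.  Degenerate (collinear) triangles fall back to a
    weighted-nearest-neighbor offset and are flagged.

    Parameters are (n, 3, 2) neighbor arrays and (n, 2) acupoints; returns
    ``(A_refFitted (n, 2), degenerate_flags (n,))``.
    """
    nei_mean = np.asarray(A_neiMean, dtype=float).reshape(-1, 3, 2)
    nei_fit = np.asarray(A_neiFitted, dtype=float).reshape(-1, 3, 2)
    a_ref = np.asarray(A_ref, dtype=float).reshape(-1, 2)
    if not (len(nei_mean) == len(nei_fit) == len(a_ref)):
        raise ValueError("acupoint count mismatch")

    out = np.zeros_like(a_ref)
    flags = np.zeros(len(a_ref), dtype=bool)
    for i in range(len(a_ref)):
        w = _barycentric_2d(a_ref[i], nei_mean[i])
        if w is None:
            # Collinear neighbors: inverse-distance weighted displacement.
            d = np.linalg.norm(nei_mean[i] - a_ref[i], axis=1)
            wts = 1.0 / np.maximum(d, _COINCIDENCE_TOL) ** 2
            wts /= wts.sum()
            out[i] = a_ref[i] + wts @ (nei_fit[i] - nei_mean[i])
            flags[i] = True
        else:
            out[i] = np.array([w[0], w[1], w[2]]) @ np.vstack(
                [nei_fit[i][0], nei_fit[i][1], nei_fit[i][2]]
            )
    return out, flags


def estimate_input_acupoints(
    L_fitted: np.ndarray,
    L_in: np.ndarray,
    A_refFitted: np.ndarray,
    alpha_w: float = 1.0,
) -> np.ndarray:
    """Deform fitted-model acupoints into the input image.

    The projected fitted-model landmarks are the source control points and
    the detected input-image landmarks the destination; each acupoint is
    carried by the affine MLS deformation between them.
    """
    L_fitted = np.asarray(L_fitted, dtype=float).reshape(-1, 2)
    L_in = np.asarray(L_in, dtype=float).reshape(-1, 2)
    if len(L_fitted) != len(L_in):
        raise ValueError("landmark count mismatch")
    return mls_affine_deform(L_fitted, L_in, A_refFitted, alpha_w=alpha_w)
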