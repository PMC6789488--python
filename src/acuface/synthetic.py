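"""Synthetic fixtures with exact ground truth.

Everything the pipeline consumes can be generated here deterministically:

* a generative face model (half-ellipsoid mean mesh plus smooth random
  bump fields as orthonormal PCA modes) with landmark and acupoint
  annotations,
* rendered 2D views (Gaussian vertex splats) with projected ground truth,
* pinhole calibration scenes with the exact image-to-arm perspective
  transform and plane-height matrix implied by the geometry,
* tracking sequences with known boxes and scripted occlusions.

Every generator is a pure function of its seed and arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull, cKDTree

from acuface.calibration import PerspectiveTransform
from acuface.geometry import Camera, Pose
from acuface.morphable import Mesh3D, MorphableModel, reconstruct

__all__ = [
    "AnnotatedFace",
    "SyntheticFaceModel",
    "SyntheticScene",
    "TrackingSequence",
    "make_generative_model",
    "sample_face",
    "render_face",
    "make_calibration_scene",
    "make_tracking_sequence",
    "frontal_pose",
]

# Semi-axes of the half-ellipsoid face in mm (half-width, half-height, depth).
_FACE_AXES = np.array([70.0, 90.0, 55.0])

# 17-point landmark scheme: unit directions on the front hemisphere, model
# coordinates x right, y down (image convention), z out of the face.
_LANDMARK_DIRS = np.array(
    [
        # jaw contour (5)
        [-0.95, 0.30, 0.15],
        [-0.65, 0.70, 0.30],
        [0.00, 0.98, 0.20],
        [0.65, 0.70, 0.30],
        [0.95, 0.30, 0.15],
        # brows (2)
        [-0.35, -0.42, 0.85],
        [0.35, -0.42, 0.85],
        # eye corners (4): outer L, inner L, inner R, outer R
        [-0.45, -0.22, 0.87],
        [-0.18, -0.22, 0.96],
        [0.18, -0.22, 0.96],
        [0.45, -0.22, 0.87],
        # nose (2): tip, base
        [0.00, 0.08, 1.00],
        [0.00, 0.25, 0.95],
        # mouth (4): corner L, top, bottom, corner R
        [-0.28, 0.48, 0.85],
        [0.00, 0.42, 0.92],
        [0.00, 0.58, 0.88],
        [0.28, 0.48, 0.85],
    ]
)

# Facial acupoint analogues (8): midline point between the brows, paired
# forehead, infraorbital and nostril-side points, and a chin midline point.
_ACUPOINT_DIRS = np.array(
    [
        [0.00, -0.32, 0.95],   # between the eyebrows (yintang analogue)
        [-0.33, -0.55, 0.80],  # forehead L (yangbai)
        [0.33, -0.55, 0.80],   # forehead R
        [-0.30, 0.02, 0.92],   # below eye L (sibai)
        [0.30, 0.02, 0.92],    # below eye R
        [-0.16, 0.30, 0.92],   # beside nostril L (yingxiang)
        [0.16, 0.30, 0.92],    # beside nostril R
        [0.00, 0.70, 0.80],    # below lower lip (chengjiang)
    ]
)

ACUPOINT_NAMES = [
    "yintang",
    "yangbai_l",
    "yangbai_r",
    "sibai_l",
    "sibai_r",
    "yingxiang_l",
    "yingxiang_r",
    "chengjiang",
]


@dataclass
class AnnotatedFace:
    """A sampled face mesh plus its ground-truth annotations."""

    mesh: Mesh3D
    landmark_indices: np.ndarray
    acupoints_3d: np.ndarray
    acupoint_neighbor_indices: np.ndarray
    shape_coefficients: np.ndarray


@dataclass
class SyntheticFaceModel(MorphableModel):
    """Generative morphable model carrying fixture annotations.

    The acupoint anchors store, per acupoint, the mean-mesh neighbor
    triangle, barycentric weights within it, and a signed offset along the
    triangle normal — enough to transfer ground-truth acupoints exactly to
    any sampled mesh.
    """

    landmark_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    anchor_neighbors: np.ndarray = field(default_factory=lambda: np.empty((0, 3), int))
    anchor_bary: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    anchor_offset: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int = 0


def _hemisphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the z>0 unit hemisphere."""
    i = np.arange(n)
    z = (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = i * golden
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _nearest_distinct(tree: cKDTree, targets: np.ndarray, taken: set[int]) -> list[int]:
    out = []
    for t in targets:
        _, idx = tree.query(t, k=8)
        pick = next(int(j) for j in np.atleast_1d(idx) if int(j) not in taken)
        taken.add(pick)
        out.append(pick)
    return out


def _triangle_frame(tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit normal and (degenerate-safe) area of a 3-point triangle."""
    n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        return np.zeros(3), 0.0
    return n / norm, norm / 2.0


def _barycentric_3d(point: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, float]:
    """Barycentric weights of the in-plane projection plus normal offset."""
    normal, _ = _triangle_frame(tri)
    offset = float(np.dot(point - tri[0], normal))
    in_plane = point - offset * normal
    # Solve in the triangle's 2D frame.
    e1, e2 = tri[1] - tri[0], tri[2] - tri[0]
    A = np.column_stack([e1, e2])
    uv, *_ = np.linalg.lstsq(A, in_plane - tri[0], rcond=None)
    w = np.array([1.0 - uv[0] - uv[1], uv[0], uv[1]])
    return w, offset


def make_generative_model(
    seed: int, n_vertices: int = 300, m: int = 5
) -> SyntheticFaceModel:
    """Build a synthetic generative face model.

    The mean mesh is a half-ellipsoid sampled quasi-uniformly and
    triangulated by its convex hull; the ``m`` shape modes are smooth
    Gaussian bump displacement fields, orthonormalized, with geometrically
    decaying mode scales (mm).  Deterministic in ``seed``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if n_vertices < 3 * m:
        raise ValueError("n_vertices must be >= 3*m")
    rng = np.random.default_rng(seed)

    unit = _hemisphere_points(n_vertices)
    verts = unit * _FACE_AXES
    hull = ConvexHull(verts)
    faces = hull.simplices.copy()

    # Smooth random bump fields as raw modes, then orthonormalize.
    raw = np.zeros((m, n_vertices, 3))
    for k in range(m):
        n_bumps = 6
        centers = unit[rng.integers(0, n_vertices, size=n_bumps)]
        widths = rng.uniform(0.25, 0.6, size=n_bumps)
        dirs = rng.normal(size=(n_bumps, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        amps = rng.uniform(0.5, 1.0, size=n_bumps)
        for c, w, d, a in zip(centers, widths, dirs, amps):
            dist2 = np.sum((unit - c) ** 2, axis=1)
            raw[k] += a * np.exp(-dist2 / (2 * w**2))[:, None] * d
    flat = raw.reshape(m, -1)
    q, _ = np.linalg.qr(flat.T)
    basis = q.T[:m]
    for row in basis:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    scales = 8.0 * 0.7 ** np.arange(m)

    model = SyntheticFaceModel(
        mean=verts.reshape(-1),
        basis=basis,
        mode_scales=scales,
        faces=faces,
        seed=seed,
    )

    tree = cKDTree(verts)
    taken: set[int] = set()
    lm_targets = (
        _LANDMARK_DIRS / np.linalg.norm(_LANDMARK_DIRS, axis=1, keepdims=True)
    ) * _FACE_AXES
    model.landmark_indices = np.array(_nearest_distinct(tree, lm_targets, taken))

    acu = (
        _ACUPOINT_DIRS / np.linalg.norm(_ACUPOINT_DIRS, axis=1, keepdims=True)
    ) * _FACE_AXES
    neighbors = np.zeros((len(acu), 3), dtype=int)
    bary = np.zeros((len(acu), 3))
    offs = np.zeros(len(acu))
    for i, a in enumerate(acu):
        _, idx = tree.query(a, k=3)
        neighbors[i] = idx
        bary[i], offs[i] = _barycentric_3d(a, verts[idx])
    model.anchor_neighbors = neighbors
    model.anchor_bary = bary
    model.anchor_offset = offs
    return model


def _transfer_acupoints(model: SyntheticFaceModel, verts: np.ndarray) -> np.ndarray:
    """Exact anchor-based acupoint positions on a deformed mesh."""
    out = np.zeros((len(model.anchor_neighbors), 3))
    for i, (nei, w, h) in enumerate(
        zip(model.anchor_neighbors, model.anchor_bary, model.anchor_offset)
    ):
        tri = verts[nei]
        normal, _ = _triangle_frame(tri)
        out[i] = w @ tri + h * normal
    return out


def sample_face(
    model: SyntheticFaceModel, alpha: np.ndarray | int | None = None
) -> AnnotatedFace:
    """Draw a face from the model.

    ``alpha`` may be a coefficient vector, an integer seed (coefficients
    drawn as N(0, mode_scales^2)), or None for the mean face.  Landmarks
    transfer by fixed vertex index; acupoints by their barycentric anchors;
    neighbor indices are recomputed as the 3 nearest vertices of the new
    mesh.
    """
    if alpha is None:
        alpha = np.zeros(model.m)
    elif isinstance(alpha, (int, np.integer)):
        rng = np.random.default_rng(int(alpha))
        alpha = rng.normal(0.0, model.mode_scales)
    alpha = np.asarray(alpha, dtype=float).reshape(-1)
    if alpha.size != model.m:
        raise ValueError(f"alpha must have {model.m} entries")
    mesh = reconstruct(model, alpha)
    acupoints = _transfer_acupoints(model, mesh.vertices)
    tree = cKDTree(mesh.vertices)
    _, nei = tree.query(acupoints, k=3)
    return AnnotatedFace(
        mesh=mesh,
        landmark_indices=model.landmark_indices.copy(),
        acupoints_3d=acupoints,
        acupoint_neighbor_indices=np.atleast_2d(nei),
        shape_coefficients=alpha,
    )


def frontal_pose(
    camera: Camera, distance: float = 600.0, yaw: float = 0.0, pitch: float = 0.0
) -> Pose:
    """Pose placing the face in front of the camera at ``distance`` mm.

    The model's +z (out of the face) is turned toward the camera; small
    ``yaw``/``pitch`` (radians) rotate the head away from frontal.
    """
    # Base: model x -> camera x, model y -> camera y, model z -> camera -z.
    base = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, -1.0]])
    base[:, 0] *= -1.0  # keep det +1: mirror x so the face looks at the camera
    cy, sy = np.cos(yaw), np.sin(yaw)
    cp, sp = np.cos(pitch), np.sin(pitch)
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rx = np.array([[1, 0, 0], [0, cp, -sp], [0, sp, cp]])
    return Pose(base @ Ry @ Rx, np.array([0.0, 0.0, distance]), camera)


def _vertex_intensities(n: int) -> np.ndarray:
    """Fixed pseudo-random per-vertex albedo, stable across faces."""
    i = np.arange(n, dtype=float)
    frac = np.modf(np.sin(i * 12.9898 + 78.233) * 43758.5453)[0]
    return 0.35 + 0.6 * np.abs(frac)


def render_face(
    face: AnnotatedFace,
    pose: Pose,
    image_size: tuple[int, int],
    splat_sigma: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a face as Gaussian vertex splats.

    Each vertex contributes a Gaussian blob at its projected location,
    weighted by a fixed per-vertex albedo and a depth cue, giving a
    deterministic face-like texture that deforms with the mesh.  Returns
    ``(image uint8 (H, W), landmarks_2d (L, 2), acupoints_2d (A, 2))``; the
    2D ground truth is the pinhole projection of the 3D annotations with
    the same camera.
    """
    w, h = int(image_size[0]), int(image_size[1])
    if w <= 0 or h <= 0:
        raise ValueError("image size must be positive")
    cam_pts = pose.transform(face.mesh.vertices)
    if np.any(cam_pts[:, 2] <= 0):
        raise ValueError("face intersects the camera plane")
    proj = pose.project(face.mesh.vertices)
    inside = (
        (proj[:, 0] >= 0) & (proj[:, 0] < w) & (proj[:, 1] >= 0) & (proj[:, 1] < h)
    )
    if not inside.any():
        raise ValueError("face fully outside the camera frustum")

    if splat_sigma is None:
        span = proj[inside].max(axis=0) - proj[inside].min(axis=0)
        area = max(float(span[0] * span[1]), 1.0)
        splat_sigma = max(1.0, 0.9 * np.sqrt(area / len(proj)))

    albedo = _vertex_intensities(len(proj))
    z = cam_pts[:, 2]
    depth_cue = 1.0 - 0.5 * (z - z.min()) / max(float(np.ptp(z)), 1e-9)
    weight = albedo * depth_cue

    img = np.zeros((h, w))
    half = int(np.ceil(3 * splat_sigma))
    ax = np.arange(-half, half + 1)
    for (u, v), wgt in zip(proj, weight):
        cu, cv = int(round(u)), int(round(v))
        if cu < -half or cu >= w + half or cv < -half or cv >= h + half:
            continue
        gx = np.exp(-((ax + cu - u) ** 2) / (2 * splat_sigma**2))
        gy = np.exp(-((ax + cv - v) ** 2) / (2 * splat_sigma**2))
        x0, x1 = max(0, cu - half), min(w, cu + half + 1)
        y0, y1 = max(0, cv - half), min(h, cv + half + 1)
        img[y0:y1, x0:x1] += wgt * np.outer(
            gy[y0 - (cv - half) : y1 - (cv - half)],
            gx[x0 - (cu - half) : x1 - (cu - half)],
        )
    peak = img.max()
    if peak > 0:
        img = img / peak
    image = (img * 255).astype(np.uint8)
    landmarks2d = pose.project(face.mesh.vertices[face.landmark_indices])
    acupoints2d = pose.project(face.acupoints_3d)
    return image, landmarks2d, acupoints2d


# ---------------------------------------------------------------------------
# Calibration scenes
# ---------------------------------------------------------------------------


@dataclass
class SyntheticScene:
    """Pinhole calibration scene with exact ground truth.

    ``points_by_height`` maps plane height (mm) to ``(image_pts, arm_pts)``
    arrays; ``true_T`` maps image coordinates at ``height_a`` to arm XY;
    ``true_F`` maps image coordinates at ``height_b`` to the image
    coordinates the same arm point would have at ``height_a``.
    """

    camera: Camera
    rotation: np.ndarray
    translation: np.ndarray
    true_T: PerspectiveTransform
    true_F: PerspectiveTransform
    height_a: float
    height_b: float
    points_by_height: dict[float, tuple[np.ndarray, np.ndarray]]
    rng_seed: int

    def homography_at(self, height: float) -> np.ndarray:
        """Exact arm-XY -> image homography for the plane at ``height``."""
        K = self.camera.matrix
        R, t = self.rotation, self.translation
        H = K @ np.column_stack([R[:, 0], R[:, 1], height * R[:, 2] + t])
        return H / H[2, 2]

    def image_of(self, arm_xy: np.ndarray, height: float) -> np.ndarray:
        H = self.homography_at(height)
        pts = np.atleast_2d(arm_xy)
        homog = np.column_stack([pts, np.ones(len(pts))]) @ H.T
        return homog[:, :2] / homog[:, 2:3]


def _staggered_grid(n: int, extent: float, rng: np.random.Generator) -> np.ndarray:
    """n reference points in a staggered-row layout over [-extent, extent]^2."""
    base_rows = [3, 4, 3, 3]
    rows: list[int] = []
    while sum(rows) < n:
        rows.append(base_rows[len(rows) % 4])
    rows[-1] -= sum(rows) - n
    pts = []
    ys = np.linspace(-extent, extent, len(rows))
    for r, (count, y) in enumerate(zip(rows, ys)):
        xs = np.linspace(-extent, extent, max(count, 1))
        if r % 2 == 1:
            xs = xs + 0.5 * (xs[1] - xs[0] if count > 1 else extent / 2)
        for x in xs[:count]:
            pts.append([x, y])
    pts = np.asarray(pts[:n])
    pts += rng.uniform(-2.0, 2.0, size=pts.shape)  # break exact collinearity
    return pts


def make_calibration_scene(
    seed: int,
    n_points: int = 13,
    heights: tuple[float, float] = (0.0, 50.0),
    extra_heights: tuple[float, ...] = (),
    perpendicular: bool = False,
    camera: Camera | None = None,
    max_offset: float = 150.0,
    extent: float = 60.0,
) -> SyntheticScene:
    """Generate a camera/robot-arm calibration scene.

    An oblique (or, with ``perpendicular=True``, exactly nadir) pinhole
    camera observes reference points on the arm's XY plane at the
    calibration height ``a`` and a higher plane ``b``; the scene stores the
    exact image/arm pairs and the exact transforms T and F implied by the
    geometry.
    """
    if n_points < 4:
        raise ValueError("n_points must be >= 4 (cannot calibrate with fewer)")
    a, b = float(heights[0]), float(heights[1])
    if a == b:
        raise ValueError("plane heights must differ")
    rng = np.random.default_rng(seed)

    camera = camera or Camera(focal=900.0, principal_point=(320.0, 240.0))
    cam_height = 650.0
    if perpendicular:
        R = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]])
        C = np.array([0.0, 0.0, cam_height])
    else:
        # Oblique view: camera offset laterally but aimed at the workspace
        # center, plus a small roll about the optical axis.
        radius = rng.uniform(0.4, 1.0) * max_offset
        azim = rng.uniform(0, 2 * np.pi)
        C = np.array(
            [radius * np.cos(azim), radius * np.sin(azim), cam_height]
        )
        z_axis = -C / np.linalg.norm(C)  # toward the workspace origin
        x_axis = np.cross(z_axis, np.array([0.0, 1.0, 0.0]))
        x_axis /= np.linalg.norm(x_axis)
        y_axis = np.cross(z_axis, x_axis)
        R = np.vstack([x_axis, y_axis, z_axis])
        roll = rng.uniform(-0.05, 0.05)
        cr, sr = np.cos(roll), np.sin(roll)
        R = np.array([[cr, -sr, 0.0], [sr, cr, 0.0], [0.0, 0.0, 1.0]]) @ R
    t = -R @ C

    scene = SyntheticScene(
        camera=camera,
        rotation=R,
        translation=t,
        true_T=PerspectiveTransform.identity(),
        true_F=PerspectiveTransform.identity(),
        height_a=a,
        height_b=b,
        points_by_height={},
        rng_seed=seed,
    )
    H_a = scene.homography_at(a)
    H_b = scene.homography_at(b)
    scene.true_T = PerspectiveTransform.from_matrix(np.linalg.inv(H_a))
    scene.true_F = PerspectiveTransform.from_matrix(H_a @ np.linalg.inv(H_b))

    arm_pts = _staggered_grid(n_points, extent=extent, rng=rng)
    for h in (a, b, *extra_heights):
        scene.points_by_height[float(h)] = (scene.image_of(arm_pts, h), arm_pts.copy())
    return scene


# ---------------------------------------------------------------------------
# Tracking sequences
# ---------------------------------------------------------------------------


@dataclass
class TrackingSequence:
    """Frames with ground-truth boxes ``(x, y, w, h)`` and occlusion flags."""

    frames: list[np.ndarray]
    true_boxes: np.ndarray
    occlusion_flags: np.ndarray
    pattern: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self) -> None:
        if not (len(self.frames) == len(self.true_boxes) == len(self.occlusion_flags)):
            raise ValueError("frame/box/flag counts must match")


def _make_pattern(rng: np.random.Generator, size: tuple[int, int]) -> np.ndarray:
    """Structured target patch: smoothed noise plus a bright center blob."""
    h, w = size
    patch = gaussian_filter(rng.uniform(0, 1, (h, w)), 1.5)
    yy, xx = np.mgrid[0:h, 0:w]
    blob = np.exp(
        -(((yy - h / 2) ** 2) / (2 * (h / 5) ** 2) + ((xx - w / 2) ** 2) / (2 * (w / 5) ** 2))
    )
    patch = 0.4 * patch + 0.8 * blob
    patch[h // 4, :] = 1.0  # horizontal bar for orientation structure
    return np.clip(patch, 0, 1)


def make_tracking_sequence(
    seed: int,
    pattern_size: tuple[int, int] = (32, 32),
    trajectory: str | tuple | list = "static",
    occlusion_spec: tuple[int, ...] = (),
    n_frames: int = 10,
    frame_size: tuple[int, int] = (128, 128),
) -> TrackingSequence:
    """Deterministic moving-target sequence over a static noisy background.

    ``trajectory`` is ``"static"``, ``("translate", dx, dy)`` per frame, or
    an explicit list of top-left positions; ``occlusion_spec`` lists frames
    whose target region is overwritten with background noise.
    """
    rng = np.random.default_rng(seed)
    fh, fw = frame_size
    ph, pw = pattern_size
    background = gaussian_filter(rng.uniform(0.15, 0.55, (fh, fw)), 2.0)
    pattern = _make_pattern(rng, (ph, pw))

    start = ((fw - pw) // 2, (fh - ph) // 2)
    if trajectory == "static":
        positions = [start] * n_frames
    elif isinstance(trajectory, tuple) and trajectory[0] == "translate":
        dx, dy = trajectory[1], trajectory[2]
        sx = (fw - pw) // 2 - dx * (n_frames - 1) // 2
        sy = (fh - ph) // 2 - dy * (n_frames - 1) // 2
        positions = [(sx + i * dx, sy + i * dy) for i in range(n_frames)]
    else:
        positions = [tuple(p) for p in trajectory]
        n_frames = len(positions)

    occluded = np.zeros(n_frames, dtype=bool)
    for i in occlusion_spec:
        occluded[i] = True

    boxes = np.array([[x, y, pw, ph] for x, y in positions], dtype=float)
    for i, (x, y) in enumerate(positions):
        vis_w = min(x + pw, fw) - max(x, 0)
        vis_h = min(y + ph, fh) - max(y, 0)
        if not occluded[i] and vis_w * vis_h < 0.5 * pw * ph:
            raise ValueError(f"frame {i}: box less than 50% inside frame")

    frames = []
    for i, (x, y) in enumerate(positions):
        frame = background.copy()
        x0, y0 = max(x, 0), max(y, 0)
        x1, y1 = min(x + pw, fw), min(y + ph, fh)
        if x1 > x0 and y1 > y0:
            if occluded[i]:
                frame[y0:y1, x0:x1] = gaussian_filter(
                    rng.uniform(0.15, 0.55, (y1 - y0, x1 - x0)), 2.0
                )
            else:
                frame[y0:y1, x0:x1] = pattern[y0 - y : y1 - y, x0 - x : x1 - x]
        frames.append((np.clip(frame, 0, 1) * 255).astype(np.uint8))

    return TrackingSequence(frames, boxes, occluded, pattern)
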