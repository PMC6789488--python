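"""Self-contained synthetic end-to-end demonstration.

Builds a complete virtual treatment scene: a generative face model with
annotated acupoints, a tilted overhead camera shared between face
rendering and hand-eye calibration, a regression-tree landmark detector
trained on rendered faces, and a short sequence of a held-out face
drifting across the robot workspace.  The online pipeline then detects,
tracks, fits and transfers the acupoints, and the results are scored
against the exact synthetic ground truth in both image (px) and arm (mm)
coordinates.

Geometry: the robot-arm frame is the world frame; the face lies on the
workspace looking up (+z), so each acupoint's height k above the
calibration plane is simply its world z coordinate, taken from the mean
model as a constant face-surface offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from acuface.calibration import (
    CalibrationResult,
    CorrespondenceSet,
    estimate_height_matrix,
    estimate_transform,
)
from acuface.ert import ERTConfig, train_cascade
from acuface.geometry import Camera, Pose
from acuface.morphable import AcupunctureModel3D
from acuface.pipeline import PipelineConfig, PipelineResult, run_online
from acuface.synthetic import (
    AnnotatedFace,
    SyntheticFaceModel,
    _transfer_acupoints,
    make_calibration_scene,
    make_generative_model,
    render_face,
    sample_face,
)
from acuface.tracking import LinearHogDetector, train_fixture_detector

__all__ = ["DemoReport", "run_demo", "build_demo_world"]

# Rotation placing the face flat on the workspace looking up:
# model x -> world -x, model y -> world -y, model z -> world +z.
_FACE_TO_WORLD = np.diag([-1.0, -1.0, 1.0])


@dataclass
class DemoReport:
    result: PipelineResult
    image_errors_px: np.ndarray  # per-frame mean acupoint error, px
    arm_errors_mm: np.ndarray  # per-frame mean acupoint error, mm
    frac_frames_ok: float  # within 3 px and 1 mm
    calibration: CalibrationResult


def _face_pose(scene, face_shift_xy: np.ndarray, yaw: float) -> Pose:
    """Model-to-camera pose for a face at ``face_shift_xy`` on the workspace."""
    cz, sz = np.cos(yaw), np.sin(yaw)
    Rz = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    R_fw = Rz @ _FACE_TO_WORLD
    t_fw = np.array([face_shift_xy[0], face_shift_xy[1], 0.0])
    R_mc = scene.rotation @ R_fw
    t_mc = scene.rotation @ t_fw + scene.translation
    return Pose(R_mc, t_mc, scene.camera)


def _world_acupoints(face: AnnotatedFace, shift_xy: np.ndarray, yaw: float):
    cz, sz = np.cos(yaw), np.sin(yaw)
    Rz = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    pts = face.acupoints_3d @ (Rz @ _FACE_TO_WORLD).T
    pts[:, 0] += shift_xy[0]
    pts[:, 1] += shift_xy[1]
    return pts


def build_demo_world(seed: int, n_train: int = 120, image_size: int = 640):
    """Generative model, scene, calibration, trained landmark cascade, detector."""
    rng = np.random.default_rng(seed)
    model = make_generative_model(seed, n_vertices=300, m=5)
    mean_acu = _transfer_acupoints(model, model.mean.reshape(-1, 3))
    acu_model = AcupunctureModel3D(
        landmark_indices=model.landmark_indices,
        acupoints_3d=mean_acu,
        neighbor_indices=model.anchor_neighbors,
    )

    camera = Camera(focal=1500.0, principal_point=(image_size / 2, image_size / 2))
    scene = make_calibration_scene(
        seed + 1,
        n_points=13,
        heights=(0.0, 70.0),
        camera=camera,
        max_offset=120.0,
        extent=55.0,
    )

    # Calibrate with the package's own estimators on the scene's point pairs.
    img_a, arm_a = scene.points_by_height[scene.height_a]
    img_b, arm_b = scene.points_by_height[scene.height_b]
    T, res_T = estimate_transform(CorrespondenceSet(img_a, arm_a))
    F, res_F = estimate_height_matrix(CorrespondenceSet(img_b, img_a))
    calibration = CalibrationResult(
        T, F, scene.height_a, scene.height_b, res_T, res_F
    )

    # Landmark cascade trained on rendered faces under demo-like motion.
    images, shapes = [], []
    for i in range(n_train):
        face = sample_face(model, rng.normal(0.0, model.mode_scales))
        shift = rng.uniform(-12, 12, size=2)
        yaw = rng.uniform(-0.07, 0.07)
        pose = _face_pose(scene, shift, yaw)
        img, lms, _ = render_face(face, pose, (image_size, image_size))
        images.append(img)
        shapes.append(lms)
    ert = train_cascade(
        images,
        np.stack(shapes),
        ERTConfig(
            n_stages=7,
            trees_per_stage=50,
            depth=3,
            n_init_per_image=2,
            box_jitter_scale=0.12,
            box_jitter_shift=0.08,
            seed=seed,
        ),
    )

    # Face detector: positives are face-box crops of the training renders.
    boxes = []
    for s in shapes:
        mn, mx = s.min(axis=0), s.max(axis=0)
        pad = 0.12 * (mx - mn)
        boxes.append((*(mn - pad), *(mx - mn + 2 * pad)))

    def pos_crop(i: int) -> np.ndarray:
        x, y, w, h = boxes[i % len(boxes)]
        x0, y0 = max(0, int(x)), max(0, int(y))
        crop = images[i % len(images)][y0 : int(y + h), x0 : int(x + w)]
        return (
            resize(crop.astype(float), (48, 48), anti_aliasing=True) * 1.0
        ).astype(np.uint8)

    detector = train_fixture_detector(pos_crop, n_pos=40, n_neg=80, seed=seed)
    # Face spans roughly half the frame; scan near window/face_size with a
    # fine stride (the cascade corrects residual box misalignment).
    med_face = float(np.median([b[2] for b in boxes]))
    s0 = 48.0 / med_face
    detector.scales = (s0, 0.9 * s0, 1.1 * s0)
    detector.stride = 4

    return model, acu_model, scene, calibration, ert, detector


def run_demo(
    seed: int = 0,
    n_frames: int = 8,
    n_train: int = 120,
    image_size: int = 640,
    out_dir=None,
) -> DemoReport:
    """Full synthetic end-to-end run; optionally writes overlays and JSON."""
    model, acu_model, scene, calibration, ert, detector = build_demo_world(
        seed, n_train=n_train, image_size=image_size
    )
    rng = np.random.default_rng(seed + 1000)

    # Held-out face drifting across the workspace.
    face = sample_face(model, rng.normal(0.0, model.mode_scales))
    shifts = np.cumsum(rng.uniform(-3, 3, size=(n_frames, 2)), axis=0)
    yaws = np.cumsum(rng.uniform(-0.01, 0.01, size=n_frames))
    frames, truth_px, truth_arm = [], [], []
    for i in range(n_frames):
        pose = _face_pose(scene, shifts[i], yaws[i])
        img, _, acu2d = render_face(face, pose, (image_size, image_size))
        frames.append(img)
        truth_px.append(acu2d)
        truth_arm.append(_world_acupoints(face, shifts[i], yaws[i])[:, :2])

    # Constant face-surface height offsets from the mean model (world z).
    k_heights = (acu_model.acupoints_3d @ _FACE_TO_WORLD.T)[:, 2]

    config = PipelineConfig(
        camera=scene.camera,
        morphable=model,
        acupuncture=acu_model,
        ert=ert,
        detector=detector,
        calibration=calibration,
        acupoint_heights=k_heights,
        landmark_refine_passes=2,
        seed=seed,
    )
    result = run_online(frames, config)

    img_err = np.full(n_frames, np.inf)
    arm_err = np.full(n_frames, np.inf)
    for i, fr in enumerate(result.frames):
        if fr.status != "ok" or fr.acupoints_px is None:
            continue
        img_err[i] = float(
            np.mean(np.linalg.norm(fr.acupoints_px - truth_px[i], axis=1))
        )
        if fr.arm_mm is not None:
            arm_err[i] = float(
                np.mean(np.linalg.norm(fr.arm_mm - truth_arm[i], axis=1))
            )
    frac_ok = float(np.mean((img_err < 3.0) & (arm_err < 1.0)))

    if out_dir is not None:
        import json
        from pathlib import Path

        from acuface.io import save_image
        from acuface.pipeline import overlay_frame

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, fr in enumerate(result.frames):
            if fr.acupoints_px is not None:
                img, _ = overlay_frame(frames[i], fr)
                save_image(img, out / f"overlay_{i:03d}.png")
        (out / "demo_result.json").write_text(
            json.dumps(
                {
                    "image_errors_px": img_err.tolist(),
                    "arm_errors_mm": arm_err.tolist(),
                    "frac_frames_ok": frac_ok,
                    "n_failed": result.n_failed,
                },
                indent=2,
            )
        )

    return DemoReport(result, img_err, arm_err, frac_ok, calibration)
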