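"""End-to-end acupoint localization pipeline.

Online flow per frame: detect/track the face, constrain the face region,
detect landmarks with the regression-tree cascade, fit the morphable model
(shape + pose), project the model landmarks and acupoint neighborhoods to
2D, transfer the acupoints into the image by the two-stage
moving-least-squares deformation, and — when a hand-eye calibration is
loaded — map the image acupoints to robot-arm coordinates with the
plane-height correction.  Failures are contained per frame.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from acuface.calibration import CalibrationResult, map_to_arm
from acuface.ert import ERTModel, predict_landmarks
from acuface.geometry import Camera
from acuface.mls import estimate_input_acupoints, estimate_ref_fitted
from acuface.morphable import (
    AcupunctureModel3D,
    Mesh3D,
    MorphableModel,
    fit_landmarks,
    project_model_points,
)
from acuface.overlay import warp_overlay
from acuface.tracking import (
    TrackerConfig,
    TrackState,
    constrain_region,
    init_filter,
    track_step,
)

__all__ = [
    "PipelineConfig",
    "FrameResult",
    "PipelineResult",
    "run_offline_annotation",
    "run_online",
]


@dataclass
class PipelineConfig:
    """In-memory pipeline configuration.

    ``acupoint_heights`` supplies the per-acupoint height k (mm above the
    arm's calibration plane) used by the parallax correction; it may be a
    scalar (constant face-surface offset) or one value per acupoint.
    """

    camera: Camera
    morphable: MorphableModel
    acupuncture: AcupunctureModel3D
    ert: ERTModel
    detector: object | None = None
    calibration: CalibrationResult | None = None
    acupoint_heights: np.ndarray | float | None = None
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    region_margin: float = 1.0  # ERT init box inflation over the tracked box
    fit_lambda: float = 1e-3
    mls_alpha_w: float = 1.0
    landmark_refine_passes: int = 1
    seed: int = 0
    init_box: tuple[float, float, float, float] | None = None


@dataclass
class FrameResult:
    index: int
    status: str = "ok"  # ok | failed
    box: tuple | None = None
    psr: float | None = None
    landmarks: np.ndarray | None = None
    alpha: np.ndarray | None = None
    acupoints_px: np.ndarray | None = None
    arm_mm: np.ndarray | None = None
    error: str | None = None
    events: list = field(default_factory=list)

    def to_jsonable(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "index": self.index,
            "status": self.status,
            "box": None if self.box is None else [float(v) for v in self.box],
            "psr": None if self.psr is None else float(self.psr),
            "landmarks": arr(self.landmarks),
            "alpha": arr(self.alpha),
            "acupoints_px": arr(self.acupoints_px),
            "arm_mm": arr(self.arm_mm),
            "error": self.error,
            "events": self.events,
        }


@dataclass
class PipelineResult:
    frames: list[FrameResult]
    elapsed_s: float = 0.0

    @property
    def n_failed(self) -> int:
        return sum(1 for f in self.frames if f.status != "ok")

    def to_json(self) -> str:
        return json.dumps(
            {
                "frames": [f.to_jsonable() for f in self.frames],
                "n_failed": self.n_failed,
            },
            indent=2,
        )


def run_offline_annotation(
    annotated_meshes: list[tuple[Mesh3D, np.ndarray]],
    landmark_indices: np.ndarray,
    model: MorphableModel,
    surface_tolerance: float = 8.0,
) -> AcupunctureModel3D:
    """Aggregate per-subject acupoint annotations into the reference model.

    Each entry pairs a mesh (in correspondence with the model topology)
    with its annotated acupoint coordinates; the reference acupoints are
    the per-acupoint means in the model frame and the neighbor indices the
    3 nearest mean-mesh vertices.  Annotations farther than
    ``surface_tolerance`` mm from the mean mesh produce a warning.
    """
    import warnings

    if not annotated_meshes:
        raise ValueError("no annotated meshes")
    n_model = model.n_vertices
    coords = []
    for mesh, acu in annotated_meshes:
        if len(mesh.vertices) != n_model:
            raise ValueError("mesh topology does not match the model")
        coords.append(np.asarray(acu, dtype=float).reshape(-1, 3))
    aref = np.mean(coords, axis=0)

    mean_verts = model.mean.reshape(-1, 3)
    tree = cKDTree(mean_verts)
    dists, nei = tree.query(aref, k=3)
    for i, d in enumerate(np.atleast_2d(dists)[:, 0]):
        if d > surface_tolerance:
            warnings.warn(
                f"acupoint {i} lies {d:.1f} mm off the mean surface",
                stacklevel=2,
            )
    return AcupunctureModel3D(
        landmark_indices=np.asarray(landmark_indices, dtype=int),
        acupoints_3d=aref,
        neighbor_indices=np.atleast_2d(nei),
    )


def _localize_frame(
    frame: np.ndarray,
    box: tuple,
    config: PipelineConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Landmarks -> fit -> projection -> MLS acupoint transfer for one frame."""
    region = constrain_region(box, config.region_margin, frame.shape[:2])
    est = predict_landmarks(config.ert, frame, region)
    for _ in range(config.landmark_refine_passes):
        mn, mx = est.landmarks.min(axis=0), est.landmarks.max(axis=0)
        pad = 0.1 * (mx - mn)
        refined_box = (*(mn - pad), *(mx - mn + 2 * pad))
        est = predict_landmarks(config.ert, frame, refined_box)
    L_in = est.landmarks

    acu = config.acupuncture
    fitted = fit_landmarks(
        config.morphable,
        L_in,
        acu.landmark_indices,
        config.camera,
        lam=config.fit_lambda,
    )
    L_fitted = project_model_points(fitted, acu.landmark_indices)

    mean_verts = config.morphable.mean.reshape(-1, 3)
    nei_mean_2d = np.stack(
        [
            project_model_points(fitted, mean_verts[idx])
            for idx in acu.neighbor_indices
        ]
    )
    nei_fit_2d = np.stack(
        [
            project_model_points(fitted, fitted.mesh.vertices[idx])
            for idx in acu.neighbor_indices
        ]
    )
    a_ref_2d = project_model_points(fitted, acu.acupoints_3d)

    a_ref_fitted, _flags = estimate_ref_fitted(nei_mean_2d, nei_fit_2d, a_ref_2d)
    a_in = estimate_input_acupoints(
        L_fitted, L_in, a_ref_fitted, alpha_w=config.mls_alpha_w
    )
    return L_in, fitted.alpha, a_in


def run_online(frames: list[np.ndarray], config: PipelineConfig) -> PipelineResult:
    """Run the online pipeline over a frame sequence.

    The face box comes from the pluggable detector (or ``config.init_box``)
    on the first frame and from the correlation tracker afterwards; a PSR
    drop below threshold triggers re-detection.  A stage failure marks only
    that frame as failed.
    """
    t0 = time.perf_counter()
    results: list[FrameResult] = []
    track_state: TrackState | None = None

    for i, frame in enumerate(frames):
        fr = FrameResult(index=i)
        try:
            if track_state is None:
                box = None
                if config.detector is not None:
                    box = config.detector(frame)
                if box is None:
                    box = config.init_box
                if box is None:
                    raise RuntimeError("no detection and no init_box configured")
                track_state = TrackState(
                    box=box, filter=init_filter(frame, box, config.tracker)
                )
                fr.events.append({"event": "detect", "box": list(box)})
            else:
                track_state, report = track_step(track_state, frame, config.tracker)
                fr.psr = report.psr
                if track_state.status == "lost":
                    fr.events.append({"event": "psr_low", "psr": float(report.psr)})
                    box = None
                    if config.detector is not None:
                        box = config.detector(frame)
                    if box is not None:
                        track_state = TrackState(
                            box=box,
                            filter=init_filter(frame, box, config.tracker),
                        )
                        fr.events.append({"event": "redetect", "box": list(box)})
                    else:
                        raise RuntimeError("track lost and re-detection failed")
            fr.box = track_state.box

            L_in, alpha, a_in = _localize_frame(frame, track_state.box, config)
            fr.landmarks = L_in
            fr.alpha = alpha
            fr.acupoints_px = a_in

            if config.calibration is not None:
                k = config.acupoint_heights
                if k is None:
                    k = config.calibration.height_a
                fr.arm_mm = map_to_arm(config.calibration, a_in, k)
        except Exception as exc:  # stage isolation: fail this frame only
            fr.status = "failed"
            fr.error = f"{type(exc).__name__}: {exc}"
            track_state = track_state  # keep whatever state we had
        results.append(fr)

    return PipelineResult(frames=results, elapsed_s=time.perf_counter() - t0)


def overlay_frame(frame: np.ndarray, fr: FrameResult):
    """Overlay a frame's acupoints/landmarks (helper for CLI output)."""
    return warp_overlay(frame, fr.acupoints_px, fr.landmarks)
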