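import numpy as np
import pytest

from acuface.geometry import Camera
from acuface.synthetic import (
    frontal_pose,
    make_calibration_scene,
    make_generative_model,
    render_face,
    sample_face,
)


@pytest.fixture(scope="session")
def face_model():
    return make_generative_model(seed=1, n_vertices=300, m=5)


@pytest.fixture(scope="session")
def camera():
    return Camera(focal=650.0, principal_point=(128.0, 128.0))


@pytest.fixture(scope="session")
def default_scene():
    """Oblique-camera calibration scene with intermediate test heights."""
    return make_calibration_scene(seed=5, extra_heights=(12.5, 25.0, 37.5))


@pytest.fixture(scope="session")
def rendered_faces(face_model, camera):
    """60 rendered faces with ground truth, shared across training tests."""
    rng = np.random.default_rng(7)
    images, shapes, acus, alphas = [], [], [], []
    for _ in range(60):
        alpha = rng.normal(0.0, face_model.mode_scales)
        face = sample_face(face_model, alpha)
        pose = frontal_pose(camera, distance=600.0, yaw=rng.uniform(-0.08, 0.08))
        img, lms, acu2d = render_face(face, pose, (256, 256))
        images.append(img)
        shapes.append(lms)
        acus.append(acu2d)
        alphas.append(alpha)
    return images, np.stack(shapes), np.stack(acus), np.stack(alphas)


@pytest.fixture(scope="session")
def small_ert(rendered_faces):
    """Small cascade for module-level behavioral tests."""
    from acuface.ert import ERTConfig, train_cascade

    images, shapes, _, _ = rendered_faces
    return train_cascade(
        images,
        shapes,
        ERTConfig(n_stages=4, trees_per_stage=30, depth=3, seed=0),
    )
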