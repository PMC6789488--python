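"""Morphable model: PCA construction, PnP, landmark fitting, projection."""

import numpy as np
import pytest

from acuface.geometry import Camera, Pose
from acuface.morphable import (
    Mesh3D,
    build_model,
    estimate_pose,
    fit_landmarks,
    project_model_points,
    reconstruct,
)
from acuface.synthetic import frontal_pose, sample_face


def _random_meshes(rng, n_meshes=6, n_verts=40):
    base = rng.uniform(-50, 50, (n_verts, 3))
    faces = np.array([[0, 1, 2]])
    return [Mesh3D(base + rng.normal(0, 3, base.shape), faces) for _ in range(n_meshes)]


class TestBuildModel:
    def test_two_mesh_axis_matches_covariance_oracle(self):
        rng = np.random.default_rng(0)
        vbar = rng.uniform(-10, 10, 30)
        u = rng.normal(size=30)
        u /= np.linalg.norm(u)
        c = 2.5
        faces = np.array([[0, 1, 2]])
        meshes = [
            Mesh3D((vbar + c * u).reshape(-1, 3), faces),
            Mesh3D((vbar - c * u).reshape(-1, 3), faces),
        ]
        model = build_model(meshes, m=1)
        assert np.allclose(model.mean, vbar, atol=1e-12)
        assert min(
            np.abs(model.basis[0] - u).max(), np.abs(model.basis[0] + u).max()
        ) < 1e-10
        # scale = singular value / sqrt(n-1); data rows are +-c*u.
        assert np.isclose(model.mode_scales[0], c * np.sqrt(2.0), atol=1e-10)

    def test_matches_dense_covariance_eigendecomposition(self):
        rng = np.random.default_rng(1)
        meshes = _random_meshes(rng)
        model = build_model(meshes, m=3)
        data = np.stack([m.flat for m in meshes])
        cov = np.cov(data.T, bias=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        for k in range(3):
            v = evecs[:, order[k]]
            assert min(
                np.abs(model.basis[k] - v).max(), np.abs(model.basis[k] + v).max()
            ) < 1e-8
            assert np.isclose(model.mode_scales[k], np.sqrt(evals[order[k]]), atol=1e-8)

    def test_identical_meshes_zero_scales(self):
        mesh = Mesh3D(np.arange(30.0).reshape(-1, 3), np.array([[0, 1, 2]]))
        model = build_model([mesh, mesh, mesh], m=1)
        assert np.array_equal(model.mean, mesh.flat)
        assert np.allclose(model.mode_scales, 0.0, atol=1e-10)

    def test_full_basis_reproduces_training_set(self):
        rng = np.random.default_rng(2)
        meshes = _random_meshes(rng, n_meshes=5)
        model = build_model(meshes, m=4)
        for mesh in meshes:
            alpha = model.basis @ (mesh.flat - model.mean)
            rec = reconstruct(model, alpha)
            assert np.abs(rec.flat - mesh.flat).max() < 1e-8

    def test_m_too_large_rejected(self):
        rng = np.random.default_rng(3)
        meshes = _random_meshes(rng, n_meshes=3)
        with pytest.raises(ValueError):
            build_model(meshes, m=3)


class TestReconstruct:
    def test_zero_alpha_and_unit_modes(self, face_model):
        assert np.array_equal(
            reconstruct(face_model, np.zeros(face_model.m)).flat, face_model.mean
        )
        e1 = np.zeros(face_model.m)
        e1[1] = 1.0
        assert np.allclose(
            reconstruct(face_model, e1).flat,
            face_model.mean + face_model.basis[1],
            atol=1e-12,
        )

    def test_dimension_mismatch(self, face_model):
        with pytest.raises(ValueError):
            reconstruct(face_model, np.zeros(face_model.m + 2))


class TestEstimatePose:
    def test_identity_pose_recovery(self, camera):
        rng = np.random.default_rng(0)
        pts3 = rng.uniform(-50, 50, (12, 3))
        true = Pose(np.eye(3), np.array([0.0, 0.0, 1000.0]), camera)
        pose = estimate_pose(true.project(pts3), pts3, camera)
        assert np.abs(pose.rotation - np.eye(3)).max() < 1e-6
        assert np.abs(pose.translation - [0, 0, 1000]).max() < 1e-3
        assert pose.residual_px < 1e-8

    def test_noise_residual_tracks_sigma(self, camera):
        rng = np.random.default_rng(1)
        pts3 = rng.uniform(-60, 60, (20, 3))
        true = frontal_pose(camera, distance=800.0, yaw=0.15)
        sigma = 0.5
        pts2 = true.project(pts3) + rng.normal(0, sigma, (20, 2))
        pose = estimate_pose(pts2, pts3, camera)
        assert sigma / 2 < pose.residual_px < sigma * 2

    def test_collinear_points_rejected(self, camera):
        t = np.linspace(0, 1, 8)
        pts3 = np.column_stack([t, 2 * t, 3 * t]) * 50
        pts2 = np.column_stack([t, t]) * 100
        with pytest.raises(ValueError):
            estimate_pose(pts2, pts3, camera)


class TestFitLandmarks:
    def test_recovers_shape_coefficients(self, face_model, camera):
        rng = np.random.default_rng(4)
        alpha_true = rng.normal(0, face_model.mode_scales)
        face = sample_face(face_model, alpha_true)
        pose = frontal_pose(camera, distance=600.0, yaw=0.07)
        lms2d = pose.project(face.mesh.vertices[face.landmark_indices])
        fit = fit_landmarks(
            face_model, lms2d, face.landmark_indices, camera, lam=1e-8
        )
        rel = np.linalg.norm(fit.alpha - alpha_true) / np.linalg.norm(alpha_true)
        assert rel < 0.05
        assert fit.rmse_px < 1e-4

    def test_large_ridge_shrinks_alpha_to_zero(self, face_model, camera):
        face = sample_face(face_model, None)  # mean face
        pose = frontal_pose(camera, distance=600.0)
        lms2d = pose.project(face.mesh.vertices[face.landmark_indices])
        fit = fit_landmarks(
            face_model, lms2d, face.landmark_indices, camera, lam=1e6
        )
        assert np.abs(fit.alpha).max() < 1e-3

    def test_rmse_history_non_increasing(self, face_model, camera):
        rng = np.random.default_rng(5)
        face = sample_face(face_model, rng.normal(0, face_model.mode_scales))
        pose = frontal_pose(camera, distance=600.0, yaw=-0.1)
        lms2d = pose.project(face.mesh.vertices[face.landmark_indices])
        lms2d += rng.normal(0, 1.0, lms2d.shape)  # noisy landmarks
        fit = fit_landmarks(face_model, lms2d, face.landmark_indices, camera)
        hist = np.array(fit.rmse_history)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_mesh_field_is_exact_reconstruction(self, face_model, camera):
        face = sample_face(face_model, 6)
        pose = frontal_pose(camera, distance=600.0)
        lms2d = pose.project(face.mesh.vertices[face.landmark_indices])
        fit = fit_landmarks(face_model, lms2d, face.landmark_indices, camera)
        assert np.array_equal(
            fit.mesh.flat, reconstruct(face_model, fit.alpha).flat
        )


class TestProjectModelPoints:
    def test_optical_axis_projects_to_principal_point(self, face_model, camera):
        face = sample_face(face_model, None)
        pose = frontal_pose(camera, distance=600.0)
        from acuface.morphable import FittedFace

        fitted = FittedFace(np.zeros(face_model.m), face.mesh, pose)
        # A model point that lands exactly on the optical axis in camera space.
        p_model = np.linalg.solve(
            pose.rotation, np.array([0.0, 0.0, camera.focal]) - pose.translation
        )
        out = project_model_points(fitted, p_model.reshape(1, 3))
        assert np.allclose(out[0], camera.principal_point, atol=1e-9)

    def test_matches_render_ground_truth(self, face_model, camera):
        from acuface.morphable import FittedFace
        from acuface.synthetic import render_face

        face = sample_face(face_model, 8)
        pose = frontal_pose(camera, distance=600.0, yaw=0.05)
        _, lms, acu2d = render_face(face, pose, (256, 256))
        fitted = FittedFace(face.shape_coefficients, face.mesh, pose)
        assert np.abs(
            project_model_points(fitted, face.landmark_indices) - lms
        ).max() < 1e-9
        assert np.abs(project_model_points(fitted, face.acupoints_3d) - acu2d).max() < 1e-9

    def test_translation_shifts_per_pinhole(self, face_model, camera):
        from acuface.morphable import FittedFace

        face = sample_face(face_model, None)
        pose = frontal_pose(camera, distance=600.0)
        shifted = Pose(
            pose.rotation, pose.translation + np.array([10.0, 0.0, 0.0]), camera
        )
        f0 = FittedFace(np.zeros(face_model.m), face.mesh, pose)
        f1 = FittedFace(np.zeros(face_model.m), face.mesh, shifted)
        p0 = project_model_points(f0, face.landmark_indices)
        p1 = project_model_points(f1, face.landmark_indices)
        z = pose.transform(face.mesh.vertices[face.landmark_indices])[:, 2]
        expected_dx = camera.focal * 10.0 / z
        assert np.allclose(p1[:, 0] - p0[:, 0], expected_dx, atol=1e-9)
        assert np.allclose(p1[:, 1], p0[:, 1], atol=1e-9)

    def test_point_behind_camera_errors(self, face_model, camera):
        from acuface.morphable import FittedFace

        face = sample_face(face_model, None)
        pose = frontal_pose(camera, distance=600.0)
        fitted = FittedFace(np.zeros(face_model.m), face.mesh, pose)
        behind = np.linalg.solve(
            pose.rotation, np.array([0.0, 0.0, -10.0]) - pose.translation
        )
        with pytest.raises(ValueError):
            project_model_points(fitted, behind.reshape(1, 3))
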