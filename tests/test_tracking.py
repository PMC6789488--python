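"""Correlation-filter tracking, PSR, HOG features, detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acuface.synthetic import make_tracking_sequence
from acuface.tracking import (
    LinearHogDetector,
    TemplateDetector,
    TrackerConfig,
    TrackState,
    compute_psr,
    constrain_region,
    detect_face,
    hog_features,
    init_filter,
    track_sequence,
    track_step,
)


def _psr_oracle(plane: np.ndarray, mask_side: int) -> tuple:
    """Naive two-pass PSR: explicit python loops over the sidelobe."""
    best = (-np.inf, 0, 0)
    for r in range(plane.shape[0]):
        for c in range(plane.shape[1]):
            if plane[r, c] > best[0]:
                best = (plane[r, c], r, c)
    peak, pr, pc = best
    half = mask_side // 2
    vals = []
    for r in range(plane.shape[0]):
        for c in range(plane.shape[1]):
            if abs(r - pr) <= half and abs(c - pc) <= half:
                continue
            vals.append(plane[r, c])
    vals = np.array(vals)
    return peak, vals.mean(), vals.std()


class TestPSR:
    @given(seed=st.integers(0, 100_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        plane = rng.normal(size=(rng.integers(12, 30), rng.integers(12, 30)))
        mask = int(rng.choice([5, 7, 11]))
        rep = compute_psr(plane, mask)
        peak, mean, std = _psr_oracle(plane, mask)
        assert rep.peak_value == peak
        assert np.isclose(rep.sidelobe_mean, mean)
        assert np.isclose(rep.sidelobe_std, std)
        assert np.isclose(rep.psr, (peak - mean) / std)

    def test_delta_plane_gives_inf(self):
        plane = np.zeros((64, 64))
        plane[10, 20] = 1.0
        rep = compute_psr(plane)
        assert rep.sidelobe_mean == 0 and rep.sidelobe_std == 0
        assert np.isinf(rep.psr) and not rep.degenerate

    def test_uniform_plane_degenerate_zero(self):
        rep = compute_psr(np.ones((64, 64)))
        assert rep.psr == 0.0 and rep.degenerate

    def test_tie_breaks_to_smallest_row_then_column(self):
        plane = np.zeros((20, 20))
        plane[5, 7] = plane[5, 12] = plane[9, 3] = 2.0
        plane[0, 0] = 1.0
        assert compute_psr(plane, 5).peak_location == (5, 7)

    def test_small_plane_rejected(self):
        with pytest.raises(ValueError):
            compute_psr(np.ones((8, 8)), mask_side=11)


class TestFilter:
    def test_self_response_peaks_at_center(self):
        seq = make_tracking_sequence(1, trajectory="static", n_frames=2)
        box = tuple(seq.true_boxes[0])
        cfg = TrackerConfig()
        filt = init_filter(seq.frames[0], box, cfg)
        from acuface.tracking import _get_patch, _preprocess

        size = filt.window_size
        center = (box[0] + box[2] / 2, box[1] + box[3] / 2)
        pre, _ = _preprocess(_get_patch(seq.frames[0], center, size))
        resp = np.real(np.fft.ifft2(filt.H * np.fft.fft2(pre)))
        r, c = np.unravel_index(resp.argmax(), resp.shape)
        assert abs(r - size[0] // 2) <= 1 and abs(c - size[1] // 2) <= 1

    def test_same_seed_identical_filters(self):
        seq = make_tracking_sequence(2, trajectory="static", n_frames=2)
        box = tuple(seq.true_boxes[0])
        a = init_filter(seq.frames[0], box, TrackerConfig(seed=5))
        b = init_filter(seq.frames[0], box, TrackerConfig(seed=5))
        assert np.array_equal(a.numerator, b.numerator)
        assert np.array_equal(a.denominator, b.denominator)

    def test_flat_patch_flags_zero_information(self):
        img = np.full((64, 64), 100, dtype=np.uint8)
        filt = init_filter(img, (16, 16, 32, 32), TrackerConfig(n_aug=0))
        assert filt.zero_information

    def test_tiny_box_rejected(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        with pytest.raises(ValueError):
            init_filter(img, (0, 0, 8, 8))


class TestTracking:
    def test_static_sequence_low_drift(self):
        seq = make_tracking_sequence(1, trajectory="static", n_frames=10)
        cfg = TrackerConfig()
        st_ = TrackState(
            box=tuple(seq.true_boxes[0]),
            filter=init_filter(seq.frames[0], tuple(seq.true_boxes[0]), cfg),
        )
        for f in seq.frames[1:]:
            st_, _ = track_step(st_, f, cfg)
        drift = np.abs(np.array(st_.box[:2]) - seq.true_boxes[-1][:2]).max()
        assert drift <= 1.0

    def test_translation_tracked_within_one_pixel(self):
        seq = make_tracking_sequence(2, trajectory=("translate", 3, 0), n_frames=10)
        cfg = TrackerConfig()
        st_ = TrackState(
            box=tuple(seq.true_boxes[0]),
            filter=init_filter(seq.frames[0], tuple(seq.true_boxes[0]), cfg),
        )
        for i, f in enumerate(seq.frames[1:], 1):
            st_, _ = track_step(st_, f, cfg)
            err = np.abs(np.array(st_.box[:2]) - seq.true_boxes[i][:2]).max()
            assert err <= 1.0

    def test_occlusion_drops_psr_and_flips_lost(self):
        seq = make_tracking_sequence(
            3, trajectory="static", n_frames=12, occlusion_spec=(5, 6)
        )
        cfg = TrackerConfig()
        st_ = TrackState(
            box=tuple(seq.true_boxes[0]),
            filter=init_filter(seq.frames[0], tuple(seq.true_boxes[0]), cfg),
        )
        psrs, statuses = [], []
        for f in seq.frames[1:]:
            st_, rep = track_step(st_, f, cfg)
            psrs.append(rep.psr)
            statuses.append(st_.status)
        psrs = np.array(psrs)
        occluded = seq.occlusion_flags[1:]
        assert psrs[occluded].max() < np.median(psrs[~occluded])
        assert all(s == "lost" for s, o in zip(statuses, occluded) if o)

    def test_translation_consistency_under_cyclic_shift(self):
        seq = make_tracking_sequence(4, trajectory="static", n_frames=6)
        cfg = TrackerConfig()
        dy, dx = 9, 13

        def run(frames, box):
            s = TrackState(box=box, filter=init_filter(frames[0], box, cfg))
            out = [s.box]
            for f in frames[1:]:
                s, _ = track_step(s, f, cfg)
                out.append(s.box)
            return np.array(out)

        base = run(seq.frames, tuple(seq.true_boxes[0]))
        shifted_frames = [np.roll(f, (dy, dx), axis=(0, 1)) for f in seq.frames]
        b0 = seq.true_boxes[0] + [dx, dy, 0, 0]
        shifted = run(shifted_frames, tuple(b0))
        assert np.abs((shifted - base) - [dx, dy, 0, 0]).max() < 1e-9


class TestRedetection:
    def test_redetect_restores_tracking_after_occlusion(self):
        positions = [(20 + 4 * i, 40) for i in range(14)]
        seq = make_tracking_sequence(
            5, trajectory=positions, occlusion_spec=(6, 7, 8)
        )
        det = TemplateDetector(seq.pattern * 255)
        boxes, reports, events = track_sequence(
            seq.frames, tuple(seq.true_boxes[0]), TrackerConfig(), detector=det
        )
        # Within 2 frames of occlusion end (frame 8), the box is back on target.
        recovered = [
            i
            for i in (9, 10)
            if np.abs(np.array(boxes[i][:2]) - seq.true_boxes[i][:2]).max() <= 2.0
        ]
        assert recovered, f"no recovery by frame 10; events={events}"


class TestHog:
    def test_constant_image_all_zero(self):
        feats = hog_features(np.full((64, 64), 77, dtype=np.uint8))
        assert np.all(feats == 0)

    def test_step_edge_energy_concentrates_and_rotates(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        img[:, 32:] = 200  # vertical edge, horizontal gradient
        feats = hog_features(img, cell_size=8, n_orientations=9)
        hist = feats.sum(axis=(0, 1, 2, 3))
        dominant = int(np.argmax(hist))
        assert hist[dominant] > 0.9 * hist.sum()
        rot = hog_features(np.rot90(img).copy(), cell_size=8, n_orientations=9)
        hist_rot = rot.sum(axis=(0, 1, 2, 3))
        assert int(np.argmax(hist_rot)) != dominant
        # Unsigned orientations: a 90 deg rotation moves the energy by half
        # the bin range (here bin 0 <-> bin n/2 boundary pair 4/5).
        assert abs(int(np.argmax(hist_rot)) - dominant) in (4, 5)

    def test_dimension_check(self):
        with pytest.raises(ValueError):
            hog_features(np.zeros((30, 30), dtype=np.uint8), cell_size=8)
        with pytest.raises(ValueError):
            hog_features(np.zeros((8, 8, 3), dtype=np.uint8))


@pytest.fixture(scope="module")
def fixture_detector(face_model, camera):
    from acuface.tracking import train_fixture_detector
    from acuface.synthetic import frontal_pose, render_face, sample_face
    from skimage.transform import resize

    rng = np.random.default_rng(0)

    def pos(i):
        face = sample_face(face_model, rng.normal(0, face_model.mode_scales))
        img, lms, _ = render_face(
            face, frontal_pose(camera, yaw=rng.uniform(-0.05, 0.05)), (256, 256)
        )
        mn, mx = lms.min(0), lms.max(0)
        pad = 0.12 * (mx - mn)
        x, y = (mn - pad).astype(int)
        x1, y1 = (mx + pad).astype(int)
        crop = img[max(y, 0) : y1, max(x, 0) : x1].astype(float)
        return resize(crop, (48, 48), anti_aliasing=True).astype(np.uint8)

    return train_fixture_detector(pos, n_pos=24, n_neg=48, seed=0)


class TestDetector:
    def test_detects_rendered_face(self, fixture_detector, face_model, camera):
        from acuface.synthetic import frontal_pose, render_face, sample_face
        from acuface.tracking import _iou

        face = sample_face(face_model, 123)
        img, lms, _ = render_face(face, frontal_pose(camera), (256, 256))
        mn, mx = lms.min(0), lms.max(0)
        pad = 0.12 * (mx - mn)
        true_box = (*(mn - pad), *(mx - mn + 2 * pad))
        med = true_box[2]
        fixture_detector.scales = tuple(48.0 / med * np.array([1.0, 0.9, 1.1]))
        box = detect_face(img, fixture_detector)
        assert box is not None
        assert _iou(box, true_box) >= 0.5

    def test_pure_noise_yields_none(self, fixture_detector):
        rng = np.random.default_rng(9)
        noise = rng.integers(0, 255, (256, 256), dtype=np.uint8)
        fixture_detector.scales = (0.3, 0.5, 1.0)
        assert detect_face(noise, fixture_detector) is None


class TestConstrainRegion:
    @pytest.mark.parametrize(
        "box,margin,dims,expected",
        [
            ((10, 20, 30, 40), 1.0, None, (10, 20, 30, 40)),
            ((78, 78, 100, 100), 1.4, (256, 256), (58, 58, 140, 140)),
            ((0, 0, 40, 40), 1.5, (64, 64), (0, 0, 50, 50)),
        ],
    )
    def test_inflation_and_clipping(self, box, margin, dims, expected):
        out = constrain_region(box, margin, dims)
        assert np.allclose(out, expected)
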