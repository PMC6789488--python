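"""Correlation-filter tracking with PSR gating, HOG features and detection.

The tracker is a MOSSE-style adaptive correlation filter: the face patch
is log-normalized, cosine-windowed and correlated in the frequency domain
against a filter trained to produce a Gaussian response at the target
center.  Tracking quality is gated by the peak-to-sidelobe ratio (PSR) of
the response plane — the peak height relative to the mean and standard
deviation of the sidelobe region outside an 11x11 central mask.  When the
PSR falls below a threshold the target is declared lost and re-detected by
a pluggable detector (the default fixture detector is a linear scorer over
HOG features trained on synthetic rendered faces).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.feature import hog as _skimage_hog
from skimage.transform import resize as _resize

__all__ = [
    "TrackerConfig",
    "CorrelationFilter",
    "PSRReport",
    "TrackState",
    "init_filter",
    "track_step",
    "track_sequence",
    "compute_psr",
    "hog_features",
    "detect_face",
    "constrain_region",
    "LinearHogDetector",
    "TemplateDetector",
    "train_fixture_detector",
]


@dataclass
class TrackerConfig:
    """MOSSE tracker settings (learning rate and reg_eps follow the
    original correlation-filter conventions)."""

    learning_rate: float = 0.125
    reg_eps: float = 1e-5
    sigma_resp: float = 2.0
    psr_threshold: float = 7.0
    psr_mask_side: int = 11
    window_padding: float = 2.0  # correlation window size relative to the box
    n_aug: int = 8
    seed: int = 0
    redetect_every: int | None = None  # forced re-detection cadence, frames


@dataclass
class CorrelationFilter:
    """Frequency-domain filter as running numerator/denominator sums."""

    numerator: np.ndarray
    denominator: np.ndarray
    window_size: tuple[int, int]  # (h, w)
    learning_rate: float
    reg_eps: float
    zero_information: bool = False

    @property
    def H(self) -> np.ndarray:
        return self.numerator / (self.denominator + self.reg_eps)


@dataclass
class PSRReport:
    peak_location: tuple[int, int]  # (row, col)
    peak_value: float
    sidelobe_mean: float
    sidelobe_std: float
    psr: float
    mask_side: int = 11
    degenerate: bool = False


@dataclass
class TrackState:
    box: tuple[float, float, float, float]  # (x, y, w, h)
    filter: CorrelationFilter
    last_psr: float = np.inf
    status: str = "tracking"  # tracking | lost
    frame_index: int = 0


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    return np.outer(np.hanning(shape[0]), np.hanning(shape[1]))


def _preprocess(patch: np.ndarray) -> tuple[np.ndarray, bool]:
    """Log compression, zero-mean unit-norm, cosine window."""
    p = np.log1p(patch.astype(float))
    std = p.std()
    if std < 1e-12:
        return np.zeros_like(p), True
    p = (p - p.mean()) / std
    return p * _hann2d(p.shape), False


def _get_patch(image: np.ndarray, center: tuple[float, float], size: tuple[int, int]):
    """Crop (h, w) patch centered at (cx, cy), clamping at borders."""
    h, w = size
    cx, cy = center
    x0 = int(round(cx - w / 2))
    y0 = int(round(cy - h / 2))
    ys = np.clip(np.arange(y0, y0 + h), 0, image.shape[0] - 1)
    xs = np.clip(np.arange(x0, x0 + w), 0, image.shape[1] - 1)
    return image[np.ix_(ys, xs)]


def _gaussian_response(shape: tuple[int, int], sigma: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return np.exp(-(((yy - h // 2) ** 2 + (xx - w // 2) ** 2) / (2 * sigma**2)))


def init_filter(
    image: np.ndarray,
    box: tuple[float, float, float, float],
    config: TrackerConfig | None = None,
) -> CorrelationFilter:
    """Train a MOSSE filter on the target patch plus small jittered copies.

    The desired response is a Gaussian peaked at the patch center; the
    filter is accumulated over ``n_aug`` seeded rotation/scale jitters of
    the patch for robustness.  Deterministic for a given config.
    """
    config = config or TrackerConfig()
    x, y, w, h = box
    if w < 16 or h < 16:
        raise ValueError("box must be at least 16x16 px")
    pad = config.window_padding
    size = (int(round(h * pad)), int(round(w * pad)))
    center = (x + w / 2, y + h / 2)
    patch = _get_patch(image, center, size)

    G = np.fft.fft2(_gaussian_response(size, config.sigma_resp))
    rng = np.random.default_rng(config.seed)
    A = np.zeros(size, dtype=complex)
    B = np.zeros(size, dtype=complex)
    zero_info = True
    variants = [patch]
    for _ in range(config.n_aug):
        angle = rng.uniform(-5, 5)
        variants.append(
            ndimage.rotate(patch.astype(float), angle, reshape=False, mode="reflect")
        )
    for var in variants:
        pre, flat = _preprocess(var)
        if flat:
            continue
        zero_info = False
        F = np.fft.fft2(pre)
        A += G * np.conj(F)
        B += F * np.conj(F)
    return CorrelationFilter(
        numerator=A,
        denominator=B.real.astype(float),
        window_size=size,
        learning_rate=config.learning_rate,
        reg_eps=config.reg_eps,
        zero_information=zero_info,
    )


def compute_psr(response: np.ndarray, mask_side: int = 11) -> PSRReport:
    """Peak-to-sidelobe ratio of a correlation response plane.

    The peak is the argmax (ties broken toward the smallest row, then
    column); the sidelobe is everything outside the ``mask_side`` square
    centered on the peak.  A zero sidelobe deviation yields +inf for a
    strict peak and 0 (flagged degenerate) for a flat plane.
    """
    resp = np.asarray(response, dtype=float)
    if resp.size == 0:
        raise ValueError("empty response plane")
    if resp.shape[0] < mask_side or resp.shape[1] < mask_side:
        raise ValueError("response plane smaller than the central mask")
    r, c = np.unravel_index(int(np.argmax(resp)), resp.shape)
    peak = float(resp[r, c])
    half = mask_side // 2
    mask = np.ones(resp.shape, dtype=bool)
    mask[
        max(0, r - half) : r + half + 1,
        max(0, c - half) : c + half + 1,
    ] = False
    sidelobe = resp[mask]
    mean = float(sidelobe.mean())
    std = float(sidelobe.std())
    if std == 0.0:
        if peak > mean:
            return PSRReport((r, c), peak, mean, std, np.inf, mask_side)
        return PSRReport((r, c), peak, mean, std, 0.0, mask_side, degenerate=True)
    return PSRReport((r, c), peak, mean, std, (peak - mean) / std, mask_side)


def track_step(
    state: TrackState,
    frame: np.ndarray,
    config: TrackerConfig | None = None,
) -> tuple[TrackState, PSRReport]:
    """One tracking update: correlate, move to the peak, adapt the filter.

    The response is evaluated on the window centered at the previous box;
    the box moves by the (wrap-corrected) peak displacement.  If the PSR is
    below threshold the state flips to ``lost``, the box is left unchanged
    and the filter is not updated.
    """
    config = config or TrackerConfig()
    filt = state.filter
    x, y, w, h = state.box
    size = filt.window_size
    center = (x + w / 2, y + h / 2)
    patch = _get_patch(frame, center, size)
    pre, flat = _preprocess(patch)
    F = np.fft.fft2(pre)
    response = np.real(np.fft.ifft2(filt.H * F))
    report = compute_psr(response, config.psr_mask_side)

    if flat or report.psr < config.psr_threshold:
        new_state = replace(
            state,
            last_psr=report.psr,
            status="lost",
            frame_index=state.frame_index + 1,
        )
        return new_state, report

    # Displacement from window center, wrap-corrected, with parabolic
    # sub-pixel refinement (the cosine window biases the raw argmax).
    r0, c0 = report.peak_location
    dr = float(r0 - size[0] // 2)
    dc = float(c0 - size[1] // 2)
    if dr > size[0] // 2:
        dr -= size[0]
    if dc > size[1] // 2:
        dc -= size[1]
    for axis, d in ((0, dr), (1, dc)):
        prev = response[(r0 - 1) % size[0], c0] if axis == 0 else response[r0, (c0 - 1) % size[1]]
        nxt = response[(r0 + 1) % size[0], c0] if axis == 0 else response[r0, (c0 + 1) % size[1]]
        denom = prev - 2 * response[r0, c0] + nxt
        if denom < -1e-12:
            frac = float(np.clip(0.5 * (prev - nxt) / denom, -0.5, 0.5))
            if axis == 0:
                dr = d + frac
            else:
                dc = d + frac
    new_box = (x + dc, y + dr, w, h)

    new_center = (new_box[0] + w / 2, new_box[1] + h / 2)
    new_patch = _get_patch(frame, new_center, size)
    pre2, flat2 = _preprocess(new_patch)
    if not flat2:
        F2 = np.fft.fft2(pre2)
        G = np.fft.fft2(_gaussian_response(size, config.sigma_resp))
        lr = filt.learning_rate
        filt = replace(
            filt,
            numerator=(1 - lr) * filt.numerator + lr * G * np.conj(F2),
            denominator=(1 - lr) * filt.denominator + lr * (F2 * np.conj(F2)).real,
        )
    new_state = TrackState(
        box=new_box,
        filter=filt,
        last_psr=report.psr,
        status="tracking",
        frame_index=state.frame_index + 1,
    )
    return new_state, report


def track_sequence(
    frames: list[np.ndarray],
    init_box: tuple[float, float, float, float],
    config: TrackerConfig | None = None,
    detector=None,
) -> tuple[list[tuple[float, float, float, float]], list[PSRReport], list[dict]]:
    """Track through a sequence with PSR-gated re-detection.

    On a lost frame (or every ``config.redetect_every`` frames when set)
    the detector is asked for a fresh box; a successful detection re-
    initializes the filter.  Returns per-frame boxes, PSR reports, and a
    structured event log.
    """
    config = config or TrackerConfig()
    state = TrackState(box=init_box, filter=init_filter(frames[0], init_box, config))
    boxes = [state.box]
    reports: list[PSRReport] = []
    events: list[dict] = [{"frame": 0, "event": "init", "box": list(init_box)}]
    for i, frame in enumerate(frames[1:], start=1):
        forced = config.redetect_every is not None and i % config.redetect_every == 0
        state, report = track_step(state, frame, config)
        reports.append(report)
        if (state.status == "lost" or forced) and detector is not None:
            found = detector(frame)
            if found is not None:
                state = TrackState(
                    box=found,
                    filter=init_filter(frame, found, config),
                    last_psr=np.inf,
                    status="tracking",
                    frame_index=i,
                )
                events.append({"frame": i, "event": "redetect", "box": list(found)})
            else:
                events.append({"frame": i, "event": "lost"})
        boxes.append(state.box)
    return boxes, reports, events


def hog_features(
    image: np.ndarray, cell_size: int = 8, n_orientations: int = 9
) -> np.ndarray:
    """Block-normalized HOG feature map of a grayscale image.

    Thin wrapper with strict input checking; returns the per-block
    histogram array (blocks_row, blocks_col, 2, 2, n_orientations).
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("image must be grayscale (2D)")
    if img.shape[0] % cell_size or img.shape[1] % cell_size:
        raise ValueError("image dims must be divisible by cell_size")
    return _skimage_hog(
        img.astype(float),
        orientations=n_orientations,
        pixels_per_cell=(cell_size, cell_size),
        cells_per_block=(2, 2),
        block_norm="L2-Hys",
        feature_vector=False,
    )


def _iou(a, b) -> float:
    ax0, ay0, aw, ah = a
    bx0, by0, bw, bh = b
    ix0, iy0 = max(ax0, bx0), max(ay0, by0)
    ix1, iy1 = min(ax0 + aw, bx0 + bw), min(ay0 + ah, by0 + bh)
    inter = max(0.0, ix1 - ix0) * max(0.0, iy1 - iy0)
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def _nms(boxes: list, scores: list, iou_thresh: float = 0.3):
    order = np.argsort(scores)[::-1]
    keep = []
    for i in order:
        if all(_iou(boxes[i], boxes[j]) < iou_thresh for j in keep):
            keep.append(i)
    return [boxes[i] for i in keep], [scores[i] for i in keep]


@dataclass
class LinearHogDetector:
    """Linear scorer over HOG features of a fixed-size sliding window."""

    weights: np.ndarray
    bias: float
    window: int = 48
    cell_size: int = 8
    n_orientations: int = 9
    score_threshold: float = 0.0
    stride: int = 8
    scales: tuple[float, ...] = (1.0, 0.75, 1.25)

    def score_window(self, crop: np.ndarray) -> float:
        feats = hog_features(crop, self.cell_size, self.n_orientations).ravel()
        return float(feats @ self.weights + self.bias)

    def __call__(self, image: np.ndarray):
        return detect_face(image, self)


@dataclass
class TemplateDetector:
    """Normalized cross-correlation re-detector for arbitrary targets."""

    template: np.ndarray
    threshold: float = 0.7

    def __call__(self, image: np.ndarray):
        from skimage.feature import match_template

        img = image.astype(float)
        if img.shape[0] < self.template.shape[0] or img.shape[1] < self.template.shape[1]:
            return None
        ncc = match_template(img, self.template.astype(float), pad_input=False)
        r, c = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
        if ncc[r, c] < self.threshold:
            return None
        th, tw = self.template.shape
        return (float(c), float(r), float(tw), float(th))


def detect_face(image: np.ndarray, detector: LinearHogDetector):
    """Sliding-window detection with greedy non-maximum suppression.

    Scans the detector's window over a small scale pyramid, scores each
    crop, suppresses overlaps at IoU >= 0.3 and returns the best box
    ``(x, y, w, h)`` above the score threshold, or None.
    """
    img = np.asarray(image, dtype=float)
    win = detector.window
    boxes, scores = [], []
    for scale in detector.scales:
        sh, sw = int(round(img.shape[0] * scale)), int(round(img.shape[1] * scale))
        if sh < win or sw < win:
            continue
        scaled = _resize(img, (sh, sw), anti_aliasing=True, preserve_range=True)
        for y0 in range(0, sh - win + 1, detector.stride):
            for x0 in range(0, sw - win + 1, detector.stride):
                s = detector.score_window(scaled[y0 : y0 + win, x0 : x0 + win])
                if s > detector.score_threshold:
                    boxes.append(
                        (x0 / scale, y0 / scale, win / scale, win / scale)
                    )
                    scores.append(s)
    if not boxes:
        return None
    kept, _ = _nms(boxes, scores)
    return kept[0]


def train_fixture_detector(
    render_fn,
    n_pos: int = 40,
    n_neg: int = 80,
    window: int = 48,
    seed: int = 0,
) -> LinearHogDetector:
    """Train the default linear detector on synthetic faces vs background.

    ``render_fn(i)`` must return the i-th positive training image (window
    sized, uint8); negatives are seeded noise and smooth-gradient crops.
    A logistic regression over HOG features provides the linear scorer.
    """
    from sklearn.linear_model import LogisticRegression

    rng = np.random.default_rng(seed)
    X, y = [], []
    for i in range(n_pos):
        img = render_fn(i)
        X.append(hog_features(img, 8, 9).ravel())
        y.append(1)
    for _ in range(n_neg):
        kind = rng.integers(0, 3)
        if kind == 0:
            neg = rng.uniform(0, 255, (window, window))
        elif kind == 1:
            neg = ndimage.gaussian_filter(rng.uniform(0, 255, (window, window)), 3)
        else:
            gx = np.linspace(0, rng.uniform(50, 255), window)
            neg = np.tile(gx, (window, 1)) + rng.normal(0, 5, (window, window))
        X.append(hog_features(neg.astype(np.uint8), 8, 9).ravel())
        y.append(0)
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(np.array(X), np.array(y))
    return LinearHogDetector(
        weights=clf.coef_.ravel(),
        bias=float(clf.intercept_[0]),
        window=window,
        score_threshold=0.0,
    )


def constrain_region(
    box: tuple[float, float, float, float],
    margin_factor: float = 1.4,
    frame_dims: tuple[int, int] | None = None,
) -> tuple[float, float, float, float]:
    """Inflate a box about its center and clip it to the frame.

    ``frame_dims`` is (height, width); with ``margin_factor`` 1.0 the box
    is returned unchanged (up to clipping).
    """
    x, y, w, h = box
    cx, cy = x + w / 2, y + h / 2
    nw, nh = w * margin_factor, h * margin_factor
    nx, ny = cx - nw / 2, cy - nh / 2
    if frame_dims is not None:
        H, W = frame_dims
        nx2, ny2 = min(nx + nw, W), min(ny + nh, H)
        nx, ny = max(0.0, nx), max(0.0, ny)
        nw, nh = nx2 - nx, ny2 - ny
    return (nx, ny, nw, nh)
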