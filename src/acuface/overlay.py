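"""Overlay rendering: acupoints as crosses, landmarks as dots."""

from __future__ import annotations

import numpy as np

__all__ = ["warp_overlay"]


def _to_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 2:
        return np.stack([img] * 3, axis=-1).astype(np.uint8)
    return img.astype(np.uint8).copy()


def _draw_cross(img: np.ndarray, x: int, y: int, size: int, color) -> None:
    h, w = img.shape[:2]
    for d in range(-size, size + 1):
        if 0 <= y < h and 0 <= x + d < w:
            img[y, x + d] = color
        if 0 <= y + d < h and 0 <= x < w:
            img[y + d, x] = color


def _draw_dot(img: np.ndarray, x: int, y: int, color) -> None:
    h, w = img.shape[:2]
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if 0 <= y + dy < h and 0 <= x + dx < w:
                img[y + dy, x + dx] = color


def warp_overlay(
    image: np.ndarray,
    acupoints: np.ndarray | None = None,
    landmarks: np.ndarray | None = None,
    cross_size: int = 4,
) -> tuple[np.ndarray, dict]:
    """Draw acupoints (red crosses) and landmarks (green dots) on a copy.

    Out-of-bounds points are clipped from the drawing and counted in the
    returned metadata; the function is pure (same inputs, same bytes).
    Returns ``(rgb image uint8, {"clipped": int, "drawn": int})``.
    """
    img = _to_rgb(image)
    h, w = img.shape[:2]
    clipped = drawn = 0

    if landmarks is not None:
        for x, y in np.atleast_2d(np.asarray(landmarks, dtype=float)):
            xi, yi = int(round(x)), int(round(y))
            if 0 <= xi < w and 0 <= yi < h:
                _draw_dot(img, xi, yi, (0, 200, 0))
                drawn += 1
            else:
                clipped += 1
    if acupoints is not None:
        for x, y in np.atleast_2d(np.asarray(acupoints, dtype=float)):
            xi, yi = int(round(x)), int(round(y))
            if 0 <= xi < w and 0 <= yi < h:
                _draw_cross(img, xi, yi, cross_size, (230, 30, 30))
                drawn += 1
            else:
                clipped += 1
    return img, {"clipped": clipped, "drawn": drawn}
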