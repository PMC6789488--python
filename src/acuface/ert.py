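"""Cascaded ensemble-of-regression-trees landmark detector.

A scaled-down face-alignment cascade in the gradient-boosting style: the
shape estimate starts as the mean shape placed in the face box and is
refined by a sequence of stages; each stage samples a pool of pixel
locations indexed relative to the current shape (anchored to the nearest
landmark in the mean-shape frame) and boosts depth-limited regression
trees whose split features are differences of two pool-pixel intensities.
Leaf values are shrunken mean shape residuals in the normalized
(mean-shape) frame, so the cascade is equivariant to similarity
transforms of the input up to resampling error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import SimilarityTransform, estimate_transform

__all__ = [
    "ERTConfig",
    "ERTModel",
    "ShapeEstimate",
    "train_cascade",
    "predict_landmarks",
    "save_model",
    "load_model",
]


@dataclass
class ERTConfig:
    n_stages: int = 6
    trees_per_stage: int = 50
    depth: int = 3
    shrinkage: float = 0.1
    pool_size: int = 200
    n_candidate_splits: int = 20
    exp_lambda: float = 0.1  # pair-distance prior scale, mean-shape units
    n_init_per_image: int = 1  # extra jittered-box initializations
    box_jitter_scale: float = 0.0  # relative size jitter of training boxes
    box_jitter_shift: float = 0.0  # relative position jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_stages, self.trees_per_stage, self.pool_size) < 1:
            raise ValueError("config counts must be positive")
        if self.depth < 0 or not (0 < self.shrinkage <= 1):
            raise ValueError("invalid depth or shrinkage")


@dataclass
class Tree:
    """Heap-ordered binary tree: splits (n_internal, 3) = (u, v, thresh),
    leaves (2^depth, 2L) shrunken residual increments."""

    splits: np.ndarray
    leaves: np.ndarray
    depth: int

    def leaf_index(self, feat_values: np.ndarray) -> int:
        idx = 0
        for _ in range(self.depth):
            u, v, thr = self.splits[idx]
            if feat_values[int(u)] - feat_values[int(v)] > thr:
                idx = 2 * idx + 1
            else:
                idx = 2 * idx + 2
        return idx - (2**self.depth - 1)


@dataclass
class Stage:
    pool_anchors: np.ndarray  # (P,) nearest-landmark index per pool point
    pool_offsets: np.ndarray  # (P, 2) offset from anchor, mean-shape frame
    trees: list[Tree]


@dataclass
class ERTModel:
    mean_shape: np.ndarray  # (L, 2), normalized to the unit box
    stages: list[Stage]
    shrinkage: float
    train_rms_history: list[float] = field(default_factory=list)

    @property
    def n_landmarks(self) -> int:
        return len(self.mean_shape)


@dataclass
class ShapeEstimate:
    landmarks: np.ndarray  # (L, 2) image px
    normalization: np.ndarray  # 3x3 similarity, mean-shape frame -> image


def _similarity(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    tf = estimate_transform("similarity", src, dst)
    return tf


def _sample_pixels(
    image: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Nearest-pixel intensities with border clamping."""
    cols = np.clip(np.round(points[:, 0]).astype(int), 0, image.shape[1] - 1)
    rows = np.clip(np.round(points[:, 1]).astype(int), 0, image.shape[0] - 1)
    return image[rows, cols].astype(float)


def _pool_image_points(
    shape: np.ndarray,
    tf_linear: np.ndarray,
    anchors: np.ndarray,
    offsets: np.ndarray,
) -> np.ndarray:
    """Warp pool points into the image: anchor landmark + rotated offset."""
    return shape[anchors] + offsets @ tf_linear.T


def _shape_in_box(mean_shape: np.ndarray, box) -> np.ndarray:
    x, y, w, h = box
    return mean_shape * [w, h] + [x, y]


def _grow_tree(
    feats: np.ndarray,
    residuals: np.ndarray,
    sample_idx: np.ndarray,
    pool_xy: np.ndarray,
    config: ERTConfig,
    rng: np.random.Generator,
) -> Tree:
    """Fit one depth-limited regression tree on pixel-difference features."""
    n_internal = 2**config.depth - 1
    n_leaves = 2**config.depth
    splits = np.zeros((max(n_internal, 1), 3))
    leaves = np.zeros((n_leaves, residuals.shape[1]))
    # Pair-distance prior for candidate split features.
    P = len(pool_xy)

    node_samples: dict[int, np.ndarray] = {0: sample_idx}
    for node in range(n_internal):
        idx = node_samples.get(node, np.empty(0, dtype=int))
        best = None
        if len(idx) >= 2:
            for _ in range(config.n_candidate_splits):
                u = int(rng.integers(0, P))
                d = np.linalg.norm(pool_xy - pool_xy[u], axis=1)
                prob = np.exp(-d / config.exp_lambda)
                prob[u] = 0.0
                if prob.sum() <= 0:
                    continue
                v = int(rng.choice(P, p=prob / prob.sum()))
                fvals = feats[idx, u] - feats[idx, v]
                lo, hi = fvals.min(), fvals.max()
                if hi - lo < 1e-12:
                    continue
                thr = rng.uniform(lo, hi)
                mask = fvals > thr
                nl, nr = int(mask.sum()), int((~mask).sum())
                if nl == 0 or nr == 0:
                    continue
                ml = residuals[idx[mask]].mean(axis=0)
                mr = residuals[idx[~mask]].mean(axis=0)
                gain = nl * ml @ ml + nr * mr @ mr
                if best is None or gain > best[0]:
                    best = (gain, u, v, thr, mask)
        if best is None:
            # No usable split: send everything left with an impossible test.
            splits[node] = [0, 0, np.inf]
            node_samples[2 * node + 1] = np.empty(0, dtype=int)
            node_samples[2 * node + 2] = idx
        else:
            _, u, v, thr, mask = best
            splits[node] = [u, v, thr]
            node_samples[2 * node + 1] = idx[mask]
            node_samples[2 * node + 2] = idx[~mask]

    first_leaf = n_internal
    for leaf in range(n_leaves):
        idx = node_samples.get(first_leaf + leaf, sample_idx if n_internal == 0 else np.empty(0, dtype=int))
        if n_internal == 0:
            idx = sample_idx
        if len(idx):
            leaves[leaf] = config.shrinkage * residuals[idx].mean(axis=0)
    return Tree(splits=splits, leaves=leaves, depth=config.depth)


def train_cascade(
    images: list[np.ndarray],
    true_shapes: np.ndarray,
    config: ERTConfig | None = None,
    init_boxes: np.ndarray | None = None,
) -> ERTModel:
    """Train the landmark cascade on images with ground-truth shapes.

    ``init_boxes`` defaults to the padded bounding box of each true shape.
    Residuals are regressed in the mean-shape frame; the recorded
    ``train_rms_history`` (one entry per boosted tree) is non-increasing
    by construction of the shrunken mean-leaf updates.
    """
    config = config or ERTConfig()
    true_shapes = np.asarray(true_shapes, dtype=float)
    N = len(images)
    if N < 20:
        raise ValueError("need at least 20 training images")
    if len(true_shapes) != N:
        raise ValueError("images/shapes length mismatch")
    rng = np.random.default_rng(config.seed)

    if init_boxes is None:
        init_boxes = []
        for s in true_shapes:
            mn, mx = s.min(axis=0), s.max(axis=0)
            pad = 0.1 * (mx - mn)
            origin = mn - pad
            size = mx - mn + 2 * pad
            init_boxes.append([origin[0], origin[1], size[0], size[1]])
        init_boxes = np.asarray(init_boxes)

    # Mean shape in the unit box frame.
    normed = []
    for s, b in zip(true_shapes, init_boxes):
        normed.append((s - [b[0], b[1]]) / [b[2], b[3]])
    mean_shape = np.mean(normed, axis=0)

    # Training samples: each image once with its base box, plus optional
    # jittered-box replicas so the cascade learns to correct imperfect
    # detection boxes.
    img_idx: list[int] = []
    boxes_all: list[np.ndarray] = []
    for i in range(N):
        img_idx.append(i)
        boxes_all.append(np.asarray(init_boxes[i], dtype=float))
        for _ in range(config.n_init_per_image - 1):
            bx, by, bw, bh = init_boxes[i]
            s = 1.0 + rng.uniform(-config.box_jitter_scale, config.box_jitter_scale)
            cx = bx + bw / 2 + rng.uniform(-1, 1) * config.box_jitter_shift * bw
            cy = by + bh / 2 + rng.uniform(-1, 1) * config.box_jitter_shift * bh
            boxes_all.append(
                np.array([cx - bw * s / 2, cy - bh * s / 2, bw * s, bh * s])
            )
            img_idx.append(i)
    M = len(img_idx)
    sample_true = true_shapes[img_idx]

    L = true_shapes.shape[1]
    shapes = np.stack([_shape_in_box(mean_shape, b) for b in boxes_all])
    model = ERTModel(mean_shape=mean_shape, stages=[], shrinkage=config.shrinkage)

    for _stage in range(config.n_stages):
        # Similarity normalizations, current residual targets.
        tfs = [_similarity(mean_shape, shapes[i]) for i in range(M)]
        linears = np.stack([tf.params[:2, :2] for tf in tfs])
        inv_linears = np.stack([np.linalg.inv(lin) for lin in linears])
        targets = np.einsum(
            "nij,nlj->nli", inv_linears, sample_true - shapes
        ).reshape(M, 2 * L)

        # Stage feature pool, anchored to nearest mean-shape landmark.
        pool_xy = rng.uniform(
            mean_shape.min(axis=0) - 0.05,
            mean_shape.max(axis=0) + 0.05,
            size=(config.pool_size, 2),
        )
        d2 = np.sum((pool_xy[:, None] - mean_shape[None]) ** 2, axis=2)
        anchors = np.argmin(d2, axis=1)
        offsets = pool_xy - mean_shape[anchors]

        feats = np.zeros((M, config.pool_size))
        for i in range(M):
            pts = _pool_image_points(shapes[i], linears[i], anchors, offsets)
            feats[i] = _sample_pixels(images[img_idx[i]], pts)

        prediction = np.zeros((M, 2 * L))
        trees: list[Tree] = []
        all_idx = np.arange(M)
        for _t in range(config.trees_per_stage):
            residual = targets - prediction
            tree = _grow_tree(feats, residual, all_idx, pool_xy, config, rng)
            for i in range(M):
                prediction[i] += tree.leaves[tree.leaf_index(feats[i])]
            trees.append(tree)
            model.train_rms_history.append(
                float(np.sqrt(np.mean((targets - prediction) ** 2)))
            )
        model.stages.append(Stage(anchors, offsets, trees))

        # Apply the stage increments in image coordinates.
        inc = prediction.reshape(M, L, 2)
        shapes = shapes + np.einsum("nij,nlj->nli", linears, inc)
    return model


def predict_landmarks(
    model: ERTModel, image: np.ndarray, init_box
) -> ShapeEstimate:
    """Run the cascade from the mean shape placed in ``init_box``."""
    x, y, w, h = init_box
    H, W = image.shape[:2]
    if x >= W or y >= H or x + w <= 0 or y + h <= 0 or w <= 0 or h <= 0:
        raise ValueError("init_box outside image")
    shape = _shape_in_box(model.mean_shape, init_box)
    L = model.n_landmarks
    tf = None
    for stage in model.stages:
        tf = _similarity(model.mean_shape, shape)
        linear = tf.params[:2, :2]
        pts = _pool_image_points(shape, linear, stage.pool_anchors, stage.pool_offsets)
        feats = _sample_pixels(image, pts)
        inc = np.zeros(2 * L)
        for tree in stage.trees:
            inc += tree.leaves[tree.leaf_index(feats)]
        shape = shape + inc.reshape(L, 2) @ linear.T
    final_tf = _similarity(model.mean_shape, shape)
    return ShapeEstimate(landmarks=shape, normalization=final_tf.params.copy())


def save_model(model: ERTModel, json_path, array_path) -> None:
    """Serialize to a JSON structure file plus an array archive."""
    arrays: dict[str, np.ndarray] = {"mean_shape": model.mean_shape}
    struct = {
        "shrinkage": model.shrinkage,
        "n_stages": len(model.stages),
        "trees_per_stage": [len(s.trees) for s in model.stages],
        "depths": [
            [t.depth for t in s.trees] for s in model.stages
        ],
        "train_rms_history": model.train_rms_history,
    }
    for si, stage in enumerate(model.stages):
        arrays[f"s{si}_anchors"] = stage.pool_anchors
        arrays[f"s{si}_offsets"] = stage.pool_offsets
        for ti, tree in enumerate(stage.trees):
            arrays[f"s{si}_t{ti}_splits"] = tree.splits
            arrays[f"s{si}_t{ti}_leaves"] = tree.leaves
    with open(json_path, "w") as fh:
        json.dump(struct, fh)
    np.savez_compressed(array_path, **arrays)


def load_model(json_path, array_path) -> ERTModel:
    with open(json_path) as fh:
        struct = json.load(fh)
    data = np.load(array_path)
    stages = []
    for si in range(struct["n_stages"]):
        trees = [
            Tree(
                splits=data[f"s{si}_t{ti}_splits"],
                leaves=data[f"s{si}_t{ti}_leaves"],
                depth=struct["depths"][si][ti],
            )
            for ti in range(struct["trees_per_stage"][si])
        ]
        stages.append(Stage(data[f"s{si}_anchors"], data[f"s{si}_offsets"], trees))
    return ERTModel(
        mean_shape=data["mean_shape"],
        stages=stages,
        shrinkage=struct["shrinkage"],
        train_rms_history=list(struct["train_rms_history"]),
    )
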