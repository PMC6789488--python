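"""Plain-text serialization helpers (OBJ meshes, JSON sidecars, CSV points)."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from PIL import Image

from acuface.calibration import CorrespondenceSet
from acuface.morphable import AcupunctureModel3D, Mesh3D

__all__ = [
    "save_mesh_obj",
    "load_mesh_obj",
    "save_annotations",
    "load_annotations",
    "save_image",
    "load_image",
    "save_points_csv",
    "load_points_csv",
    "load_correspondences_csv",
    "save_correspondences_csv",
]


def save_mesh_obj(mesh: Mesh3D, path) -> None:
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.8g} {v[1]:.8g} {v[2]:.8g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def load_mesh_obj(path) -> Mesh3D:
    verts, faces = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    return Mesh3D(np.array(verts), np.array(faces, dtype=int))


def save_annotations(acu: AcupunctureModel3D, path, alpha=None) -> None:
    payload = {
        "landmark_indices": acu.landmark_indices.tolist(),
        "acupoints": acu.acupoints_3d.tolist(),
        "neighbor_indices": acu.neighbor_indices.tolist(),
    }
    if alpha is not None:
        payload["alpha"] = np.asarray(alpha).tolist()
    Path(path).write_text(json.dumps(payload, indent=2))


def load_annotations(path) -> tuple[AcupunctureModel3D, np.ndarray | None]:
    d = json.loads(Path(path).read_text())
    acu = AcupunctureModel3D(
        landmark_indices=np.array(d["landmark_indices"], dtype=int),
        acupoints_3d=np.array(d["acupoints"], dtype=float),
        neighbor_indices=np.array(d["neighbor_indices"], dtype=int),
    )
    alpha = np.array(d["alpha"], dtype=float) if "alpha" in d else None
    return acu, alpha


def save_image(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image)).save(path)


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path))


def save_points_csv(points: np.ndarray, path, names=None) -> None:
    pts = np.atleast_2d(points)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "x", "y"])
        for i, p in enumerate(pts):
            name = names[i] if names is not None else f"p{i}"
            writer.writerow([name, f"{p[0]:.8g}", f"{p[1]:.8g}"])


def load_points_csv(path) -> tuple[np.ndarray, list[str]]:
    names, pts = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            names.append(row["name"])
            pts.append([float(row["x"]), float(row["y"])])
    return np.array(pts), names


def save_correspondences_csv(corr: CorrespondenceSet, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["x_img", "y_img", "X_arm", "Y_arm"]
        if corr.height is not None:
            header.append("height")
        writer.writerow(header)
        for s, d in zip(corr.src, corr.dst):
            row = [f"{v:.10g}" for v in (*s, *d)]
            if corr.height is not None:
                row.append(f"{corr.height:.10g}")
            writer.writerow(row)


def load_correspondences_csv(path) -> CorrespondenceSet:
    src, dst, heights = [], [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            src.append([float(row["x_img"]), float(row["y_img"])])
            dst.append([float(row["X_arm"]), float(row["Y_arm"])])
            if "height" in row and row["height"] not in (None, ""):
                heights.append(float(row["height"]))
    height = heights[0] if heights else None
    return CorrespondenceSet(np.array(src), np.array(dst), height=height)
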