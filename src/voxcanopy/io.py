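"""Plain-text and npz I/O for point clouds, scan grids and transforms.

Labeled point clouds travel as ASCII PLY with an integer ``class`` vertex
property (the convention downstream tools expect) or as XYZ CSV; organized
scans as npz bundles or (azimuth_index, elevation_index, range) CSV
triplets.  Meshes go through trimesh.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .registration import RigidTransform
from .scan import ScanGrid

__all__ = [
    "write_ply_points",
    "read_ply_points",
    "write_xyz_csv",
    "read_xyz_csv",
    "save_scan_grid",
    "load_scan_grid",
    "scan_grid_to_csv",
    "write_transform_json",
    "read_transform_json",
]


def write_ply_points(path, points: np.ndarray, classes: np.ndarray | None = None) -> None:
    """ASCII PLY with x, y, z (double) and an optional int class property."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(points)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if classes is not None:
            fh.write("property int class\n")
        fh.write("end_header\n")
        if classes is None:
            for p in points:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        else:
            for p, c in zip(points, classes):
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {int(c)}\n")


def read_ply_points(path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an ASCII PLY vertex list; returns (points, classes or None)."""
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path} is not a PLY file")
        n = None
        props = []
        while True:
            line = fh.readline()
            if not line:
                raise ValueError("unexpected end of PLY header")
            tok = line.split()
            if tok[0] == "format" and tok[1] != "ascii":
                raise ValueError("only ASCII PLY is supported")
            if tok[0] == "element" and tok[1] == "vertex":
                n = int(tok[2])
            elif tok[0] == "property":
                props.append(tok[2])
            elif tok[0] == "end_header":
                break
        data = np.loadtxt(fh, max_rows=n).reshape(n, len(props))
    cols = {name: i for i, name in enumerate(props)}
    pts = data[:, [cols["x"], cols["y"], cols["z"]]]
    classes = data[:, cols["class"]].astype(np.int64) if "class" in cols else None
    return pts, classes


def write_xyz_csv(path, points: np.ndarray, classes: np.ndarray | None = None) -> None:
    df = pd.DataFrame(np.asarray(points, dtype=float), columns=["x", "y", "z"])
    if classes is not None:
        df["class"] = np.asarray(classes, dtype=np.int64)
    df.to_csv(path, index=False)


def read_xyz_csv(path) -> tuple[np.ndarray, np.ndarray | None]:
    df = pd.read_csv(path)
    pts = df[["x", "y", "z"]].to_numpy()
    classes = df["class"].to_numpy(dtype=np.int64) if "class" in df.columns else None
    return pts, classes


def save_scan_grid(path, grid: ScanGrid) -> None:
    np.savez_compressed(
        path,
        azimuth_deg=grid.azimuth_deg,
        elevation_deg=grid.elevation_deg,
        range=grid.range,
        points=grid.points,
        scanner_position=grid.scanner_position,
        labels=grid.labels if grid.labels is not None else np.empty(0, dtype=np.int64),
    )


def load_scan_grid(path) -> ScanGrid:
    z = np.load(path)
    labels = z["labels"]
    return ScanGrid(
        azimuth_deg=z["azimuth_deg"],
        elevation_deg=z["elevation_deg"],
        range=z["range"],
        points=z["points"],
        scanner_position=z["scanner_position"],
        labels=None if labels.size == 0 else labels,
    )


def scan_grid_to_csv(path, grid: ScanGrid) -> None:
    """(azimuth_index, elevation_index, range) triplets of valid returns."""
    el, az = np.nonzero(grid.valid_mask())
    pd.DataFrame(
        {"azimuth_index": az, "elevation_index": el, "range": grid.range[el, az]}
    ).to_csv(path, index=False)


def write_transform_json(path, transform: RigidTransform) -> None:
    with open(path, "w") as fh:
        json.dump(transform.to_dict(), fh, indent=2)


def read_transform_json(path) -> RigidTransform:
    with open(path) as fh:
        d = json.load(fh)
    return RigidTransform(
        np.array(d["rotation_row_major"]).reshape(3, 3),
        np.array(d["translation"]),
        rms=d.get("rms"),
    )
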