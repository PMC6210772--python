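"""Leaf / trunk separation via octree-style connected components.

Points are binned into cubic cells at the octree leaf level (default
0.25 m) and connected under a chosen cell adjacency (default 26).  A
component is a trunk when its bounding box is slender and vertical: height
at least three times the shortest horizontal extent, with the two
horizontal extents within a ratio of 0.66-1.5; everything else is foliage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "OctreeComponent",
    "build_components",
    "classify_components",
    "classify_points",
    "remove_ground",
]

LABEL_LEAF = 0
LABEL_TRUNK = 1

_MAX_CELLS = 400_000_000  # dense occupancy guard (~0.4 GB of uint8)


@dataclass
class OctreeComponent:
    """A connected set of occupied cells and the points inside them."""

    point_indices: np.ndarray
    bbox_min: np.ndarray  # (3,)
    bbox_max: np.ndarray
    n_cells: int

    @property
    def extent(self) -> np.ndarray:
        """(dx, dy, dz) of the member-point bounding box, m."""
        return self.bbox_max - self.bbox_min


def build_components(
    points: np.ndarray,
    min_cell_size: float = 0.25,
    connectivity: int = 26,
) -> list[OctreeComponent]:
    """Connected components of the occupied-cell graph.

    Two points share a component iff a chain of occupied leaf-level cells
    connects them under the chosen adjacency (6, 18 or 26).  The result is
    independent of input point order (components are identified by their
    member sets; the returned list is sorted by first occupied cell).
    """
    if min_cell_size <= 0:
        raise ValueError("min_cell_size must be > 0")
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("empty point cloud")
    origin = pts.min(axis=0)
    idx = np.floor((pts - origin) / min_cell_size).astype(np.int64)
    dims = idx.max(axis=0) + 1
    if int(np.prod(dims)) > _MAX_CELLS:
        raise ValueError(
            f"occupancy grid {tuple(dims)} too large at cell {min_cell_size} m"
        )
    occ = np.zeros(dims, dtype=np.uint8)
    occ[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    labeled, n_comp = ndimage.label(occ, structure=structure)
    comp_of_point = labeled[idx[:, 0], idx[:, 1], idx[:, 2]]
    order = np.argsort(comp_of_point, kind="stable")
    sorted_comp = comp_of_point[order]
    boundaries = np.searchsorted(sorted_comp, np.arange(1, n_comp + 2))
    cell_counts = np.bincount(labeled.ravel())[1:]
    comps = []
    for c in range(n_comp):
        members = order[boundaries[c]:boundaries[c + 1]]
        p = pts[members]
        comps.append(
            OctreeComponent(
                point_indices=members,
                bbox_min=p.min(axis=0),
                bbox_max=p.max(axis=0),
                n_cells=int(cell_counts[c]),
            )
        )
    return comps


def classify_components(components: list[OctreeComponent]) -> np.ndarray:
    """Trunk/leaf label per component from bounding-box geometry.

    Trunk iff dz ≥ 3·min(dx, dy) and 0.66 ≤ dx/dy ≤ 1.5 (the window is
    symmetric: 1/1.5 = 0.66̄).  A degenerate horizontal extent (dx or dy
    zero) cannot satisfy the ratio test and is classified as foliage.
    """
    labels = np.empty(len(components), dtype=np.int64)
    for i, comp in enumerate(components):
        dx, dy, dz = comp.extent
        if dy == 0.0 or dx == 0.0:
            if dz > 0:
                log.debug("component %d has a degenerate horizontal extent; leaf", i)
            labels[i] = LABEL_LEAF
            continue
        ratio = dx / dy
        slender = dz >= 3.0 * min(dx, dy)
        labels[i] = LABEL_TRUNK if (slender and 0.66 <= ratio <= 1.5) else LABEL_LEAF
    return labels


def classify_points(
    points: np.ndarray,
    min_cell_size: float = 0.25,
    connectivity: int = 26,
) -> tuple[np.ndarray, list[OctreeComponent], np.ndarray]:
    """Per-point leaf/trunk labels.

    Returns (labels (n,), components, component label per component).
    Every point receives exactly one label.
    """
    comps = build_components(points, min_cell_size, connectivity)
    comp_labels = classify_components(comps)
    labels = np.empty(len(points), dtype=np.int64)
    for comp, lab in zip(comps, comp_labels):
        labels[comp.point_indices] = lab
    return labels, comps, comp_labels


def remove_ground(points: np.ndarray, height_above: float = 0.2) -> np.ndarray:
    """Mask of points more than ``height_above`` m over a fitted ground plane.

    The plane z = ax + by + c is fitted by least squares to the lowest
    0.5 m band of the cloud — adequate for the near-level terrain the
    generator produces.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    zmin = pts[:, 2].min()
    low = pts[pts[:, 2] <= zmin + 0.5]
    a = np.column_stack([low[:, 0], low[:, 1], np.ones(len(low))])
    coef, *_ = np.linalg.lstsq(a, low[:, 2], rcond=None)
    plane_z = pts[:, 0] * coef[0] + pts[:, 1] * coef[1] + coef[2]
    return pts[:, 2] - plane_z > height_above
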