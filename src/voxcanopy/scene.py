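"""Renderable canopy scenes: leaf triangles, trunk meshes, soil, clones.

Each leaf voxel is abstracted by one equilateral triangle of fixed one-sided
area (default 400 mm² = 4e-4 m²) centered on the voxel, with a fixed normal
zenith angle (default 42.5°, a plagiophile average for beech) and an azimuth
drawn uniformly from [0°, 360°).  Trunks are open-ended triangle tubes —
reconstructed from points by ball pivoting, or parametric cylinders when
the trunk geometry is known.  A scene clones its core tile on a regular
grid to emulate a laterally extended, homogeneous forest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .ballpivot import ball_pivot, boundary_edge_fraction
from .spectra import Spectrum
from .stand import CLASS_LEAF, CLASS_SOIL, CLASS_TRUNK

log = logging.getLogger(__name__)

__all__ = [
    "LeafTriangle",
    "LeafTriangles",
    "CanopyScene",
    "build_leaves",
    "build_trunk_mesh",
    "cylinder_tube_mesh",
    "clone_scene",
    "build_scene",
]

LEAF_AREA_QUANTUM = 4e-4  # m², one-sided
LEAF_ZENITH_DEG = 42.5


@dataclass
class LeafTriangle:
    vertices: np.ndarray  # (3, 3)
    normal: np.ndarray  # unit
    material: str = "leaf"

    @property
    def area(self) -> float:
        e1 = self.vertices[1] - self.vertices[0]
        e2 = self.vertices[2] - self.vertices[0]
        return 0.5 * float(np.linalg.norm(np.cross(e1, e2)))


class LeafTriangles:
    """Array-of-structs container for many leaf triangles."""

    def __init__(self, vertices: np.ndarray, normals: np.ndarray):
        self.vertices = vertices  # (n, 3, 3)
        self.normals = normals  # (n, 3)

    def __len__(self) -> int:
        return len(self.vertices)

    def __getitem__(self, i: int) -> LeafTriangle:
        return LeafTriangle(self.vertices[i], self.normals[i])

    def areas(self) -> np.ndarray:
        e1 = self.vertices[:, 1] - self.vertices[:, 0]
        e2 = self.vertices[:, 2] - self.vertices[:, 0]
        return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)

    def zenith_angles(self) -> np.ndarray:
        """Angle between each normal and +z, radians."""
        return np.arccos(np.clip(self.normals[:, 2], -1.0, 1.0))

    def azimuth_angles(self) -> np.ndarray:
        return np.mod(np.arctan2(self.normals[:, 1], self.normals[:, 0]), 2 * np.pi)


def build_leaves(
    leaf_centers: np.ndarray,
    zenith_deg: float = LEAF_ZENITH_DEG,
    quantum: float = LEAF_AREA_QUANTUM,
    seed: int = 0,
) -> LeafTriangles:
    """One equilateral triangle per leaf center.

    The triangle centroid coincides with the center; the normal has the
    fixed zenith angle and an i.i.d. uniform azimuth; the one-sided area is
    exactly ``quantum``.  Normals point into the upper hemisphere (leaves
    are two-sided in the renderer, so the sign is radiometrically neutral).
    """
    centers = np.asarray(leaf_centers, dtype=float).reshape(-1, 3)
    n = len(centers)
    rng = np.random.default_rng(seed)
    theta = np.deg2rad(zenith_deg)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    normals = np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi),
         np.full(n, np.cos(theta))]
    )
    # in-plane frame: u horizontal, v = n x u
    u = np.column_stack([-np.sin(phi), np.cos(phi), np.zeros(n)])
    v = np.cross(normals, u)
    side = np.sqrt(4.0 * quantum / np.sqrt(3.0))
    circum = side / np.sqrt(3.0)
    verts = np.empty((n, 3, 3))
    for k, ang in enumerate((0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)):
        verts[:, k, :] = centers + circum * (np.cos(ang) * u + np.sin(ang) * v)
    return LeafTriangles(verts, normals)


def cylinder_tube_mesh(
    center_xy: tuple[float, float],
    radius: float,
    z0: float,
    z1: float,
    n_segments: int = 24,
) -> trimesh.Trimesh:
    """Open-ended vertical tube (no end caps), bottom at ``z0``."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_segments, endpoint=False)
    ring = np.column_stack([np.cos(theta), np.sin(theta)]) * radius
    bottom = np.column_stack([ring[:, 0] + center_xy[0], ring[:, 1] + center_xy[1],
                              np.full(n_segments, z0)])
    top = bottom.copy()
    top[:, 2] = z1
    verts = np.vstack([bottom, top])
    faces = []
    for i in range(n_segments):
        j = (i + 1) % n_segments
        faces.append([i, j, n_segments + i])
        faces.append([j, n_segments + j, n_segments + i])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def _fit_cylinder_mesh(points: np.ndarray) -> trimesh.Trimesh:
    center = points[:, :2].mean(axis=0)
    radius = float(np.linalg.norm(points[:, :2] - center, axis=1).mean())
    radius = max(radius, 1e-3)
    return cylinder_tube_mesh(tuple(center), radius, points[:, 2].min(), points[:, 2].max())


def build_trunk_mesh(
    points: np.ndarray,
    ball_radius: float | None = None,
    fallback_boundary_fraction: float = 0.2,
) -> trimesh.Trimesh:
    """Triangle mesh of a trunk from its surface points.

    Ball-pivoting reconstruction with ball radius defaulting to 3x the mean
    nearest-neighbor spacing.  If the reconstructed surface leaves more
    than ``fallback_boundary_fraction`` boundary edges, a fitted vertical
    cylinder tube is returned instead (logged).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < 3:
        raise ValueError("need at least 3 points to build a trunk mesh")
    if ball_radius is None:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(points).query(points, k=2)
        ball_radius = 3.0 * float(d[:, 1].mean())
    faces = ball_pivot(points, ball_radius)
    frac = boundary_edge_fraction(faces)
    if frac > fallback_boundary_fraction:
        log.warning(
            "ball pivoting left %.0f%% boundary edges; falling back to a "
            "fitted cylinder tube", 100 * frac,
        )
        return _fit_cylinder_mesh(points)
    return trimesh.Trimesh(vertices=points, faces=faces, process=False)


@dataclass
class CanopyScene:
    """Renderable world: core-tile geometry plus a clone offset grid.

    Core geometry lives in tile coordinates ``[0, tile_width)²``; clones are
    exact translates at ``clone_offsets`` (which always includes the core's
    own offset).  Totals across clones are available as properties; use
    :meth:`materialize` to realize explicit copies.
    """

    leaf_vertices: np.ndarray  # (n, 3, 3)
    trunk_vertices: np.ndarray  # (m, 3, 3)
    soil_vertices: np.ndarray  # (2, 3, 3)
    tile_width: float
    clone_offsets: np.ndarray  # (k, 2) incl. (0, 0) translate of the core
    materials: dict[str, Spectrum] = field(default_factory=dict)

    REQUIRED_MATERIALS = (
        "leaf_reflectance",
        "leaf_transmittance",
        "trunk_reflectance",
        "soil_reflectance",
    )

    @property
    def n_clones(self) -> int:
        return len(self.clone_offsets)

    @property
    def n_leaf_triangles(self) -> int:
        return len(self.leaf_vertices) * self.n_clones

    @property
    def n_triangles(self) -> int:
        core = len(self.leaf_vertices) + len(self.trunk_vertices) + len(self.soil_vertices)
        return core * self.n_clones

    def total_leaf_area(self) -> float:
        if len(self.leaf_vertices) == 0:
            return 0.0
        e1 = self.leaf_vertices[:, 1] - self.leaf_vertices[:, 0]
        e2 = self.leaf_vertices[:, 2] - self.leaf_vertices[:, 0]
        return float(0.5 * np.linalg.norm(np.cross(e1, e2), axis=1).sum()) * self.n_clones

    def core_triangles(self) -> tuple[np.ndarray, np.ndarray]:
        """(triangles (t,3,3), material class per triangle) of the core tile."""
        tris = []
        mats = []
        for verts, cls in (
            (self.leaf_vertices, CLASS_LEAF),
            (self.trunk_vertices, CLASS_TRUNK),
            (self.soil_vertices, CLASS_SOIL),
        ):
            if len(verts):
                tris.append(verts)
                mats.append(np.full(len(verts), cls, dtype=np.int64))
        if not tris:
            return np.empty((0, 3, 3)), np.empty(0, dtype=np.int64)
        return np.concatenate(tris), np.concatenate(mats)

    def materialize(self) -> "CanopyScene":
        """Explicit geometry copies for every clone offset."""
        off3 = np.zeros((self.n_clones, 1, 1, 3))
        off3[:, 0, 0, :2] = self.clone_offsets

        def tile(verts):
            if len(verts) == 0:
                return verts
            return (verts[None, ...] + off3).reshape(-1, 3, 3)

        return CanopyScene(
            leaf_vertices=tile(self.leaf_vertices),
            trunk_vertices=tile(self.trunk_vertices),
            soil_vertices=tile(self.soil_vertices),
            tile_width=self.tile_width,
            clone_offsets=np.zeros((1, 2)),
            materials=dict(self.materials),
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        tris, _ = self.core_triangles()
        lo = tris.reshape(-1, 3).min(axis=0)
        hi = tris.reshape(-1, 3).max(axis=0)
        lo2 = lo.copy()
        hi2 = hi.copy()
        lo2[:2] += self.clone_offsets.min(axis=0)
        hi2[:2] += self.clone_offsets.max(axis=0)
        return lo2, hi2

    def export(self, directory) -> None:
        """Write OBJ per material group plus a JSON manifest."""
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        groups = {
            "leaves": self.leaf_vertices,
            "trunks": self.trunk_vertices,
            "soil": self.soil_vertices,
        }
        manifest = {"tile_width": self.tile_width,
                    "clone_offsets": self.clone_offsets.tolist(),
                    "groups": {}}
        for name, verts in groups.items():
            if len(verts) == 0:
                continue
            flat = verts.reshape(-1, 3)
            faces = np.arange(len(flat)).reshape(-1, 3)
            mesh = trimesh.Trimesh(vertices=flat, faces=faces, process=False)
            path = directory / f"{name}.obj"
            mesh.export(path)
            manifest["groups"][name] = path.name
        for key, spec in self.materials.items():
            spec.to_csv(directory / f"{key}.csv")
        manifest["materials"] = {k: f"{k}.csv" for k in self.materials}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def build_scene(
    leaf_centers: np.ndarray,
    trunk_meshes: list[trimesh.Trimesh],
    tile_width: float,
    materials: dict[str, Spectrum],
    zenith_deg: float = LEAF_ZENITH_DEG,
    quantum: float = LEAF_AREA_QUANTUM,
    seed: int = 0,
    soil_margin: float = 0.0,
) -> CanopyScene:
    """Assemble a single-tile scene from leaf centers and trunk meshes."""
    leaves = build_leaves(leaf_centers, zenith_deg=zenith_deg, quantum=quantum, seed=seed)
    if trunk_meshes:
        trunk_verts = np.concatenate(
            [m.vertices[m.faces] for m in trunk_meshes if len(m.faces)]
        )
    else:
        trunk_verts = np.empty((0, 3, 3))
    w = tile_width
    a, b = -soil_margin, w + soil_margin
    soil = np.array(
        [
            [[a, a, 0.0], [b, a, 0.0], [b, b, 0.0]],
            [[a, a, 0.0], [b, b, 0.0], [a, b, 0.0]],
        ]
    )
    return CanopyScene(
        leaf_vertices=leaves.vertices,
        trunk_vertices=trunk_verts,
        soil_vertices=soil,
        tile_width=tile_width,
        clone_offsets=np.zeros((1, 2)),
        materials=materials,
    )


def clone_scene(core: CanopyScene, grid_n: int = 5) -> CanopyScene:
    """Tile the core scene on a centered ``grid_n`` x ``grid_n`` grid.

    ``grid_n = 5`` adds 24 clone instances around a 30 m core, producing a
    150 x 150 m homogeneous forest block with the core in the central tile.
    """
    if grid_n < 1:
        raise ValueError("grid_n must be >= 1")
    w = core.tile_width
    half = (grid_n - 1) // 2
    shift = np.arange(grid_n) - half
    offsets = np.array([(i * w, j * w) for i in shift for j in shift], dtype=float)
    return CanopyScene(
        leaf_vertices=core.leaf_vertices,
        trunk_vertices=core.trunk_vertices,
        soil_vertices=core.soil_vertices,
        tile_width=w,
        clone_offsets=offsets,
        materials=dict(core.materials),
    )
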