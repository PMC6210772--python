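"""TLS scan simulation on organized azimuth × elevation grids.

Each scanner position fires one ray per grid cell; only the first surface
hit per ray produces a return (z-buffer contract), emulating occlusion.
"Ghost" returns — the mixed-pixel artifact of phase-shift scanners — are
injected on rays whose neighborhood spans a depth discontinuity, at a
uniformly random range strictly between the near and far surface, replacing
the true return.  Every return carries a ground-truth class (leaf, trunk,
soil, sphere, ghost) so filters and classifiers can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from . import tracing
from .scene import build_leaves, cylinder_tube_mesh
from .stand import (
    CLASS_GHOST,
    CLASS_LEAF,
    CLASS_SOIL,
    CLASS_SPHERE,
    CLASS_TRUNK,
    Stand,
)

__all__ = ["ScanSetup", "ScanGrid", "simulate_scan", "stand_surface_triangles"]


@dataclass
class ScanSetup:
    """Multi-scan acquisition parameters.

    Angular resolution defaults to 0.036°, typical of a phase-shift
    scanner; the azimuth/elevation windows keep synthetic scans affordable
    and default to a full panorama.
    """

    scanner_positions: list = field(default_factory=lambda: [np.array([15.0, 15.0, 1.5])])
    sphere_targets: list = field(default_factory=list)  # [(center (3,), radius), ...]
    angular_resolution: float = 0.036  # degrees
    max_range: float = 76.0
    ghost_point_rate: float = 0.0
    azimuth_window: tuple[float, float] = (0.0, 360.0)
    elevation_window: tuple[float, float] = (-30.0, 90.0)
    ghost_depth_gap: float = 0.5  # m; discontinuity that can spawn a ghost

    def __post_init__(self) -> None:
        if self.max_range <= 0:
            raise ValueError("max_range must be > 0")
        if not (0.0 <= self.ghost_point_rate <= 1.0):
            raise ValueError("ghost_point_rate must be in [0, 1]")
        if self.angular_resolution <= 0:
            raise ValueError("angular_resolution must be > 0")


@dataclass
class ScanGrid:
    """One organized scan: per-cell range and 3-D point on an az × el raster.

    ``range`` is NaN where the ray produced no return; ``points`` rows are
    consistent with (azimuth, elevation, range) around ``scanner_position``.
    ``labels`` holds ground-truth classes (-1 where no return).
    """

    azimuth_deg: np.ndarray  # (cols,)
    elevation_deg: np.ndarray  # (rows,)
    range: np.ndarray  # (rows, cols), NaN = no return
    points: np.ndarray  # (rows, cols, 3)
    scanner_position: np.ndarray  # (3,)
    labels: np.ndarray | None = None  # (rows, cols) int, -1 = no return

    @property
    def shape(self) -> tuple[int, int]:
        return self.range.shape

    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.range)

    def directions(self) -> np.ndarray:
        """(rows, cols, 3) unit ray directions."""
        az = np.deg2rad(self.azimuth_deg)[None, :]
        el = np.deg2rad(self.elevation_deg)[:, None]
        return np.stack(
            [np.cos(el) * np.cos(az) + 0 * az,
             np.cos(el) * np.sin(az) + 0 * az,
             np.sin(el) + 0 * az],
            axis=-1,
        )

    def to_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten valid cells to (points (n,3), labels (n,))."""
        m = self.valid_mask()
        pts = self.points[m]
        if self.labels is None:
            labels = np.full(len(pts), -1, dtype=np.int64)
        else:
            labels = self.labels[m]
        return pts, labels

    def consistency_error(self) -> float:
        """Max |point − (scanner + range·direction)| over valid cells, m."""
        m = self.valid_mask()
        if not m.any():
            return 0.0
        recon = self.scanner_position + self.range[m, None] * self.directions()[m]
        return float(np.abs(recon - self.points[m]).max())

    def transformed(self, rotation_z_deg: float, new_origin: np.ndarray) -> "ScanGrid":
        """Express the scan in a frame rotated by yaw and translated.

        A pure yaw keeps the raster structure intact: azimuth columns shift,
        elevations and ranges are invariant.
        """
        yaw = np.deg2rad(rotation_z_deg)
        c, s = np.cos(yaw), np.sin(yaw)
        rz = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])  # R_z(-yaw)
        pts = (self.points - self.scanner_position) @ rz.T + new_origin
        return ScanGrid(
            azimuth_deg=np.mod(self.azimuth_deg - rotation_z_deg, 360.0),
            elevation_deg=self.elevation_deg.copy(),
            range=self.range.copy(),
            points=pts,
            scanner_position=np.asarray(new_origin, dtype=float),
            labels=None if self.labels is None else self.labels.copy(),
        )


def stand_surface_triangles(
    stand: Stand,
    sphere_targets: list | None = None,
    leaf_seed: int = 0,
    soil_margin: float = 5.0,
    sphere_subdivisions: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth surface soup of a stand: (triangles, class per triangle).

    Leaves become fixed-area triangles (same abstraction the renderer
    uses), trunks open tubes, soil a plane quad, reference spheres
    icospheres.
    """
    p = stand.params
    tris = []
    classes = []
    if len(stand.leaf_positions):
        leaves = build_leaves(stand.leaf_positions, quantum=p.leaf_quantum, seed=leaf_seed)
        tris.append(leaves.vertices)
        classes.append(np.full(len(leaves), CLASS_LEAF, dtype=np.int64))
    for tree in stand.trees:
        tube = cylinder_tube_mesh((tree.x, tree.y), tree.trunk_radius, 0.0, tree.crown_base)
        tris.append(tube.vertices[tube.faces])
        classes.append(np.full(len(tube.faces), CLASS_TRUNK, dtype=np.int64))
    a, b = -soil_margin, p.plot_size + soil_margin
    soil = np.array(
        [[[a, a, 0.0], [b, a, 0.0], [b, b, 0.0]],
         [[a, a, 0.0], [b, b, 0.0], [a, b, 0.0]]]
    )
    tris.append(soil)
    classes.append(np.full(2, CLASS_SOIL, dtype=np.int64))
    for center, radius in sphere_targets or []:
        ico = trimesh.creation.icosphere(subdivisions=sphere_subdivisions, radius=radius)
        tris.append(np.asarray(ico.vertices[ico.faces]) + np.asarray(center))
        classes.append(np.full(len(ico.faces), CLASS_SPHERE, dtype=np.int64))
    return np.concatenate(tris), np.concatenate(classes)


def _inject_ghosts(
    rng: np.random.Generator,
    rng_grid: np.ndarray,
    labels: np.ndarray,
    rate: float,
    depth_gap: float,
) -> np.ndarray:
    """Replace a fraction of edge-grazing returns by mixed-pixel ghosts.

    A candidate ray has its own hit at r0 and an 8-neighbor hit at
    r1 > r0 + depth_gap; the ghost range is uniform strictly inside
    (r0, r1).  Returns the new range array; ``labels`` is updated in place.
    """
    rows, cols = rng_grid.shape
    far = np.full((rows, cols), np.nan)
    pad = np.pad(rng_grid, 1, constant_values=np.nan)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = pad[1 + dr : 1 + dr + rows, 1 + dc : 1 + dc + cols]
            cand = (nb - rng_grid) > depth_gap
            upd = cand & (np.isnan(far) | (nb < far))
            far[upd] = nb[upd]
    candidates = np.isfinite(far) & np.isfinite(rng_grid)
    pick = candidates & (rng.random(rng_grid.shape) < rate)
    if not pick.any():
        return rng_grid
    r0 = rng_grid[pick]
    r1 = far[pick]
    u = rng.random(r0.shape)
    ghost = r0 + (0.02 + 0.96 * u) * (r1 - r0)
    out = rng_grid.copy()
    out[pick] = ghost
    labels[pick] = CLASS_GHOST
    return out


def simulate_scan(
    stand: Stand,
    setup: ScanSetup,
    leaf_seed: int = 0,
    ghost_seed: int = 1,
    triangles: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[ScanGrid]:
    """Simulate one ScanGrid per scanner position (world frame).

    ``triangles`` may supply a pre-built (soup, classes) pair; otherwise the
    stand's ground-truth surfaces (plus sphere targets) are generated.
    """
    if triangles is None:
        tris, classes = stand_surface_triangles(stand, setup.sphere_targets, leaf_seed)
    else:
        tris, classes = triangles
    bvh = tracing.build_bvh(tris)
    classes_sorted = classes[bvh.order]
    offsets = np.zeros((1, 2))
    res = setup.angular_resolution
    az = np.arange(setup.azimuth_window[0], setup.azimuth_window[1], res)
    el = np.arange(setup.elevation_window[0], setup.elevation_window[1], res)
    ghost_rng = np.random.default_rng(ghost_seed)
    grids = []
    for pos in setup.scanner_positions:
        pos = np.asarray(pos, dtype=float)
        azr = np.deg2rad(az)[None, :]
        elr = np.deg2rad(el)[:, None]
        dirs = np.stack(
            [np.cos(elr) * np.cos(azr) + 0 * azr,
             np.cos(elr) * np.sin(azr) + 0 * azr,
             np.sin(elr) + 0 * azr],
            axis=-1,
        ).reshape(-1, 3)
        t, i, _ = tracing.cast_rays(
            pos, np.ascontiguousarray(dirs), 1e-9, setup.max_range,
            offsets, *bvh.args(),
        )
        hit = i >= 0
        rng_grid = np.where(hit, t, np.nan).reshape(len(el), len(az))
        labels = np.where(hit, classes_sorted[np.where(hit, i, 0)], -1)
        labels = labels.reshape(len(el), len(az)).astype(np.int64)
        if setup.ghost_point_rate > 0:
            rng_grid = _inject_ghosts(
                ghost_rng, rng_grid, labels, setup.ghost_point_rate, setup.ghost_depth_gap
            )
        pts = pos + np.where(np.isnan(rng_grid), 0.0, rng_grid)[..., None] * dirs.reshape(
            len(el), len(az), 3
        )
        pts[np.isnan(rng_grid)] = np.nan
        grids.append(
            ScanGrid(
                azimuth_deg=az, elevation_deg=el, range=rng_grid,
                points=pts, scanner_position=pos, labels=labels,
            )
        )
    return grids
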