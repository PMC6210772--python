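"""Voxelized canopy: occupancy grid, LAI/LAD, and structural manipulation.

Labeled points are binned into cubic voxels (default 2 cm); a voxel is
filled when it contains at least one return, and carries a class (leaf or
trunk; trunk wins ties).  Each leaf voxel represents a fixed one-sided leaf
area quantum (default 4e-4 m² = 400 mm²), which makes LAI pure bookkeeping:

    LAI = n_leaf_voxels · quantum / ground_area

and the leaf area density profile LAD(z) follows by counting leaf voxels in
horizontal layers.  Structural manipulations operate on the leaf voxel set:
``reduce_lai`` empties a per-layer fraction (thinning every layer equally,
so the LAD profile scales), ``translate_lad`` moves leaf area from the
upper canopy into lower layers while conserving total LAI exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "VoxelGrid",
    "LADProfile",
    "voxelize",
    "lad_profile",
    "reduce_lai",
    "translate_lad",
]

DEFAULT_VOXEL_SIDE = 0.02
DEFAULT_QUANTUM = 4e-4


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class VoxelGrid:
    """Sparse occupancy grid with per-voxel class.

    ``leaf_cells``/``trunk_cells`` hold integer cell indices (k, 3); a cell
    covers the half-open cube ``origin + side·[i, i+1)`` per axis.
    ``ground_area`` is the reference ground area for LAI bookkeeping.
    """

    origin: np.ndarray  # (3,)
    side: float
    dims: np.ndarray  # (3,) int
    leaf_cells: np.ndarray  # (n, 3) int64, unique rows
    trunk_cells: np.ndarray  # (m, 3) int64, unique rows
    ground_area: float

    @property
    def n_leaf(self) -> int:
        return len(self.leaf_cells)

    @property
    def n_trunk(self) -> int:
        return len(self.trunk_cells)

    @property
    def n_filled(self) -> int:
        return self.n_leaf + self.n_trunk

    def leaf_centers(self) -> np.ndarray:
        return self.origin + (self.leaf_cells + 0.5) * self.side

    def trunk_centers(self) -> np.ndarray:
        return self.origin + (self.trunk_cells + 0.5) * self.side

    def lai(self, quantum: float = DEFAULT_QUANTUM) -> float:
        if self.ground_area <= 0:
            raise ValueError("ground_area must be > 0")
        return self.n_leaf * quantum / self.ground_area

    def save(self, path) -> None:
        """Sparse cell lists (binary npz) + embedded header."""
        np.savez_compressed(
            path,
            origin=self.origin, side=self.side, dims=self.dims,
            leaf_cells=self.leaf_cells, trunk_cells=self.trunk_cells,
            ground_area=self.ground_area,
        )

    @classmethod
    def load(cls, path) -> "VoxelGrid":
        z = np.load(path)
        return cls(
            origin=z["origin"], side=float(z["side"]), dims=z["dims"],
            leaf_cells=z["leaf_cells"], trunk_cells=z["trunk_cells"],
            ground_area=float(z["ground_area"]),
        )


@dataclass
class LADProfile:
    """Vertical leaf-area-density profile in uniform layers."""

    edges: np.ndarray  # (n_layers + 1,) m
    lad: np.ndarray  # (n_layers,) m²/m³
    leaf_area_quantum: float
    ground_area: float

    @property
    def layer_dz(self) -> float:
        return float(self.edges[1] - self.edges[0]) if len(self.edges) > 1 else 0.0

    @property
    def lai(self) -> float:
        return float(np.sum(self.lad) * self.layer_dz)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"z_low": self.edges[:-1], "z_high": self.edges[1:], "lad": self.lad}
        ).to_csv(path, index=False)


def voxelize(
    points: np.ndarray,
    labels: np.ndarray | None = None,
    side: float = DEFAULT_VOXEL_SIDE,
    origin: np.ndarray | None = None,
    ground_area: float | None = None,
) -> VoxelGrid:
    """Bin labeled points into a voxel grid (half-open cells).

    ``labels``: 0 = leaf, 1 = trunk per point (all-leaf when omitted).  A
    filled voxel is trunk when any trunk point falls inside it, else leaf.
    An empty input yields a valid empty grid.
    """
    if side <= 0:
        raise ValueError("voxel side must be > 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if labels is None:
        labels = np.zeros(len(pts), dtype=np.int64)
    labels = np.asarray(labels)
    if origin is None:
        origin = np.zeros(3) if len(pts) == 0 else np.floor(pts.min(axis=0) / side) * side
    origin = np.asarray(origin, dtype=float)
    if len(pts) == 0:
        return VoxelGrid(origin, side, np.zeros(3, dtype=np.int64),
                         np.empty((0, 3), dtype=np.int64),
                         np.empty((0, 3), dtype=np.int64),
                         ground_area if ground_area else 0.0)
    idx = np.floor((pts - origin) / side).astype(np.int64)
    dims = idx.max(axis=0) + 1
    # unique cells with a trunk-wins class resolution
    key = (idx[:, 0] * dims[1] + idx[:, 1]) * dims[2] + idx[:, 2]
    order = np.argsort(key, kind="stable")
    k_sorted = key[order]
    is_trunk = (labels[order] == 1).astype(np.int64)
    uniq, start = np.unique(k_sorted, return_index=True)
    trunk_any = np.maximum.reduceat(is_trunk, start) > 0
    cells = np.column_stack(
        [uniq // (dims[1] * dims[2]), (uniq // dims[2]) % dims[1], uniq % dims[2]]
    )
    if ground_area is None:
        ground_area = float(dims[0] * dims[1]) * side * side
    return VoxelGrid(
        origin=origin, side=side, dims=dims,
        leaf_cells=np.ascontiguousarray(cells[~trunk_any]),
        trunk_cells=np.ascontiguousarray(cells[trunk_any]),
        ground_area=ground_area,
    )


def _layer_of(grid: VoxelGrid, cells: np.ndarray, layer_dz: float) -> np.ndarray:
    """Layer index of each cell, from voxel-center z, layers at grid origin."""
    zc = grid.origin[2] + (cells[:, 2] + 0.5) * grid.side
    return np.floor((zc - grid.origin[2]) / layer_dz).astype(np.int64)


def lad_profile(
    grid: VoxelGrid,
    layer_dz: float = 1.0,
    quantum: float = DEFAULT_QUANTUM,
) -> LADProfile:
    """Leaf area density per horizontal layer; trunk voxels excluded.

    ``layer_dz`` must be an integer multiple of the voxel side so every
    voxel belongs to exactly one layer.
    """
    if grid.ground_area <= 0:
        raise ValueError("ground_area must be > 0 for a LAD profile")
    ratio = layer_dz / grid.side
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("layer_dz must be a multiple of the voxel side")
    if grid.n_leaf == 0:
        edges = grid.origin[2] + layer_dz * np.arange(2)
        return LADProfile(edges, np.zeros(1), quantum, grid.ground_area)
    layers = _layer_of(grid, grid.leaf_cells, layer_dz)
    n_layers = int(layers.max()) + 1
    counts = np.bincount(layers, minlength=n_layers)
    lad = counts * quantum / (grid.ground_area * layer_dz)
    edges = grid.origin[2] + layer_dz * np.arange(n_layers + 1)
    return LADProfile(edges, lad, quantum, grid.ground_area)


def reduce_lai(
    grid: VoxelGrid,
    fraction: float,
    seed: int = 0,
    layer_dz: float = 1.0,
) -> VoxelGrid:
    """Empty ``round(f·n)`` leaf voxels per height layer, uniformly at random.

    Thinning each layer by the same fraction scales the LAD profile by
    (1 − f) within one voxel quantum per layer; trunk voxels are untouched.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0.0 or grid.n_leaf == 0:
        return replace(grid, leaf_cells=grid.leaf_cells.copy())
    rng = np.random.default_rng(seed)
    layers = _layer_of(grid, grid.leaf_cells, layer_dz)
    keep = np.ones(grid.n_leaf, dtype=bool)
    for layer in np.unique(layers):
        members = np.flatnonzero(layers == layer)
        k = _round_half_away(fraction * len(members))
        if k > 0:
            drop = rng.choice(members, size=k, replace=False)
            keep[drop] = False
    return replace(grid, leaf_cells=np.ascontiguousarray(grid.leaf_cells[keep]))


def _encode(cells: np.ndarray, m1: int, m2: int) -> np.ndarray:
    return (cells[:, 0] * m1 + cells[:, 1]) * m2 + cells[:, 2]


def _decode(keys: np.ndarray, m1: int, m2: int) -> np.ndarray:
    return np.column_stack([keys // (m1 * m2), (keys // m2) % m1, keys % m2])


def _in_sorted(keys: np.ndarray, sorted_keys: np.ndarray) -> np.ndarray:
    pos = np.searchsorted(sorted_keys, keys)
    pos = np.minimum(pos, max(len(sorted_keys) - 1, 0))
    if len(sorted_keys) == 0:
        return np.zeros(len(keys), dtype=bool)
    return sorted_keys[pos] == keys


def _receiving_candidates(
    grid: VoxelGrid,
    layer: int,
    layer_dz: float,
    floor_height: float,
    split_height: float,
    occupied_sorted: np.ndarray,
    hull,
    xy_bbox: tuple[int, int, int, int],
    quota: int,
    rng: np.random.Generator,
    m1: int,
    m2: int,
) -> np.ndarray:
    """Sample ``quota`` empty cells inside the layer's convex footprint."""
    x0, x1, y0, y1 = xy_bbox
    # z sheets of this layer whose voxel centers satisfy the height window
    z_lo = layer * layer_dz / grid.side
    sheets = np.arange(int(round(z_lo)), int(round(z_lo + layer_dz / grid.side)))
    zc = grid.origin[2] + (sheets + 0.5) * grid.side
    sheets = sheets[(zc > floor_height) & (zc < split_height)]
    if len(sheets) == 0:
        raise ValueError(
            f"insufficient empty voxels in receiving layer {layer}: deficit {quota}"
        )
    chosen = np.empty(0, dtype=np.int64)
    for _ in range(60):
        if len(chosen) >= quota:
            break
        m = max(4 * (quota - len(chosen)), 1024)
        xs = rng.integers(x0, x1 + 1, size=m)
        ys = rng.integers(y0, y1 + 1, size=m)
        zs = rng.choice(sheets, size=m)
        if hull is not None:
            inside = hull.find_simplex(np.column_stack([xs, ys]).astype(float)) >= 0
            xs, ys, zs = xs[inside], ys[inside], zs[inside]
        keys = _encode(np.column_stack([xs, ys, zs]), m1, m2)
        keys = keys[~_in_sorted(keys, occupied_sorted)]
        chosen = np.unique(np.concatenate([chosen, keys]))
    if len(chosen) < quota:
        # exhaustive fallback: enumerate the whole candidate region
        n_region = (x1 - x0 + 1) * (y1 - y0 + 1) * len(sheets)
        if n_region <= 20_000_000:
            gx, gy, gz = np.meshgrid(
                np.arange(x0, x1 + 1), np.arange(y0, y1 + 1), sheets, indexing="ij"
            )
            cells = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
            if hull is not None:
                inside = hull.find_simplex(cells[:, :2].astype(float)) >= 0
                cells = cells[inside]
            keys = _encode(cells, m1, m2)
            chosen = keys[~_in_sorted(keys, occupied_sorted)]
        if len(chosen) < quota:
            raise ValueError(
                f"insufficient empty voxels in receiving layer {layer}: "
                f"deficit {quota - len(chosen)}"
            )
    pick = rng.choice(len(chosen), size=quota, replace=False)
    return _decode(chosen[pick], m1, m2)


def translate_lad(
    grid: VoxelGrid,
    move_fraction: float = 0.5,
    split_height: float = 17.0,
    floor_height: float = 1.3,
    seed: int = 0,
    layer_dz: float = 1.0,
) -> VoxelGrid:
    """Move leaf area from the upper canopy into lower layers, LAI-neutral.

    Exactly ``round(move_fraction · n_upper)`` leaf voxels with center
    z ≥ ``split_height`` are removed (uniformly at random); the same number
    of new leaf voxels is created in currently-empty cells with center z in
    (``floor_height``, ``split_height``), allocated across receiving layers
    proportionally to their existing leaf counts (largest-remainder
    rounding, residue on the most-populated layer) and horizontally inside
    the convex footprint of that layer's leaves.  Total leaf-voxel count —
    hence LAI — is conserved exactly; trunk voxels are untouched.
    """
    if not (0.0 <= move_fraction <= 1.0):
        raise ValueError("move_fraction must be in [0, 1]")
    if split_height <= floor_height:
        raise ValueError("split_height must exceed floor_height")
    if move_fraction == 0.0 or grid.n_leaf == 0:
        return replace(grid, leaf_cells=grid.leaf_cells.copy())
    rng = np.random.default_rng(seed)
    zc = grid.origin[2] + (grid.leaf_cells[:, 2] + 0.5) * grid.side
    upper = np.flatnonzero(zc >= split_height)
    k = _round_half_away(move_fraction * len(upper))
    if k == 0:
        return replace(grid, leaf_cells=grid.leaf_cells.copy())
    drop = rng.choice(upper, size=k, replace=False)
    keep_mask = np.ones(grid.n_leaf, dtype=bool)
    keep_mask[drop] = False

    receiving = np.flatnonzero((zc > floor_height) & (zc < split_height) & keep_mask)
    if len(receiving) == 0:
        raise ValueError("no receiving layers: no existing leaf voxels below the split")
    layers_all = _layer_of(grid, grid.leaf_cells, layer_dz)
    rec_layers = layers_all[receiving]
    uniq_layers, counts = np.unique(rec_layers, return_counts=True)
    # largest-remainder allocation proportional to existing occupancy
    quota_f = k * counts / counts.sum()
    quotas = np.floor(quota_f).astype(np.int64)
    rem = k - quotas.sum()
    if rem > 0:
        frac_order = np.argsort(-(quota_f - quotas), kind="stable")
        quotas[frac_order[:rem]] += 1
    residue = k - quotas.sum()
    quotas[np.argmax(counts)] += residue  # reconcile on the largest layer

    all_cells = np.concatenate([grid.leaf_cells[keep_mask], grid.trunk_cells])
    m1 = int(max(grid.dims[1], all_cells[:, 1].max() + 2))
    m2 = int(max(grid.dims[2], all_cells[:, 2].max() + 2))
    occupied_sorted = np.sort(_encode(all_cells, m1, m2))
    new_cells = []
    for layer, quota in zip(uniq_layers, quotas):
        if quota <= 0:
            continue
        members = grid.leaf_cells[receiving[rec_layers == layer]]
        xy = np.unique(members[:, :2], axis=0)
        hull = None
        if len(xy) >= 4:
            try:
                hull = Delaunay(xy.astype(float))
            except Exception:
                hull = None
        bbox = (int(xy[:, 0].min()), int(xy[:, 0].max()),
                int(xy[:, 1].min()), int(xy[:, 1].max()))
        cells = _receiving_candidates(
            grid, int(layer), layer_dz, floor_height, split_height,
            occupied_sorted, hull, bbox, int(quota), rng, m1, m2,
        )
        occupied_sorted = np.sort(
            np.concatenate([occupied_sorted, _encode(cells, m1, m2)])
        )
        new_cells.append(cells)
    leaf_cells = np.concatenate([grid.leaf_cells[keep_mask]] + new_cells)
    assert len(leaf_cells) == grid.n_leaf
    return replace(grid, leaf_cells=np.ascontiguousarray(leaf_cells))
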