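"""Synthetic beech-stand generator.

Emulates an even-aged broad-leaved stand (defaults: 223 trees/ha, mean DBH
40.4 cm, mean height 32.3 m, crown base 14.3 m, target LAI 2.32 m²/m²) on a
square plot.  Crowns are prolate ellipsoids between crown base and tree top;
leaf "positions" are centers of distinct cells of a 2 cm lattice, sampled
with a beta-shaped vertical density peaking at the configured height band.
Placing leaves on distinct lattice cells makes the stand's leaf count — and
hence its LAI at the configured per-leaf area quantum — exact by
construction, and voxelizing the ground truth reproduces it cell for cell.

Every generated element carries a ground-truth class so downstream filtering
and classification stages can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StandParameters", "Tree", "Stand", "generate_stand", "stand_point_cloud"]

#: ground-truth / material class codes used across the package
CLASS_LEAF = 0
CLASS_TRUNK = 1
CLASS_SOIL = 2
CLASS_SPHERE = 3
CLASS_GHOST = 4

CLASS_NAMES = {
    CLASS_LEAF: "leaf",
    CLASS_TRUNK: "trunk",
    CLASS_SOIL: "soil",
    CLASS_SPHERE: "sphere",
    CLASS_GHOST: "ghost",
}


@dataclass
class StandParameters:
    """Stand-level description of the synthetic forest.

    All lengths in meters.  ``target_lai`` is one-sided leaf area per unit
    ground area; each leaf contributes ``leaf_quantum`` m² so the generated
    leaf count is ``round(target_lai * plot_size² / leaf_quantum)``.
    """

    trees_per_ha: float = 223.0
    dbh_mean: float = 0.404
    tree_height_mean: float = 32.3
    crown_base_height: float = 14.3
    plot_size: float = 30.0
    target_lai: float = 2.32
    lad_peak_height_range: tuple[float, float] = (20.0, 25.0)
    rng_seed: int = 0
    # free structural choices (see methods note)
    crown_radius: float = 5.5
    crown_lift: float = 1.0  # bole top to lowest foliage (branch standoff)
    min_spacing: float = 4.0
    leaf_quantum: float = 4e-4
    lattice_side: float = 0.02
    height_rel_sd: float = 0.04
    dbh_rel_sd: float = 0.08

    def __post_init__(self) -> None:
        for name in ("dbh_mean", "tree_height_mean", "crown_base_height",
                     "plot_size", "crown_radius", "leaf_quantum", "lattice_side"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.trees_per_ha < 0:
            raise ValueError("trees_per_ha must be >= 0")
        if self.crown_base_height >= self.tree_height_mean:
            raise ValueError("crown_base_height must be below tree_height_mean")
        if self.target_lai < 0:
            raise ValueError("target_lai must be >= 0")
        lo, hi = self.lad_peak_height_range
        if not (lo < hi):
            raise ValueError("lad_peak_height_range must be (low, high) with low < high")

    @property
    def n_trees(self) -> int:
        return int(round(self.trees_per_ha * self.plot_size**2 / 1e4))

    @property
    def n_leaves(self) -> int:
        return int(round(self.target_lai * self.plot_size**2 / self.leaf_quantum))


@dataclass
class Tree:
    x: float
    y: float
    height: float
    crown_base: float
    dbh: float
    crown_radius: float

    @property
    def trunk_radius(self) -> float:
        return self.dbh / 2.0


@dataclass
class Stand:
    """A generated stand: tree list plus exact leaf positions.

    ``leaf_positions`` are centers of distinct ``lattice_side`` cells, so
    ``len(leaf_positions) * leaf_quantum / plot_size²`` equals the target
    LAI up to the rounding of the leaf count.
    """

    params: StandParameters
    trees: list[Tree]
    leaf_positions: np.ndarray  # (N, 3)

    @property
    def lai(self) -> float:
        return len(self.leaf_positions) * self.params.leaf_quantum / self.params.plot_size**2

    def leaf_height_histogram(self, dz: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """(edges, counts) of leaf heights in layers of thickness ``dz``."""
        zmax = max((t.height for t in self.trees), default=0.0)
        edges = np.arange(0.0, zmax + dz, dz)
        counts, _ = np.histogram(self.leaf_positions[:, 2], bins=edges)
        return edges, counts


def _beta_params_for_mode(mode_frac: float, a: float = 3.0) -> tuple[float, float]:
    """Beta(a, b) whose mode is at ``mode_frac`` of the unit interval."""
    m = min(max(mode_frac, 0.05), 0.95)
    b = 1.0 + (a - 1.0) * (1.0 - m) / m
    return a, b


def _place_trees(params: StandParameters, rng: np.random.Generator) -> list[Tree]:
    n = params.n_trees
    positions: list[tuple[float, float]] = []
    spacing = params.min_spacing
    attempts = 0
    while len(positions) < n:
        x, y = rng.uniform(0.0, params.plot_size, size=2)
        ok = all((x - px) ** 2 + (y - py) ** 2 >= spacing**2 for px, py in positions)
        if ok:
            positions.append((x, y))
        attempts += 1
        if attempts > 2000 * n:
            # plot too crowded for the requested spacing; relax it
            spacing *= 0.8
            attempts = 0
    trees = []
    for x, y in positions:
        h = params.tree_height_mean * (1.0 + params.height_rel_sd * rng.standard_normal())
        h = max(h, params.crown_base_height + 1.0)
        dbh = params.dbh_mean * max(0.3, 1.0 + params.dbh_rel_sd * rng.standard_normal())
        trees.append(
            Tree(x, y, h, params.crown_base_height, dbh, params.crown_radius)
        )
    return trees


def _sample_crown_leaves(
    tree: Tree,
    n: int,
    peak_range: tuple[float, float],
    rng: np.random.Generator,
    lift: float = 0.0,
) -> np.ndarray:
    """Sample ``n`` points inside the tree's prolate-ellipsoid crown.

    ``lift`` raises the foliage envelope above the bole top: the lowest
    leaves of a closed-canopy broadleaf sit on branches that leave the
    trunk at the crown base and arch upward, not on the bole itself.
    """
    base = min(tree.crown_base + lift, tree.height - 1.0)
    top = tree.height
    zc, rz = 0.5 * (base + top), 0.5 * (top - base)
    mode_z = 0.5 * (peak_range[0] + peak_range[1])
    a, b = _beta_params_for_mode((mode_z - base) / (top - base))
    z = base + (top - base) * rng.beta(a, b, size=n)
    u = (z - zc) / rz
    rmax = tree.crown_radius * np.sqrt(np.maximum(1.0 - u**2, 0.0))
    r = rmax * np.sqrt(rng.random(n))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([tree.x + r * np.cos(phi), tree.y + r * np.sin(phi), z])


def generate_stand(params: StandParameters) -> Stand:
    """Generate a stand with an exact leaf count matching the target LAI.

    Raises
    ------
    ValueError
        If the plot is too small to hold a single tree at the requested
        density (``trees_per_ha > 0`` but the rounded count is zero).
    """
    rng = np.random.default_rng(params.rng_seed)
    if params.trees_per_ha == 0:
        return Stand(params, [], np.empty((0, 3)))
    if params.n_trees < 1:
        raise ValueError(
            f"plot of {params.plot_size} m holds no tree at "
            f"{params.trees_per_ha} trees/ha; enlarge the plot"
        )
    trees = _place_trees(params, rng)
    n_leaves = params.n_leaves
    if n_leaves == 0:
        return Stand(params, trees, np.empty((0, 3)))

    volumes = np.array(
        [t.crown_radius**2 * (t.height - t.crown_base) for t in trees]
    )
    weights = volumes / volumes.sum()

    side = params.lattice_side
    seen: np.ndarray | None = None  # unique occupied cells (k,3) int64
    chunks: list[np.ndarray] = []
    need = n_leaves
    while need > 0:
        batch = int(need * 1.15) + 64
        counts = rng.multinomial(batch, weights)
        pts = np.concatenate(
            [
                _sample_crown_leaves(t, c, params.lad_peak_height_range, rng,
                                     lift=params.crown_lift)
                for t, c in zip(trees, counts)
                if c > 0
            ]
        )
        # crowns may overhang the plot edge: wrap toroidally so the tile
        # clones seamlessly into a homogeneous forest
        pts[:, :2] %= params.plot_size
        cells = np.floor(pts / side).astype(np.int64)
        if seen is None:
            all_cells = cells
        else:
            all_cells = np.concatenate([seen, cells])
        seen = np.unique(all_cells, axis=0)
        need = n_leaves - len(seen)
    order = rng.permutation(len(seen))
    cells = seen[order[:n_leaves]]
    leaf_positions = (cells + 0.5) * side
    return Stand(params, trees, leaf_positions)


def stand_point_cloud(
    stand: Stand,
    trunk_point_spacing: float = 0.03,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled ground-truth point cloud of a stand (no occlusion).

    Trunk cylinders are sampled on a regular surface grid at roughly
    ``trunk_point_spacing``; leaves contribute their positions.  Returns
    ``(points (n,3), classes (n,))`` with classes in {CLASS_LEAF,
    CLASS_TRUNK}.  Used to exercise classification independently of the
    scan simulator.
    """
    rng = rng or np.random.default_rng(stand.params.rng_seed + 1)
    pts = [stand.leaf_positions]
    cls = [np.full(len(stand.leaf_positions), CLASS_LEAF, dtype=np.int64)]
    for tree in stand.trees:
        r = tree.trunk_radius
        n_theta = max(6, int(round(2 * np.pi * r / trunk_point_spacing)))
        n_z = max(2, int(round(tree.crown_base / trunk_point_spacing)))
        theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
        z = np.linspace(0.0, tree.crown_base, n_z)
        tt, zz = np.meshgrid(theta, z)
        p = np.column_stack(
            [
                tree.x + r * np.cos(tt).ravel(),
                tree.y + r * np.sin(tt).ravel(),
                zz.ravel(),
            ]
        )
        pts.append(p)
        cls.append(np.full(len(p), CLASS_TRUNK, dtype=np.int64))
    return np.concatenate(pts), np.concatenate(cls)
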