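import numpy as np
import pytest

from voxcanopy.filtering import FilterParameters, filter_ghost_points
from voxcanopy.scan import ScanSetup, ScanGrid, simulate_scan, stand_surface_triangles
from voxcanopy.stand import CLASS_GHOST, CLASS_SOIL, CLASS_SPHERE, StandParameters, generate_stand


@pytest.fixture(scope="module")
def scan_fixture(small_stand):
    setup = ScanSetup(
        scanner_positions=[np.array([4.0, 4.0, 1.5])],
        sphere_targets=[
            (np.array([2.0, 2.0, 1.2]), 0.0725),
            (np.array([6.0, 2.5, 1.3]), 0.0725),
            (np.array([3.0, 6.0, 1.1]), 0.0725),
        ],
        angular_resolution=0.15,
        ghost_point_rate=0.3,
        azimuth_window=(0.0, 360.0),
        elevation_window=(-25.0, 80.0),
    )
    return simulate_scan(small_stand, setup, leaf_seed=3, ghost_seed=5)[0], setup


def test_returns_lie_on_rays_and_points_consistent(scan_fixture):
    grid, _ = scan_fixture
    assert grid.consistency_error() < 1e-6


def test_clean_scan_returns_lie_on_surfaces(small_stand):
    setup = ScanSetup(
        scanner_positions=[np.array([4.0, 4.0, 1.5])],
        angular_resolution=0.4, ghost_point_rate=0.0,
        azimuth_window=(0.0, 90.0), elevation_window=(-20.0, 60.0),
    )
    grid = simulate_scan(small_stand, setup, leaf_seed=3)[0]
    # re-trace every return against the exact surface soup: the recorded
    # range must match the true first hit to well under a millimeter
    tris, classes = stand_surface_triangles(small_stand, None, leaf_seed=3)
    from voxcanopy import tracing
    bvh = tracing.build_bvh(tris)
    m = grid.valid_mask()
    dirs = grid.directions()[m]
    t, i, _ = tracing.cast_rays(
        np.asarray(grid.scanner_position), np.ascontiguousarray(dirs),
        1e-9, setup.max_range, np.zeros((1, 2)), *bvh.args(),
    )
    assert np.abs(t - grid.range[m]).max() < 1e-3


def test_occlusion_only_first_hit_returns(small_stand):
    # two parallel walls: every return must be on the near wall
    wall1 = np.array([[[5.0, -50, -50], [5.0, 50, -50], [5.0, 0, 100]]])
    wall2 = np.array([[[9.0, -50, -50], [9.0, 50, -50], [9.0, 0, 100]]])
    tris = np.concatenate([wall1, wall2])
    classes = np.array([CLASS_SOIL, CLASS_SOIL])
    setup = ScanSetup(
        scanner_positions=[np.zeros(3)], angular_resolution=0.5,
        azimuth_window=(-20.0, 20.0), elevation_window=(-20.0, 20.0),
    )
    grid = simulate_scan(generate_stand(StandParameters(trees_per_ha=0.0)),
                         setup, triangles=(tris, classes))[0]
    r = grid.range[grid.valid_mask()]
    assert len(r) > 0
    assert r.max() < 6.0  # nothing beyond the first wall


def test_ghosts_flagged_and_strictly_behind_true_surface(small_stand, scan_fixture):
    grid, setup = scan_fixture
    ghosts = (grid.labels == CLASS_GHOST) & grid.valid_mask()
    assert ghosts.sum() > 100
    # a ghost replaces the true first return and sits strictly beyond it
    # (between the near surface and a farther one seen by a neighbor ray)
    tris, classes = stand_surface_triangles(small_stand, setup.sphere_targets, leaf_seed=3)
    from voxcanopy import tracing
    bvh = tracing.build_bvh(tris)
    dirs = grid.directions()[ghosts]
    t_true, i_true, _ = tracing.cast_rays(
        np.asarray(grid.scanner_position), np.ascontiguousarray(dirs),
        1e-9, setup.max_range, np.zeros((1, 2)), *bvh.args(),
    )
    r_ghost = grid.range[ghosts]
    hit = i_true >= 0
    assert hit.all()
    assert np.all(r_ghost > t_true - 1e-6)
    assert np.all(r_ghost <= setup.max_range)


def test_ghost_rate_zero_means_no_ghosts(small_stand):
    setup = ScanSetup(
        scanner_positions=[np.array([4.0, 4.0, 1.5])],
        angular_resolution=0.4, ghost_point_rate=0.0,
        azimuth_window=(0.0, 90.0), elevation_window=(-20.0, 60.0),
    )
    grid = simulate_scan(small_stand, setup, leaf_seed=3)[0]
    assert not np.any(grid.labels == CLASS_GHOST)


def test_sphere_targets_produce_dense_front_returns(scan_fixture):
    grid, setup = scan_fixture
    sphere_pts = grid.points[(grid.labels == CLASS_SPHERE) & grid.valid_mask()]
    assert len(sphere_pts) > 50
    # returns lie on a target sphere's front (scanner-facing) hemisphere
    from voxcanopy.registration import fit_sphere
    centers = np.array([c for c, _ in setup.sphere_targets])
    d = np.linalg.norm(sphere_pts[:, None, :] - centers[None], axis=2).min(axis=1)
    assert np.all(d < 0.08)


def test_two_scans_related_by_rigid_transform(scan_fixture):
    grid, setup = scan_fixture
    local = grid.transformed(rotation_z_deg=40.0, new_origin=np.zeros(3))
    assert local.consistency_error() < 1e-6
    # ranges invariant; points rotated/translated
    np.testing.assert_allclose(local.range[local.valid_mask()],
                               grid.range[grid.valid_mask()])


def test_ghost_filter_recall_and_precision_on_labeled_scan(scan_fixture):
    grid, _ = scan_fixture
    keep = filter_ghost_points(grid, FilterParameters())
    valid = grid.valid_mask()
    is_ghost = (grid.labels == CLASS_GHOST) & valid
    removed = valid & ~keep
    recall = (is_ghost & removed).sum() / is_ghost.sum()
    kept = valid & keep
    precision = ((~is_ghost) & kept).sum() / kept.sum()
    assert recall >= 0.9
    assert precision >= 0.99


def test_setup_validation():
    with pytest.raises(ValueError):
        ScanSetup(max_range=0.0)
    with pytest.raises(ValueError):
        ScanSetup(ghost_point_rate=1.5)
    with pytest.raises(ValueError):
        ScanSetup(angular_resolution=0.0)
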